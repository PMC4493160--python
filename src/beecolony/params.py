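"""Model constants and configuration.

Every rate, day range and feedback parameter of the colony model lives in
one validated, immutable bundle (:class:`ColonyParams`).  All rates are
stored as daily survival probabilities; mortalities are converted at the
boundary (``m = 1 - S``) so a single convention holds throughout.

The three published survival presets are available by name:

========  =====================================================
preset    daily survival (egg, larvae, pupae, hive, forager)
========  =====================================================
``I``     .97, .99, .999, .985, .955
``II``    .94, .917, .985, .985, .9
``III``   1.0 everywhere (lossless reference)
========  =====================================================
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "CasteSchedule",
    "SurvivalProfile",
    "ConsumptionProfile",
    "PheromoneParams",
    "ScarcityParams",
    "SeasonParams",
    "ColonyParams",
    "SURVIVAL_PRESETS",
    "load_params",
    "survival_by_age",
]


class ParamError(ValueError):
    """A configuration value violates a model invariant."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParamError(msg)


@dataclass(frozen=True)
class CasteSchedule:
    """Days spent in each developmental caste.

    The transient model tracks one age class per day of life, so the five
    ranges must tile ages 1..55 exactly.
    """

    n_egg: int = 3
    n_larvae: int = 5
    n_pupae: int = 12
    n_hive: int = 21
    n_forager: int = 14

    def __post_init__(self) -> None:
        for name in ("n_egg", "n_larvae", "n_pupae", "n_hive", "n_forager"):
            v = getattr(self, name)
            _check(isinstance(v, int) and v > 0, f"{name} must be a positive integer, got {v!r}")

    @property
    def total_days(self) -> int:
        return self.n_egg + self.n_larvae + self.n_pupae + self.n_hive + self.n_forager

    def boundaries(self) -> tuple[int, int, int, int, int]:
        """Cumulative last day of each caste (egg, larvae, pupae, hive, forager)."""
        c1 = self.n_egg
        c2 = c1 + self.n_larvae
        c3 = c2 + self.n_pupae
        c4 = c3 + self.n_hive
        return (c1, c2, c3, c4, c4 + self.n_forager)


@dataclass(frozen=True)
class SurvivalProfile:
    """Daily survival probability within each caste, each in (0, 1]."""

    S_egg: float = 0.97
    S_larvae: float = 0.99
    S_pupae: float = 0.999
    S_hive: float = 0.985
    S_forager: float = 0.955

    def __post_init__(self) -> None:
        for name in ("S_egg", "S_larvae", "S_pupae", "S_hive", "S_forager"):
            v = getattr(self, name)
            _check(0.0 < v <= 1.0, f"{name} must lie in (0, 1], got {v!r}")

    def replace(self, **kw: float) -> "SurvivalProfile":
        return dataclasses.replace(self, **kw)

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.S_egg, self.S_larvae, self.S_pupae, self.S_hive, self.S_forager)


SURVIVAL_PRESETS: dict[str, SurvivalProfile] = {
    "I": SurvivalProfile(0.97, 0.99, 0.999, 0.985, 0.955),
    "II": SurvivalProfile(0.94, 0.917, 0.985, 0.985, 0.9),
    "III": SurvivalProfile(1.0, 1.0, 1.0, 1.0, 1.0),
}


@dataclass(frozen=True)
class ConsumptionProfile:
    """Food consumption in grams per bee per day; eggs and pupae eat nothing."""

    C_egg: float = 0.0
    C_larvae: float = 0.018
    C_pupae: float = 0.0
    C_hive: float = 0.007
    C_forager: float = 0.007

    def __post_init__(self) -> None:
        for name in ("C_egg", "C_larvae", "C_pupae", "C_hive", "C_forager"):
            _check(getattr(self, name) >= 0.0, f"{name} must be non-negative")


@dataclass(frozen=True)
class PheromoneParams:
    """Healthy caste ratios and maturation-feedback constants.

    ``RFH_healthy`` is the target hive:forager ratio maintained by ethyl
    oleate, ``RLH_healthy`` the hive:larvae ratio signalled by brood
    pheromone, and ``RLN_healthy`` the nurse:larvae ratio used for the
    nurse-shortage penalty in the transient model (half of RLH_healthy).
    ``xi`` scales how strongly a food deficit lowers the target hive:forager
    ratio; ``n_a`` is how many of the oldest hive-age classes respond to the
    pheromone acceleration, which is clamped to ``a_total_bounds``.
    """

    RFH_healthy: float = 2.3
    RLH_healthy: float = 2.0
    RLN_healthy: float = 1.0
    RFQ_healthy: float = 0.8
    xi: float = 0.5
    n_a: int = 6
    a_total_bounds: tuple[float, float] = (1.0 / 3.0, 3.0)
    a_brood_bounds: tuple[float, float] = (0.5, 2.0)
    steady_food_ratio_drop: float = 0.5

    def __post_init__(self) -> None:
        for name in ("RFH_healthy", "RLH_healthy", "RLN_healthy", "RFQ_healthy"):
            _check(getattr(self, name) > 0.0, f"{name} must be positive")
        _check(self.a_total_bounds[0] < self.a_total_bounds[1], "a_total_bounds must be ordered")
        _check(self.a_brood_bounds[0] < self.a_brood_bounds[1], "a_brood_bounds must be ordered")
        _check(self.n_a >= 1, "n_a must be at least 1")


@dataclass(frozen=True)
class ScarcityParams:
    """Food-scarcity machinery: inaccessible reserve, survival floors,
    cannibalism credit and larval weights (grams at ages 4..8)."""

    f_i: float = 100.0
    S_min_L: float = 0.2
    S_min_H: float = 0.5
    S_min_F: float = 0.67
    gamma_L: float = 0.5
    larvae_weights: tuple[float, float, float, float, float] = (
        0.0001,
        0.0006,
        0.020,
        0.080,
        0.150,
    )

    def __post_init__(self) -> None:
        for name in ("S_min_L", "S_min_H", "S_min_F"):
            v = getattr(self, name)
            _check(0.0 < v < 1.0, f"{name} must lie in (0, 1)")
        _check(0.0 <= self.gamma_L <= 1.0, "gamma_L must lie in [0, 1]")
        _check(self.f_i >= 0.0, "f_i must be non-negative")
        w = self.larvae_weights
        _check(len(w) == 5 and all(b > a for a, b in zip(w, w[1:])), "larvae_weights must be 5 strictly increasing values")


@dataclass(frozen=True)
class SeasonParams:
    """Seasonal forcing coefficients and the winter calendar.

    ``x1..x5`` parameterize the two-sigmoid annual curve s(t); ``xt4``/``xt5``
    the single-knob variant s̃(t) used in the summer-length study.  Winter
    runs from ``winter_start`` (Sep 17, day 260) through ``winter_end``
    (Mar 5, day 64) on a non-leap calendar; with ``use_summer_window`` the
    winter is instead the complement of the s̃ threshold window.
    """

    x1: float = 385.0
    x2: float = 30.0
    x3: float = 36.0
    x4: float = 155.0
    x5: float = 30.0
    xt4: float = 150.0
    xt5: float = 30.0
    onset_threshold: float = 0.15
    end_threshold: float = 0.05
    winter_start: int = 260
    winter_end: int = 64
    winter_hive_mortality: float = 0.01
    s_form: str = "max"
    use_summer_window: bool = False

    def __post_init__(self) -> None:
        _check(0.0 < self.end_threshold < self.onset_threshold < 1.0,
               "thresholds must satisfy 0 < end < onset < 1")
        _check(self.s_form in ("max", "product"), "s_form must be 'max' or 'product'")
        _check(0.0 <= self.winter_hive_mortality < 1.0, "winter_hive_mortality must lie in [0, 1)")
        _check(1 <= self.winter_start <= 365 and 1 <= self.winter_end <= 365,
               "winter day numbers must be days of year")


@dataclass(frozen=True)
class ColonyParams:
    """The complete parameter bundle for both models."""

    E0: float = 1500.0
    p: float = 0.1
    alpha: float = 0.25
    schedule: CasteSchedule = field(default_factory=CasteSchedule)
    survival: SurvivalProfile = field(default_factory=lambda: SURVIVAL_PRESETS["I"])
    consumption: ConsumptionProfile = field(default_factory=ConsumptionProfile)
    pheromone: PheromoneParams = field(default_factory=PheromoneParams)
    scarcity: ScarcityParams = field(default_factory=ScarcityParams)
    season: SeasonParams = field(default_factory=SeasonParams)
    collapse_hive_threshold: float = 1000.0

    def __post_init__(self) -> None:
        _check(self.E0 >= 0.0, "E0 must be non-negative")
        _check(self.p >= 0.0, "p must be non-negative")
        _check(0.0 < self.alpha <= 1.0, "alpha must lie in (0, 1]")
        _check(self.collapse_hive_threshold > 0.0, "collapse threshold must be positive")

    # -- convenience ----------------------------------------------------
    def replace(self, **kw: Any) -> "ColonyParams":
        return dataclasses.replace(self, **kw)

    def with_survival(self, **kw: float) -> "ColonyParams":
        return self.replace(survival=self.survival.replace(**kw))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @staticmethod
    def from_dict(d: Mapping[str, Any]) -> "ColonyParams":
        return _build(dict(d))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


_GROUPS = {
    "schedule": CasteSchedule,
    "survival": SurvivalProfile,
    "consumption": ConsumptionProfile,
    "pheromone": PheromoneParams,
    "scarcity": ScarcityParams,
    "season": SeasonParams,
}

_SCALARS = {"E0", "p", "alpha", "collapse_hive_threshold"}

# flat key -> group, for config files that use a flat key set
_FLAT: dict[str, str] = {}
for _g, _cls in _GROUPS.items():
    for _f in dataclasses.fields(_cls):
        _FLAT[_f.name] = _g


def _coerce(cls: type, raw: Mapping[str, Any]) -> Any:
    kw = {}
    for f in dataclasses.fields(cls):
        if f.name in raw:
            v = raw[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kw[f.name] = v
    return cls(**kw)


def _build(doc: dict[str, Any]) -> ColonyParams:
    groups: dict[str, dict[str, Any]] = {g: {} for g in _GROUPS}
    scalars: dict[str, Any] = {}
    preset = doc.pop("survival_preset", None)

    for key, val in doc.items():
        if key in _SCALARS:
            scalars[key] = val
        elif key in _GROUPS:
            if not isinstance(val, Mapping):
                raise ParamError(f"section {key!r} must be a mapping")
            for k2, v2 in val.items():
                if k2 not in _FLAT or _FLAT[k2] != key:
                    raise ParamError(f"unknown key {key}.{k2!r}")
                groups[key][k2] = v2
        elif key in _FLAT:
            groups[_FLAT[key]][key] = val
        else:
            raise ParamError(f"unknown configuration key {key!r}")

    if preset is not None:
        if preset not in SURVIVAL_PRESETS:
            raise ParamError(f"unknown survival preset {preset!r}; choose from {sorted(SURVIVAL_PRESETS)}")
        base = SURVIVAL_PRESETS[preset]
        merged = {f.name: getattr(base, f.name) for f in dataclasses.fields(SurvivalProfile)}
        merged.update(groups["survival"])
        groups["survival"] = merged

    parts = {g: _coerce(cls, groups[g]) for g, cls in _GROUPS.items()}
    return ColonyParams(**scalars, **parts)


def load_params(source: str | Mapping[str, Any] | io.TextIOBase | None = None) -> ColonyParams:
    """Build a :class:`ColonyParams` from a structured-text config.

    ``source`` may be ``None`` (all defaults: preset I survival, published
    day ranges and consumption rates), a YAML/JSON string, an open text
    stream, or an already-parsed mapping.  Keys may be flat (``S_hive: .99``)
    or grouped (``survival: {S_hive: .99}``); the special key
    ``survival_preset: I|II|III`` selects a published survival row.

    Raises :class:`ParamError` for unknown keys or invariant violations,
    naming the offending field.
    """
    if source is None:
        return ColonyParams()
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        text = source.read() if hasattr(source, "read") else source
        if not text.strip():
            return ColonyParams()
        doc = yaml.safe_load(text)
        if doc is None:
            return ColonyParams()
        if not isinstance(doc, dict):
            raise ParamError("config document must be a mapping")
    return _build(doc)


def survival_by_age(params: ColonyParams, i: int) -> float:
    """Daily survival for the caste containing day-of-life ``i`` (1..55
    for the default schedule): eggs 1-3, larvae 4-8, pupae 9-20, hive 21-41,
    foragers 42-55."""
    b = params.schedule.boundaries()
    if not 1 <= i <= b[-1]:
        raise ParamError(f"age {i} outside 1..{b[-1]}")
    s = params.survival
    if i <= b[0]:
        return s.S_egg
    if i <= b[1]:
        return s.S_larvae
    if i <= b[2]:
        return s.S_pupae
    if i <= b[3]:
        return s.S_hive
    return s.S_forager


def params_to_json(params: ColonyParams) -> str:
    return json.dumps(params.to_dict(), indent=2)
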