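"""Closed-form steady-state caste model with colony-level feedbacks.

With a constant egg-laying rate E0 and constant daily survival within each
caste, the long-run number of bees in a caste is a finite geometric series:
each age class holds the survivors of one day's laying, so e.g.

    E = E0 * (1 - S_egg**n_egg) / (1 - S_egg)

and each later caste is scaled by the cumulative survival of the stages
before it.  On top of this linear cascade the module layers the feedbacks
that operate on long time scales:

* a self-sustainability check — forager food income F*p must cover the
  colony's daily consumption;
* reduced larval survival when the hive:larvae ratio falls below its
  healthy value (nurse shortage), S_larvae * r**alpha;
* pheromone-driven re-allocation of adult days between the hive and forager
  castes (ethyl oleate targets the hive:forager ratio, brood pheromone the
  hive:larvae ratio); and
* cannibalism of larvae to offset a food deficit.

The composite solver iterates these to a fixed point of the total
population T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .params import (
    CasteSchedule,
    ColonyParams,
    SurvivalProfile,
    SURVIVAL_PRESETS,
)

__all__ = [
    "CasteSizes",
    "SteadyStateResult",
    "SweepPoint",
    "ModuleFlags",
    "caste_sizes",
    "caste_sizes_by_age",
    "is_self_sustaining",
    "reduced_larvae_survival",
    "adjust_hive_days",
    "cannibalized_larvae",
    "solve_steady_state",
    "mortality_sweep",
]

#: grams of food credited per cannibalized larva: mean larval weight 50 mg
#: at half nutritional value.
LARVA_FOOD_VALUE = 0.025

_CONV_TOL = 1e-6
_MAX_ITER = 200


@dataclass(frozen=True)
class CasteSizes:
    E: float
    L: float
    P: float
    H: float
    F: float

    @property
    def T(self) -> float:
        return self.E + self.L + self.P + self.H + self.F

    def shares_percent(self) -> tuple[float, float, float, float, float]:
        t = self.T
        if t == 0:
            return (0.0,) * 5
        return tuple(100.0 * x / t for x in (self.E, self.L, self.P, self.H, self.F))


def _geom(s: float, n: int) -> float:
    """Sum of s**k for k = 0..n-1, with the lossless limit n at s = 1."""
    if s == 1.0:
        return float(n)
    return (1.0 - s**n) / (1.0 - s)


def caste_sizes(
    E0: float,
    survival: SurvivalProfile,
    schedule: CasteSchedule | None = None,
) -> CasteSizes:
    """Steady-state caste sizes from the geometric-series cascade.

    Exact closed form, no iteration; the degenerate S = 1 castes evaluate to
    E0 * n (every day's cohort survives in full).
    """
    if E0 < 0:
        raise ValueError("E0 must be non-negative")
    sch = schedule or CasteSchedule()
    s = survival
    castes = [
        (s.S_egg, sch.n_egg),
        (s.S_larvae, sch.n_larvae),
        (s.S_pupae, sch.n_pupae),
        (s.S_hive, sch.n_hive),
        (s.S_forager, sch.n_forager),
    ]
    sizes = []
    cum = 1.0
    for srate, ndays in castes:
        sizes.append(E0 * cum * _geom(srate, ndays))
        cum *= srate**ndays
    return CasteSizes(*sizes)


def caste_sizes_by_age(
    E0: float,
    survival: SurvivalProfile,
    schedule: CasteSchedule | None = None,
    *,
    larvae_survival: float | None = None,
    larvae_removal_per_day: float = 0.0,
) -> CasteSizes:
    """Per-age-class evaluation of the steady state.

    Walks the 55-day chain one age at a time: age 1 holds E0 entrants, each
    later age holds the previous age times its daily survival.  Used both as
    the independent check on :func:`caste_sizes` and as the engine of the
    feedback solver, where it supports an overridden larval survival and a
    constant daily removal of larvae (cannibalism) spread uniformly over the
    larval ages.
    """
    sch = schedule or CasteSchedule()
    b = sch.boundaries()
    s_larv = survival.S_larvae if larvae_survival is None else larvae_survival
    removal = larvae_removal_per_day / sch.n_larvae if sch.n_larvae else 0.0

    sums = [0.0] * 5
    prev = E0
    for age in range(1, b[-1] + 1):
        if age <= b[0]:
            caste, s = 0, survival.S_egg
        elif age <= b[1]:
            caste, s = 1, s_larv
        elif age <= b[2]:
            caste, s = 2, survival.S_pupae
        elif age <= b[3]:
            caste, s = 3, survival.S_hive
        else:
            caste, s = 4, survival.S_forager
        if age == 1:
            count = prev
        else:
            count = prev_s * prev
        if caste == 1:
            count = max(count - removal, 0.0)
        sums[caste] += count
        prev, prev_s = count, s
    return CasteSizes(*sums)


def is_self_sustaining(
    F: float,
    L: float,
    H: float,
    p: float,
    consumption,
) -> tuple[bool, float]:
    """Whether forager income meets colony consumption, with the margin.

    Income is F*p grams/day; the need is L*C_larvae + H*C_hive + F*C_forager.
    Returns (income >= need, income - need).
    """
    income = F * p
    need = L * consumption.C_larvae + H * consumption.C_hive + F * consumption.C_forager
    margin = income - need
    return margin >= 0.0, margin


def reduced_larvae_survival(
    S_larvae: float,
    R: float,
    R_healthy: float,
    alpha: float,
) -> float:
    """Larval survival under a nurse shortage: S_larvae * r**alpha.

    r is the ratio of the actual to the healthy hive:larvae (or
    nurse:larvae) ratio, capped at 1 — surplus nurses confer no bonus.
    """
    if R_healthy <= 0:
        raise ValueError("R_healthy must be positive")
    r = min(R / R_healthy, 1.0)
    return S_larvae * r**alpha


def cannibalized_larvae(deficit: float) -> float:
    """Larvae consumed per day to offset a food deficit in grams/day."""
    if deficit < 0:
        raise ValueError("deficit must be non-negative")
    return deficit / LARVA_FOOD_VALUE


def adjust_hive_days(
    mode: str,
    params: ColonyParams,
    food_deficient: bool = False,
    *,
    larvae_survival: float | None = None,
    larvae_removal_per_day: float = 0.0,
) -> tuple[int, int]:
    """Pheromone-driven integer split of adult days between hive and forager.

    Searches every split (n_hive_eff, n_forager_eff) with both castes kept
    at >= 1 day and the total conserved, re-evaluating the steady state for
    each, and returns the split whose caste ratio lies closest to the
    pheromone's healthy target: hive:forager ~ RFH_healthy for ethyl oleate
    (lowered by ``steady_food_ratio_drop`` when food is short, recruiting
    extra foragers) or hive:larvae ~ RLH_healthy for brood pheromone.  Ties
    break toward the unmodified schedule.
    """
    if mode not in ("ethyl_oleate", "brood_pheromone"):
        raise ValueError(f"unknown pheromone mode {mode!r}")
    sch = params.schedule
    total = sch.n_hive + sch.n_forager
    if mode == "ethyl_oleate":
        target = params.pheromone.RFH_healthy
        if food_deficient:
            target -= params.pheromone.steady_food_ratio_drop
    else:
        target = params.pheromone.RLH_healthy

    best: tuple[float, int, int] | None = None
    for n_h in range(1, total):
        n_f = total - n_h
        trial = replace(sch, n_hive=n_h, n_forager=n_f)
        sizes = caste_sizes_by_age(
            params.E0,
            params.survival,
            trial,
            larvae_survival=larvae_survival,
            larvae_removal_per_day=larvae_removal_per_day,
        )
        if mode == "ethyl_oleate":
            ratio = sizes.H / sizes.F if sizes.F > 0 else math.inf
        else:
            ratio = sizes.H / sizes.L if sizes.L > 0 else math.inf
        err = abs(ratio - target)
        key = (err, abs(n_h - sch.n_hive))
        if best is None or key < (best[0], abs(best[1] - sch.n_hive)):
            best = (err, n_h, n_f)
    assert best is not None
    return best[1], best[2]


@dataclass(frozen=True)
class ModuleFlags:
    """Which steady-state feedbacks are active."""

    nurse_feedback: bool = False
    ethyl_oleate: bool = False
    brood_pheromone: bool = False
    cannibalism: bool = False

    def __post_init__(self) -> None:
        if self.ethyl_oleate and self.brood_pheromone:
            raise ValueError(
                "ethyl oleate and brood pheromone both re-allocate hive days; "
                "enable at most one in the steady model"
            )


@dataclass(frozen=True)
class SteadyStateResult:
    E: float
    L: float
    P: float
    H: float
    F: float
    T: float
    n_hive_eff: int
    n_forager_eff: int
    S_larvae_eff: float
    sustainable: bool
    sustain_margin: float
    viable: bool
    cannibalized_per_day: float
    converged: bool
    iterations: int


def _evaluate(params: ColonyParams, split: tuple[int, int], s_larv: float, cann: float) -> CasteSizes:
    sch = replace(params.schedule, n_hive=split[0], n_forager=split[1])
    return caste_sizes_by_age(
        params.E0,
        params.survival,
        sch,
        larvae_survival=s_larv,
        larvae_removal_per_day=cann,
    )


def solve_steady_state(
    params: ColonyParams,
    modules: ModuleFlags | None = None,
) -> SteadyStateResult:
    """Fixed-point solution of the steady state with feedbacks.

    Starting from the unadjusted cascade, each iteration (1) applies the
    nurse-shortage larval survival using the hive:larvae ratio, (2) re-runs
    the pheromone day-split, and (3) sets the cannibalism removal to offset
    any food deficit, until the total population changes by less than 1e-6
    relative (or 200 iterations).  Non-convergence is reported on the last
    iterate with ``converged=False`` — in practice this happens only in the
    collapsing cannibalism regime, where larvae removal and food deficit
    chase each other downward.
    """
    flags = modules or ModuleFlags()
    sch = params.schedule
    split = (sch.n_hive, sch.n_forager)
    s_larv = params.survival.S_larvae
    cann = 0.0

    sizes = _evaluate(params, split, s_larv, cann)
    T_prev = sizes.T
    converged = False
    iterations = 0

    for it in range(1, _MAX_ITER + 1):
        iterations = it
        if flags.nurse_feedback:
            R_LH = sizes.H / sizes.L if sizes.L > 0 else math.inf
            s_larv = reduced_larvae_survival(
                params.survival.S_larvae, R_LH, params.pheromone.RLH_healthy, params.alpha
            )
        sustainable, margin = is_self_sustaining(
            sizes.F, sizes.L, sizes.H, params.p, params.consumption
        )
        if flags.ethyl_oleate or flags.brood_pheromone:
            mode = "ethyl_oleate" if flags.ethyl_oleate else "brood_pheromone"
            split = adjust_hive_days(
                mode,
                params,
                food_deficient=not sustainable,
                larvae_survival=s_larv,
                larvae_removal_per_day=cann,
            )
        if flags.cannibalism:
            deficit = max(-margin, 0.0)
            cann = cannibalized_larvae(deficit)

        sizes = _evaluate(params, split, s_larv, cann)
        T_new = sizes.T
        if abs(T_new - T_prev) <= _CONV_TOL * max(abs(T_prev), 1.0):
            converged = True
            T_prev = T_new
            break
        T_prev = T_new

    sustainable, margin = is_self_sustaining(
        sizes.F, sizes.L, sizes.H, params.p, params.consumption
    )
    viable = converged and sizes.H >= params.collapse_hive_threshold
    return SteadyStateResult(
        E=sizes.E,
        L=sizes.L,
        P=sizes.P,
        H=sizes.H,
        F=sizes.F,
        T=sizes.T,
        n_hive_eff=split[0],
        n_forager_eff=split[1],
        S_larvae_eff=s_larv,
        sustainable=sustainable,
        sustain_margin=margin,
        viable=viable,
        cannibalized_per_day=cann,
        converged=converged,
        iterations=iterations,
    )


@dataclass(frozen=True)
class SweepPoint:
    caste: str
    mortality: float
    result: SteadyStateResult


_CASTE_FIELD = {
    "egg": "S_egg",
    "larvae": "S_larvae",
    "pupae": "S_pupae",
    "hive": "S_hive",
    "forager": "S_forager",
}


def mortality_sweep(
    params: ColonyParams,
    caste: str,
    mortality_grid: Sequence[float] | Iterable[float],
    modules: ModuleFlags | None = None,
) -> tuple[list[SweepPoint], float | None, float | None]:
    """Raise one caste's daily mortality across a grid and solve each point.

    Returns the sweep points plus the first mortality at which the colony is
    no longer viable (hive below the collapse threshold) and the first at
    which it is no longer food self-sustaining.
    """
    if caste not in _CASTE_FIELD:
        raise ValueError(f"unknown caste {caste!r}; choose from {sorted(_CASTE_FIELD)}")
    grid = list(mortality_grid)
    if any(not 0.0 <= m < 1.0 for m in grid):
        raise ValueError("mortalities must lie in [0, 1)")
    if grid != sorted(grid):
        raise ValueError("mortality grid must be sorted ascending")

    points: list[SweepPoint] = []
    first_collapse = None
    first_unsustainable = None
    for m in grid:
        p2 = params.with_survival(**{_CASTE_FIELD[caste]: 1.0 - m})
        res = solve_steady_state(p2, modules)
        points.append(SweepPoint(caste, m, res))
        if first_collapse is None and not res.viable:
            first_collapse = m
        if first_unsustainable is None and not res.sustainable:
            first_unsustainable = m
    return points, first_collapse, first_unsustainable
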