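"""Seasonal forcing and the winter calendar.

Two annual multipliers modulate the queen's egg laying and the foraging
rate:

* ``s_egg`` — the two-sigmoid curve s(t) with a spring rise (x1, x2) and an
  autumn fall (x3, x4, x5); near zero in mid-winter, ≈0.98 near day 150.
* ``s_tilde`` — a single-knob variant s̃(t) whose width parameter x̃5
  stretches or shrinks the productive season symmetrically about day 150,
  where it attains its global maximum 36/37 ≈ 0.973.

Day-of-year convention: t = 1 is January 1 on a non-leap calendar;
multi-year times are folded with ``t mod 365`` (day 0 maps to 365) so the
annual cycle repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import SeasonParams

__all__ = ["SummerWindow", "s_egg", "s_tilde", "summer_window", "is_winter"]

#: s̃ values are compared against thresholds at the precision they are
#: reported (three decimals); the printed integer-day windows are recovered
#: exactly under this convention.
_THRESHOLD_DECIMALS = 3


def _fold(t: float) -> float:
    d = t % 365.0
    return 365.0 if d == 0.0 else d


@dataclass(frozen=True)
class SummerWindow:
    """First and last day of year on which s̃ clears its thresholds."""

    onset_day: int
    end_day: int

    def __post_init__(self) -> None:
        if not (1 <= self.onset_day < self.end_day <= 365):
            raise ValueError(f"invalid summer window ({self.onset_day}, {self.end_day})")

    def contains(self, t: float) -> bool:
        return self.onset_day <= _fold(t) <= self.end_day


def s_egg(t: float, season: SeasonParams | None = None) -> float:
    """Annual multiplier s(t) in [0, 1] applied to egg laying and foraging.

    The default form combines the spring and autumn sigmoids with a max;
    ``season.s_form = "product"`` selects the alternative product reading.
    """
    season = season or SeasonParams()
    td = _fold(t)
    spring = 1.0 - 1.0 / (1.0 + season.x1 * math.exp(-2.0 * td / season.x2))
    autumn = 1.0 / (1.0 + season.x3 * math.exp(-2.0 * (td - season.x4) / season.x5))
    if season.s_form == "max":
        s = 1.0 - max(spring, autumn)
    else:
        s = 1.0 - spring - autumn  # product-form reading: both depressions act
    return min(max(s, 0.0), 1.0)


def s_tilde(t: float, season: SeasonParams | None = None) -> float:
    """Single-parameter seasonal multiplier s̃(t) in [0, 1].

    Spring branch (t < 150) widens the sigmoid by 5 days relative to the
    autumn branch; the two branches agree at t = 150 where
    s̃ = 1 - 1/(1 + x3) = 36/37 for the default x3.
    """
    season = season or SeasonParams()
    td = _fold(t)
    if td < 150.0:
        val = 1.0 - 1.0 / (1.0 + season.x3 * math.exp(2.0 * (td - season.xt4) / (season.xt5 + 5.0)))
    else:
        val = 1.0 - 1.0 / (1.0 + season.x3 * math.exp(-2.0 * (td - season.xt4) / season.xt5))
    return min(max(val, 0.0), 1.0)


def summer_window(season: SeasonParams | None = None) -> SummerWindow:
    """Integer-day productive season under the s̃ thresholds.

    Onset is the first day of year with s̃ ≥ ``onset_threshold`` (default
    .15), the end the last day with s̃ ≥ ``end_threshold`` (default .05);
    values are compared at 3-decimal precision.
    """
    season = season or SeasonParams()
    onset = None
    end = None
    for day in range(1, 366):
        v = round(s_tilde(day, season), _THRESHOLD_DECIMALS)
        if onset is None and v >= season.onset_threshold:
            onset = day
        if v >= season.end_threshold:
            end = day
    if onset is None or end is None or end <= onset:
        raise ValueError("seasonal thresholds never reached; no summer window exists")
    return SummerWindow(onset, end)


def is_winter(t: float, season: SeasonParams | None = None) -> bool:
    """Whether day ``t`` falls in the winter phase.

    By default winter is the calendar window Sep 17 (day 260) through Mar 5
    (day 64).  With ``season.use_summer_window`` winter is instead the
    complement of the s̃ threshold window, as in the summer-length study.
    """
    season = season or SeasonParams()
    d = _fold(t)
    if season.use_summer_window:
        w = summer_window(season)
        return not (w.onset_day <= d <= w.end_day)
    return d >= season.winter_start or d <= season.winter_end
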