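"""Transient 55-age-class colony model.

One ordinary differential equation per day of a bee's life,

    dB_i/dt = a_{i-1} S_{i-1} B_{i-1} - a_i B_i ,      B_0 = s(t) E0,

integrated with the explicit Euler method.  The aging-rate multipliers a_i
(pheromone control of hive-bee maturation) act on the oldest hive-age
classes only and carry the aged flux with them, so bees accelerated out of
one class arrive in the next; with a_i = 1 everywhere the scheme reduces to
the plain cascade that the analytic oracle solves.  Per-age survival is the
caste base rate, modified multiplicatively by the nurse-shortage factor
r**alpha (larvae), and by the food-scarcity factors S_L/S_H/S_F.

Food stores evolve as

    df/dt = s(t) f_Q p F + gamma_L * sum_i w_i d_i - f_d ,

income from foragers (cut by the processing-caste factor f_Q), a cannibalism
credit from larvae dying during a deficit, minus the colony's consumption.

Winter (September 17 - March 5 by default): the queen stops laying, the
pheromone terms switch off, and the adult population forms a dormant
cluster — hive bees and foragers stop aging and die at the reduced winter
rate (default 1%/day).  Brood already in the pipeline keeps developing and
newly emerged adults join the (frozen) youngest hive class.  Clustered hive
bees do not draw on the tracked food store; foragers and larvae do.  See the
methods note for the evidence behind this winter treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .params import ColonyParams
from .season import is_winter, s_egg, s_tilde

__all__ = [
    "ColonyState",
    "CasteCounts",
    "ScarcityFactors",
    "StepDiagnostics",
    "SimToggles",
    "Trajectory",
    "SimulationError",
    "aggregate",
    "nurse_factor",
    "processing_factor",
    "scarcity",
    "acceleration",
    "step",
    "simulate",
    "initial_state",
]

_N_AGES = 55
# age-range slices (0-based, half-open): ages 1-3, 4-8, 9-20, 21-30, 31-41, 21-41, 42-55
_EGG = slice(0, 3)
_LARVAE = slice(3, 8)
_PUPAE = slice(8, 20)
_NURSE = slice(20, 30)
_PROC = slice(30, 41)
_HIVE = slice(20, 41)
_FORAGER = slice(41, 55)

_DIVERGE_LIMIT = 1e12


class SimulationError(RuntimeError):
    """The integration produced a non-finite state."""


@dataclass
class ColonyState:
    """Simulation state: clock (days since Jan 1 of year 1), the 55
    age-class abundances, and the food store in grams."""

    t: float
    B: np.ndarray
    f: float

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape != (_N_AGES,):
            raise ValueError(f"B must have {_N_AGES} age classes, got {self.B.shape}")
        if self.f < 0:
            raise ValueError("food store must be non-negative")

    def copy(self) -> "ColonyState":
        return ColonyState(self.t, self.B.copy(), self.f)


@dataclass(frozen=True)
class CasteCounts:
    E: float
    L: float
    P: float
    N: float
    Q: float
    H: float
    F: float

    @property
    def adults(self) -> float:
        return self.H + self.F

    @property
    def brood(self) -> float:
        return self.E + self.L + self.P

    @property
    def total(self) -> float:
        return self.brood + self.adults


def aggregate(B: np.ndarray) -> CasteCounts:
    """Caste head-counts from the age vector (eggs 1-3, larvae 4-8, pupae
    9-20, nurses 21-30, processors 31-41, hive = nurses + processors,
    foragers 42-55)."""
    B = np.asarray(B, dtype=float)
    if B.shape != (_N_AGES,):
        raise ValueError(f"expected {_N_AGES} age classes, got {B.shape}")
    N = float(B[_NURSE].sum())
    Q = float(B[_PROC].sum())
    return CasteCounts(
        E=float(B[_EGG].sum()),
        L=float(B[_LARVAE].sum()),
        P=float(B[_PUPAE].sum()),
        N=N,
        Q=Q,
        H=N + Q,
        F=float(B[_FORAGER].sum()),
    )


def nurse_factor(N: float, L: float, RLN_healthy: float, alpha: float) -> float:
    """Larval survival multiplier r**alpha from the nurse:larvae ratio.

    r = min(N / (L * RLN_healthy), 1); with no larvae there is nothing to
    nurse and the factor is 1.
    """
    if L <= 0:
        return 1.0
    r = min(max(N / (L * RLN_healthy), 0.0), 1.0)
    return r**alpha


def processing_factor(Q: float, F: float, RFQ_healthy: float) -> float:
    """Foraging-rate multiplier f_Q from the processor:forager ratio.

    Foragers can only collect what the processing caste can receive and
    store: f_Q = min(R_FQ / RFQ_healthy, 1), and 1 with no foragers.
    """
    if F <= 0:
        return 1.0
    return min(max(Q / (F * RFQ_healthy), 0.0), 1.0)


@dataclass(frozen=True)
class ScarcityFactors:
    """Food-deficit outputs for one step (all per day)."""

    f_a: float
    f_L: float
    f_H: float
    f_F: float
    f_d: float
    D: float
    S_L: float
    S_H: float
    S_F: float
    d: np.ndarray
    gamma_L_active: float


def scarcity(
    state: ColonyState,
    counts: CasteCounts,
    params: ColonyParams,
    *,
    larvae_survival_factor: float = 1.0,
    hive_consumes: bool = True,
) -> ScarcityFactors:
    """Evaluate the food budget and the scarcity survival factors.

    Only stores above the inaccessible reserve f_i are available:
    f_a = max(f - f_i, 0).  When the daily requirement f_d exceeds f_a the
    deficit D > 0 triggers reduced survival, allocated so hive and forager
    bees feed first:

    1. f_H + f_F <= f_a < f_d — adults are fed, larvae share the remainder:
       S_L = max((f_a - f_H - f_F)/f_L, S_min_L), S_H = S_F = 1;
    2. 0 < f_a < f_H + f_F — larvae at the floor, adults share f_a:
       S_H = max(f_a/(f_H+f_F), S_min_H), S_F likewise with its floor;
    3. f_a = 0 — every factor at its floor.

    ``d`` holds the larvae deaths per day in ages 4..8 (all deaths during a
    deficit are available for cannibalism), and ``gamma_L_active`` the
    nutritional credit factor (gamma_L during a deficit, else 0).
    ``hive_consumes=False`` drops the hive caste from the requirement (the
    dormant winter cluster).
    """
    sc = params.scarcity
    cons = params.consumption
    f_a = max(state.f - sc.f_i, 0.0)
    f_L = counts.L * cons.C_larvae
    f_H = counts.H * cons.C_hive if hive_consumes else 0.0
    f_F = counts.F * cons.C_forager
    f_d = f_L + f_H + f_F
    D = max(f_d - f_a, 0.0)

    S_L = S_H = S_F = 1.0
    gamma = 0.0
    d = np.zeros(5)
    if D > 0.0:
        gamma = sc.gamma_L
        adult_need = f_H + f_F
        if adult_need <= f_a:
            S_L = max((f_a - adult_need) / f_L, sc.S_min_L) if f_L > 0 else 1.0
        elif f_a > 0.0:
            S_L = sc.S_min_L
            S_H = max(f_a / adult_need, sc.S_min_H)
            S_F = max(f_a / adult_need, sc.S_min_F)
        else:
            S_L, S_H, S_F = sc.S_min_L, sc.S_min_H, sc.S_min_F
        s_base = params.survival.S_larvae * larvae_survival_factor * S_L
        d = state.B[_LARVAE] * (1.0 - s_base)
    return ScarcityFactors(f_a, f_L, f_H, f_F, f_d, D, S_L, S_H, S_F, d, gamma)


def acceleration(
    counts: CasteCounts,
    D: float,
    f_d: float,
    params: ColonyParams,
    winter: bool = False,
) -> np.ndarray:
    """Pheromone aging multipliers a_i for all 55 classes (1 outside the
    responsive window).

    Ethyl oleate steers the hive:forager ratio toward a food-modified target
    R_mod = RFH_healthy - xi*D/f_d (scarcity recruits foragers early):
    a^e = clamp(1 + (R_FH - R_mod)/R_mod, 1/3, 3).  Brood pheromone steers
    hive:larvae with half weight: a^b = clamp(1 + .5*(R_LH - RLH_healthy)/
    RLH_healthy, 1/2, 2).  The product, clamped to [1/3, 3], applies to ages
    41-n_a .. 41; in winter every a_i is 1.  Missing castes (F = 0 or L = 0)
    read as an infinite ratio, i.e. maximal acceleration — no pheromone
    source means no brake on maturation.
    """
    a = np.ones(_N_AGES)
    if winter:
        return a
    ph = params.pheromone
    lo, hi = ph.a_total_bounds
    blo, bhi = ph.a_brood_bounds

    ratio_drop = ph.xi * (D / f_d) if f_d > 0 else 0.0
    R_mod = ph.RFH_healthy - ratio_drop
    R_FH = counts.H / counts.F if counts.F > 0 else math.inf
    h_e = (R_FH - R_mod) / R_mod
    a_e = min(max(1.0 + h_e, lo), hi)

    R_LH = counts.H / counts.L if counts.L > 0 else math.inf
    h_b = (R_LH - ph.RLH_healthy) / ph.RLH_healthy
    a_b = min(max(1.0 + 0.5 * h_b, blo), bhi)

    a_val = min(max(a_e * a_b, lo), hi)
    n_hive_last = params.schedule.n_egg + params.schedule.n_larvae + params.schedule.n_pupae + params.schedule.n_hive
    first = n_hive_last - ph.n_a  # age 41 - n_a, 1-based
    a[first - 1 : n_hive_last] = a_val
    return a


@dataclass(frozen=True)
class SimToggles:
    """Feedback switches for the transient model.

    ``pheromones`` drives the aging multipliers (both pheromones act
    together in the transient model); ``seasonal`` applies s(t) to laying
    and foraging (off means s = 1); ``winter`` enables the winter phase;
    ``season_fn`` picks the annual curve ("s" or "s_tilde").
    """

    pheromones: bool = True
    cannibalism: bool = True
    nurse_feedback: bool = True
    processing_feedback: bool = True
    scarcity: bool = True
    seasonal: bool = True
    winter: bool = True
    season_fn: str = "s"

    @staticmethod
    def all_off() -> "SimToggles":
        return SimToggles(False, False, False, False, False, False, False)


@dataclass(frozen=True)
class StepDiagnostics:
    r_alpha: float
    a: np.ndarray
    f_Q: float
    s_t: float
    winter: bool
    scarcity: ScarcityFactors


def _season_value(t: float, params: ColonyParams, toggles: SimToggles) -> float:
    if not toggles.seasonal:
        return 1.0
    fn: Callable[[float], float] = s_egg if toggles.season_fn == "s" else s_tilde
    return fn(t, params.season)


def step(
    state: ColonyState,
    params: ColonyParams,
    dt: float,
    toggles: SimToggles | None = None,
) -> tuple[ColonyState, StepDiagnostics]:
    """One explicit Euler step of length ``dt`` days.

    Every factor (season, winter flag, f_Q, scarcity, nurse factor,
    acceleration) is evaluated from the pre-step state and applied
    simultaneously — the scheme is fully explicit and first-order.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tg = toggles or SimToggles()
    B = state.B
    counts = aggregate(B)
    t = state.t

    s_t = _season_value(t, params, tg)
    winter = tg.winter and is_winter(t, params.season)

    f_Q = (
        processing_factor(counts.Q, counts.F, params.pheromone.RFQ_healthy)
        if tg.processing_feedback
        else 1.0
    )
    r_alpha = (
        nurse_factor(counts.N, counts.L, params.pheromone.RLN_healthy, params.alpha)
        if tg.nurse_feedback
        else 1.0
    )
    if tg.scarcity:
        sc = scarcity(
            state,
            counts,
            params,
            larvae_survival_factor=r_alpha,
            hive_consumes=not winter,
        )
    else:
        f_L = counts.L * params.consumption.C_larvae
        f_H = counts.H * params.consumption.C_hive if not winter else 0.0
        f_F = counts.F * params.consumption.C_forager
        sc = ScarcityFactors(
            max(state.f - params.scarcity.f_i, 0.0),
            f_L, f_H, f_F, f_L + f_H + f_F,
            0.0, 1.0, 1.0, 1.0, np.zeros(5), 0.0,
        )

    if tg.pheromones:
        a = acceleration(counts, sc.D, sc.f_d, params, winter)
    else:
        a = np.ones(_N_AGES)

    # effective per-age survival from the pre-step state
    S = np.empty(_N_AGES)
    sv = params.survival
    S[_EGG] = sv.S_egg
    S[_LARVAE] = sv.S_larvae * r_alpha * sc.S_L
    S[_PUPAE] = sv.S_pupae
    S[_HIVE] = sv.S_hive * sc.S_H
    S[_FORAGER] = sv.S_forager * sc.S_F

    B0 = 0.0 if winter else s_t * params.E0

    inflow = np.empty(_N_AGES)
    inflow[0] = B0  # a_0 = S_0 = 1
    inflow[1:] = a[:-1] * S[:-1] * B[:-1]
    dB = inflow - a * B

    if winter:
        # dormant cluster: adults stop aging and die at the winter rate;
        # newly emerged adults still join the youngest hive class
        wm = params.season.winter_hive_mortality
        dB[_HIVE] = -wm * B[_HIVE]
        dB[20] += inflow[20]
        dB[_FORAGER] = -wm * B[_FORAGER]

    income = 0.0 if winter else s_t * f_Q * params.p * counts.F
    recycle = sc.gamma_L_active * float(np.dot(params.scarcity.larvae_weights, sc.d)) if tg.cannibalism else 0.0

    B_new = B + dt * dB
    f_new = max(state.f + dt * (income + recycle - sc.f_d), 0.0)

    diag = StepDiagnostics(r_alpha=r_alpha, a=a, f_Q=f_Q, s_t=s_t, winter=winter, scarcity=sc)
    return ColonyState(t + dt, B_new, f_new), diag


@dataclass
class Trajectory:
    """Time-ordered record of one simulation."""

    rows: list[dict] = field(default_factory=list)
    collapse_day: float | None = None
    diverged: bool = False
    final_state: ColonyState | None = None
    min_age_class: float = 0.0  # most negative abundance seen (0 if none)

    def append(self, t: float, counts: CasteCounts, f: float, diag: StepDiagnostics) -> None:
        self.rows.append(
            {
                "t": t,
                "E": counts.E,
                "L": counts.L,
                "P": counts.P,
                "N": counts.N,
                "Q": counts.Q,
                "H": counts.H,
                "F": counts.F,
                "adults": counts.adults,
                "brood": counts.brood,
                "food_g": f,
                "r_alpha": diag.r_alpha,
                "a_i": float(diag.a[40]),  # age 41, always inside the responsive window
                "f_Q": diag.f_Q,
                "s_t": diag.s_t,
                "D": diag.scarcity.D,
                "winter": diag.winter,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    @property
    def peak_adults(self) -> float:
        return max(r["adults"] for r in self.rows)

    @property
    def peak_brood(self) -> float:
        return max(r["brood"] for r in self.rows)

    @property
    def max_deficit(self) -> float:
        return max(r["D"] for r in self.rows)

    @property
    def final_adults(self) -> float:
        return self.rows[-1]["adults"]


def simulate(
    initial: ColonyState,
    params: ColonyParams,
    t_end: float,
    dt: float,
    toggles: SimToggles | None = None,
    record_every: int = 1,
) -> Trajectory:
    """Integrate from ``initial.t`` to ``t_end`` with step ``dt``.

    Records one row per ``record_every`` steps (plus the final step) and the
    first time the adult population drops below the collapse threshold.  A
    non-finite or runaway state (unstable time step) stops the run with
    ``diverged=True`` instead of raising, so stability studies can inspect
    the partial trajectory.
    """
    if t_end <= initial.t:
        raise ValueError("t_end must exceed the initial time")
    tg = toggles or SimToggles()
    n_steps = int(round((t_end - initial.t) / dt))
    traj = Trajectory()
    state = initial.copy()

    for k in range(n_steps):
        new_state, diag = step(state, params, dt, tg)
        counts = aggregate(state.B)
        if traj.collapse_day is None and counts.adults < params.collapse_hive_threshold:
            traj.collapse_day = state.t
        if k % record_every == 0 or k == n_steps - 1:
            traj.append(state.t, counts, state.f, diag)
        traj.min_age_class = min(traj.min_age_class, float(new_state.B.min()))
        if not np.isfinite(new_state.B).all() or np.abs(new_state.B).max() > _DIVERGE_LIMIT:
            traj.diverged = True
            traj.final_state = new_state
            return traj
        state = new_state

    traj.final_state = state
    counts = aggregate(state.B)
    if traj.collapse_day is None and counts.adults < params.collapse_hive_threshold:
        traj.collapse_day = state.t
    return traj


def initial_state(
    n_hive_bees: float,
    n_foragers: float = 0.0,
    food: float = 2000.0,
    t0: float = 60.0,
) -> ColonyState:
    """A fresh colony: hive bees spread uniformly over ages 21-41, foragers
    over 42-55, no brood."""
    if n_hive_bees < 0 or n_foragers < 0:
        raise ValueError("bee counts must be non-negative")
    B = np.zeros(_N_AGES)
    B[_HIVE] = n_hive_bees / 21.0
    if n_foragers:
        B[_FORAGER] = n_foragers / 14.0
    return ColonyState(t=t0, B=B, f=food)
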