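"""Declarative reproduction of the published experiments.

Each ``run_*`` function builds its scenario from the parameter bundle,
executes the model, and returns plain DataFrames; the CLI writes them as CSV
with a full parameter echo alongside for provenance.  Everything here is
deterministic — the model has no stochastic terms — so re-running a spec
yields identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .params import ColonyParams, SURVIVAL_PRESETS
from .season import s_tilde, summer_window
from .steady import ModuleFlags, caste_sizes, mortality_sweep, solve_steady_state
from .transient import SimToggles, Trajectory, initial_state, simulate

__all__ = [
    "run_table4",
    "run_convergence",
    "run_sensitivity",
    "run_three_year",
    "run_mortality_sweep",
    "fig8_scenario",
    "forage_scenario",
    "write_experiment",
]

#: transient scenarios use the seasonal egg-laying amplitude of 1600/day
TRANSIENT_E0 = 1600.0
DT_DEFAULT = 0.1  # 2.4 hours


def run_table4(E0: float = 1500.0, presets: Sequence[str] = ("I", "II", "III")) -> pd.DataFrame:
    """Steady-state caste percentages and totals for the survival presets."""
    rows = []
    for name in presets:
        sizes = caste_sizes(E0, SURVIVAL_PRESETS[name])
        e, l, p, h, f = sizes.shares_percent()
        rows.append(
            {
                "preset": name,
                "E_pct": round(e, 1),
                "L_pct": round(l, 1),
                "P_pct": round(p, 1),
                "H_pct": round(h, 1),
                "F_pct": round(f, 1),
                "T": int(round(sizes.T, -3)),
                "T_exact": sizes.T,
            }
        )
    return pd.DataFrame(rows)


def fig8_scenario(params: ColonyParams | None = None) -> tuple[ColonyParams, SimToggles]:
    """The 200-day reference run: 8000 hive bees and 2 kg of food on March 1
    (day 60), seasonal laying at 1600 s(t)."""
    base = params or ColonyParams()
    return base.replace(E0=TRANSIENT_E0), SimToggles()


def convergence_scenario(params: ColonyParams | None = None) -> tuple[ColonyParams, SimToggles]:
    """The time-step study: 150 days from January 1 with 8000 hive bees and
    seasonal laying, before any winter special-casing enters the model."""
    base = params or ColonyParams()
    return base.replace(E0=TRANSIENT_E0), SimToggles(winter=False)


def run_convergence(
    dt_hours: Sequence[float] = (16.8, 12.0, 6.0, 2.4),
    days: float = 150.0,
    reference_dt_hours: float = 2.4,
) -> pd.DataFrame:
    """Stability and time-step refinement on the 150-day seasonal scenario.

    A run is flagged unstable if it diverges, if any abundance leaves the
    physical domain (an age class or the adult total more than one bee
    negative — the explicit scheme preserves positivity only for stable time
    steps), or if its peak exceeds 10x the reference peak.  Stable runs
    report the sup-norm deviation of the adult-population curve from the
    reference run, compared on the coarse run's own time grid and normalized
    by the reference peak.
    """
    params, toggles = convergence_scenario()

    def run(dth: float) -> Trajectory:
        st = initial_state(8000, 0, 2000, t0=1.0)
        return simulate(st, params, 1.0 + days, dth / 24.0, toggles)

    ref = run(reference_dt_hours)
    ref_df = ref.to_frame()
    ref_peak = ref_df["adults"].max()

    rows = []
    for dth in dt_hours:
        traj = run(dth)
        df = traj.to_frame()
        adults = df["adults"].to_numpy()
        unstable = (
            traj.diverged
            or traj.min_age_class < -1.0
            or bool((adults < -1.0).any())
            or bool(adults.max() > 10 * ref_peak)
        )
        sup = np.nan
        if not unstable:
            interp = np.interp(df["t"], ref_df["t"], ref_df["adults"])
            denom = max(float(np.abs(interp).max()), 1.0)
            sup = float(np.abs(adults - interp).max()) / denom
        rows.append(
            {
                "dt_hours": dth,
                "unstable": unstable,
                "sup_norm_vs_ref": sup,
                "peak_adults": float(adults.max()),
                "min_age_class": traj.min_age_class,
            }
        )
    return pd.DataFrame(rows)


def run_mortality_sweep(
    caste: str,
    grid: Sequence[float],
    modules: ModuleFlags | None = None,
    params: ColonyParams | None = None,
) -> pd.DataFrame:
    """Steady-state sweep of one caste's mortality (the Fig 2-5 studies)."""
    base = params or ColonyParams()
    points, first_collapse, first_unsustainable = mortality_sweep(
        base, caste, grid, modules or ModuleFlags(nurse_feedback=True, ethyl_oleate=True)
    )
    df = pd.DataFrame(
        {
            "caste": pt.caste,
            "mortality": pt.mortality,
            "E": pt.result.E,
            "L": pt.result.L,
            "P": pt.result.P,
            "H": pt.result.H,
            "F": pt.result.F,
            "T": pt.result.T,
            "viable": pt.result.viable,
            "sustainable": pt.result.sustainable,
        }
        for pt in points
    )
    df.attrs["first_collapse_mortality"] = first_collapse
    df.attrs["first_unsustainable_mortality"] = first_unsustainable
    return df


def forage_scenario(p: float, params: ColonyParams | None = None) -> tuple:
    """The foraging-rate stress test: day 210, 10,400 hive bees, 5,600
    foragers, 2 kg of food."""
    base = params or ColonyParams()
    return (
        initial_state(10400, 5600, 2000, t0=210.0),
        base.replace(E0=TRANSIENT_E0, p=p),
    )


def _summary_row(label: str, traj: Trajectory) -> dict:
    return {
        "scenario": label,
        "peak_adults": traj.peak_adults,
        "peak_brood": traj.peak_brood,
        "collapse_day": traj.collapse_day,
        "final_adults": traj.final_adults,
        "final_food_g": traj.rows[-1]["food_g"],
        "max_food_deficit": traj.max_deficit,
        "survived": traj.final_adults >= 1000.0 and not traj.diverged,
    }


def run_sensitivity(
    study: str,
    grid: Sequence | None = None,
    dt: float = DT_DEFAULT,
    record_every: int = 10,
) -> pd.DataFrame:
    """One of the published sensitivity studies.

    ``alpha`` and ``rfh_healthy`` run one year from day 60 with 8000 hive
    bees; ``summer_length`` uses the single-knob season with the threshold
    winter; ``forage_rate`` and ``pheromone_cannibalism`` run the day-210
    food-stress scenario for 500 days.
    """
    base = ColonyParams(E0=TRANSIENT_E0)
    rows = []

    if study == "alpha":
        for a in grid or (0.25, 0.4, 1.0):
            st = initial_state(8000, 0, 2000, t0=60.0)
            traj = simulate(st, base.replace(alpha=a), 60.0 + 365.0, dt, SimToggles(), record_every)
            rows.append({"alpha": a, **_summary_row(f"alpha={a}", traj)})
    elif study == "rfh_healthy":
        for r in grid or (1.5, 2.3, 3.0):
            p2 = base.replace(pheromone=dataclasses.replace(base.pheromone, RFH_healthy=r))
            st = initial_state(8000, 0, 2000, t0=60.0)
            traj = simulate(st, p2, 60.0 + 365.0, dt, SimToggles(), record_every)
            rows.append({"RFH_healthy": r, **_summary_row(f"RFH={r}", traj)})
    elif study == "summer_length":
        for xt5 in grid or (35.0, 30.0, 20.0):
            p2 = base.replace(
                season=dataclasses.replace(base.season, xt5=xt5, use_summer_window=True)
            )
            w = summer_window(p2.season)
            st = initial_state(8000, 0, 2000, t0=60.0)
            traj = simulate(
                st, p2, 60.0 + 365.0, dt, SimToggles(season_fn="s_tilde"), record_every
            )
            rows.append(
                {
                    "xt5": xt5,
                    "summer_onset": w.onset_day,
                    "summer_end": w.end_day,
                    **_summary_row(f"xt5={xt5}", traj),
                }
            )
    elif study == "forage_rate":
        for p in grid or (0.02, 0.04, 0.055, 0.06):
            st, p2 = forage_scenario(p)
            traj = simulate(st, p2, 210.0 + 500.0, dt, SimToggles(), record_every)
            rows.append({"p": p, **_summary_row(f"p={p}", traj)})
    elif study == "pheromone_cannibalism":
        combos = grid or (
            ("pheromones+cannibalism", True, True),
            ("no_pheromones", False, True),
            ("no_cannibalism", True, False),
        )
        for label, pher, cann in combos:
            st, p2 = forage_scenario(0.055)
            tg = SimToggles(pheromones=pher, cannibalism=cann)
            traj = simulate(st, p2, 210.0 + 500.0, dt, tg, record_every)
            rows.append({"modules": label, **_summary_row(label, traj)})
    else:
        raise ValueError(f"unknown sensitivity study {study!r}")
    return pd.DataFrame(rows)


@dataclass
class ThreeYearReport:
    trajectory: pd.DataFrame
    annual: pd.DataFrame
    scarcity_deficit_days: int
    collapse_day: float | None


def run_three_year(
    params: ColonyParams | None = None,
    dt: float = DT_DEFAULT,
    record_every: int = 10,
) -> ThreeYearReport:
    """Three annual cycles from day 60 with the winter rules active.

    Reports the trajectory, per-year adult/brood peaks and food range, and
    the number of recorded steps in food deficit (expected zero with the
    default 2 kg of starting stores).
    """
    base = (params or ColonyParams()).replace(E0=TRANSIENT_E0)
    t0 = 60.0
    st = initial_state(8000, 0, 2000, t0=t0)
    traj = simulate(st, base, t0 + 3 * 365.0, dt, SimToggles(), record_every)
    df = traj.to_frame()
    df["year"] = np.minimum((df["t"] - t0) // 365, 2).astype(int) + 1
    annual = (
        df.groupby("year")
        .agg(
            peak_adults=("adults", "max"),
            peak_brood=("brood", "max"),
            min_food_g=("food_g", "min"),
            max_food_g=("food_g", "max"),
        )
        .reset_index()
    )
    deficit_days = int((df["D"] > 0).sum())
    return ThreeYearReport(df, annual, deficit_days, traj.collapse_day)


def write_experiment(df: pd.DataFrame, out: Path | str, params: ColonyParams | None = None) -> None:
    """Write an experiment CSV plus the resolved parameter echo beside it."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False)
    echo = out.with_suffix(out.suffix + ".params.yaml")
    echo.write_text((params or ColonyParams()).to_yaml())
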