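# Methods

This note documents the model as implemented: its assumptions, parameters,
numerical scheme, the design choices made where the formulation was
genuinely open, and what the package's tests do and do not establish.

## 1. State and castes

A worker bee's caste is a deterministic function of its age in days:

| ages  | caste      | daily survival (preset I) | consumption g/(bee·day) |
|-------|------------|---------------------------|-------------------------|
| 1–3   | egg        | 0.97                      | 0                       |
| 4–8   | larva      | 0.99                      | 0.018                   |
| 9–20  | pupa       | 0.999                     | 0                       |
| 21–30 | nurse      | 0.985                     | 0.007                   |
| 31–41 | processor  | 0.985                     | 0.007                   |
| 42–55 | forager    | 0.955                     | 0.007                   |

Nurses and processors together form the hive caste. Survival preset II
(0.94/0.917/0.985/0.985/0.9) is an alternative field-derived set; preset
III (all 1.0) is the lossless reference in which each caste's steady size
is exactly `E0 × days`. Drones are not modelled separately; they are lumped
with hive bees. The transient state is the 55-vector of age-class
abundances `B_1..B_55` (real-valued), the food store `f` in grams, and the
clock `t` in days (t = 1 is January 1; seasonal functions fold `t mod 365`,
so multi-year runs repeat the annual cycle on a non-leap calendar).

## 2. Steady-state model

The closed form is the geometric-series cascade (module `steady`). Feedback
solving iterates three maps to a fixed point of the total population `T`
(relative tolerance 1e-6, cap 200 iterations): nurse-shortage larval
survival using the hive:larvae ratio, the pheromone day-split, and the
cannibalism removal that offsets any food deficit. Choices:

* **Integer day-splits.** The pheromone re-allocation searches every
  integer split of the 35 adult days with both castes kept at ≥ 1 day,
  re-evaluating the steady state per trial and minimizing the distance of
  the resulting caste ratio from its healthy target (2.3 for hive:forager
  under ethyl oleate, lowered by 0.5 when the colony is not
  self-sustaining; 2.0 for hive:larvae under brood pheromone). Ties break
  toward the unmodified schedule. The two pheromones are mutually exclusive
  here since both re-allocate the same days.
* **Cannibalism bookkeeping.** The deficit in grams/day divided by 0.025 g
  (50 mg mean larval weight at half nutritional value) gives larvae removed
  per day, spread uniformly over the five larval ages inside a per-age
  re-evaluation of the cascade. The removal–deficit loop can fail to
  converge in the collapsing regime; the solver then reports the last
  iterate with `converged=False`, treated as collapse.
* **No survival bonus.** The nurse ratio factor `r` is capped at 1; surplus
  nurses never raise larval survival above its base rate.

## 3. Transient model

### Aging flux

The per-age equation is `dB_i/dt = a_{i−1} S_{i−1} B_{i−1} − a_i B_i` with
`S_0 = a_0 = 1` and influx `B_0 = s(t)·E0`. The multiplier `a_i` differs
from 1 only on ages 35–41, where the pheromone control acts, and the flux
leaving one class under acceleration is exactly the flux entering the
next (times survival). The alternative of multiplying the whole bracket
`(S_{i−1}B_{i−1} − B_i)` by `a_i` is equivalent for every interior class of
the uniform acceleration block and whenever `a ≡ 1`, but at the block
boundaries it silently creates bees on entry and destroys up to two thirds
of them on exit; under that reading no overwintered colony can survive its
spring, so flux continuity was adopted. All correctness oracles
(steady-state agreement, the analytic solution) run at `a ≡ 1`, where the
two readings coincide.

### Feedback factors (evaluated from the pre-step state, fully explicit)

* nurse shortage: `r = min(N/(L·1.0), 1)`, larval survival multiplied by
  `r^α`, default `α = 0.25` (`r = 1` when there are no larvae);
* processing bottleneck: foraging income multiplied by
  `f_Q = min(Q/(0.8·F), 1)` (`1` with no foragers);
* scarcity: only stores above the 100 g inaccessible reserve count,
  `f_a = max(f − 100, 0)`. When the daily requirement
  `f_d = 0.018·L + 0.007·H + 0.007·F` exceeds `f_a`, adults feed first:
  larvae share what remains above the adult need (floor 0.2), then adults
  share `f_a` (floors 0.5 hive, 0.67 forager), and with `f_a = 0` every
  factor sits at its floor. The factors multiply the base survivals inside
  the daily flux, matching the per-day rate convention of the scheme rather
  than actuarial `S^dt` compounding.
* cannibalism: during a deficit all larval deaths
  `d_i = B_i (1 − S_i S_L r^α)` are recycled at `γ_L = 0.5` of the age
  weights (0.1, 0.6, 20, 80, 150 mg) — colonies consume dying brood
  regardless of the proximate cause of death;
* pheromones: `a^e = clamp(1 + (R_FH − R_mod)/R_mod, 1/3, 3)` with
  `R_mod = 2.3 − 0.5·D/f_d` (a deficit recruits foragers early), and
  `a^b = clamp(1 + 0.5·(R_LH − 2)/2, 1/2, 2)`; the product is clamped to
  [1/3, 3] and applied to ages 35–41 (`n_a = 6`). A missing caste (no
  foragers, no larvae) reads as an infinite ratio — no pheromone source, no
  brake — giving maximal acceleration.

The evaluation order within a step is: aggregates → season → winter flag →
f_Q → scarcity → nurse factor → acceleration → population update → food
update, all from the state at time `t`. Food is clamped at zero after the
update; the full requirement `f_d` is drawn each step even when stores run
short (the survival floors, not the ledger, carry the starvation effect).

### Seasonal forcing

`s(t) = 1 − max{1 − 1/(1 + 385 e^{−2t/30}), 1/(1 + 36 e^{−2(t−155)/30})}`,
clamped to [0, 1]: near zero through winter, ≈ 0.98 near day 150. The
printed source of this curve is ambiguous between a max and a
sum/product combination of the two sigmoids; the forms differ by < 0.03
everywhere, the max form is the default, and `s_form = "product"` selects
the alternative. The single-knob variant
`s̃(t)` uses width `x̃5` (autumn) and `x̃5 + 5` (spring) around day 150,
where both branches equal `36/37 ≈ 0.973`. The productive-season window is
the first day with `s̃ ≥ 0.15` through the last with `s̃ ≥ 0.05`,
**with s̃ compared at its reported 3-decimal precision** — the convention
that reproduces the published integer windows (44–264, 57–248, 84–215 for
x̃5 = 35/30/20); at full float precision the middle window would end one
day earlier.

### Winter rules

Winter is Sep 17 (day 260) through Mar 5 (day 64), or the complement of the
s̃ window in the summer-length study. During winter:

* the queen lays no eggs and the pheromone multipliers are 1;
* all adults (hive bees *and* foragers) form a dormant cluster: aging and
  maturation stop, and mortality is the flat winter rate 0.01/day applied
  as an explicit death term. Freezing the whole adult age clock — rather
  than letting hive bees pile into the terminal age class — preserves the
  age structure (in particular, nurses) through winter; a terminal pile-up
  leaves no nurses at winter exit, every spring larva then dies of nurse
  shortage, and no colony can ever overwinter;
* brood continues developing normally (larvae eat and are subject to
  scarcity), and newly emerged adults join the frozen youngest hive class;
* clustered hive bees do not draw on the tracked food store; foragers and
  larvae do. Charging the full hive consumption through a 169-day winter
  empties any achievable autumn store (a mid-sized cluster needs 2–10 kg),
  which would starve even the well-provisioned multi-year baseline — at
  odds with the near-flat winter store levels and multi-winter survival the
  model is meant to exhibit. The dormant-cluster reading reproduces both,
  and makes the food-stress scenario collapse exactly when its stores run
  out at the end of winter;
* scarcity floors do not apply to clustered adults (their mortality is
  *replaced* by the winter rate); they resume at winter exit.

### Integration and stability

Explicit Euler with default `dt = 0.1` day (2.4 h). The linearized
per-class decay factor is `1 − a_i·dt`, so with the acceleration cap
`a = 3` the scheme is stable exactly for `dt ≤ 2/3` day (16 h); this
if-and-only-if threshold is property-tested on the constant-coefficient
chain, where it is exact. On the full nonlinear seasonal scenario the
practical instability symptom is loss of positivity: abundances stay
non-negative for `dt ≤ 1/3` day (where `1 − a·dt ≥ 0`), while runs at
9.6 h and above drive age classes hundreds to thousands of bees negative.
The time-step study (150 days from January 1, winterless, 8000 hive bees,
seasonal laying at 1600·s(t)) flags a run unstable when any abundance goes
more than one bee negative or the adult peak exceeds 10× the reference:
16.8 h is unstable, 6 h agrees with the 2.4 h reference within 1.4 %
sup-norm, and errors against a dt = 0.005 day reference scale at first
order. Because that reference itself carries O(dt) error, measured
error ratios follow `(2Δ − 0.005)/(Δ − 0.005)` rather than exactly 2; the
tests use step pairs far above the reference where this is within 2 ± 20 %.
The integrator does not clamp abundances: stable steps keep them
non-negative by construction, and unstable runs are allowed to expose
themselves (a run is truncated and flagged only on overflow).

### Analytic oracle

With constant rates and no feedbacks the cascade has the closed form
`B_i(t) = steady_i + Σ_k (suffix survival products)·(initial deviation)·
t^k e^{−t}/k!`. The Poisson weights are accumulated incrementally
(`f_k = f_{k−1}·t/k`) to avoid factorial overflow; for `S ≡ 1` and an empty
start the solution reduces to Poisson tail probabilities, cross-checked
against an independent statistical library. The integrator at dt = 0.01 day
tracks the closed form within 0.5 % in every age class for a
fully-populated initial state; for a near-empty colony the advancing wave
front makes *relative* error on near-zero classes meaningless, so oracle
comparisons use populated initials.

## 4. Scenarios and experiment harness

The bundled scenarios are parameter-defined, not data-driven; they emulate
a managed colony's annual cycle (founding in early March with 8000 hive
bees and 2 kg of stores; laying amplitude 1600 eggs/day) and a food-stress
variant founded in late July (day 210, 10,400 hive bees + 5,600 foragers,
2 kg stores, reduced foraging rate). They do not emulate disease, mite
load, weather-limited foraging days, spatial forage landscapes, queen
failure or beekeeping interventions — passing tests say nothing about
those. All experiments are deterministic and write CSV plus a parameter
echo.

Observed behavior of the stress scenario (dt = 2.4 h): at
p = 0.04 g/(bee·day) the colony's stores run out during winter and the
adult population first crosses the 1000-bee collapse threshold at day
≈ 429 (early March); at p = 0.06 stores last through winter. The collapse
threshold (1000 adults, configurable) is evaluated as a first-crossing
time.

## 5. Known limitations

* Under severe forage restriction (p ≤ 0.02) autumn starvation outpaces
  the winter freeze: stores empty in October and the colony dies near day
  248 rather than surviving to a late-winter collapse. The fall food
  budget (16,000 adults drawing ~112 g/day against ~600 g of income)
  admits no other outcome under the stated consumption rates.
* Any colony entering winter below ≈ 5,500 adults passes below the
  1000-adult threshold before new spring brood can mature (169 days at
  1 %/day, plus a ~45-day gap between winter exit and the first spring
  adults). In the stress scenario even the food-sufficient p = 0.06 run
  therefore dips below the threshold in early spring; with ≈ 260 g of
  stores at winter exit and ~10 g/day net spring losses it does not
  recover. Experiment summaries report both the first-crossing day and the
  terminal state to keep the two notions distinct.
* The pheromone module's effect on the stress scenario is small (~2 days,
  ~150 g of winter-exit stores): with autumn larvae scarce, the
  brood-pheromone arm *accelerates* maturation and largely cancels the
  ethyl-oleate brake, so no pheromone rescue materializes at p = 0.055.
* The steady-state model has no seasonality by construction; its
  sustainability verdicts are long-run averages.
* Real colonies do consume stored honey over winter; the dormant-cluster
  treatment trades that realism for a consistent annual cycle under the
  model's foraging-income budget (see §3, winter rules).
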