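# Methods

## The model

`oncoeco` describes a tissue as a consumer–resource system with two cell
phenotypes competing for one abiotic resource:

```
dH/dt = d·c·R·H·(1 − (H+C)/K) − ρₛ·H − ε·H
dC/dt = a_c·g(C)·R·C·(1 − C/K) + ε·H − ρ_c·C − θ·C
dR/dt = σ − c·R·H − a·R·C
g(C)  = exp(−b_c · exp(−d_c · C))
```

Assumptions:

* **Continuous densities.** H, C, R are deterministic continuous
  quantities; fractional cells are meaningful, and suppressing the growth
  of sub-unit cancer populations is exactly the Gompertz gate's job.
* **One homogeneous resource, no decay.** Resource enters at a constant
  rate σ and leaves only through consumption (`c·R·H + a·R·C`); there is no
  spatial structure and no abiotic loss term.
* **Healthy cells are cooperative consumers.** Their birth flux is
  conversion efficiency `d` times their consumption flux `c·R·H`, throttled
  by total crowding `(1 − (H+C)/K)`: healthy tissue respects contact
  inhibition with respect to *all* cells.
* **Cancerous cells are profiteers.** They consume at the high per-capita
  rate `a` (an order of magnitude above `c` at the defaults — metabolic
  wastefulness), but their division rate `a_c·g(C)·R` is set by the gated
  proliferative machinery, not by consumption efficiency; and they ignore
  crowding by healthy cells, feeling only their own density through
  `(1 − C/K)` — escape from contact inhibition.  The total population can
  therefore transiently overshoot K slightly (see *Numerical choices*).
* **Seeding and surveillance.** Healthy cells convert to cancerous ones at
  rate ε (the flux ε·H leaves H and enters C: the conversion event
  conserves cells); the immune system removes cancerous cells at rate θ.
* **Proliferation threshold.** The Gompertz gate g(C) is a function of the
  *absolute* cancer population.  With the default shape (b_c = 10⁵,
  d_c = 15 cell⁻¹) it is closed (≈e⁻¹⁰⁰⁰⁰⁰) at C = 0, half-open at
  C½ = ln(b_c/ln 2)/d_c ≈ 0.79 cells and fully open by C ≈ 2, so the
  mutational influx ε·H (hundreds of cells per year at the defaults) opens
  it readily.  Scaling the argument by K instead would place the threshold
  at ~79% of capacity, unreachable by mutational influx alone, and no
  disturbance response would exist.
* An option (`gate_consumption`) also throttles cancerous *consumption* by
  the same gate; it is off by default because the threshold is a statement
  about proliferation, and at the defaults the gate is open wherever C is
  non-negligible, so the option barely changes trajectories.

### Why the birth terms are asymmetric

The equation structure was the main genuinely open design choice, and the
symmetric alternatives fail on dimensional-balance grounds with the shipped
constants.  The steady state of a consumer–resource pair is governed by
break-even resource levels (the R* rule).  If both phenotypes' per-capita
birth rates are proportional to the same factor `R·(1 − (H+C)/K)` — e.g.
cancer births written as conversion × consumption, `b(C)·a·R·C`, with the
shared logistic — then the phenotype with the lower break-even always
excludes the other *regardless of σ*: with the default constants cancer's
break-even `(ρ_c+θ)/(a_c·a) ≈ 0.0023` sits far below the healthy value
`(ρₛ+ε)/(d·c) ≈ 0.021` for any plausible θ, predicting ~100% cancer
everywhere and no dependence on resource supply at all.  Conversely, making
cancer births `a_c·g·R·C` with the *shared* logistic makes cancer strictly
inferior everywhere.  Either way the model could not express the phenomenon
it exists to study — a joint (θ, σ) invasibility surface with a
low-burden baseline.

Decoupling the crowding terms is what creates an interior coexistence
equilibrium: healthy cells must meet `R(1 − (H+C)/K) = (ρₛ+ε)/(d·c)` while
cancerous cells must meet `R(1 − C/K) ≈ (ρ_c+θ)/a_c`, and both conditions
can hold at once.  Solving them together with the resource balance
σ = R(cH + aC) gives, in closed form,

```
C/(K−C) = (σ/K − A·c·(r−1)) / (r·A·a),   r = B/A,
A = (ρₛ+ε)/(d·c),  B = (ρ_c+θ)/a_c,
```

so the equilibrium cancer fraction rises linearly-in-odds with σ and falls
with θ — exactly the joint surface the sweep reproduces numerically (the
numerical equilibria sit slightly above this closed form because the
mutational influx ε·H adds to the cancer balance).  At the baseline
(θ = 365/25, σ = 4·10⁴) the predicted fraction is ≈0.03–0.06 (numerically
0.0548): a healthy tissue harbouring a small, immune-controlled cancerous
subpopulation, which is the correct starting point for disturbance
experiments.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| ε | healthy→cancer conversion | 365/1000 | 1/yr |
| K | carrying capacity | 10³ | cells |
| ρₛ | healthy death rate | 365/40 | 1/yr |
| ρ_c | cancer death rate | 365/15 | 1/yr |
| a | cancer consumption | 365 | 1/(resource·yr) per cell |
| c | healthy consumption | 365/10 | 1/(resource·yr) per cell |
| d | healthy birth conversion | 365/30 | cells/resource |
| a_c | cancer division-rate asymptote | 365/8 | 1/(resource·yr) |
| b_c | gate displacement | 10⁵ | — |
| d_c | gate steepness | 15 | 1/cell |
| θ | immune elimination | 365/25 | 1/yr |
| σ | resource input | 4·10⁴ | resource/yr |

The printed "per cell per year" convention of the source constants is not
dimensionally consistent across roles; the package takes the numerical
values verbatim with time in years and documents per-role effective units
as above, performing no conversion.

## Disturbances

A disturbance is a rectangular pulse on θ (immune) or σ (resource) over a
half-open window `[start, start+duration)` — half-open so back-to-back
pulses never double-apply at the seam.  Modes: `replace`, `scale`, `add`;
overlapping pulses on one target compose in declaration order.  The
canonical pulses are a 2-month (2/12 yr) immunosuppression window with θ
replaced by 0, and a 10-day (10/365 yr) resource surge with σ scaled by a
factor (default 10; the acceptance sweep uses {5, 10, 25, 50, 100}).  The
magnitudes are modelling choices exposed in configuration — full
immunosuppression is the natural extreme case, and the factor grid spans
mild to severe caloric excess.  The five canonical timings (immune-only,
resource-only, resource before/after/during immune) share one post-burn-in
start offset (0.5 yr) and matched magnitudes.

## Protocols and numerical choices

* **Burn-in (initial conditions).** All experiments start from the
  converged undisturbed state reached from H = K/2, C = 0,
  R = σ/(c·H); ε seeds C immediately.  Convergence: maximum relative
  change of (H, C, R) over a trailing 1-year window < 10⁻⁸, with a
  500-simulated-year cap (non-convergence is a flagged result, and limit
  cycles would be flagged the same way, not raised).  At the defaults the
  system equilibrates in well under 5 years.
* **Integrator.** `scipy.integrate.solve_ivp` with LSODA (stiffness-
  switching; the gate makes the cancer equation stiff near C ≈ 0), rtol
  10⁻⁸, atol 10⁻⁹.  Integration restarts at every pulse edge so the
  discontinuous forcing is never smoothed; output is sampled daily plus at
  every edge.  Tightening tolerances tenfold changes scenario peak
  fractions by < 10⁻⁴.
* **Cross-check.** An independent fixed-step classical RK4 integrator
  (`oncoeco.reference`) reproduces trajectories to < 10⁻⁴ maximum relative
  state discrepancy at step 10⁻⁵ yr.  Being explicit, it is only stable
  below step ≈ 2·10⁻⁵ yr during strong resource surges, where the fastest
  rate constants reach ~10⁵/yr.
* **Gate underflow/overflow.** g(C) is computed in log space as
  `exp(−exp(ln b_c − d_c·C))` with the inner exponent clamped, safe for
  b_c up to at least 10⁹; underflow returns exactly 0.
* **Exact invariants.** With ε = 0 the set {C = 0} is an invariant
  manifold (dC/dt ≡ 0 on it); the integrator projects out the
  roundoff-scale drift the solver's linear algebra introduces, since in
  invasible parameter regions even a 10⁻²⁴-cell seed would grow
  exponentially.  Tiny negative excursions (≤10⁻⁶) are clamped to zero;
  larger ones raise.
* **Capacity band.** Because cancer ignores healthy crowding, extreme
  resource surges can push H + C a few percent past K before healthy-cell
  crowding (whose birth term turns negative above K) pulls the total back;
  the runtime invariant therefore allows a 15% transient band, while
  equilibria satisfy H + C ≤ K strictly.
* **Summaries.** Peak fraction over the dense samples; time above a
  threshold by linear interpolation between samples; burden integral by
  trapezoid rule.  The cancer fraction of an empty state is defined as 0 so
  extinct trajectories summarize cleanly.
* **Sweep grid.** θ log-spaced over [365/200, 365/2] descending, σ
  log-spaced over [10³, 10⁶] ascending, 20×20, with the nearest points
  snapped to the baseline (365/25, 4·10⁴) so it is an interior anchor cell.
  Cells are independent (identical burn-in protocol), so evaluation order
  cannot matter; non-converged cells are flagged and excluded from the
  monotonicity report.

## Synthetic inputs

The generator produces the two randomized objects the analysis consumes:

* **Sporadic schedules.** Pulse arrivals per target follow a homogeneous
  Poisson process (exponential gaps — the minimal single-parameter model of
  "sporadic"), with the canonical durations and configurable magnitude
  ranges, truncated at the horizon.  Defaults: 0.5 immune pulses/yr
  (roughly every other winter), 2 resource pulses/yr (a few feasts),
  immune replace-to-0, resource scale factor uniform on [5, 100].
* **Jittered parameter sets.** Every constant is multiplied by an
  independent mean-1 log-normal factor with a chosen coefficient of
  variation (K re-rounded to an integer), for sensitivity and robustness
  runs; `scenario_ordering_robustness` reports how often the
  disturbance-timing conclusions survive cv = 0.1 jitter.

Both are driven by explicit integer seeds through `numpy.random.default_rng`;
no global random state is used.  What the synthetic inputs do *not*
emulate: seasonality (arrivals are time-homogeneous), correlated parameter
uncertainty (fields are jittered independently), and any demographic or
measurement noise — the dynamics themselves stay deterministic.  Passing
tests therefore demonstrate the model's internal logic and its robustness
to parameter perturbation, not agreement with clinical or epidemiological
data.

## Problem sizes

The shipped test-suite and acceptance runs use the scales at which the
results are already converged: 4–6-year disturbance horizons (peaks occur
within weeks of the pulses), the 20×20 equilibrium grid (~3 s), a 1-year
oracle-comparison window at step 10⁻⁵ yr, and 8-draw robustness reports in
tests (50 draws from the API for the quoted proportions).  The entire suite
runs in well under a minute.

## Known limitations

* The system is deterministic and non-spatial: no demographic noise, no
  clonal heterogeneity, no metastasis, no tumor microenvironment geometry.
* Long-run consequences of repeated disturbances (e.g. ratcheting,
  evolution of a) are outside scope: after any pulse sequence the system
  relaxes to its unique baseline attractor, by construction.
* Disturbance magnitudes are scenario parameters, not fitted quantities;
  nothing here quantifies the real-world strength of immunosuppression or
  caloric excess.
* The equation structure is a reconstruction constrained by the verbal
  model description and its published constants; the asymmetric-crowding
  choice above is the only structure we found under which those constants
  yield the documented joint invasibility surface, but other closures with
  additional constants could do so too.
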