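# Methods

## Growth backbone

Tumor volume follows logistic growth `dV/dt = λV(1 − V/K)` with constant
carrying capacity `K` between radiation fractions. Because `K` is piecewise
constant, the ODE has an exact solution on every inter-fraction interval,

    V(t + Δt) = V K / (V + (K − V) e^{−λΔt}),

and the simulator uses this closed form everywhere instead of a numerical
integrator. This removes integrator error from all downstream comparisons
(the test suite checks agreement with fine-step `solve_ivp` integration to
better than 1e−8 relative) and makes every result independent of the
reporting grid. The map is equally valid for `V > K`, where the volume
decays monotonically toward `K` — the regime the capacity-reduction model
relies on.

The initial volume is normalized to `V₀ = 1` (arbitrary units) by default:
every reported quantity is a relative volume reduction, so the absolute
scale cancels. `PSI = V₀/K₀` may be 1 exactly (fully saturated tumor);
`PSI = 0` is not constructible since it would need infinite capacity.

### Prospective capacity estimation

Given a diagnosis volume `V_Dx`, a planning volume `V₀` and the `Δt` days
between them, the unique capacity consistent with logistic growth at rate
`λ` is the algebraic inversion of the logistic solution,

    K = V₀ V_Dx (e^{λΔt} − 1) / (V_Dx e^{λΔt} − V₀),

whose defining property (and the property the tests enforce) is the
roundtrip `grow(V_Dx, K, λ, Δt) = V₀`. The estimate requires net growth
slower than exponential (`V_Dx e^{λΔt} > V₀`); otherwise no finite capacity
exists and the function raises. In the no-net-growth limit `V₀ → V_Dx` the
estimate tends to `V_Dx` (PSI → 1).

## Radiation response operators

Fractions are instantaneous state changes. Per-fraction kill under direct
volume reduction (DVR) uses the linear-quadratic survival model,
`γ = 1 − e^{−(αd + βd²)}`, with `β` always derived from `α` through a fixed
`α/β` ratio (default 10 Gy, typical of tumors treated with fractionated RT)
so that inconsistent `(α, β)` pairs cannot be constructed. Only the
proliferating fraction `(1 − V/K)` of the volume is at risk, which is what
couples DVR efficacy to PSI. Carrying-capacity reduction (CCR) multiplies
`K` by `(1 − δ)` per fraction; `δ` is defined *per fraction*, not per Gy —
the dose dependence of microenvironmental damage is unknown — so the model
is only used with the standard 2 Gy fractionation. `δ = 1` collapses the
capacity and raises immediately rather than poisoning the next propagation.

The combined operator applies both updates at one fraction instant,
computing both from the pre-fraction state ("simultaneous"). Updating the
volume first is algebraically identical; updating the capacity first
("ccr_first", exposed as an option) lets the kill term see the reduced
capacity and is the one genuinely different ordering. The combination is
known to be ill-behaved — once V/K crosses 1 the kill term changes sign and
fractions *add* volume — and is retained purely as a diagnostic; the
artifact survey quantifies how widespread the problem is across parameter
space (over 80% of surveyed cells spike at default settings).

## Scheduling and simulation conventions

- Treatment starts on a Monday (day 0), 5 fractions per full week, so
  `weeks` full weeks deliver exactly `5·weeks` fractions with 24 h weekday
  gaps and a 72 h Friday→Monday gap. Fractions are delivered at hour 9 of
  each treatment day; any fixed hour preserves the gap structure.
- Dynamics are advanced exactly between events and *sampled* on an hourly
  grid; results are grid-independent by construction.
- At a grid point coinciding with a fraction instant the post-fraction
  state is stored (right-continuous convention, matching the cumulative
  dose step function). Whether plotted series in prior art store pre- or
  post-fraction values at those instants is not documented anywhere we know
  of; right-continuity is our convention.
- The default horizon is the last fraction time: the models describe
  on-treatment dynamics only. The D_min search extends the horizon to the
  end of the final week so continuous post-fraction shrinkage under CCR
  still counts (credited at the full delivered dose).
- Sweep presets default to 5-week courses, matching the trajectory-family
  analyses; the D_min search caps courses at 8 weeks. Course length is an
  explicit argument everywhere.

## D_min search

Locoregional control is proxied by a ≥ 32.2% volume reduction relative to
the pre-treatment volume, a threshold taken from clinical mid-treatment
response data for head-and-neck cancer. The search simulates up to 8 weeks
of 2 Gy weekday fractions (80 Gy cap) and returns the cumulative dose at
the first hourly grid time at which the reduction meets the threshold;
parameter combinations that never reach it are *censored* results, not
errors. Crossing is checked hourly rather than only at fraction instants so
the CCR model's continuous between-fraction decline is captured; delivered
dose accounting is unchanged by this choice. Every non-censored D_min is an
exact multiple of the dose per fraction, so the landscape is quantized and
"iso-dose" contours are boundaries of constant-dose cell regions.

Landscape defaults: `λ = 0.07`/day, PSI strictly inside (0.6, 1.0) at step
0.01, `α` inside (0.06, 0.14) Gy⁻¹ and `δ` inside (0.01, 0.09) at step
0.002 (39 × 39 grids). Grid steps are configurable; the defaults give
smooth landscapes at desk-scale runtime (a few seconds per grid). Sweep
ranges open at 0 — `α, δ ∈ (0, 0.20]`, `λ ∈ (0, 0.10]`/day, step 0.01 —
are realized as half-open grids because 0 is the degenerate no-treatment
case, shown separately as the untreated growth curve.

## Exponential fits

`D_min(x) = a e^{bx} + c` is fit by least squares (`scipy.curve_fit`) after
excluding censored cells (≥ 4 points required). Seeding anchors `c` just
outside the data range (below the minimum for the positive-amplitude
branch, above the maximum for the negative branch) and estimates `(a, b)`
from a straight-line fit of `log|y − c₀|` against `x`; both branches are
attempted and the smaller-residual solution kept. Constant data returns a
degenerate fit (`a = 0, c = mean`) rather than an ill-posed optimization;
optimizer failure from both seeds returns an explicit non-converged result
carrying the initialization used.

## Diagnostics

`detect_capacity_violations` reports every grid point with `V/K > 1 + 1e−12`
and, separately, *spike events*: a relative volume increase above 0.005
within a single hour. Continuous logistic growth adds at most `λ/24`
relative volume per hour (≈ 0.004 at the largest swept rate,
`λ = 0.1`/day), so only discontinuous radiation-induced jumps — the
combined model's artifact — can register. Plain CCR courses legitimately
cross `V/K = 1` but never spike; plain DVR courses do neither.

## Determinism

Nothing in the package draws random numbers: trajectories, grids and fits
are bit-reproducible, and recomputing any grid cell in isolation reproduces
the grid value exactly. The CLI `--seedless` flag asserts at run time that
the executed pipeline left the global RNG state untouched.

## What the analyses do and do not show

All inputs are parameter sets, not data; the analyses characterize the
*models*, not any tumor cohort. Passing tests demonstrate internal
consistency and the qualitative orderings (monotone sweep families, the
opposite PSI dependence of D_min, the combined-model artifact), not
predictive validity for real patients: fitting either model to longitudinal
clinical volume series, post-treatment regression, immune clearance, and
below-detection stochastic dynamics are all out of scope. The 32.2%
threshold is a single-cohort, single-site figure carried as a constant, and
the CCR model's `δ` has no established dose dependence, so CCR conclusions
should not be extrapolated to non-standard fractionations.
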