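# Methods

## Model

`kuznefit` fits a simplified Kuznetsov model of tumor–immune interaction
to per-patient time series of target-lesion longest diameter (LD). The
dimensional system tracks effector cells E (CTL/NK) and tumor cells T,
whose transient conjugates C form at rate k₁, dissociate at k₋₁, and
resolve irreversibly into lethally hit tumor cells (rate k₂) or
inactivated effectors (rate k₃). Because conjugation kinetics are fast
compared with cell turnover, a quasi-steady-state assumption eliminates
C ≈ K·E·T with K = k₁/(k₂ + k₃ − k₋₁); the invariant k₂ + k₃ > k₋₁ keeps
K positive. Inactivated cells are sinks and carry no feedback, so their
balances are not integrated. The logistic crowding term of the original
model is deliberately absent: growth limitation is carried entirely by
the immune interaction.

After rescaling E by E₀ = 10⁷ cells, T by T₀ = 10⁹ cells and time by a
lumped rate, the working model is

    dx/dτ = σ + ρxy/(η + y) − δx − μxy
    dy/dτ = αy − (E₀/T₀)·xy

with x = E/E₀, y = T/T₀ and six dimensionless parameters: σ (baseline
effector influx), ρ (stimulated recruitment), η (recruitment
half-saturation), μ (effector inactivation by tumor contact), δ (effector
death/efflux) and α (intrinsic tumor growth). The tumor-free equilibrium
(x, y) = (σ/δ, 0) with local tumor growth exponent α − (E₀/T₀)σ/δ serves
as the analytic anchor for verification.

The lumped time factor is not derivable from LD data alone; the package
fixes `time_scale = 0.01/day` (τ = t_days/100), which keeps trial
durations of a few hundred days at τ of order 1–10. The wide parameter
bounds absorb most of this gauge freedom; the constant is configurable.

## Data handling

Input is a long-format CSV (patient_id, study, arm, treatment, time_days,
ld_mm) with times in days relative to treatment start (negative values
are pre-treatment scans; times are never re-zeroed). Cleaning drops null
LD rows and repeated measurements: exact duplicates collapse, and when
two rows share a time with different LD the first occurrence wins — a
deterministic, order-preserving rule, logged per patient. "Net"
measurements are those surviving cleaning; patients with fewer than seven
are dropped so that at least three points remain for fitting after
holding out the final two or three visits.

LD in mm converts to cell count as packing·(π/6)·LD³/v with packing 0.75
and v = 8·10⁻⁶ mm³ per cell (spherical lesion, tumor cells occupying
three quarters of its volume); division by T₀ gives the dimensionless
observation y.

## Estimation

Each patient is fitted independently by least squares on normalized y
with uniform weights. Decision variables are the six parameters and the
initial effector level x₁ (unknown clinically); y₁ is pinned to the first
measurement, so the first residual is structurally zero. All decision
variables are bounded to [10⁻², 10²], reflecting the expectation that
nondimensionalized quantities are of order one.

The objective is nonconvex and multimodal, so the solver is a multistart
global search: differential evolution over log₁₀-transformed variables
(the bounds span four decades), followed by bounded quasi-Newton polish
of the best population members — distinct members typically occupy
distinct basins, and polishing several recovers narrow optima the
population misses. Seeds derive from a spawned sequence, so runs are
reproducible and the start schedule is prefix-stable: adding starts can
only improve the best objective. Divergent integrations return a finite
penalty (10¹²) that dominates any attainable residual. Budgets are
per-start (evaluations and wall time); an optional stop target of
SSR = 10⁻⁹ — the solver's effective convergence floor, per-point
residuals around 10⁻⁵ — short-circuits remaining starts on noise-free
data.

Goodness of fit is reported as MAE, RMSE and R² on normalized y. R² may
be negative, and is reported as missing for flat (zero-variance)
observation vectors.

## Numerical integration

The dynamics are integrated with a stiff-capable variable-step,
variable-order multistep method (LSODA) with an analytic Jacobian,
nominal tolerances rtol 10⁻³ / atol 10⁻⁶ and maximum step one tenth of
the span. Because a multistep method's tolerance bounds only local error,
requested tolerances are treated as *delivered-accuracy* targets: the
integrator runs internally at tolerances tightened by a safety factor
(default 100), which measured global deviation against independent
tight-tolerance references (BDF at rtol 10⁻⁹) keeps below ~2·10⁻⁴ on
well-conditioned problems. Optimization inner loops (estimation,
feasibility searches, envelope solves) use safety 10: their integration
error remains orders of magnitude below the residual and tolerance scales
they work at, and the global search repeatedly visits stiff parameter
regions where tight tolerances are expensive. A normalized tumor burden
above 10³ (10¹² cells, far beyond lesion scale) or any integrator failure
is treated as divergence.

## Practical identifiability

For each fitted patient the ε-feasible set contains every parameter
vector whose predictions (with x₁ fixed at the fitted value) stay within
a relative ε of the optimal predictions at every measurement time;
ε = 20% by default, motivated by the 1–2 mm manual-measurement margin of
LD reads. The feasible set is summarized by its smallest axis-aligned
bounding box, found by maximizing and minimizing each parameter in turn
(12 constrained solves) with a penalized global search seeded at the
optimum. Returned points are re-verified by an independent feasibility
check; a failing point is contracted toward the (always feasible) optimum
by bisection, and a final one-dimensional outward push tightens each edge.
The re-check — not the solver — is the contract, so box edges are always
realized by verified-feasible parameter vectors.

Stochastic approximations of nested sets need not nest, so boxes for a
family of tolerances are computed tightest-first, each seeding the next
(`nested_boxes`); since feasibility at a smaller ε implies feasibility at
a larger one, the chained boxes nest by construction. Cohort-level
summaries average box indicator functions on a logarithmic grid (200
points per parameter), giving range-frequency curves in [0, 1]. No
identifiability cutoff is imposed; box widths are reported for
qualitative judgment.

## Forecasting and extreme-case envelopes

The forecasting experiment refits each patient on the first N − ζ points
(ζ = 2 by default, 3 as an alternative), extrapolates to the final
measurement time, and scores the held-out points with MAPE
(mean |(observed − predicted)/observed|). All-points MAE/RMSE/R² are
reported alongside.

The envelope asks how far extrapolation could plausibly stray: maximize
(upper branch) and minimize (lower branch) the terminal prediction over
parameters and x₁ subject to staying within θ = 10% of the truncated
fit's predictions at every *fitted* time. The joint objective (terminal
separation) and the constraints are separable across branches, so the two
problems are solved independently. Each branch runs a deterministic
presampling sweep around the incumbent (whose deviation is zero, hence
always feasible), a seeded differential-evolution search with a penalty
on constraint violation, and sequential-quadratic polishing of the best
candidates onto the constraint boundary; the returned branch is the most
extreme verified-feasible candidate, never worse than the incumbent. A
smaller-θ envelope can seed a larger-θ solve, making terminal spread
monotone across a θ sweep.

## Synthetic cohorts

The generator emulates the statistical structure of the clinical setting:
7–12 visits at a 42-day re-staging cadence, baseline LD 10–80 mm,
parameters and x₁ drawn log-uniformly within the estimation bounds (α
capped at 6.5 — normalized tumor growth rates saturate well below the
generic bound), and additive Gaussian LD noise of 1 mm (truncated below
1 mm by redraw), matching the absolute reading margin of manual CT
measurements. Draws are rejected when the noise-free trajectory leaves
(10⁻⁴, 100) in normalized burden, or when its LD dynamic range is below
5 mm: near-static lesions carry no longitudinal signal at the read
precision (variance explained is undefined in practice even for the
generating parameters), whereas patients followed over many visits in
practice show measurable response or progression.

What passing on synthetic cohorts does and does not show: recovery tests
demonstrate that the pipeline solves its inverse problem — trajectories
(not parameter vectors, which are often non-identifiable) are recovered,
forecasts are consistent, and the box/envelope guarantees hold. They do
not certify fit quality on real trajectories, which include measurement
artifacts, treatment-change discontinuities and dynamics outside this
model family.

## Problem sizes and defaults

The shipped experiments use a 10-patient noise-free cohort (9 visits) at
3 starts × 2·10⁴ evaluations for recovery, a 20-patient 1 mm-noise cohort
at 2 × 8·10³ for noisy-fit quality, 500-evaluation extremal solves for
boxes and 2.5·10³-evaluation branch solves for envelopes. Box and
envelope guarantees (containment, nesting, ordering, feasibility of
returned points) are enforced by construction and re-checks rather than
search effort, so modest budgets exercise the machinery honestly; larger
budgets tighten the boxes and widen the envelopes toward their true
extrema.

## Known limitations

- The model has no explicit treatment term; treatment labels are
  metadata only.
- Single target lesion per patient; no SD handling or multi-lesion
  aggregation.
- Per-patient estimation only; no cross-patient (global) parameters or
  mixed-effects structure.
- Envelopes are deterministic extreme cases, not probabilistic intervals.
- The time-scale constant is a gauge choice; absolute τ values are not
  comparable across analyses using a different constant.
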