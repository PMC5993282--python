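# Methods

## Model and estimation problem

`odestep` estimates the parameters and initial values of an autonomous
ordinary differential equation system

    x'(t) = F(x(t); θ),    x(t₁) = ξ,    t ∈ [t₁, T],

with state dimension d and parameter dimension p, from noisy
observations

    Y_ij = x_i(η₀, t_j) + ε_ij,    ε_ij ~ N(0, σ_i²) i.i.d.,

where η = (ξ, θ) collects the d + p unknowns and the ε_ij are additive,
independent measurement errors.  Non-autonomous systems are reduced to
this form by appending time as an extra state (`wrap_nonautonomous`).
The initial condition is attached to the first design time; for every
built-in scenario except the α-pinene network that time is 0.

The gold standard is nonlinear least squares (NLS): minimize
R_n(η) = Σ_ij (Y_ij − x_i(η, t_j))² over η, which requires iterative
optimization with repeated numerical integration.  The package instead
implements the one-step (Le Cam) construction: starting from any
√n-consistent preliminary estimate η̂ it applies a single Newton-type
update

    η̄ = η̂ − M(η̂)⁻¹ Ψ_n(η̂),        Ψ_n(η) = Σ_j s(t_j)ᵀ (Y_j − x(η, t_j)),

where s(t) = ∂x/∂η solves the linear sensitivity system
s' = F_x s + [0 | F_θ], s(t₁) = [I_d | 0], integrated once jointly with
the state.  Asymptotically η̄ is equivalent to the NLS estimator.

Three step matrices M are available:

* `newton` — the full derivative of Ψ_n, using second-order
  sensitivities z = ∂²x/∂η² from the variational equations (z(t₁) = 0);
* `gauss_newton` — the surrogate −Σ_j s_jᵀ s_j, which drops the
  z-weighted residual term;
* `damped` (default) — the Gauss–Newton surrogate minus λI with
  λ = 0.01, i.e. exactly one Levenberg–Marquardt iteration.  The λI
  form deliberately freezes directions whose curvature is far below λ
  (statistically flat valleys, e.g. the (θ₁, θ₃) ridge of the Robertson
  system); this is the numerically robust behaviour intended by the
  damping.

If a step solve fails or returns a non-finite update, λ is multiplied
by 10 (up to 10⁶) and the step is retried; the `newton` and
`gauss_newton` variants escalate by falling back to damping.

### Capped-budget refinement

A literal single update inherits the quadratic linearization remainder
of the step.  On strongly curved problems (exponential growth over ten
time units makes the NLS valley narrower than any smoothing-based
preliminary can reach) that remainder leaves the residual sum of
squares orders of magnitude above the noise floor, which would corrupt
the plug-in noise variance below.  The pipeline therefore follows the
practical scheme of running a damped (Levenberg–Marquardt) optimizer
with a small budget: after the defining one-step update, the selected
candidate is polished by up to `max_steps − 1 = 7` further accepted LM
steps (λ ÷ 10 on acceptance, × 10 on rejection), early-stopped on
score and criterion tolerances.  On benign problems this converges to
the NLS minimizer in 2–4 cheap steps; on hard ones it behaves like the
bare one-step estimator.  `max_steps=1` recovers the strict one-step
estimator, and all algebraic identities (one damped update ≡ one LM
iteration) are stated and tested at that setting.

## Preliminary estimators

Both preliminaries consume a nonparametric smooth of the data.

* **Smooth-and-match (SME):** θ̂ minimizes the quadrature approximation
  of ∫ ‖x̂'(t) − F(x̂(t); θ)‖² w(t) dt, with w the indicator of the
  interior of the span (5% trimmed at each end, removing boundary bias
  of the derivative estimate).  Closed-form weighted linear least
  squares when F is linear in θ; numeric otherwise.
* **Direct integral estimator (default):** (ξ̂, θ̂) jointly minimize the
  quadrature approximation of ∫ ‖x̂(t) − ξ − ∫_{t₁}^t F(x̂(s); θ) ds‖² dt,
  avoiding derivative estimation; inner integrals by cumulative
  trapezoid on the evaluation grid.  For parameter-linear F this is a
  single linear least squares solve.

Initial values at a given θ̂ are the quadrature-weighted time average
of x̂(t) − ∫_{t₁}^t F(x̂(s); θ̂) ds, the closed-form minimizer of the
integral criterion in ξ.

When initial values are declared known, the integral preliminary can
still fit free per-state intercepts (`free_xi_prelim`), which are reset
to their known values before the correction.  This matters for stiff
systems sampled after an unresolvable initial boundary layer (the
Robertson x₂ transient lasts ~1 ms against a 0.5 s sampling interval):
the layer's accumulated integral error is absorbed by the nuisance
intercept instead of biasing the rates by ~10%.

All registry models except the Goodwin oscillator declare the
parameter-linear decomposition F(x; θ) = G(x) θ + g0(x), so their
preliminaries are closed-form.

### Partially observed Goodwin oscillator

For the Goodwin system observed on (x₁, x₂) only, with θ₂..θ₄ and the
zero initial state known, the unobserved x₃ is reconstructed by the
exact integrating-factor recursion for x₃' = θ₄ x̂₂ − θ₅ x₃.  Given θ₅
the integral criterion is linear in θ₁ and is profiled; the profile is
minimized over θ₅ on a 60-point grid on [0.02, 2] refined by bounded
scalar minimization.  The cascade preliminary pins θ₅ down tightly;
θ₁ carries a visible bias (the tenth-power Hill term amplifies
smoothing bias in the reconstructed x₃) that the downstream correction
removes.

## Smoothing and bandwidth selection

Each observed state is smoothed by local polynomial regression of
degree 2 with the Epanechnikov kernel; the fitted intercept estimates
x(t) and the slope x'(t).  The evaluation grid is max(n, 101)
equispaced points spanning the design.  Windows near the boundary are
asymmetric (no reflection), and in the pipeline a window holding fewer
than degree + 1 observations is widened, at that evaluation point only,
to 1.1× the distance of the (degree+1)-th nearest observation.  This
nearest-neighbor floor turns too-small candidate bandwidths into
near-interpolants instead of failures; `local_poly_fit(widen=False)`
preserves the strict behaviour (a singular-window error naming the
grid point).

Candidate bandwidths follow the n^(−1/3) rate required for
√n-consistency of the preliminaries: b_k = n^(−1/3) · c_k · (span/10)
with ten equispaced multipliers c ∈ [0.02, 3].  The multipliers were
designed for a 10-unit time axis and are rescaled linearly for other
horizons.  Selection is data-driven: each candidate runs
smooth → preliminary → one-step, the model is integrated at each
corrected estimate, and the candidate with the smallest R_n against
the raw observations wins (ties go to the smallest bandwidth;
candidates failing anywhere are skipped with a logged warning).  The
selected candidate is then polished as described above.

## Inference

The noise variance is estimated by the pooled residual formula
σ̂² = [d_obs(n−1)]⁻¹ Σ_ij (Y_ij − x_i(η̄, t_j))² over observed states; a
per-state variant (divisor n−1 per state) is available for
heteroscedastic error models.  The Fisher information per observation
is

    I(η) = Σ_i σ_i⁻² ∫ (∂x_i/∂η)ᵀ (∂x_i/∂η) dF_T(t),

summed over observed states with fixed parameters' rows and columns
removed.  Two approximations of the design distribution F_T are
provided:

* `design="points"` (default for confidence intervals): point mass 1/n
  on each actual design time, i.e. the standard nonlinear-regression
  plug-in σ̂²(JᵀJ/n)⁻¹.  For designs whose information integrand varies
  quickly between observations (exponential decay sampled every 0.5
  time units) this differs from the continuous-uniform value by tens
  of percent, and it is the version whose intervals are calibrated
  against the empirical estimator spread.
* `design="uniform"`: dense trapezoid over the design span, the
  limiting information of a uniform random design; used for
  true-asymptotic-variance computations.

Confidence intervals are Wald intervals
η̄_j ± z_{1−α/2} √((I⁻¹)_jj / n) with the standard-normal quantile
(1.959964 at 95%).  All linear solves involving these matrices use
Jacobi equilibration because kinetic models mix O(1) initial values
with O(10⁻⁵)–O(10⁷) rates (raw condition numbers beyond 10¹²).

The NLS baseline (`nls_fit`) is a full Levenberg–Marquardt minimizer
of R_n with sensitivity-equation Jacobians, tenfold damping updates,
and component-wise relative step tolerances (a norm-based step
tolerance silently freezes small-scale parameters when others are of
order 10⁷).

## Synthetic-data scenarios

The registry (`load_scenario`) encodes the benchmark experiments with
their published constants:

* `table1_{A..D}_{n21,n51}` — scalar exponential model x' = θx at the
  four corners (ξ₀, θ₀) ∈ {0.5, 1} × {−1, 1}, equidistant designs on
  [0, 10], σ = 0.05, 500 replicates.
* `table2_{n21,n51}` — Lotka–Volterra predator–prey, ξ₀ = (1, 0.5),
  θ₀ = (0.5, 0.5, 0.5, 0.5), σ = 0.05 on both states, 500 replicates.
* `table4_n{250,500,1000}_s{01,02,03}` — the true-variance study for
  the linear model at ξ₀ = θ₀ = 1 and σ ∈ {0.1, 0.2, 0.3}.  The time
  horizon is [0, 1]: every published cell of that study matches the
  closed-form information on a unit interval (and cannot be produced
  on [0, 10], where the asymptotic SD would be ~3·10⁻⁵).
* `table6` — nitrogen-oxide kinetics x' = θ₁(126.2−x)(91.9−x)² − θ₂x²,
  ξ = 0 estimated, 21 times on [0, 40], noise variance 0.25.
* `table9_{a002,a010}` — the five-state α-pinene isomerization network
  with known initial values (88.35, 7.3, 2.3, 0.4, 1.75), the eight
  published design times up to 36 420 s, and per-state noise SDs
  a × (44.68, 36.41, 4.96, 1.63, 12.41).  Inference uses the pooled
  σ̂², which under the heteroscedastic truth widens the intervals of
  the small-signal channels (θ₃..θ₅ over-cover) and narrows those of
  the large ones (θ₁, θ₂ under-cover) — the characteristic published
  coverage split.
* `robertson` — the stiff kinetics benchmark, θ₀ = (10⁴, 0.04, 3·10⁷),
  known ξ₀ = (1, 0, 0), 21 times on [0, 10], 100 replicates, BDF
  integration.  The noise level "0.01 times the mean values of the
  true solutions" is implemented as per-state SD = 0.01 × the time
  average of that state's trajectory; of the possible readings this is
  the only one under which the rates are recoverable at all (reading
  it as a variance makes the x₂ channel pure noise).
* `goodwin_s{001,015,025}` — the partially observed oscillator, 50
  equidistant times on [0, 80] (the published description does not fix
  the grid type; an i.i.d.-uniform design is available as an option),
  x₃ unobserved, (θ₁, θ₅) estimated.

Datasets are generated by integrating the truth at rtol 10⁻⁸ and
adding independent Gaussian noise; each (base seed, scenario,
replicate) triple seeds an independent `numpy` generator stream, so
runs are reproducible and replicates are exchangeable across workers.

What the generator does *not* emulate: correlated or heavy-tailed
measurement error, observation times informative about the state,
partially missing individual readings (missingness is whole-state),
model misspecification, or positivity constraints on concentrations
(noise can push small states negative, as in the published setups).
Passing tests therefore demonstrate statistical correctness of the
estimator under the stated error model, not robustness to real
laboratory artifacts.

## Numerical choices and problem sizes

* Integration: adaptive explicit Runge–Kutta (DOP853) at rtol 10⁻⁸ /
  atol 10⁻¹⁰; BDF with analytic state Jacobian for models flagged
  stiff.
* Quadrature: trapezoid on the smoothing grid for the preliminary
  criteria; 1001-point trapezoid (or exact design points) for the
  information integral.
* Second derivatives: analytic for the linear and nitrogen-oxide
  models; elsewhere central finite differences of the analytic
  Jacobians with step 10⁻⁵(1 + |value|).
* Degenerate inputs: all-missing observations contribute zero to the
  score; singular local windows, degenerate preliminary designs and
  integrator blow-ups at a candidate bandwidth skip that candidate;
  estimation aborts only when every candidate fails.
* Monte-Carlo sizes follow the published studies (500 replicates, 100
  for Robertson and Goodwin).  The asymptotic-efficiency and normality
  property checks use 400 replicates at n = 1001, and the
  √n-consistency check 200 replicates per sample size — sizes chosen
  so the checks complete in minutes while keeping the Monte-Carlo
  error of each assertion well inside its tolerance.

## Known limitations

* The one-step correction is only as good as the preliminary's
  attraction basin; for flat likelihood valleys (Robertson's (θ₁, θ₃)
  ridge) the damped update intentionally stays near the preliminary,
  and point estimates inherit its spread.  The Robertson θ₂ intervals
  consequently cover ~0.85–0.90 rather than the nominal 0.95: the
  pooled σ̂² plug-in understates the sandwich variance of the
  unweighted estimator under heteroscedastic noise.
* The SME requires a usable derivative estimate and degrades on sparse
  designs; the integral estimator is the default for that reason.
* Identifiability is assumed, not checked: a rank-deficient information
  matrix surfaces as a singular-information error at interval
  construction, not earlier.
* Bandwidth multipliers are rescaled linearly with the horizon; for
  designs whose information is concentrated on a small sub-interval a
  user-supplied grid will do better.
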