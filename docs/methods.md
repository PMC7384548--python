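# Methods

## Setting and estimands

Two randomized trials share a comparator: an *AB* trial with individual
patient data (IPD) and an *AC* trial known only through published
aggregates — covariate means (and variances), the relative effect
d̂_AC on its link scale with a standard error, and optionally the
absolute outcome on *C*. The package estimates the *marginal* contrast of
*C* vs *B* **in the AC population**, the population in which d̂_AC was
measured. This choice matters for non-collapsible scales (logit): the
synthetic-data truth is likewise defined as the marginal contrast in the
AC population, so estimator and estimand match by construction.

Anchored mode differences out the shared comparator,
d̂_BC = d̂_AC − (g(ŷ_B) − g(ŷ_A)), and requires only effect modifiers to
be balanced. Unanchored mode, d̂_BC = g(ȳ_C) − g(ŷ_B), additionally
requires all prognostic factors to be balanced; every unanchored result
carries a warning string saying so.

## Weight estimation

Per-subject moment functions are centered at the aggregate targets:
`x − μ` for a mean constraint and `x² − (σ² + μ²)` for a variance
constraint. Centering the *squared covariate at the target second raw
moment* (rather than squared deviations at σ²) keeps every constraint
linear in the weights, which is what makes both objectives convex with a
unique common minimizer; it is also the construction under which the
equivalence identity below is exact. The alternative dialect (centering
squared deviations from the weighted mean) is deliberately not offered.

Both estimators are exponential tilts `w_i ∝ w⁰_i exp(z_iᵀα)`:

- `H_MM(α) = Σ exp(z_iᵀα)` — method of moments, uniform base weights;
- `H_EB(α) = log Σ w⁰_i exp(z_iᵀα)` — entropy balancing, the
  unconstrained dual of minimizing Σ w_i log(w_i/w⁰_i) subject to
  `Zᵀw = 0`, `Σw = 1`.

With uniform base weights `H_EB = log H_MM − log N` identically, so the
two routes share their minimizer and their first-order condition — the
weighted moment columns average to zero, i.e. exact balance.
`check_equivalence` certifies this per instance by (a) probing the
identity at random α and (b) solving by both routes and comparing weights
elementwise. The two routes really are distinct code paths (different
objective, gradient, Hessian, and iterate sequence), so the certificate
is informative rather than tautological.

Non-uniform base weights generalize the entropy route only; the
method-of-moments objective has no base-weight analogue and rejects them.
Base weights are normalized internally (any positive rescaling is
equivalent) and are the fixed point of the solver when the targets equal
the base-weighted sample moments.

## Solver

Both objectives are smooth and strictly convex on the span of a
non-degenerate Z, with cheap analytic Hessians at MAIC-typical dimensions
(p ≤ ~10). The solver is damped Newton from α = 0 with Armijo
backtracking. Near the optimum the Armijo decrease (~‖g‖²/2) falls below
the floating-point resolution of the objective while the Newton step
still contracts the gradient quadratically; a step is therefore also
accepted when it at least halves the gradient max-norm without materially
increasing the objective. This reaches gradient norms near machine
epsilon in 2–6 iterations and avoids the classic stall at ~1e−8.

Numerical choices:

- columns of Z are standardized (sample sd) for conditioning; α is
  reported on the raw scale and weights are invariant to the rescaling;
- exponentials go through shift-guarded log-sum-exp; the raw-scale
  method-of-moments objective raises a numeric error if its *value*
  overflows (the log-scale route cannot);
- convergence: gradient max-norm ≤ 1e−10 on the standardized scale
  (relative to the objective value for the raw-scale objective, which
  makes the two stopping rules measure the same residual imbalance);
  max_iter 500; both surfaced as arguments;
- feasibility is checked before solving: each target must lie strictly
  inside the open range of its sample moment (a weighted mean of strictly
  positive weights cannot reach the hull boundary). A covariate constant
  at its target is dropped as trivially balanced, with a warning; one
  constant away from its target is an error naming it.

## Uncertainty

The bootstrap resamples subjects with replacement within each arm,
rebuilds the centered columns, re-solves the weights, and re-forms the
contrast, so weight-estimation noise propagates into the SE. Replicates
that fail (infeasible resample, non-convergence) are dropped and counted;
more than 20% failures aborts with a poor-overlap diagnosis. In anchored
mode the reported SE is `√(se_boot² + se_AC²)` (independent trials), and
the percentile interval additionally draws d̂_AC ~ N(d̂_AC, se_AC²) per
replicate so both noise sources enter the interval; se_boot is reported
separately. The bootstrap was chosen over a sandwich variance because it
handles both solver routes and the within-arm renormalization without
extra derivation; treating the weights as fixed would understate the SE.

## Synthetic scenarios

`simulate_scenario` draws an AB trial (1:1 randomized) and a large AC
trial (default n = 100 000, so aggregate sampling noise is negligible
next to AB noise), summarizes the AC trial into the aggregate-target
structure, and returns the exact truth: closed form for gaussian
outcomes, a seeded 10⁶-draw Monte Carlo integral of the marginal log odds
ratio for logistic outcomes. The default demo scenario has one normal
effect modifier shifted by 1 sd between populations (interaction −0.3
with treatment B on the log-odds scale), one balanced bernoulli
covariate, and a logistic outcome with intercept −0.5, main effects
(0.5, 0.3), and treatment effects δ_B = −1.0, δ_C = −0.5. These values
are the package's own choice of a realistic moderate-effect-modification
setting; under them the naive indirect comparison is biased by ≈ 0.27 on
the log-odds scale while the adjusted estimator's bias is below 0.01
(500 replicates at n_AB = 2000 — the sizes used by the bias study and the
acceptance script).

Because the shifted covariate is normal with equal variance in both
populations, an exponential tilt on its mean matches the whole
distribution, so mean-matching suffices for consistency in the demo. Real
data offer no such guarantee: unmodeled distribution differences beyond
the matched moments, measurement error, and missing effect modifiers are
all outside what the generator emulates, so passing tests demonstrate
correctness of the estimator under its assumptions, not robustness to
their violation. The generator also does not produce survival outcomes or
treatment switching; non-uniform base weights are attached ad hoc
(log-normal) purely to exercise that pathway.

## Design choices left open elsewhere

- Which moments to match is exposed per covariate (means, or means and
  variances); the default is means-only, logged. Binary covariates are
  matched as proportions only — their variance is a function of the mean,
  and a variance target for them is rejected at configuration time.
- Missing covariate values are a hard error, never imputed.
- Weights are normalized to sum to 1 internally; the CLI also writes a
  column rescaled to sum to N, the convention applied users expect.
- `maic run` defaults to solving by both routes and embedding the
  equivalence certificate in the results; the marginal cost is one extra
  convex solve.
- Entropy-optimality is verified against an independent closed-form
  oracle (projection of uniform weights onto the constraint set in the
  Euclidean metric), applicable whenever that projection is strictly
  positive.

## Known limitations

- Two IPD arms only; no multi-arm or network structure beyond the
  two-trial contrast.
- No survival/time-to-event outcomes.
- The aggregate trial's covariate summaries are treated as exact;
  uncertainty in published means/variances is not propagated (the
  generator can be configured with a small AC trial to study this, but
  the estimator does not model it).
- Percentile bootstrap intervals can undercover at small N or extreme
  weight concentration; the effective sample size and the bootstrap
  failure fraction are the intended diagnostics.
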