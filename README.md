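# maic

Matching-adjusted indirect comparison (MAIC) for evidence synthesis, with
weight estimation by **method of moments** and by **entropy balancing** —
two routes that this package implements as genuinely separate convex
solvers and certifies, numerically and on your own data, to yield
identical weights.

## The problem

Health-technology assessment routinely needs the relative effect of two
treatments *B* and *C* that were never compared head-to-head but share a
common comparator *A* in separate trials. The standard (Bucher) indirect
comparison,

    d̂_BC = d̂_AC − d̂_AB ,

is biased when the two trial populations differ in *effect modifiers* —
covariates that change the magnitude of a relative effect. When
individual patient data (IPD) are available from the *AB* trial but only
published aggregates from the *AC* trial, MAIC reweights the IPD so its
covariate moments match the *AC* aggregates, then compares effects in the
matched population.

## The estimator

With covariates centered at the *AC* targets (so the target means are 0),
both weight-estimation approaches are exponential tilting
`w_i ∝ w⁰_i exp(z_iᵀα)` over the centered moment matrix `Z`, differing
only in the objective minimized over α:

- method of moments: `H_MM(α) = Σ_i exp(z_iᵀα)`
- entropy balancing (dual of the KL projection onto the moment
  constraints, base weights `w⁰`): `H_EB(α) = log Σ_i w⁰_i exp(z_iᵀα)`

With uniform base weights, `H_EB(α) = log H_MM(α) − log N` for every α, so
the minimizers — and hence the normalized weights

    w_i = exp(z_iᵀα̂) / Σ_u exp(z_uᵀα̂)

— coincide exactly. A practical corollary: standard MAIC weights are as
close to uniform as the moment constraints allow (in Kullback–Leibler
divergence), the "optimality" often attributed to entropy balancing
alone. `check_equivalence` certifies both facts on any instance;
non-uniform base weights (e.g. from a prior treatment-switching
adjustment) are supported through the entropy-balancing route.

Weighted arm means `ŷ_k = Σ y_i w_i / Σ w_i` (within-arm renormalization)
feed either the **anchored** contrast `d̂_BC = d̂_AC − (g(ŷ_B) − g(ŷ_A))`
or the **unanchored** contrast `d̂_BC = g(ȳ_C) − g(ŷ_B)` on an identity,
logit, or log link scale `g`. Standard errors come from a stratified
bootstrap that re-solves the weights per replicate, plus the reported
*AC* variance in anchored mode.

## Worked example

Simulate a two-trial scenario whose populations differ by one standard
deviation on a normal effect modifier (logistic outcome, interaction
γ_B = −0.3), then run the full pipeline:

```sh
maic simulate --out-dir demo --seed 42 --n-ab 500 --n-ac 20000
maic run --ipd demo/ipd.csv --target demo/target.yaml \
         --out-dir out --n-boot 500 --seed 1
```

`out/results.json` from this exact invocation contains (abridged):

```
d_AB_adjusted : -1.2323          # B vs A, logit scale, in the AC population
d_BC          :  0.7178          # C vs B = d_AC − d_AB
se_d_BC       :  0.3002          # bootstrap + reported AC variance
ci            : [0.1579, 1.3081] # 95% percentile interval
ess           :  189.0           # effective sample size of 500 weighted subjects
balance: x1.mean delta 1.5e-14, sex.mean delta 1.1e-15
equivalence: max_identity_gap 8.9e-16, max_weight_discrepancy 1.2e-12
```

The generating truth for this scenario (`demo/truth.json`) is
`d_BC = 0.5338` on the log-odds scale: the interval covers it, while the
naive comparison is biased upward by ≈ 0.27 (see the simulation below).
The balance deltas show every matched moment reproduced to solver
precision, and the equivalence block is the built-in certificate that the
method-of-moments and entropy-balancing solutions agree on these data —
`maic run` defaults to `--method both`, so this theorem is re-verified on
every analysis. `maic check-equivalence` runs the same certification over
a randomized grid of instances.

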