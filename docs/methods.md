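# Methods

## Model

All fitted models are exponential-family log-linear models for a vector of
k categorical variables with codes 0..mᵢ. The subpopulation model over a
support B assigns

    P(Y = y | B) = exp f(y; θ) / κ_B(θ),   κ_B(θ) = Σ_{y∈B} exp f(y; θ),

with f linear in θ: f(y; θ) = x(y)′θ for a family-specific design row x(y).
The analyst chooses B: the observed patterns O, the full Cartesian set A,
O plus hand-picked extra patterns, or the patterns with frequency ≥ n₀.
O ⊆ B is required at fit time. Zero-count members of B are retained — they
enter κ_B and therefore change the fit; this is the mechanism by which
support choice expresses structural-zero assumptions.

Built-in families and their free-parameter counts e (the normalizing
intercept δ = ln(n/κ_B) is never counted):

| family | design row | e |
|---|---|---|
| saturated | pattern indicators over B | \|B\| − 1 |
| two_way (order 1) | dummy main effects | Σmᵢ |
| two_way (order 2) | + all pairwise dummy products | Σmᵢ + Σ_{i<j} mᵢmⱼ |
| ising (binary) | yᵢ and yᵢyⱼ | k + k(k−1)/2 |
| epcm / extended_rasch | dummies + C(t, r), r = 2..k, t = Σyᵢ | Σmᵢ + k − 1 |
| cn_er (binary) | yᵢ and t(t−1)/2 | k + 1 |
| custom | user callable | declared |

Identification uses reference-cell coding (category 0; for the saturated
family, the first pattern of B in canonical order). The paper-style
sum-zero coding of the saturated model is available as an option; the test
suite verifies both codings give identical fitted probabilities. Bilinear
association structures (log-multiplicative models, conditional multinormal
partial credit) are out of scope: their estimation is not a plain
log-linear maximization.

## Estimation

The multinomial log-likelihood l(θ) = Σ_O n_y f(y;θ) − n ln κ_B(θ) is
concave; the primary maximizer is a damped Newton iteration with analytic
gradient X′(c − n·p) and Hessian −n X′(diag(p) − pp′)X, started at θ = 0
(the uniform distribution over B, a safe interior point). Convergence is
declared at gradient max-norm ≤ 1e-9 or relative log-likelihood change
≤ 1e-12 (with a residual-gradient check ≤ 1e-6); at most 500 iterations;
step halving (≤ 40 halvings) guards the ascent. Non-convergence is flagged
on the result and warned about, never silently ignored. η = Xθ is centered
by log-sum-exp before exponentiation so κ_B is finite far from the
optimum. The equivalent Poisson log-linear route ln μ_y = δ + f(y; θ)
(fitted via a GLM) is exposed as `method="poisson"`; both routes solve the
same estimating equations and the suite checks agreement to 1e-6.

Aliased design columns on the bound support (e.g. an item constant on B, or
an association column collinear with main effects inside a small group) are
detected by a greedy Gram–Schmidt pass against the intercept (threshold
1e-8 relative to the column norm) and dropped; the result records the
estimable mask and the *effective* e, which all df formulas downstream use.
Saturated fits use the closed form π̂ = n_y/n (refusing supports with
zero-count cells, where the MLE is at the boundary).

Standard errors come from the subpopulation Fisher information
I_B(θ̂) = X′(diag(p̂) − p̂p̂′)X as sqrt(diag((n I_B)⁻¹)); for this family
observed and expected information coincide. The simulation harness verifies
that the average squared SE tracks the empirical estimator variance.

The two partition-based enlargements are fitted by the same machinery:
groupwise (first generalization) as g independent maximizations over the
B_p with their own aliasing checks; common-θ (second generalization) as a
single Newton iteration on the pooled gradient/Hessian with one intercept
per group, aliasing judged against the span of the g group indicators. A
partition group without observations is an error (its likelihood term is
undefined); singleton groups are legal and contribute zero log-likelihood
and zero effective parameters.

## Tests

CS and LRs use df = |B| − 1 − e (effective e). Both refuse to run when more
than 20% of expected counts fall below 5 — the regime where they are far
from χ² — unless forced; the Monte-Carlo harness forces them, since their
miscalibration under sparsity is itself a finding the harness reproduces.
The partition tests use

    LR1  = −2[ln L̂_B − (Σ_p ln L̂_p + Σ_p n_p ln(n_p/n))],  df = Σ_p e_p + (g−1) − e
    LR2  = −2[ln L̂_B − (ln L̂_C + Σ_p n_p ln(n_p/n))],      df = e_C + (g−1) − e
    LR12 = −2[ln L̂_C − Σ_p ln L̂_p],                        df = Σ_p e_p − e_C

(nominally (g−1)(e+1), g−1, and (g−1)e; the effective forms absorb
per-group non-estimability, and both values are reported). LR1 = LR2 + LR12
and df additivity hold identically. p-values are χ² upper tails; df = 0
yields p = 1. Statistics are clipped at 0 with tolerance 1e-10.

## Prediction and cross-validation

Out-of-sample predicted frequencies are n̂_y = n₀ · exp f(y;θ̂)/κ_{B₀} over
a target support B₀. g-fold CV uses the partition groups as folds: fit on
D_p = B \ B_p, score the held-out patterns, default scaling n over B (the
alternative n_p over B_p is a flag), overall score Σ_B (n_y − ñ_y)²/|B|.
Folds with rank-reduced fits proceed with a logged warning, mirroring the
estimation policy.

## Synthetic-data generators

The simulator emulates the study conditions exactly: it enumerates the true
support S, computes exp f(y;θ₀)/κ_S with log-sum-exp centering, and draws n
i.i.d. categorical samples — no MCMC, valid because every built-in
condition has |S| ≤ 1024.

Generator defaults (binary items):

* cn-ER: β = (−3.5, −2.5, −1.5, −0.5, 0.5) for k=5;
  β = (−5.0, −4.5, …, −0.5) for k=10; σ₂ = 0.63.
* Ising: same β; σᵢⱼ ~ Normal(0.30, 0.5) for k=5, Normal(0.30, 0.1) for
  k=10, drawn **once per configuration** and held fixed across replicates
  so that bias against θ₀ is well defined. Association scales of order 30
  would concentrate essentially all probability on the all-ones pattern
  (a degenerate |O| = 1 regime); the weak-association scale is the one
  that produces the observed-pattern counts the study conditions are
  defined by. At the k=5 scale the resulting median |O| ≈ 22 at n = 250;
  the k=10 draw Normal(0.30, 0.1) yields a sparser pattern spectrum
  (median |O| ≈ 56 at n = 250) and is a known limitation of this
  parameter reading.
* Restricted true supports drop the lowest-probability patterns of A down
  to a target cardinality (ties broken by canonical pattern order):
  |S| = 15 / 19 for k=5 cn-ER / Ising, 202 / 198 for k=10.

What the generators do *not* emulate: latent-trait response processes,
within-subject dependence beyond the specified log-linear associations, or
measurement error in the codes. A passing harness therefore certifies the
estimation and testing machinery under the stated models, not robustness
to real-data violations of them.

## Monte-Carlo harness

`run_condition` draws R replicates (default 2,000 — roughly a fifth of a
full-scale 10,000-replicate study, chosen to keep a condition in the tens
of seconds on one CPU; the bundled comparisons carry the matching binomial
band ±3·sqrt(p(1−p)/R)). Per replicate it tabulates O, fits under each
requested support policy (B = O and, when A is materializable, B = A),
draws a fresh random g = 2 partition (re-drawn until every group contains
an observed pattern), runs all five tests at the nominal level (.05), and
accumulates estimator summaries. Replicates that fail to converge or have
non-estimable parameters are excluded from the bias/MSE/variance averages
and counted; test decisions always count. The MSE decomposition
avg MSE = avg var + avg bias² holds per parameter by construction. Power
runs (generator family ≠ fitted family) skip the bias summaries, which are
undefined under misspecification. Per-replicate seeds spawn from the root
seed, so any replicate is individually reproducible.

## Numerical and design choices

* Pattern order is lexicographic with the last variable fastest; all
  constructors emit it, making runs byte-reproducible.
* Random partitions assign i.i.d. uniform group labels and redraw (≤ 1000
  times) on empty groups — the minimal reading of "randomly assigned";
  balanced assignment is deliberately not imposed. Size-balanced behavior
  can be had through the percentile scheme.
* The full-support enumerator refuses to materialize more than 10⁶
  patterns (configurable); size queries are closed-form.
* Saturated fits on B = O use the closed form rather than the optimizer.
* The top-order association of the extended partial credit family may be
  inestimable on small supports; this is handled by the generic rank
  diagnostics rather than assumed away.

## Known limitations

* No regularized or pseudo-likelihood estimation; no Bayesian fitting.
* No exact/Monte-Carlo conditional p-values for the sparse regime — the
  partition tests are the offered remedy.
* Supports too large to enumerate cannot be simulated from (no MCMC path).
* The k=10 Ising generator reading is uncertain (see above); all bundled
  quantitative comparisons use k=5 conditions.
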