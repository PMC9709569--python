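# Methods

## Model

The generative model is a p-dimensional Ornstein–Uhlenbeck (OU) process
`dx_t = P(x_t − m)dt + D dW_t` whose drift has reduced rank: `P = ab′`
with `a, b ∈ R^{p×r}`, `b′a` nonsingular and all its eigenvalues with
strictly negative real part.  Under these conditions the process is null
recurrent with exactly `p − r` stochastic trends and `r` mean-reverting
combinations `b′x`.  Observed at equidistant times with timestep Δ the
process satisfies a VAR(1) with `A = e^{PΔ}`, `μ = (I − A)m` and
`Σ = ∫₀^Δ e^{uP} DD′ e^{uP′} du`, written as the vector error-correction
model (VECM) `Δx_n = μ + Πx_{n−1} + ε_n` with `Π = A − I = αβ′` of the
same rank as `P`.  The rank trichotomy matters for interpretation: `r = 0`
is a set of p random walks, `r = p` an asymptotically stationary system,
and `0 < r < p` the cointegrated case the package targets.

Trials (epochs) are treated as independent realizations of one VECM.
Estimation pools over trials: grand-mean centering of increments and lags
over *all* trials and samples (per-trial centering would change μ̂ and is
deliberately not done), product-moment matrices `S00, S01, S11` with
denominator `Ntot = Σ_m (N_m − 1)` increment/lag pairs, and the
generalized eigenproblem `λ S11 v = S01′S00⁻¹S01 v`.  Increment/lag pairs
never straddle a trial boundary.

## Numerical choices

- **Σ integral.** The discretization covariance is computed exactly by
  the Van Loan block-matrix exponential (`expm` of
  `[[−P, DD′], [0, P′]]·Δ`), which is well defined when P has zero
  eigenvalues, where a Lyapunov solve would degenerate.  A
  composite-Simpson quadrature oracle backs it in the tests.
- **Eigenproblem.** Solved by whitening: Cholesky `S11 = LL′`, symmetric
  eigendecomposition of `L⁻¹S01′S00⁻¹S01L′⁻¹`, back-transform.  This
  yields the normalization `v_i′S11v_j = δ_ij` directly.  Eigenvalues are
  sorted descending with a stable sort (ties keep original order) and
  checked against [0, 1]; all p pairs are returned, including degenerate
  λ = 0 vectors.
- **Sign convention.** The sign of a cointegration vector is meaningless;
  for determinism each eigenvector's largest-magnitude entry is made
  positive.
- **Singularity policy.** A condition number above 1e10 in `S00` or `S11`
  raises an error naming the matrix — it almost always means a redundant
  common-average reference channel was not dropped.  No silent
  pseudo-inverses.
- **Likelihood.** The Gaussian conditional log-likelihood of increments
  given lags; the `−(Ntot·p/2)log 2π` constant is off by default and on
  for the per-trial classifier feature `d_m` so each term is a true
  log-likelihood.  Both models in any difference must use the same flag;
  with equal dimensions the constant cancels.
- **Degenerate eigenvalues in rank statistics.** λ is clamped to
  `[0, 1 − 1e−12]` before logs so numerically degenerate values cannot
  produce −∞; an exact λ ≥ 1 is an error.

## Common-average reference

Zero-sum data satisfy `S11·1_p = 0`, so estimation runs on `p − 1`
channels (default: the last channel dropped, configurable by label).  The
reduced β is re-expanded by appending the free constant
`c_j = −(1/p)Σ_i β_ij` per column — the norm-minimizing choice; any
constants may be supplied.  α, Σ and μ of the expanded model are
re-estimated from the full p-dimensional closed forms with the expanded β
(not by expanding α).  Raw `Π̂` entries are basis dependent across dropped
channels; only the product `Π̂x_{n−1}` is invariant, and
`check_invariance` verifies it together with the row-shift invariance
(`Π̂ + d·1′` acts identically on zero-sum data).  Likelihood-based
quantities (Chow tests, `d_m`) are computed in the reduced dimension,
which is also the dimension entering degree-of-freedom formulas.

## Regularized loadings

With β̂ fixed, the elastic-net objective on α separates across channels,
so each row is an ordinary elastic-net regression of that channel's
centered increments on the r stationary predictors `u = β̂′z1`; the rows
are solved by scikit-learn's coordinate descent (tolerance 1e−10), with
closed forms at γ = 0 (least squares) and ω = 0 (ridge).  Predictors are
not standardized — the Johansen normalization already puts them on unit
scale, keeping γ interpretable — and no intercept is fitted because the
streams are pre-centered.  Penalizing α cannot move the estimated
cointegration space.  The cross-validation tuner (`tune_penalty`,
trial-wise folds, one-step prediction MSE, ties broken toward the
sparser model) is this package's own procedure: how penalty values were
chosen in prior analyses of this kind is generally not documented, so
published values can also be supplied verbatim.

## Rank determination

Four diagnostics are computed and weighed jointly rather than combined
into one test, because asymptotic critical values for the trace and
maximum-eigenvalue statistics exist only for small dimensions and
bootstrap nulls are computationally prohibitive; the statistics are
therefore reported raw, without p-values.

The rank selection criterion (RSC) counts eigenvalues of `Z0′P_{Z1}Z0`
at or above `θ = 2(p+q)/(p(Ntot−q)) · RSS_p`, with q the SVD rank of the
stacked lag matrix.  Written with normalized product-moment matrices this
means comparing `Ntot·eig(S01S11⁻¹S10)` against θ: that scaling is pinned
by the exact equivalence with the rank-penalized least-squares estimator
`argmin RSS(Π) + θ·rank(Π)`, which the tests verify by brute force.  Two
behavioral notes: the threshold's theory assumes stationary regressors,
and under a pure random-walk null the criterion typically reports rank 1
rather than 0 (the spurious-regression eigenvalue sits at the same
`Ntot·λ = O(1)` scale as θ for any sample size); with genuine
cointegration present it recovers the true rank reliably at the tested
sizes.

Fold-based diagnostics partition **trials**, never time points, so the
pairing of adjacent samples survives and folds are independent.  The
matrix angle `Θ(U, V) = arccos(⟨U,V⟩_F / ‖U‖_F‖V‖_F)` (π/2 for a zero
argument, cosine clamped to [−1, 1]) compares a fold's rank-r network
against the full-rank network of the complementary folds; curves flatten
beyond the true rank.  CV-MSE divides each fold's summed p-dimensional
squared error by the fold's sample count without a 1/p factor — the
convention is stated here because either choice only rescales the curve.

## Structural (Chow) test

`Q = −2[ℓ_pooled − ℓ_A − ℓ_B]` compares rank-r fits of two trial subsets
against a pooled fit, referred to `χ²` with `p(2r+1) − r²` degrees of
freedom (p = estimation dimension).  That count covers μ (p parameters)
and the rank-r matrix Π (`2pr − r²`), and presumes a common innovation
covariance under both hypotheses; the likelihoods are therefore profiled
with a single pooled `Σ̂_c = (N_AΣ̂_A + N_BΣ̂_B)/(N_A+N_B)` under the
alternative, which keeps the statistic calibrated (letting each subset
keep its own Σ would add p(p+1)/2 effective degrees of freedom and
invalidate the reference distribution).  The subset (μ̂_k, Π̂_k) come from
separate Johansen fits — not the exact joint MLE under common Σ, but the
difference is second order and the simulated null rejection rate at
nominal 0.05 lands near 0.06.  Penalized fits are accepted but flagged
non-calibrated, since the χ² theory assumes maximum likelihood.

## Outcome prediction

`d_m` contrasts two condition-specific VECMs on one trial's pre-stimulus
window (default 100 ms — one full period of 10 Hz activity; with a 256 Hz
timestep that is 26 samples giving 25 increments).  Fitting is
leave-one-trial-out: the held-out trial never contributes to the model of
its own class.  Both condition models use the same rank and penalty.
`d_m` then enters logistic regressions with the design covariates, all
categorical (treatment coding, first sorted level as reference; the
contrast type does not affect deviance, AIC, BIC or AUC).  Conventions:
df counts non-intercept parameters, `AIC = deviance + 2(df+1)`,
`BIC = deviance + (df+1)·log n` — for a binary response the saturated
log-likelihood is zero, so this AIC is the usual `−2ℓ + 2k`.  AUC uses
the midrank (Mann–Whitney) formulation, counting tied pairs as half;
separation is detected (diverging coefficients or non-convergence) and
flagged rather than silently returned.

## Simulator: what it emulates and what it does not

The generator draws stable rank-r OU systems (`b′a = −ρ(I + K′K/r)`,
ρ = 20 s⁻¹ by default, i.e. stationary directions decorrelating over tens
of milliseconds — the scale of fast electrophysiological transients),
discretizes them exactly at Δ = 1/256 s (the common downsampled EEG
rate), and evolves each trial independently from `x₀ = m + one innovation
draw` (least-squares fixed point in the trend directions; a burn-in
option exists, default 0, since no stationary initial law exists for
r < p — how null-recurrent trends should be initialized in finite trials
is a genuinely open choice and this one is ours).  Common-average data
are produced by simulating in p dimensions and projecting, mirroring how
re-referenced recordings arise, so Σ stays nonsingular pre-projection.
Per-trial generators are spawned from one root seed, making outputs
bitwise reproducible and independent of trial count.

The task design crosses 8 orientations × 2 contrasts × 4 durations × 12
repetitions (768 trials) with per-trial fixation duration (1.5–2.5 s in
0.1 s steps) and location; outcomes are Bernoulli with a logistic linear
predictor over those covariates and optionally `d`.

Not emulated: oscillatory spectral content (alpha rhythms), volume
conduction, artifacts, or channel-specific noise floors.  Passing tests
therefore demonstrate correctness of the estimators and calibration of
the tests *under the model class*, not robustness to real-EEG deviations
from it.

## Problem sizes used in the shipped checks

Statistical checks run at deliberately modest sizes chosen to make the
asymptotic claims visible with comfortable margins: Chow calibration at
p = 6, r = 2, 5 trials × 1000 increments per subset, 200 replicates;
subspace/rank recovery at p = 10, r = 3, 50 trials × 200 samples, 20
replicates; the end-to-end classifier at p = 5, r = 2, 80 trials of 40
samples.  The degrees-of-freedom and critical-value constants of the
64-channel analysis (59/60 retained channels, rank 15) are analytic and
computed exactly.

## Known limitations

- VAR lag order is fixed at 1 (higher orders are overparametrized at
  this dimension and break the direct OU correspondence); residual
  autocorrelation should be checked on real data.
- No critical values or p-values for trace/max-eigenvalue statistics.
- The Chow test's χ² reference assumes unpenalized fits and a common Σ.
- Only common-average referencing is handled; other reference schemes
  (e.g. linked mastoids) are out of scope.
- `Π̂` entries are interpretable only up to the reference-channel basis;
  report the invariant product or fix conventions when comparing fits.
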