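# Methods

This note records the statistical models implemented in `metabopca`, the
estimation algorithms and their numerical details, what the synthetic-data
generators do and do not emulate, and the design choices made where the
methodology left the design open.

## Models and estimation

### PPCA

The model x_i = W u_i + μ + ε_i with u_i ~ N_q(0, I) and ε_i ~ N_p(0, σ²I)
has marginal covariance C = WWᵀ + σ²I. The MLE is available in closed form
from the sample-covariance eigendecomposition (divisor n): σ̂² is the mean
of the p − q discarded eigenvalues — including the structural zeros when
n − 1 < p — and column k of Ŵ is the k-th eigenvector scaled by
√(λ_k − σ̂²). `ppca_closed_form` implements this directly and doubles as
the oracle against which the EM fitter is tested.

`fit_ppca` implements the EM algorithm: the E-step computes the latent
posterior moments E(u_i) = M⁻¹Wᵀ(x_i − μ) and E(u_iu_iᵀ) = σ²M⁻¹ +
E(u_i)E(u_i)ᵀ with M = WᵀW + σ²I; the M-step is the standard coupled
update W ← SW(σ²I + M⁻¹WᵀSW)⁻¹, σ² ← tr(S − SWM⁻¹W_newᵀ)/p. μ has the
exact MLE x̄ and is held there. All likelihood algebra runs in q-dimensional
space through the Woodbury and matrix-determinant identities
(log|C| = (p−q)log σ² + log|M|; C⁻¹ = (I − WM⁻¹Wᵀ)/σ²); no p × p matrix is
ever formed, so p in the hundreds costs nothing.

**Identifiability.** The likelihood is invariant to W → WR for orthogonal
R, and EM converges to an arbitrary rotation. Every fitted W is
canonicalized via its SVD to the principal-axes representative (columns
ordered by singular value, sign fixed so each column's largest-magnitude
entry is positive). This makes EM output match the closed form and
conventional PCA loadings. Consumers comparing loadings across fits
(jackknife, tests) must still align signs, because the identity of the
largest-magnitude entry is not stable under resampling; `align_loadings`
provides per-column sign matching (default) and full orthogonal Procrustes.

### PPCCA

Covariates enter through the latent prior u_i ~ N_q(δ_i, I), δ_i = αC_i,
leaving the conditional x_i | u_i untouched; the marginal is
N_p(Wδ_i + μ, WWᵀ + σ²I) and the posterior mean gains a covariate shift
σ²M⁻¹δ_i.

`fit_ppcca` uses an expectation/conditional-maximization scheme:

- W and σ² follow the Q-function (expected complete-data likelihood)
  updates, as in PPCA but with covariate-shifted posterior moments;
- α, μ and the column scale of W are then set by an exact conditional
  maximizer of the **observed** likelihood within the current principal
  subspace (an ECME step). Writing W = QB with Q orthonormal, the model
  restricted to the subspace says Qᵀ(x_i − μ) ~ N(BαC_i, BBᵀ + σ²I_q) — an
  ordinary multivariate regression. Its MLE is the least-squares
  coefficient matrix and the residual covariance; the MLE of the
  positive-semidefinite BBᵀ is the residual covariance minus σ²I,
  eigenvalue-clipped at zero, exactly as in the closed-form PPCA solution.

The ECME step exists because pure EM is impractically slow here: the
covariate term enters the posterior mean multiplied by σ², so a Q-based α
update moves by O(σ²) per iteration. Centred spectral-bin data are
precisely the low-noise regime where this matters — on the 18 × 189
fixture, plain EM was still ~25% short of the MLE in α after 5000
iterations, while the ECME variant converges in single-digit iterations.
Both schemes share their stationary points, and every step above is
monotone in the observed likelihood (verified by the trace invariant in the
test suite).

The α update solves the design-matrix regression with a pseudoinverse: a
rank-deficient design (e.g. an all-zero covariate column, which arises
naturally when a constant covariate is standardized) produces exact zeros
for the unidentified coefficients and a warning, rather than an error.
After convergence W is canonicalized and α is rotated by the same
orthogonal transform, leaving every δ_i invariant. The covariate
standardization constants (means/sds) are stored in the model; scoring
refuses covariates prepared under a different scaling.

### MPPCA

The mixture p(x_i) = Σ_g π_g N_p(x_i; μ_g, W_gW_gᵀ + σ²I) shares one σ²
across groups for parsimony. Fitting uses the two-cycle AECM algorithm:
cycle 1 treats the memberships z as missing and updates (π, μ_g) from the
responsibilities; cycle 2 treats (z, u) as missing and updates (W_g, σ²)
from responsibility-weighted latent moments. Responsibilities are computed
in log space with log-sum-exp; per-component densities use the same
q-space Woodbury forms.

Initialization is k-means on the data (default; Dirichlet-random
responsibilities optional) with 10 restarts, keeping the best final
likelihood. Per-group loadings are initialized from each group's **own**
members' eigendecomposition — the pooled PCA directions mostly track
between-group separation and are a poor start for within-group structure —
with the pooled residual scale as the starting σ², since a closed-form σ²
from a group of 8 samples against p > 150 bins is badly underestimated. A
start whose components collapse below two effective observations is
abandoned and redrawn; the fit fails only if every start collapses.
Hard clustering is by maximum posterior membership, ties to the lowest
group index.

### Model selection

BIC = 2ℓ − K ln n, higher better. Free-parameter counts are raw:
K = pq + p + 1 (PPCA), + q(L+1) (PPCCA), (G−1) + G(pq+p) + 1 (MPPCA); a
`rotation-corrected` convention subtracting q(q−1)/2 per loadings matrix
is available, since the two conventions can select different q.

The modified BIC evaluates the likelihood at a MAP fit: σ² gets a
conjugate inverse-gamma(shape a, scale b) prior and the σ² M-step becomes
the posterior mode (RSS/2 + b)/(np/2 + a + 1), which cannot reach zero.
Default prior: a = 3, b = 2·v̄ with v̄ the mean per-bin variance of the
centred data — weakly informative, mode at v̄/2, and numerically washed out
once np is a few thousand (the suite checks agreement with the plain BIC
to 0.1% at n = 500, and the near-flat limit a → 1, b → 0). The selection
grid fits each (q, G) cell twice — MLE for the plain BIC, then a MAP refit
warm-started from it — and flags the best cell per criterion; the modified
BIC is the criterion of record.

`proportion_variance` reports the conventional cumulative eigenvalue
ratio of the preprocessed data; the model-based alternative
tr(WWᵀ)/(tr(WWᵀ) + pσ²) is deliberately not the default so that reported
percentages match what PCA users expect.

### Jackknife

For each of the n leave-one-out datasets the relevant model is refitted,
warm-started at the full-data estimates (which cuts iteration counts from
hundreds to a handful; the suite verifies warm-started SEs match a
cold-started brute-force jackknife to 1e-5). Each W^{−i} is sign-aligned
per column to the full-data W before pooling — the single most consequential
choice in this module, since unaligned sign flips masquerade as enormous
sampling variability; Procrustes alignment is available but removes genuine
rotation variability from the SEs and is therefore not the default. For
PPCCA the sign flips are propagated to the α rows. SEs follow
√[(n−1)/n Σ(w^{−i} − w̄)²]; CIs are estimate ± 1.96·SE by default, with a
t-quantile (n − 1 df) variant available. A leave-one-out refit that fails
to converge is excluded with a warning if at most 5% of refits fail,
otherwise the jackknife aborts.

Downstream, `significant_loadings` returns the bins whose CI excludes zero
and whose |loading| exceeds a cutoff, sorted by magnitude;
`cutoff_frequency` tabulates the |loading| histogram and
retained-count curve from which an analyst picks the cutoff (none is chosen
automatically); `group_bin_tests` runs Welch (unequal-variance) t-tests per
selected bin with Benjamini–Hochberg correction across exactly the listed
bins. Welch and BH are the package's choices where the methodology says
only "t-test" and "correcting for multiple testing".

## Synthetic data

All generators are pure functions of their arguments including the seed.
Loadings are built by orthonormalizing a Gaussian matrix and scaling
columns to chosen norms — giving exact control of the population
eigen-spectrum (eigenvalue k is norm_k² + σ²) — and are emitted already in
canonical principal-axes form so fitted loadings are entrywise comparable
to the truth (up to column sign, which resampling can always flip).
Column norms² default to eigengap·(q, q−1, …, 1) on the data scale; they
are deliberately not tied to σ², so the signal subspace survives the
noiseless limit and, at σ² = 1, `eigengap` reads directly as the
signal-to-noise eigenvalue ratio.

Mixture group means sit at the vertices of a regular simplex embedded by a
random orthonormal map, so all pairwise distances equal
separation·√σ² exactly.

Two named fixtures emulate the shapes of real NMR studies:

- **urine-like** (18 × 189, 9 treated / 9 control): a two-dimensional
  latent structure with the treatment effect (gap 6 latent sd) loading on
  17 designated bins and a body-weight covariate (slope 3 per standardized
  unit) driving the second dimension through a disjoint block of 30 bins.
  Intensities are exponentiated Gaussians, exp(2 + 0.05·z): positive and
  mildly right-skewed like NMR bin intensities, while the small scale keeps
  the map nearly affine so the linear-Gaussian model is only mildly
  misspecified — a deliberate stressor. Bin labels follow a 0.04-ppm grid
  that skips the 4.0–6.0 ppm water region.
- **brain-like** (33 × 164, groups of 8/8/9/8): four well-separated
  regions (separation 12 noise-sd), q = 2 within-group structure.

What the generators do **not** emulate: NMR peak shapes, chemical-shift
variation across samples, baseline artifacts, heteroscedastic per-bin
noise, and correlated (non-isotropic) residuals. Tests passing on these
fixtures therefore demonstrate the estimators and the workflow logic, not
robustness to every artifact of real spectra.

## Numerical choices

- Convergence: Aitken's acceleration on the log-likelihood sequence — stop
  when the gap between the accelerated estimate of the limit and the
  current value falls below `tol` (default 1e-4; tightened to 1e-9…1e-12
  where tests require near-exact MLEs). Max 1000 iterations by default;
  non-convergence returns a flagged result with a warning rather than an
  exception.
- σ² is floored at 1e-10; hitting the floor flags the fit, and that flag is
  what the modified BIC exists to avoid.
- Log-density computations never form p × p matrices; mixture
  responsibilities normalize via log-sum-exp.
- Exact-eigenvalue test fixtures are built by whitening a random matrix and
  recoloring to a prescribed covariance, so eigenvalue assertions
  (e.g. {5, 3, 1, 1} → σ̂² = 1) hold to machine precision.
- CSV round-trips write floats with `repr` and parse with Python's
  correctly-rounded `float()`, so written datasets re-read bit-for-bit.

## Known limitations

- Missing values are rejected, not imputed; rows and columns must be fully
  observed.
- The jackknife CI for a covariate effect on a weakly separated latent
  dimension is mildly anticonservative: finite-sample mixing between
  nearly-tied principal axes makes the null-slope estimator heavy-tailed
  relative to its SE, so the false-positive rate on a null dimension runs
  a few points above the nominal 5% when adjacent latent variances are
  within a factor of ~2 (measured ~10–12% at n = 100 with a variance ratio
  of 2). Slope CIs on well-identified dimensions calibrate at 93–96%.
- Mixtures share one σ² by design (parsimony); per-group noise variances
  and per-group q are out of scope, as are mixtures of PPCCA.
- BIC consistency for q requires genuinely strong signal when n ≪ p: with
  raw parameter counting at n = 50, p = 100, signal eigenvalues only ~4×
  the noise are below the criterion's detection threshold, and reliable
  recovery of q needs eigenvalue ratios of order 20.
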