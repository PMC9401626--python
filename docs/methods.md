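# Methods

## Central composite design and concentration scaling

`doe.make_ccd` builds a CCD with three blocks, in deterministic order
(factorial in Yates standard order, axial pairs factor by factor, then
center runs; an optional seeded shuffle randomizes run order):

* **Factorial**: full 2^k for k ≤ 4; for k = 5–8 the half fraction whose
  last factor is the product of the others (defining relation I = AB...K).
  For six factors this is the 32-run resolution-VI fraction, the
  highest-resolution half fraction, under which every main effect,
  pure quadratic and two-factor interaction of the 28-term second-order
  model is estimable (verified by full column rank in the tests).
* **Axial**: 2k star points at ±α per factor. The default α = 2.366 is
  treated as a given design constant: it is the axial distance used with
  six-factor designs of this family, and standard orthogonal-α formulas do
  not reproduce it for any integer center-run count, so the package does
  not attempt to re-derive it. It doubles as the default radius of the
  optimizer's feasibility sphere.
* **Center**: `n_center` replicate all-zero rows, default 8 (user-set; the
  center replicate count is a free choice of the experimenter and only
  affects pure-error degrees of freedom, not estimability).

Concentrations map to coded units logarithmically:
`conc(x) = 10^(log10(√(lo·hi)) + x·log10(hi/lo)/2)`, so −1/0/+1 are the low
end, the geometric mean, and the high end, and equal coded steps are equal
fold changes. Both endpoints must be strictly positive; a zero dose has no
finite coded value, which is why factor ranges exclude 0. The inverse map
round-trips to < 1e−12 (property-tested).

## Response-surface models

Counts are fitted by OLS (statsmodels) on either the raw (`identity`) or
`log1p` scale; log1p uses the natural log and back-transforms as
exp(·) − 1, clipped at 0 since counts are nonnegative. The default
transform for counts is `log1p` — multiplicative biology, additive on the
log scale — but the choice is per-response configuration. Rank deficiency
is detected before fitting and reported with the names of the aliased
terms (pivoted-QR diagnosis). An all-zero response yields zero
coefficients with R² flagged undefined rather than an error.

Third-order terms are chosen by greedy forward selection on adjusted R²:
at each step the candidate with the largest improvement is added, ties
break toward the lowest canonical term order (sort by degree, then
lexicographic exponent vector), and selection stops when no candidate
improves the criterion by more than a configurable threshold (default 0).
Adjusted R² is the operationalization of "improves the fit"; any
information criterion would serve, but adjusted R² is the least surprising
for a designed experiment with a fixed run budget.

Coefficient tables (`response, term, coefficient, transform`) are written
with `repr`-level precision (≥ 17 significant digits) so write → read →
predict is lossless, and published coefficient tables can drive the
optimizer without the raw response data.

## Desirability optimization

Each response uses a one-sided maximize ramp: d = 0 below L, 1 above U,
((y − L)/(U − L))^w between. When L and U are not supplied they default to
the minimum and maximum predicted counts over the design points — the
least arbitrary [0, 1] anchoring available without further input, and both
are overridable. The overall objective is the geometric mean of the
individual desirabilities, so any response at zero desirability
annihilates the product (no solution is acceptable if one target
population is absent).

The search runs `n_restarts` (default 25) independent basin-hopping
searches of −D, each started from a point drawn uniformly in the ball
(direction = normalized Gaussian, radius = R·u^(1/k)). Local minimizations
are unconstrained Nelder-Mead; any candidate outside ‖x‖ ≤ R is radially
projected onto the sphere before evaluation, which preserves direction and
keeps every reported solution feasible. Inside the optimizer,
desirabilities are clipped to [1e−12, 1] so the log-mean stays finite and
informative on flat-zero regions; reported D values are unclipped. The
"top 5 most desirable solutions" averaged into the final optimum are the 5
best restart outcomes, not 5 distinct basins — with a smooth polynomial
objective restarts frequently find the same basin, and averaging near-
duplicates is harmless. Results are invariant to the order of the
desirability specs (they are sorted by response name internally) and fully
determined by the config seed.

## Limiting-dilution estimation

The estimator maximizes the binomial log-likelihood
`Σᵢ [negᵢ·(−f·nᵢ) + (posᵢ)·log(1 − e^(−f·nᵢ))]` over log f with a bounded
1-D Brent search on log f ∈ [−30, 0]. The Poisson form e^(−fn) is used
(rather than the exact Bernoulli (1−f)^n) because it is the single-hit
convention under which 1/f is the dose with failure rate e⁻¹ ≈ 0.37; the
synthetic generator deliberately uses the exact Bernoulli model so the
estimator's approximation gap is exercised by the tests (it is < 1% for
f ≤ 1/57). Datasets with no positive or no negative wells return a
boundary estimate with `converged=False` and an explicit flag instead of
an infinite frequency. The default 95% CI is Wald on log f using
numerically differentiated observed information (cheap, accurate for
well-powered designs); a profile-likelihood CI is available via
`ci="profile"` for sparse designs. The ">25 viable cells" positivity rule
used when scoring wells is metadata only: wells arrive pre-scored.

## Single-cell QC and notch score

QC removes cells with total counts > 36,000, detected genes > 6,000, or
mitochondrial fraction > 0.18 (all strict inequalities — boundary cells
are kept), then genes detected in fewer than 3 remaining cells.
Mitochondrial genes are identified by the configurable name prefix `MT-`.
The report itemizes removals per rule; QC is idempotent. Normalization
scales each cell to 10⁴ total counts and applies log1p (natural log).

The signature score ranks genes by mean normalized expression, cuts them
into `n_bins` (default 25) equal-size bins, and draws 50 control genes per
signature gene from the same bin, excluding all signature genes, without
replacement when the bin is large enough (otherwise with replacement,
flagged in the result). The per-cell score is the mean over signature
genes minus the mean over the pooled controls. Subtraction is the standard
bin-matched scoring convention; a ratio mode is available behind
`mode="ratio"` since "normalized to the average" can be read either way.
Controls are pooled across signature genes before averaging (variance
stability); both readings are linear in the data, so the null-zero
property holds either way. Under the null (signature statistically
identical to its bins) the mean score is ~0, and adding a constant δ to
the signature genes shifts the score by exactly δ — both are tested.
Condition comparison reports the fold change of mean scores (undefined and
flagged when a mean is nonpositive, since a ratio of signed means is not
interpretable) and a two-sided Mann-Whitney U p-value.

## Synthetic generators

* **Dose-response**: the true polynomial is evaluated at each coded design
  point, Gaussian noise of SD `noise_sd` is added on the *transformed*
  scale, and the value is back-transformed, clipped at 0 and rounded to an
  integer count. Putting the noise on the fitting scale makes OLS the true
  MLE, so coefficient-recovery tests are exact in expectation; rounding to
  integer counts is the one mismatch, and tests use surfaces large enough
  that it is negligible where exactness is asserted.
* **LDA wells**: each seeded cell is independently a hit with probability
  p, so negatives per dose are Binomial(wells, (1−p)^n). The exact model
  is used so the estimator's Poisson approximation is stress-tested.
* **Expression**: per-gene negative-binomial counts (gamma-Poisson, var =
  µ + αµ² with dispersion α = 0.1 by default — standard overdispersion for
  droplet data, near-Poisson as α → 0). Signature-gene means are
  multiplied by the condition effect; mitochondrial genes are rescaled to
  carry a target share (default 5%) of the per-cell total. QC violators
  are injected as extra cells engineered to exceed exactly one threshold
  (≈45,000 expected counts; a flat low-mean profile detecting > 6,000
  genes at < 36,000 total, which requires > 6,000 genes in the matrix;
  ≈30% mitochondrial reads) and are flagged in the cell ids.

No published noise model exists for any of these assays; the choices above
define the package's test conditions, not the biology. In particular the
expression generator omits library-size variation across cells, gene-gene
correlation, zero-inflation beyond NB, and batch structure, so passing
tests demonstrate correctness of the scoring machinery, not robustness to
every property of real droplet data.

## Problem sizes

The test suite and acceptance script run at desk scale by design: 52-run
six-factor designs; 200-replicate Monte-Carlo checks for OLS unbiasedness
and LDA coverage; 500 wells/dose × 4 doses × 20 replicate simulations per
frequency for the recovery targets; count matrices of ~10³ cells × 10²–10³
genes. These sizes put Monte-Carlo error well inside the asserted
tolerances while keeping the full suite under a minute.
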