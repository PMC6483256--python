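# Methods

This note documents the statistical model, the estimation choices, the
design of the synthetic-study generator, and the reasoning behind the
validation regimes. Everything here is implemented in `placloop` and
exercised by the test suite.

## Background model

For a bin pair `(i, j)` at genomic distance `d_ij` the raw contact count
`x_ij` is modeled as Poisson with rate

```
log λ_ij = β0 + β_f log(f_i f_j) + β_gc log(gc_i gc_j)
         + β_m log(m_i m_j) + β_IP log(IP_i IP_j) + β_d log(d_ij)
```

conditioned on `x_ij ≥ 1`, because zero-count bin pairs are never emitted
at kilobase resolution. The model is deliberately parameterized on the
*underlying Poisson rate* λ rather than on the zero-truncated mean
`μ = λ / (1 − e^{−λ})`: λ is the physically meaningful contact intensity,
the expected count `e_ij = λ̂_ij` is directly comparable to the rate the
generator planted, and the tail p-value

```
p_ij = P(X > x_ij | X ≥ 1) = sf(x_ij; λ) / (1 − e^{−λ})
```

follows without transformation. The denominator uses `−expm1(−λ)` so tiny
rates do not lose precision, and `scipy.stats.poisson.sf` carries the
numerator well past λ = 10³.

Covariates enter as the log of the *product* of the two bins' values:
equivalent to a shared coefficient on the two log-features, which halves
the parameter count and matches the symmetry of a contact. Records in
which any covariate product is non-positive or non-finite (a bin with no
fragment end, zero ChIP signal, undefined GC) are invisible to the assay
and excluded from both fitting and scoring.

### Estimation

Maximum likelihood per (chromosome, set) group via damped Newton
iterations, initialized from an ordinary Poisson GLM. With log link the
score contribution per observation is `x − μ` and the observed-information
weight `μ (1 − μ e^{−λ})`; convergence is declared when the relative
log-likelihood change drops below 1e−8. Covariates are mean-centered
during optimization for conditioning and the intercept un-centered
afterwards. A covariate that is constant within a group is
indistinguishable from the intercept; its coefficient is pinned at zero
and absorbed, keeping the fit defined for degenerate designs. Groups with
fewer usable records than coefficients raise `InsufficientDataError`
rather than returning a meaningless fit.

The implementation is cross-checked in the tests against
`statsmodels.discrete.truncated_model.TruncatedLFPoisson` (agreement to
2e−4 per coefficient) and, for the intercept-only case, against a
brute-force one-parameter MLE.

### Outlier re-fit and FDR

True loops inflate the background estimate. Bin pairs with first-pass
`p < 1/N` (N the group size) are treated as signal and excluded from a
single re-fit; the re-fitted model then yields `ẽ` and `p̃` for *all*
records, outliers included. When nothing is flagged the re-fit is the
identity, so `ẽ = e` exactly. Benjamini–Hochberg adjustment is applied
within each (chromosome, set) group by default (`fdr_scope="genome"` pools
per set across chromosomes).

AND and XOR sets are fitted separately because the ChIP pull-down
enriches them differently; NOT pairs are tabulated but never modeled —
contacts with no anchor in a ChIP peak are outside the assay's design.

## Interaction calling

A bin pair is significant when `x ≥ 12`, `x/ẽ ≥ 2` and `q < 0.01`
simultaneously. The count and fold floors are not redundant with the FDR
threshold: the ZTP tail test is discrete, so at small expected counts the
achievable p-values step coarsely and a borderline `q` alone would admit
low-count pairs whose calibration is poorest (see *Validation regimes*).

Significant pairs are clustered by connected components: `(i, j)` and
`(m, n)` are adjacent when they share a chromosome and both anchor offsets
— left-with-left and right-with-right, never crossed — are at most 15 kb.
Components of size one are singletons, kept only below FDR 1e−4; within a
cluster every member attaining the minimum FDR is a summit (ties produce
several). Output is an 11-field BEDPE: two BED intervals, raw count,
expected count, FDR, call type, summit flag.

## Synthetic-study generator

The generator's defaults are the study conditions used throughout the
tests; they were chosen a priori from the design considerations below,
not adjusted against test outcomes.

* **Genome and digestion** — random DNA with per-bin GC levels uniform on
  `gc_range = (0.30, 0.65)`; digestion by a 6-cutter whose default motif
  `GACGTT` contains three G/C and three A/T bases, so restriction-site
  density is approximately independent of the local GC level. With an
  AT-rich motif (e.g. GAATTC) fragment density anticorrelates with GC,
  making `log f·f` and `log gc·gc` collinear and inflating the variance of
  both estimates. The residual spread of `f` and `gc` across bins is what
  identifies `β_f` and `β_gc`.
* **Mappability** — per fragment end, Beta(2, 0.5): right-skewed (most
  ends map well) but with enough spread that `β_m` is identifiable.
* **ChIP enrichment** — short-range pairs with per-bin lognormal rate
  dispersion (σ = 0.8) at peak rate 200 and background 20; the `IP`
  covariate is then *measured* from those pairs via the feature pipeline,
  so the whole feature path is exercised end to end rather than drawn
  directly.
* **Counts** — per-distance-offset vectorized rates from the model above;
  `β0 = None` (the default) is calibrated so the mean background rate over
  AND/XOR candidates equals `mean_count` (4.0). Draws are plain Poisson
  with zeros dropped, which is exactly zero-truncated sampling conditioned
  on observing the pair.
* **Planted loops** — `loop_span × loop_span` blocks (2×2) whose rate is
  multiplied by `loop_fold` (6.0). Blocks are placed only on AND/XOR
  candidates whose background rate lies in `loop_rate_band` (0.75–1.5 ×
  `mean_count`), so the planted signal is a controlled *fold* over a
  typical background rather than an artifact of already-extreme rates, and
  seeds are separated by ≥ 50 kb so clusters remain distinct.

The generator emulates count statistics and covariate structure. It does
not emulate read-level noise (chimeric alignments, mapping errors,
distance-dependent artifacts beyond the power law), translocations, copy
number, or inter-chromosomal contacts — the preprocessing of those is
tested separately with `simulate_alignment_groups`, a closed-form
alignment-stream generator with known survivor counts per stage.

## Validation regimes

* **Coefficient recovery** uses a deep-count variant (`mean_count = 50`,
  d ≤ 180 kb, ~20,000 pairs, every bin a peak so all pairs form one AND
  group). Two considerations drive this: at mean count 4 the truncation
  correction is strong and slope noise is larger; and any slope error
  propagates into the intercept as `Δβ0 ≈ −Σ Δβ_k · mean(log covariate_k)`
  with covariate means of order 10, so an intercept tolerance of 0.05
  demands slope errors an order of magnitude smaller. Observed worst
  per-coefficient mean absolute error across 10 seeds: ≈ 0.03.
* **Null calibration** uses a deep-count configuration (λ of order
  hundreds, d ≤ 30 kb). For a discrete strict-tail test,
  `P(p < α) = sf(x0 − 1; λ)` for the smallest achievable step past α,
  which at λ ≈ 4 gives ≈ 0.022 for α = 0.01 — an intrinsic
  anti-conservativeness of small-count tail tests, not an implementation
  defect. At deep counts the steps are fine and the pooled fraction of
  null `p̃ < 0.01` lands within 3 Monte-Carlo standard errors of 0.01.
  The count ≥ 12 and fold ≥ 2 floors in the caller are precisely what
  protects the sparse regime from this discreteness in practice: at the
  default study scale, 10 no-loop simulations produce 0 calls under the
  default thresholds.
* **Loop recovery** runs at the default study conditions (background
  λ ≈ 4, fold 6) and demands per-seed sensitivity ≥ 0.9 with the 15 kb
  overlap slack; clustering is compared to a brute-force
  transitive-closure oracle on every instance.
* **Bias removal** checks on no-loop defaults that
  `|corr(log fold, log IP·IP)|` falls strictly below
  `|corr(log x, log IP·IP)|`. The normalized value retains a moderate
  *negative* association — a truncation effect: for small λ the observed
  count is at least 1, so `x/ẽ` is systematically large exactly where the
  rate (and hence IP) is small. The criterion is therefore a strict
  reduction, not zero correlation.

## Limitations

* One dispersion family: the Poisson assumption has no overdispersion
  parameter; heavily overdispersed libraries will show anti-conservative
  p-values that the count/fold floors only partially absorb.
* Chromosomes are fitted independently; very small chromosomes may raise
  `InsufficientDataError` and need the genome-wide FDR scope plus pooled
  fitting upstream.
* The ZTP tail p-value is anti-conservative at small expected counts by
  discreteness (see above); interpret `q` jointly with the count and fold
  thresholds rather than in isolation.
* The generator's genome is i.i.d. within GC blocks — no repeats, so real
  mappability structure is only mimicked distributionally.
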