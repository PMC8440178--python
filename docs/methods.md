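# Methods

## Data model

A *phenotype* is a (region, measure) pair. The default registry is the
Desikan–Killiany cortical parcellation (34 regions, left/right averaged —
hemispheres are not modeled because consortium tables report the mean of
left and right structures) crossed with {thickness, surface area}, plus 7
subcortical volumes: 75 phenotypes over 41 regions. Cortical regions admit
thickness and surface area only; subcortical structures admit volume only.
A custom atlas can be swapped in from a two-column TSV.

An effect-size profile is one disorder's covariate-adjusted Cohen's *d*
(case minus control, pooled-SD units) per phenotype. Values must be finite
with |d| < 5 (published case–control SMDs for brain structure are an order
of magnitude smaller); missing phenotypes are simply absent. Case/control
counts are carried **per measure type**, because thickness, surface area and
subcortical volume typically come from different site subsets; they are
needed only by Cochran's Q.

## Pairwise concordance

For each unordered disorder pair the profiles are aligned over the
phenotypes present in both (registry order, at least 3 required), giving
df = n_overlap − 2. With the default masks the overlaps are 75, 74 and 41,
hence df ∈ {73, 72, 39}.

* `correlate` computes the product-moment correlation; Spearman is the same
  statistic on average-ranked data. Both are offered because working groups
  report either depending on the output surface; the pairwise table
  defaults to Pearson and the correlation-of-correlations to Spearman.
* Analytic significance: se = sqrt((1−r²)/df);
  p = two-sided Student-t tail at t = r·sqrt(df/(1−r²)); |r| = 1 → p = 0.
* Multiplicity: Bonferroni with m = number of pairs by default (21 for 7
  disorders); m is configurable.
* Permutation p: one profile of the pair is shuffled uniformly (shuffling
  one side is statistically equivalent to shuffling both) n_perm = 10,000
  times; p = (1 + #{|r*| ≥ |r_obs|})/(n_perm + 1). The add-one estimator
  never returns 0 and its floor at 10,000 shuffles is 1/10,001 < 10⁻⁴.
  Ties are counted by comparing against |r_obs| − 10⁻¹², so the identity
  arrangement always counts. An exhaustive mode enumerates all n!
  permutations for n ≤ 8 and returns the exact proportion.
  No spatially constrained ("spin") null is provided: the joint
  thickness + surface-area set has no single spherical map to rotate.
* Determinism: per-pair shuffle streams are seeded from (master seed,
  CRC32 of the sorted pair labels), and each pair is aligned in sorted-label
  orientation before shuffling, so the table is invariant to disorder order
  in the panel.

## Correlation of correlations

The imaging similarity vector (pairwise r) and the genetic similarity
vector (pairwise rg) are aligned **by pair identifier**, never by position;
a set mismatch raises an error listing the difference. The association is
Spearman's ρ with a t-approximation p value on n_pairs − 2 df (an empirical
permutation over pair labels is available; at n = 21 the two agree
closely). Both p values ignore the dependence induced by pairs sharing
disorders and by overlapping control samples — a known limitation of
summary-statistic analyses; interpret p conservatively. Leave-one-out
recomputes ρ with each pair excluded (requires ≥ 5 pairs) to flag
single-pair leverage.

## Per-region statistics

* Sign test: exact two-sided binomial at success probability ½, doubled
  smaller tail capped at 1. Zeros (a disorder reporting exactly no
  difference) are excluded from the trial count and reported separately.
  With 7 disorders, unanimity gives p = 2·(½)⁷ = 0.0156 < 0.05, so
  "same sign in all disorders" is always a significant call at k = 7.
* Cochran's Q: inverse-variance weights from the standard large-sample SMD
  variance v = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)) using the measure-specific
  counts; Q is chi-square with k − 1 df under homogeneity. Disorders
  lacking counts are dropped from that phenotype's test and logged — never
  silently defaulted. (Whether pooled or measure-specific counts are used
  upstream varies between consortia; measure-specific is the default here
  and the counts are plain data fields, so either convention can be fed
  in.) No random-effects quantities (τ², I²) are computed; only Q's p
  value is used.

## LD-score regression (simplified)

The genetics stage needs cross-disorder rg estimates whose estimand matches
the published method, at desk scale and fully testable. The implementation
is intentionally minimal:

* Filters first: INFO < 0.90 dropped (records lacking INFO are kept and
  logged — several real files omit the column), MHC (hg19 chr6:25–35 Mb,
  inclusive at both ends, no liftover) dropped, markers kept only if present
  in the reference panel with MAF ≥ 5%. Per-rule drop counts are returned.
* Univariate: weighted least squares of z² on a single LD-score component
  with a free intercept, weights 1/max(ℓ, 1) (no iterative
  heteroskedasticity reweighting); h² = slope·M/mean(N).
* Bivariate: z₁z₂ on ℓ after allele harmonization (z flipped when A1/A2
  are swapped; strand-ambiguous A/T and C/G markers dropped); genetic
  covariance = slope·M/√(N̄₁N̄₂); rg = cov/√(h²₁h²₂) with both h² estimated
  on the same SNP intersection, which makes self-correlation exactly 1. The
  free bivariate intercept absorbs sample overlap; no explicit overlap
  correction is applied. |rg| > 1.25 triggers a warning, not an error
  (jackknife noise can push a true |rg| ≈ 1 past 1); non-positive h² makes
  rg undefined and raises.
* Standard errors: delete-one-block jackknife over n_blocks = 200
  contiguous blocks in (chromosome, position) order, computed exactly via
  per-block partial normal equations (so delete-one-SNP, n_blocks = M,
  reproduces the textbook delete-one jackknife). For rg the full ratio is
  recomputed per deleted block, so the SE reflects all three regressions.

This estimator is *not* a re-implementation of the reference software: no
partitioned heritability, constrained intercepts, or liability-scale
conversion. Simulation recovery (below) is the calibration evidence.

## Synthetic data

* **Effect panels**: for each phenotype independently, a D-vector is drawn
  from a multivariate normal with the scenario's correlation matrix (via an
  eigenvalue square root, so singular targets such as a perfectly
  correlated pair are admissible); disorder i contributes
  mean_i + scale_i·z_i. Default scenario: 7 disorders; correlation target =
  the observed cross-disorder imaging pattern (PSD-projected); means from
  −0.22 (schizophrenia-like) to −0.018 (depression-like) with scales
  0.05–0.12, matching published profile summaries; masks giving
  shared-phenotype counts {75, 74, 41} (the missing OCD-like phenotype is a
  surface-area one, so its overlap with the epilepsy-like profile stays
  41); measure-specific case/control counts at published magnitudes
  (≈1,500–4,500 cases per disorder).
* **GWAS pairs**: LD scores ℓ = 1 + Gamma(2, 15) (mean ≈ 31, strictly > 1);
  given ℓ, (z₁, z₂) are bivariate normal with var = 1 + N h² ℓ/M and
  cov = √(N₁N₂)·rg·√(h²₁h²₂)·ℓ/M. SNPs are independent given ℓ — exactly
  the regression's expectation model. This deliberately omits realized LD,
  allele-frequency structure and ancestry: recovery tests validate the
  estimator's calibration, not its robustness to genome realism.
* **Joint scenarios**: the panel's off-diagonal correlation targets are a
  strictly monotone squash (0.2 + 0.65·tanh(·/2), spanning roughly the
  observed −0.45…0.85 range) of latent values ρ_p·g + √(1−ρ_p²)·ε, where g
  are Blom normal scores of the rg ranks and ρ_p = 2 sin(π·coupling/6) —
  the Pearson correlation whose bivariate-normal grade correlation equals
  the requested Spearman coupling. After PSD projection (eigenvalue clip at
  10⁻⁸ + diagonal rescale) both the pre- and post-projection couplings are
  reported; if projection destroys the requested rank structure the
  generator raises with the achievable value. End-to-end recovery is mildly
  attenuated by finite-phenotype sampling noise in the pairwise r
  estimates: at coupling 0.44 the mean recovered ρ is ≈ 0.40.

Because every generator draws from the model the estimators assume, passing
tests demonstrate correctness and calibration of the statistics — not
robustness to spatial autocorrelation between neighboring regions, shared
controls between working groups, or LD structure, none of which the
simulator emulates.

## Numerical and design choices

* Correlations are clipped to [−1, 1] after computation; zero variance in
  either input raises a degenerate-input error rather than returning NaN.
* The null Spearman ρ between independent vectors over 21 pairs has
  sd 1/√20 ≈ 0.224, so single-draw recovered couplings scatter widely; all
  recovery checks therefore average over replicates.
* Effect-table writing uses shortest-round-trip floats, so load → write →
  load is bit-identical; report p values are serialized in 3-significant-
  digit scientific notation with a full-precision companion column.
* Reruns with the same config and seed produce byte-identical TSVs;
  figures (SVG) are best-effort and excluded from that guarantee.
* Problem sizes used by the test suite and acceptance script — e.g.
  M = 20,000 SNPs, N = 50,000, 50–200 LDSC replicates, 200–500 coupling
  replicates — were chosen so each recovery check has comfortable
  statistical resolution while the whole suite stays interactive.

## Known limitations

* The analytic pairwise p values inherit downward bias from spatial
  coherence of neighboring regions; the permutation column does not fix
  this (it permutes phenotypes exchangeably), it only removes the
  parametric-form assumption.
* The LDSC stand-in is calibrated on its own generative model; for real
  summary statistics, externally estimated rg tables can (and usually
  should) be supplied via the pass-through reader.
* Bonferroni m defaults to the number of correlation tests (21 for seven
  disorders); analyses that also count the concordance test among the
  family may prefer m = 22, which is a config switch.
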