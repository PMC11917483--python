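# Methods

This note documents the statistical models implemented in `landgea`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that affect results.

## Genotype handling

Genotypes are alternate-allele counts (0/1/2) for diploid bi-allelic SNPs,
with −1 as the missing sentinel; multi-allelic and non-SNP VCF records are
skipped (counted, not fatal). Filtering applies, in order: (1) samples
with genotyping rate ≤ 0.80 removed, (2) loci with MAF ≤ 0.05 removed
(MAF recomputed on retained samples; the boundary is inclusive), (3) loci
with heterozygote fraction ≥ 0.50 removed. The order matters — per-locus
statistics change once low-callrate samples are gone — so it is fixed and
asserted by a test. Missing calls are imputed with the per-locus modal
genotype; ties break toward the smaller allele count, which favours the
major allele under the MAF filter and keeps imputation deterministic.
Candidate loci are annotated against GFF3 gene features within a 1-kb
margin (1-based inclusive on both sides), with upstream/downstream
resolved by annotated strand.

## Environmental predictors

Bioclimatic variables carry incommensurate units (°C, mm, m), so PCA is
always on the correlation matrix and pairwise distances use standardized
values by default. Collinearity pruning is greedy: pairs with |Pearson r|
above the threshold (default 0.70) are visited in descending |r| and the
member with the larger mean |r| to all remaining variables is dropped;
the output satisfies the threshold by construction and is order-stable.
Because the choice of which member of a correlated pair to keep is not
canonical, an explicit keep-list can override pruning. VIF_j =
1/(1 − R²_j) from an intercept OLS of variable j on the others
(statsmodels); values ≥ 5 are flagged, perfect collinearity reports +∞.

Standardization is always relative to an explicit reference — the
training-site means and SDs — and the same reference is applied to
current and future grids. Re-standardizing a future grid against itself
would silently absorb the climate shift that the genomic offset is meant
to measure.

## RDA and outlier detection

The constrained ordination is multivariate least squares of the centered
allele-count matrix Y on standardized predictors X, followed by SVD of
the fitted values: eigenvalue_k = s_k²/(n − 1), R² = ‖Ŷ‖²/‖Y‖², locus
loadings are right singular vectors × singular values ("species scores"
scaling — cosmetic for outlier calling, which standardizes loadings), and
predictor scores are the correlations of X columns with the site scores
(the biplot arrows). Partial RDA residualizes both Y and X on the
conditioning matrix (with intercept) first; conditioning on X itself
legitimately leaves R² = 0. Adjusted R² is Ezekiel's
1 − (1 − R²)(n − 1)/(n − m − 1) with m the number of constrained
predictor columns; this reproduces the published full-model
(0.202 → 0.120 at n = 87, m = 8) and climate-only (0.075 → 0.006, m = 6)
worked examples at 3 decimals. The published pure-structure row
(R² 0.115 → adjusted 0.115) is not Ezekiel-consistent (the formula gives
≈ 0.094); it is recorded here and deliberately not used as a check.

Variance partitioning fits full, climate-only and structure-only models
and derives pure fractions by subtraction of adjusted R²; the confounded
fraction can be slightly negative and is reported as computed. Note the
subtraction is exact on R² but only approximate on the adjusted scale, so
even sample-orthogonal predictor sets show a small nonzero confounded
term of order m/n; with n in the hundreds it is below 0.01.

The permutation ANOVA uses the pseudo-F
(SS_fit/m)/(SS_res/(n − m − 1 − rank Z)) with rows of the (residualized)
predictors permuted — reduced-model permutation, which controls type-I
error under conditioning — and p = (1 + #{F* ≥ F})/(1 + n_perm), default
999 permutations.

Outliers are loci whose loading lies more than 3.29 SD from the mean
loading on any retained axis (default: first 2 axes, matching a
scree-plot choice); 3.29 is the two-sided standard-normal critical value
at tail mass 0.001. Each outlier is assigned the predictor with the
highest |Pearson r| against its allele counts, ties to the first
predictor in model order.

## Population structure

Genetic PCA is the SVD of the centered (optionally unit-scaled) imputed
genotype matrix. Cluster number is selected by fitting K-means (10
restarts) for K = 1..10 on retained PCs and minimizing a spherical-
Gaussian (x-means style) BIC; cross-validated silhouette is available as
an alternative criterion. Discriminant axes are LDA on retained PCs (a
reduced DAPC), with enough PCs for 80 % of variance capped at n − K − 1,
reducing further if the within-class scatter is singular.

Distances: great-circle (haversine) with mean Earth radius 6371.0 km
(configurable, since geodesy tools differ on the radius), environmental
Euclidean over standardized variables, and pairwise Weir–Cockerham FST
with negative estimates clamped to zero. Mantel tests use Spearman
correlation of off-diagonal entries with joint row/column permutation of
the second matrix and a two-tailed p over 9,999 permutations (delegated
to scikit-bio's seeded implementation, whose p-value definition matches
exactly; an independent hand-coded oracle cross-checks the statistic in
the tests).

## Selection scans

**Environment-stratified FST.** Samples are split at the 25th/75th
percentiles (linear interpolation, boundaries inclusive) of a predictor;
per site the two-population Weir–Cockerham (1984) variance components
are, with group sizes nᵢ, ALT frequencies pᵢ, heterozygote fractions hᵢ,
n̄ the mean size, n_c = Σn − Σn²/Σn, p̄ and h̄ weighted means, and
s² = Σnᵢ(pᵢ − p̄)²/n̄:

    a = (n̄/n_c)[s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − s²/2 − ((2n̄−1)/(4n̄)) h̄]
    c = h̄/2

Windows are fixed 20-kb tiles (step = size, 1-based inclusive; only BED
export is 0-based half-open); the windowed statistic is Σa/Σ(a+b+c) over
included sites, windows ≤ 0 are omitted, and the top ceiling(1 %) of the
remainder is flagged.

**iHH12.** EHH12 partitions haplotypes by their allele string from the
core outward and pools the two largest classes:
[n₁₂(n₁₂−1) + Σ_{i>2} nᵢ(nᵢ−1)]/[n(n−1)]. The profile is monotone
non-increasing, so integration (trapezoid vs physical distance, left +
right) can truncate exactly at the first marker below the 0.05 cutoff;
gaps > 200 kb terminate a side, and cores whose profile reaches a
chromosome edge above the cutoff are flagged edge-truncated. The cutoff
and gap defaults follow the conventional scanning-tool defaults. Scores
are z-normalized genome-wide (no frequency binning), windows take the
max normalized score (mean available by flag), and the top ceiling(1 %)
is flagged.

## Adaptive index and genomic offset

The enriched RDA refits the discovery model on outlier loci only. For
each retained axis, AI(pixel) = Σᵢ aᵢbᵢ with aᵢ the predictor biplot
score (raw regression coefficients available by flag) and bᵢ the pixel's
standardized variable value. The genomic offset is the unweighted
Euclidean distance between current and future AI vectors over the first
two axes (eigenvalue weighting optional). Offsets are proxies: they
assume linear genotype–environment relationships and are not fitness
measurements. Multi-model climate ensembles are reduced by a per-pixel
arithmetic mean before projection. Rasters are handled as grid CSV
(row, col, lat, lon, variables).

## Synthetic data

The generator reproduces the statistical structure the analyses assume,
at test scale (10³–10⁴ loci, ~90 individuals from a landscape of ~75–90
sites), not the biology of any particular genome:

- **Environment**: each variable is a linear gradient in a random (or
  fixed) direction plus Gaussian-smoothed low-frequency noise, scaled to
  plausible ranges; sites are sampled pixels. This gives smooth, spatially
  autocorrelated surfaces but no topography or seasonality structure.
- **Neutral genotypes**: Balding–Nichols — per-population allele
  frequencies Beta-distributed around an ancestral p₀ ~ U(0.1, 0.9) with
  variance set by the neutral FST (default 0.05, the low-to-moderate
  differentiation regime); genotypes Binomial(2, p). Hardy–Weinberg
  within populations — a deliberate simplification for a selfing crop,
  whose excess homozygosity the generator does not emulate (one visible
  consequence: the heterozygosity filter removes more simulated than real
  loci).
- **Adaptive loci**: individual-level frequency
  expit(logit p₀ + β·z_env), so environmental association can exist
  without spatial genetic structure (environment-associated loci with
  minimal isolation by distance). β = 2 is the moderate default; the
  strong-effect recovery experiments use β = 4, which sweeps the allele
  frequency across most of (0, 1) over ±1 SD of the gradient.
- **Missingness** is uniform at random (default rate 0.1438, the observed
  missing fraction in the motivating dataset); no call-rate structure by
  sample or locus.
- **Sweeps**: a fraction of haplotypes share one identical allele string
  over a span centered on the core; other entries are i.i.d.
  Bernoulli(0.5). There is no recombination-driven EHH decay, so the
  iHH12 signal is a flat-topped plateau over the span. The recovery
  experiments therefore use a sweep span equal to the 20-kb scan window,
  so the "core window in the top 1 %" question is well-posed; with spans
  much wider than a window the plateau ties across several windows and
  the top-fraction flag becomes a lottery among them.

Consequently, passing tests demonstrate internal statistical correctness
and recovery under the generator's idealizations; they do not establish
performance under linkage disequilibrium, allele-frequency clines with
drift, non-random missingness, or selfing.

## Problem sizes and numerics

Recovery experiments run at 10 replicates × 5,000 loci × 90 individuals
(outliers), 2,000 loci × 2 populations (FST calibration), 100 paired
3,000-marker scans (sweeps), and 20 × 9,999-permutation Mantel tests —
sizes chosen so the whole suite completes in a couple of minutes while
keeping Monte-Carlo error well inside the asserted margins. Determinism:
every stochastic routine takes an explicit seed (numpy Generator);
identical configurations produce byte-identical outputs. Degenerate
inputs error loudly rather than silently: zero-SD standardization,
constant Mantel matrices, zero-variance iHH12 scores, all-missing loci,
rank-deficient predictor sets (collinear columns are named).
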