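# Methods

`ctdbalance` re-implements, as a tested library, a promoter-level analysis
of RNA polymerase II (RNAPII) C-terminal-domain (CTD) modifications: ChIP
tag quantification around transcription start sites (TSS), enrichment
calling by Bayesian change-point segmentation, rule-based gene
classification, the K7 methylation/acetylation ratio statistic, and a suite
of dependency analyses (Spearman and partial correlations, exhaustive
best-subset regression, cross-validated LASSO) linking promoter marks to
productive elongation (S2p measured after the transcript end site, TES) and
mRNA. A synthetic-data generator plants the statistical structure the
downstream stages are meant to recover, so the whole chain can be validated
end to end without sequencing data.

## Tag processing and quantification

Tags are mapped-read 5′ positions (BED). Duplicate filtering caps the
multiplicity of each (chromosome, position, strand) site at the nearest-rank
95th percentile of the multiplicity distribution over occupied sites,
rounded up to an integer. Capping (rather than deleting whole stacks)
preserves one representative read per site, the usual deduplication
semantics; a `drop_stacks` flag selects full-stack removal, and the
percentile population is all occupied sites (taking it over duplicated sites
only would be an alternative reading; the cap is returned so callers can
audit it).

Promoter windows are `[TSS - w, TSS + w)` with `w = 1000` bp by default —
"2 kb around the TSS". Published descriptions of this analysis family
alternate between ±1 kb and ±2 kb promoter windows; the width is therefore a
parameter everywhere it is used. TES windows cover the 2 kb immediately
downstream of the TES in transcription orientation. Window counts are tag
counts in the half-open interval; depth scaling is `count x 1e7 /
total_mapped` (per 10 million non-duplicated mapped tags).

## Enrichment calling

Binned counts (default 200 bp) are modelled as piecewise-constant Poisson.
Within a block the rate carries a conjugate Gamma(α, β) prior (α = β = 1)
and is integrated out analytically; a change point occurs at each bin
boundary independently with probability p = 0.01, making block lengths
geometric. The maximum-a-posteriori partition is computed exactly by an
O(n²) dynamic program (the per-bin factor Π 1/c_i! is partition-independent
and dropped). On genome-scale tracks the DP is banded (`max_block`, default
100 bins in the pipeline = 20 kb); this caps block length but leaves
enrichment calls unchanged because long homogeneous background simply
splits into adjacent low-rate blocks. Tests verify the unbanded DP against
exhaustive enumeration of all 2^(n-1) partitions for n ≤ 12.

A block is enriched when its posterior mean treatment rate
(α + S)/(β + n) is at least `fold_threshold` (default 2) times the posterior
mean of the depth-scaled control count over the same block; the shared
prior regularizes empty control blocks. Adjacent qualifying blocks merge.
An empty control triggers a warning and a fall-back to the global treatment
mean. Raising the fold threshold can only shrink the enriched footprint
(tested as a monotonicity property).

## Promoter positivity and gene classes

A promoter is positive for a mark when its window intersects an enriched
region and its count exceeds the nearest-rank 10th percentile of counts
among region-overlapping promoters (the "10% tail cut"). The percentile
population is a genuine ambiguity — the published histograms draw the cut
on both the all-promoters and the overlapping-promoters distributions — so
`percentile_population` selects either, with "overlapping" the default.
Exclusion rules then set status to NA: positive TSS windows that overlap
other positive TSS windows for the same mark (both removed), and positive
genes lying inside other positive genes (internal gene removed). Exclusions
never convert negative to positive.

Classes: **active** = S5p+, S7p+, S2p+ (TES window), FPKM > 1, and negative
for the polycomb marks H3K27me3 and H2Aub1; **PRCr** (polycomb-repressed) =
H3K27me3+, H2Aub1+, S5p+ with 8WG16− and S2p−; **inactive** = negative for
all of H3K27me3, H2Aub1, S5p, S2p, 8WG16; anything else is NA (no call).
Cohort flags mark non-overlapping active genes and the TSS-anchored subset
whose 8WG16 maximum lies within 50 bp of the TSS ("within 50 bp" and "a 100
bp window centered at the TSS" are treated as the same criterion,
|offset| ≤ 50). Peak offsets use fine bins (≤ 10 bp); ties resolve toward
the TSS, and a symmetric up/downstream tie resolves downstream. top15 /
bottom15 flags take the ⌊0.15 m⌋ highest/lowest FPKM genes among the m
polycomb-negative genes.

Classification recovery on synthetic data is scored as balanced accuracy
over genes receiving a definite active/inactive call; NA is an abstention,
not a miscall. This matters because the 10% tail cut by construction turns
the weakest ~10% of region-overlapping promoters negative per mark, so a
fraction of planted-active genes always lands in NA; the NA rate is
reported alongside (`count_na=True` gives the strict score).

## Profiles

Metagene profiles average per-bin tag counts (10 bp bins, 5 kb span) across
genes anchored at TSS or TES, flipping − strand genes. Depth is 5′-position
counts per bin; the sources do not state whether fragment-extended coverage
was used, so an optional extension length is provided but off by default.
Heatmap matrices (±500 bp, 5 bp bins; −500..+1000 for S2p) are z-scored per
gene with the sample (n−1) standard deviation; constant rows map to zeros.
Rows can be ordered by the K7me2/K7ac ratio, highest first. GRO-seq windows
(−500..+1000 bp of the TSS, 10 bp bins) split tags into sense/antisense by
gene strand; RPKM uses the tag count from TSS to TES:
`count x 1e9 / (length x total_mapped)`. Expression transforms use
log10(FPKM + 1e-4).

## Ratio statistic and group tests

The per-gene ratio is (me per 10M) / (ac per 10M) over the promoter window;
it is NA when the acetylation count is zero. Tertiles (low/medium/high) are
rank-based with stable tie-breaking; remainders go to the low group first,
so sizes differ by at most one. Group differences use the two-sided
Wilcoxon rank-sum test (exact enumeration when the smaller group has ≤ 10
observations and no ties; otherwise the normal approximation with
tie-corrected variance and continuity correction). The TSA
(histone-deacetylase-inhibitor) response analysis dichotomizes fold changes
symmetrically (≥ 2 up, ≤ 0.5 down; others excluded) and tests the high-vs-
low 2×2 table with the two-sided Fisher exact test using the
probability-mass convention (sum of hypergeometric probabilities no larger
than the observed table's), the convention of the common statistical
environments. The odds ratio is the sample cross-product, reported as
infinity when the denominator product is zero. Whether the medium tertile
enters any pairwise test is not pinned down by the sources; the pipeline
reports high-vs-low (tested) plus the other two pairwise Wilcoxon
comparisons descriptively.

## Dependency analyses

All regression inputs are centered and scaled. When the mark table is built
from window counts, counts are log-transformed first (log(x + half the
smallest positive value)): the generator plants its structural model on the
log scale, and log transformation of ChIP counts before linear modelling is
standard practice; `transform="none"` reproduces raw-scale analysis.

Partial correlations are computed from the precision matrix Ω of the
correlation matrix of [x, y, conditioning set]:
r = −Ω_xy / √(Ω_xx Ω_yy), with p-values from
t = r √((n − k − 2)/(1 − r²)) on n − k − 2 degrees of freedom. By default
columns are rank-transformed first so marginal and partial analyses share
the Spearman convention; whether the original analysis ran its partial
correlations on ranks or on raw scaled counts is not stated, so both modes
are exposed (`method="spearman"|"pearson"`). Near-collinear conditioning
sets raise an error naming the variables.

Best-subset regression enumerates all predictor subsets of size 1..5 and
ranks them by adjusted R², reporting coefficient signs, t-test significance
codes (\*\*\* ≤ 0.001, \*\* ≤ 0.01, \* ≤ 0.05), adjusted R², AIC (Gaussian
log-likelihood including the constant; within a fixed dataset the constant
cancels), and Mallow's Cp referenced to the full model over the declared
predictor set (the seven CTD/CpG predictors by default, so the full model's
Cp equals p + 1 exactly).

The LASSO runs over a 100-point geometric penalty grid from the critical
penalty (all coefficients zero) down by 1e-4, with seeded 10-fold
cross-validation. The selected penalty is the largest whose mean CV error
is within one standard error of the minimum (the 1-SE rule); the reported
coefficients come from refitting at that penalty on all genes. The path's
zero-penalty endpoint equals the OLS solution (tested).

`CTDMarkModel(table, response="S2p").fit(seed=...)` packages the four
analyses into a results object with a text `summary()`.

## Synthetic data: what is planted and what is not

Per active gene a latent activity factor A ~ N(0,1) drives the promoter
marks: each of S5p, S7p, 8WG16, K7ac and a shared methylation factor K7me
is `w·A + √(1−w²)·ε` with loading w = 0.85 (pairwise mark correlation
w² ≈ 0.72, at the low end of the published 0.72–0.86 band). K7me1 and K7me2
load on K7me with planted mutual correlation 0.93 (their published
self-correlation). Elongation is the structural equation

    S2p = a·S7p + b·K7ac + c·S5p + d·K7me + 0.5·ε

on the standardized log scale with defaults a = 0.45, b = 0.40, c = 0.25,
d = −0.35. The sources report no effect sizes for the negative methylation
path; these defaults are this package's choice, fixed analytically so that
(i) the partial correlation of K7me2 with S2p given any single one of
{S5p, K7ac} is approximately zero — with equal loadings the condition is
w(1−w²)(sum of remaining positive paths)·w + d(1−w²w²) ≈ 0 — and (ii) the
partial correlation given {S7p, S5p, K7ac} is strictly negative
(its covariance reduces to d·var(residual) < 0), reproducing the reported
sign structure without tuning to any numerical target.

Latent masses become expected tag weights exp(0.8·latent); per-mark totals
are Poisson around `depth_per_mark` (200,000), split multinomially across
genes and placed by mark-specific kernels in transcription orientation:
K7me1/K7me2 sharp Gaussians at the TSS (sd 80 bp), K7ac shifted downstream
(+250 bp, sd 200), 8WG16 an equal mixture of N(0, 60) and N(+140, 60)
(promoter-proximal pausing), S5p and S7p broader initiation kernels, S2p
35% uniform gene body plus a post-TES Gaussian, polycomb marks broad
(sd 1200) on PRCr genes only. A uniform background (1e-3 tags/bp) underlies
every mark; the mock track is background only, hence a shallower library —
as real mock immunoprecipitations are — and depth scaling handles the
difference. PRCr genes receive S5p (poised polymerase at a reduced level)
and polycomb marks but no S7p/S2p/8WG16/K7 mass; inactive genes have
FPKM = 0 and background only. mRNA is log-normal around the S2p latent;
GRO-seq places 90% sense tags along gene bodies proportional to
FPKM x length plus 10% antisense near promoters (divergent transcription).
TSA fold changes are planted as log2fc = z(K7me2 − K7ac latent) + N(0,1),
so high-ratio genes are enriched for ≥ 2-fold up-regulation. CpG is a
positive covariate mildly correlated with activity (its published
definition defers to earlier work and is out of scope).

Default cohort sizes are 500 active / 150 PRCr / 350 inactive genes on one
25 Mb chromosome — a deliberately reduced genome that keeps every
experiment a pure function of the config seed. What passing tests show is
that the algorithms recover structure of the planted kind at realistic
signal-to-noise; they do not show robustness to features real ChIP data has
and the generator lacks: mappability artifacts, copy-number variation,
fragment-length effects, antibody efficiency differences, overlapping
transcription units, or multi-chromosome genomes.

## Numerical choices and degenerate inputs

Nearest-rank percentiles (no interpolation) everywhere a percentile is a
cut-off. Zero acetylation counts give NA ratios; all-zero fine tracks give
undefined peak offsets (gene fails the anchored criterion). Constant
columns give NaN correlation entries; a constant heatmap row z-scores to
zeros; identical groups give Wilcoxon p = 1. Fisher's test on a table with
an empty margin raises. The Cp reference model excludes the mock control
(seven predictors), matching the declared best-subset predictor set.

## Known limitations

The change-point caller is this package's own Poisson-Gamma MAP model — it
matches the published caller's role (defining promoter positivity), not its
internals or output format. GRO-seq emulation is a thin sense/antisense
sketch, not a run-on simulation. The published genome-scale gene counts and
correlation magnitudes derive from real sequencing depth and a specific
aligner stack and are not reproduced at this scale; the package targets the
sign structure and the procedures, which is what its tests assert.
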