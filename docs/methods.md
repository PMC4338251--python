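# Methods

## Data model and conventions

All genomic coordinates are 0-based half-open; no module emits 1-based
values. A per-CpG record carries a methylation level (methylated-read
fraction) and a read count; a CpG with zero coverage has an *undefined*
level and is excluded from every mean — it is never treated as 0%
methylated. CpGs are assumed strand-merged (symmetric); the format keeps a
strand column but nothing interprets it. Every regional methylation value
in the package is the coverage-weighted mean Σ(level·reads)/Σ(reads).

## Segmentation model

HMR and PMD calling share a two-state hidden-state chain along the genome,
the model family of the standard WGBS segmentation tools.

**HMRs.** Observations are per-CpG (methylated, total) read pairs.
Emissions are beta-binomial with state means fitted by EM and a fixed
concentration ν = 15 (larger ν → closer to binomial; the within-region
variance of real data is not identifiable from the synthetic benchmarks, so
ν is a documented free parameter, not a fitted one). Initialization is
deterministic from the level histogram: the low-state mean starts at the
mean of levels < 0.5, the high state at the mean of the rest; transitions
start at 0.99 self-transition. Decoding is posterior (low state where its
posterior exceeds 0.5). Chromosomes are fragmented wherever consecutive
assessable CpGs are more than `max_cpg_gap` = 1 kb apart *before* decoding,
so no call can span such a gap; fragments share parameters but are decoded
independently. Low-state runs with ≥ `min_cpg` = 4 CpGs become HMRs
(`min_cpg` is unstated upstream and surfaced as a flag). Two guards keep
degenerate inputs sane: if EM leaves the two state means closer than 0.2
the track is treated as homogeneous (a uniformly methylated track yields
no HMRs), and a candidate whose mean is not below the genome-wide weighted
mean is dropped.

**PMDs.** The track is summarized into 1 kb bins (coverage-weighted mean;
bins with < 3 CpGs are masked) and fragmented at CpG gaps > 20 kb. A
two-state Gaussian chain with fitted means and variances (self-transition
0.998) is decoded the same way; low-state runs shorter than `min_domain` =
100 kb (a flag; unstated upstream) are discarded, and a domain's mean level
must fall strictly inside (0.15, 0.75) — between HMR-like and fully
methylated. Boundaries are bin-edge precise, so planted domains are
recovered to within a bin or two.

A consequence worth knowing: in PMD-rich samples the HMR caller emits calls
*inside* PMDs (the 0.45-level domain is "low" relative to a 0.8
background). That mirrors how the underlying two-state model behaves on
real cancer methylomes; benchmarks that measure HMR precision therefore use
PMD-free scenarios, and atlas construction on PMD-rich panels inherits
extra intergenic rows from domain interiors.

## Reference atlas and clustering

Per-sample HMR sets are merged (union of maximal disjoint intervals;
book-ended runs coalesce) into the reference set, which is re-scored in
every sample. Entries with fewer than `min_cpg` assessable CpGs are
missing. Regions are classified promoter / intragenic / intergenic with
priority promoter > intragenic (a region touching any TSS ± 1 kb window is
promoter even when it also lies in a gene body).

Clustering is per location class: pairwise Gower dissimilarity — the mean
over columns assessable in both rows of |x_ic − x_jc|/range_c — followed by
Ward linkage on the precomputed matrix (Lance–Williams recurrence, scipy)
cut at k = 8 (a flag; eight clusters per class is the presentation the
atlas emulates, not a model-selection result). Design choices around
missingness, all made here because no upstream prescription exists:

- rows missing in more than half the samples are excluded from clustering
  (label 0) and reported;
- row pairs sharing no assessable column get the maximum observed
  dissimilarity;
- columns whose range is below 0.02 (measurement-noise scale) are dropped
  inside atlas construction, so a class whose rows all share one profile
  collapses to a single cluster instead of an arbitrary 8-way split; the
  standalone `gower_dissimilarity` applies no such floor.

Cluster ids within a class are renumbered by ascending mean methylation —
cluster 1 is always the most hypomethylated group. Classes larger than
50,000 rows are clustered on a seeded subsample and remaining rows assigned
to the nearest cluster medoid, because an all-pairs dissimilarity matrix at
full atlas scale (hundreds of thousands of rows) is not desk-sized; the cap
is configurable.

## Width dynamics, regulatory potential, tests

Width matching sums the *full* widths of all other-sample HMRs overlapping
a reference HMR (≥ 1 bp): a split HMR has not contracted in covered bases,
so widths add rather than taking the largest piece. Bin boundaries (0.19,
1, 3 in |log2 FC|) assign boundary values to the larger-change bin; the
rule is fixed and exhaustively tested because the interval notation it
derives from is ambiguous.

Regulatory potential counts distinct feature *tracks* overlapped (≥ 1 bp),
not elements — five TFBS peaks in one track count once; ≥ 4 of 8 is
"High". Top-quantile signal flags use `score ≥ quantile(1 − q)` with ties
at the cut included (all-equal scores all flag). Cluster-state association
runs a two-sided Fisher exact test per (cluster, state) pair with
Benjamini–Hochberg adjustment across all pairs (the adjustment method is a
flag; BH is the default choice). The two-proportion z-test uses the pooled
variance and is undefined when the pooled proportion is 0 or 1.

Cohen's d uses the (n−1)-weighted pooled SD with sign convention
tumor − normal; magnitudes bin at |d| = 0.2/0.5/0.8. Group tests default
to Welch; a `student` flag switches to pooled-variance Student's t to
mirror classical usage. The internal differential-expression test (Welch
on log2(CPM + 0.5), BH FDR ≤ 0.05) is plumbing for the synthetic
benchmarks; externally produced DE labels are accepted verbatim.

## XCI dysregulation

Per patient, `mean_x_delta` is the mean over assessable X-linked promoters
of tumor − normal methylation, excluding XIST (whose promoter moves the
other way: hypermethylated where XCI is lost). Patients with fewer than 5
assessable X promoters are excluded and reported. The cohort is split by a
1-D two-component Gaussian mixture fitted by EM with quantile-based
initialization (q25/q75), written in-package because it must be invariant
to patient order and equivariant under a common shift of all deltas —
properties the library mixtures' kmeans-style initializations do not
guarantee. The lower-mean component is the dysregulated one; if the
component means are closer than a separation floor (default 0.1) the cohort
is called single-population and no patient is flagged, which is what makes
a null cohort produce zero calls. A plain threshold mode (delta < −0.1) is
available as a flag. Escapee-like calls require *both* significant promoter
hypomethylation and significant over-expression in the dysregulated group
(two-sided p < 0.01 with the required directions); genes with degenerate
variance are skipped and reported.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Genome.** Small multi-chromosome genomes (default 2 autosomes + one
X-like chromosome, 8.4 Mb total) with background CpG density 0.005/bp
(≈ 1 per 200 bp), CpG islands at 0.10/bp in an 800 bp core around each TSS,
and elevated density (0.03/bp) across planted regions so they are
CpG-supported to their edges. Genes (default 150, spans 5–20 kb, both
strands) occupy the first 55% of each chromosome; a CpG-poor desert tiled
with 250 kb candidate PMD blocks fills the tail. Every gene promoter
(TSS ± 1 kb) is a planted promoter-class cluster region; most genes also
carry one intragenic region > 1 kb from either TSS, and disjoint intergenic
regions are slotted between gene territory and desert. Eight regulatory
feature tracks and per-cell-type chromatin-state segments
(promoter/enhancer/heterochromatin) are derived from this structure, along
with fragile-site-like blocks half of which coincide with PMD candidates.

**Archetypes.** Seven samples emulate a breast panel: normal tissue (NB),
benign tumor (BT089), two invasive carcinomas (BT126, BT198) and three
cultured lines (HMEC, MCF7, HCC1954). Background level 0.8, HMR level 0.05,
PMD level 0.45; planted PMD genome fractions 0 / 0.5% / 7% / 16% / 30%
(< 1% for normal-like tissue, 25–35% band for lines, intermediate for
invasive tumors). Mean depth is 18.8 reads per CpG — the panel's average
sequencing depth — with reads ~ Poisson(depth) and methylated reads
beta-binomial around the regional target with overdispersion ρ = 0.05
(ν = (1−ρ)/ρ = 19); ρ is a documented free parameter since the true
within-HMR variance is not published for this design. With ρ = 0 and
infinite depth the observed track equals the planted piecewise-constant
level function exactly. The 24-cluster profile table assigns each
(class, cluster) a 7-sample high/low pattern (0.85/0.08); cluster 1 is low
everywhere (the housekeeping-like majority class), and promoter cluster 8
is reserved for X-linked promoters, sitting at 0.5 (allelic methylation)
in XCI-intact samples and 0.08 in MCF7/HCC1954. XIST's promoter is 0.5 in
XCI-intact samples and 0.9 where XCI is lost. A male-like archetype (X
promoters low, XIST promoter high) supports the male-pattern comparison.
Truth objects (HMR/PMD intervals, region tables, labels) are returned
alongside and written as sidecar files, never embedded in the data formats.

**Expression.** Counts are negative-binomial with lognormal per-gene
baselines; for genes in linked promoter clusters, expected log2-expression
is log2(base) + slope·(0.5 − promoter methylation) (slope 4 by default), so
hypermethylated linked promoters are repressed; unlinked genes ignore
methylation.

**Cohort.** Default 78 patients with 36 (the planted fraction 36/78)
XCI-loss cases: affected patients' X promoters shift by −0.3 on average
(patient-level SD 0.05, per-gene noise SD 0.03), XIST shifts +0.3 and its
expression drops 4-fold, and a 40% subset of X genes gains 4-fold
expression. Normal-tissue X promoters sit at 0.5, autosomal promoters at
0.12.

**What the generator does not emulate** — and hence what passing benchmarks
do not demonstrate about real data: read-level artifacts (bisulfite
conversion failure, mapping bias, PCR duplicates), strand asymmetry and
non-CpG methylation, copy-number and tumor-purity effects on levels,
spatially correlated noise beyond the planted blocks, CGI shores with
graded methylation, and realistic expression covariance structure. Planted
cluster patterns are near-binary; real atlas clusters are fuzzier, so ARI
at the benchmark's noise level is an upper bound on real-data performance.

## Benchmark problem sizes

The shipped benchmarks use sizes chosen to exercise each stage at realistic
density while staying desk-sized: one 5 Mb chromosome (~27,000 CpGs, ~100
planted HMRs, depth ~19) for HMR recovery; a 12 Mb chromosome with ten
380 kb planted domains for PMD boundary accuracy plus the default 8.4 Mb
panel genome for archetype PMD fractions; 2,400 reference rows across the
24 planted profiles × 20 seeds for atlas recovery; 100×7 matrices, 10 kb
per-base masks, and all 2×2 tables with margins ≤ 30 for the oracle
equivalences; n = 1,000 per group × 100 replicates for Cohen's d
calibration; 40 seeds for the methylation–expression asymmetry; and the
78-patient cohort for XCI recovery. `tests/` re-runs the same checks at
these or smaller sizes.

## Known limitations

- Exact numeric agreement with the classical segmentation tools is not a
  goal; the model family matches but the parameterization beyond the two
  gap limits is this package's own, and planted-truth recovery is the
  correctness standard.
- The beta-binomial concentration and the PMD level band are fixed defaults;
  heavily dispersed real libraries may need them re-examined.
- Ward on Gower dissimilarities treats the dissimilarity as if Euclidean
  (the standard `hclust`-style usage); the tree is well-defined but the
  variance interpretation is heuristic.
- The mixture-based XCI split assumes the dysregulated population is
  location-shifted; gradual continua of X hypomethylation will be cut
  somewhere between the modes.
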