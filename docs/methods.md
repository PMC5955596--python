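# Methods

## Problem and model

Halved-embryo ATAC-seq yields three coverage tracks — anterior half,
posterior half, and whole embryo — over the same genome. For a genomic
region *R* with per-base signal summed to `X_ant(R)` and `X_post(R)`,
the positional skew score

    s(R) = (X_ant − X_post) / (X_ant + X_post)

is the natural bounded measure of differential accessibility: it is
antisymmetric under exchanging halves, invariant to common rescaling of
both halves, and confined to [−1, 1]. The accessibility skew score is
`±s(R)` with the sign chosen so that positive means "more accessible in
the half where the region drives expression" (+ for anterior-active,
− for posterior-active regions; undefined for dorsal/ventral regions,
which serve as axis controls).

A region's skew is only interpretable against the skew that counting
noise alone produces at comparable signal. The null model therefore
draws, for each region of interest (ROI), `k` random genomic regions
with the same length and the same total signal on a reference track
(within a relative tolerance), outside an exclusion mask of genes and
annotated regulatory regions. The positional skews of all matched
regions are pooled and summarised by a single fitted normal (μ, σ);
a D'Agostino–Pearson K² statistic is attached as a normality
diagnostic. Each ROI is scored as z = (s − μ)/σ with a two-tailed
normal p, significant at p < 0.05 (raw, per region; Benjamini–Hochberg
q-values are reported alongside but do not drive any call). Pooling
one normal across ROIs (rather than per-ROI nulls) matches how the
random-region histogram is summarised in this analysis tradition; its
cost is mild anti-conservatism when ROI signal totals are heterogeneous
(see Calibration below).

The z statistic is computed from the positional skew. For
anterior-active regions this equals the accessibility-skew form; for
posterior-active regions only the sign of z flips and the two-tailed p
is unchanged whenever μ ≈ 0. The positional form is the only one that
extends to genome-wide peaks, which have no annotated active half.

## Preprocessing

- **Read shift.** Tn5 inserts as a dimer leaving a 9-bp duplication;
  fragments are shifted +4 bp (plus strand) / −5 bp (minus strand),
  both endpoints moving, before pile-up. Fragments emptied by clipping
  at chromosome bounds are dropped (count logged).
- **Coverage.** Per-base signal is the number of fragments covering the
  base (difference-array pile-up, O(fragments + genome)).
- **Depth scaling.** Tracks are scaled to a common mapped-read count
  (default 10 million).
- **Regression normalization.** Each half track is regressed on the
  whole-embryo track over adjacent tiling bins (default 1 kb) with no
  intercept: slope = Σxy/Σx² over bins with reference signal > 0 (the
  zero-inflated empty fraction of the genome would otherwise pull the
  fit). The half track is divided by the slope, so refitting returns
  slope 1. Order of operations: depth-scale, then regress — the
  regression then compares depth-comparable tracks. The fit is on
  linear bin sums; log-transformed display conventions do not enter the
  fit.

## Region catalog and filters

Catalog rows carry chrom/start/end/name, kind (enhancer | promoter),
class (anterior | posterior | dorsal | ventral), and a
maternal/zygotic flag. Two filters precede scoring: regions must
overlap (≥ 1 bp — the weakest reading of "overlap", configurable) a
peak called in at least one sample, and must carry total signal
strictly above a threshold (default 200) on the whole-embryo normalized
track. The signal filter is interpreted as a region **total** (the
matching quantity in the null model); per-base max or mean readings are
possible but not used. Both filters are idempotent and commute.
Exclusion of regions whose expression straddles the slice plane is a
curation act: an optional boolean catalog column is honored, never
computed.

## Matched-region sampling

Candidates are drawn uniformly over genome positions (chromosomes
weighted by placeable positions) and rejected unless they avoid the
exclusion mask entirely and match the ROI's total reference signal
within tolerance (default 5% relative). Matched regions inherit the
ROI's length — stricter than matching on signal alone, removing length
as a confounder. Defaults: k = 10 draws per ROI, max_tries = 50,000
candidate draws per ROI (the acceptance rate for a 5% match at
realistic signal densities is ~0.1%, so the conventional 10,000 tries
regularly falls one or two matches short; candidate evaluation is
vectorized prefix-sum lookups, so the larger budget costs
milliseconds). The first k acceptable candidates under the seeded
generator are taken — reproducibility over optimality. If a σ of
exactly/numerically zero results (e.g. proportional half tracks), the
null is refused as degenerate.

Open choices resolved: the reference track for matching totals is the
whole-embryo sample (not the sum of halves) — it is the track the
signal filter already uses and is independent of the half-split noise
being tested.

## Peaks and enrichment

Reproducible peaks are merged-sample peaks overlapping (≥ 1 bp) a call
in each of two replicates; merged-set coordinates are retained to
preserve peak identity. Peaks are scored with the same null machinery
and partitioned into AntSig (s > 0, p < 0.05), PostSig (s < 0,
p < 0.05) and NotSig (everything else; degenerate zero-signal peaks are
NotSig with a flag). Overlap of a peak class with a transcription
factor's ChIP peaks is summarised in a 2×2 table over the peak universe
and tested with a one-tailed Fisher's exact test (hypergeometric tail
sums); the reported odds ratio is the sample cross-product ratio
(a·d)/(b·c), with +∞ when b·c = 0 and a·d > 0 and NaN when both
products vanish.

Group-level comparison of mean positional skew across region classes
uses one-way fixed-effects ANOVA with Tukey's HSD (statsmodels), with
the `diff` column recomputed exactly as the difference of group means
(the statsmodels summary table rounds), plus unadjusted pairwise
two-sample t-tests.

## ChIP signal matrices

ChIP tracks are divided by their genome-wide mean (deviation-from-
background units; idempotent up to float tolerance), aggregated over a
window (default 3 kb) centred on the region midpoint
`mid = (start+end)//2`, window `[mid − w/2, mid + w/2)` clipped at
chromosome ends (mean taken over the clipped extent), min–max scaled to
[0, 1] per factor (constant columns map to 0 with a warning), and rows
ordered by descending positional skew with name-lexicographic
tie-break. Hierarchical clustering is out of scope; the TSV writer
emits a matrix consumable by standard clustering tools.

## Synthetic data

The generator states a world and realises it with Poisson noise:

- Genome: one 2 Mb chromosome by default.
- Peaks: non-overlapping footprints of 6 peak-width SDs (default SD
  150 bp → 900 bp), placed uniformly among non-overlapping
  arrangements. A peak has amplitude A (expected fragments, both halves
  combined; default uniform in 100–1000, roughly tens-to-hundreds of
  fragments per accessible site at 10 M-read depth) and true skew s:
  anterior expects A(1+s)/2 fragments, posterior A(1−s)/2, so the skew
  of the expectations is exactly s.
- Decoy peaks: optional additional zero-skew peaks standing for the
  genome's many unannotated accessible sites. They are what makes
  signal-matched sampling outside the annotation possible, mirroring
  the real genome where annotated patterning enhancers are a tiny
  minority of accessible regions.
- Fragments: counts Poisson; midpoints Gaussian around the peak centre;
  background homogeneous Poisson (default 5 fragments/kb per half);
  lengths log-normal (median 120 bp, σ_log 0.45, typical of
  nucleosome-free ATAC libraries) with fragments over 500 bp discarded,
  mimicking library size selection; strands Bernoulli(½).
- Replicate variability: one multiplicative log-normal factor per
  sample (SD 0.15), emulating global efficiency differences — exactly
  the distortion the regression normalization removes.
- Whole embryo: an independent draw at the combined rates (separately
  sequenced whole sample); a whole-as-sum switch covers the other
  convention.
- Determinism: all draws flow from a single integer seed; identical
  spec + seed gives bit-identical output.

What the generator does **not** emulate: sequence-level reads (no
mappability/GC bias), overdispersion beyond Poisson + global jitter
(no per-region biological variability), correlated replicate structure,
or single-nucleus sparsity. A green test on this world therefore
establishes the statistical machinery (estimator accuracy, null
calibration, monotone power, determinism), not robustness to alignment
artefacts or covariate-dependent accessibility bias.

## Calibration and recovery (what the test suite establishes)

- On zero-skew worlds at defaults (20 seeds × 500 regions), the
  fraction of regions called significant at α = 0.05 falls in
  [0.03, 0.07]. The pooled-normal null is slightly anti-conservative
  (~0.06) because ROI signal totals are heterogeneous while σ is
  pooled — inherent to the single-fitted-normal design.
- Planted skews in {−0.8, −0.4, 0, 0.4, 0.8} at ≥ 500 expected
  fragments per region are recovered with per-level mean absolute
  error ≤ 0.05 after regression normalization, and detection frequency
  is non-decreasing in |s| and in depth.
- Through-origin regression recovers planted scale factors within 1%
  under Poisson noise and exactly (refit slope 1 ± 1e−9) without noise.
- Fisher one-tailed p agrees to 1e−12 with exhaustive hypergeometric
  enumeration over all 2×2 tables with row margins ≤ 12.
- Interval operations agree with brute-force all-pairs oracles.
- The end-to-end report is byte-identical across reruns at fixed seed.

## Numerical and degenerate-input conventions

- Internal coordinates are 0-based half-open everywhere; wiggle's
  1-based inclusive convention is converted at the I/O boundary only.
  Bases with no wiggle/bedGraph record are 0, not missing. Writers emit
  6 significant digits; round trips are exact to that precision.
- Chromosome names are matched exactly (no "chr" aliasing).
- Degenerate region (both halves zero): skew reported as 0 with a flag,
  z/p unset, never significant, excluded from group means.
- Null σ ≤ 1e−12 is treated as exactly degenerate (proportional tracks
  give bit-near-identical RandSkewScores).
- Tukey `diff` is mean(group2) − mean(group1); Fisher odds-ratio
  conventions as above.

## Limitations

- The normal null is an approximation; no empirical (rank-based)
  per-region p-values are offered.
- Matching is on length and total signal only — no GC, mappability or
  chromatin-context covariates.
- One pooled null per analysis; regions with extreme signal totals are
  tested against a σ that averages over the set.
- BAM/SAM parsing, peak calling, deduplication and motif discovery are
  upstream/downstream of this package and are consumed or emitted as
  files only.
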