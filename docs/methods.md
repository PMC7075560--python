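# Methods

This note documents the models implemented in `metharray`, the design
choices made where the procedure was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Preprocessing

**Probe filters.** Applied sequentially, so per-criterion removal counts
are well defined: (1) non-CpG probes (including negative controls and SNP
genotyping probes), (2) probes failing the fluorescence detection limit —
detectable at p ≤ 0.01 in at least 95% of samples, with missing cells
excluded from a probe's denominator, (3) probes with multiple genomic
targets, (4) probes with a SNP at or within 10 bp of the target CpG at
minor-allele frequency ≥ 0.05. Filtering is idempotent, and the report
carries both the input and retained counts; note that the number of probes
actually pooled into a downstream distribution can differ again from the
post-filter count (e.g. after per-analysis missing-value removal), so the
report never conflates the two.

**Detection p-values.** The array chemistry's detection call is not a
published formula, so the package derives it from first principles: for
probe *n* in sample *s*, p = 1 − ecdf(total fluorescence) over that
sample's negative-control probes (≥ 20 required). A pass-through mode
accepts externally supplied detection p-values instead.

**Normalization.** Each channel (methylated, unmethylated) is quantile-
normalized separately across samples: every sample's distribution is
mapped onto the across-sample mean quantile function (midpoint convention;
average ranks, so ties share the mean of their target quantiles). This
subsumes inter-sample color-balance differences; no separate dye-chemistry
model is fitted. *Caveat:* quantile normalization assumes comparable
global distributions. Between a globally hypomethylated tumor group and
normal cells this assumption fails by construction and the transform
partially flattens exactly that global difference — the class-profile
benchmark therefore measures β computed from filtered raw channels.

**Probe-type bias.** Type II probes report compressed β relative to
type I. Rather than a three-state beta-mixture fit, each sample's type II
β values are monotonically quantile-mapped onto that sample's type I β
distribution (piecewise-linear, midpoint convention: identical
distributions map to themselves exactly). The mode is recorded in output
metadata as `quantile-map` so results are never conflated with a
mixture-model correction. Samples with < 50 probes of either design are
skipped with a warning.

**β/M.** β = meth/(meth+unmeth); both channels zero → missing. M =
log₂(β/(1−β)) with β clamped to [ε, 1−ε], ε = 10⁻³, bounding |M| at
log₂(999) ≈ 9.96 so region medians stay finite.

**Stage order** is fixed and logged in metadata: filter → quantile
normalize → β → type-bias correct → M. Whether detection filtering
precedes normalization is an open choice; fixing it keeps per-criterion
accounting stable.

## DMR detection

Candidate regions are maximal chains: walking each chromosome in position
order, a probe extends the open chain iff its gap to the previous probe is
≤ 200 bp (inclusive); chains with ≥ 4 CpGs become candidates. Chains never
span chromosomes, and chaining is invariant to input order (sorting is
internal).

The test populations are the pooled per-probe-per-sample M values of the
region in each group — a region-level distribution comparison rather than
per-probe tests combined. The group construct is the default (the
reported DMR counts are group-level); a pairwise-sample mode accepts
explicit sample lists. U is oriented as the number of (a, b) pairs with
a > b, ties counting ½; effect signs are group_a − group_b.

**Mann-Whitney implementation.** Exact two-sided p for combined n ≤ 30:
tie-aware enumeration of group assignments when the combination count is
feasible (≤ 2·10⁵), otherwise the classic no-tie count recurrence
count(u; m, n) = count(u−n; m−1, n) + count(u; m, n−1). Beyond n = 30, a
normal approximation with tie-corrected variance and a ±½ continuity
correction. Two-sided p doubles the smaller tail (point mass included) and
caps at 1; an all-tied region returns p = 1 without dividing by a zero
variance. The implementation is cross-checked in the test suite against
full permutation enumeration (n ≤ 10) and against an independent library
implementation on the no-tie path — the library is never the
implementation.

**Multiplicity.** Benjamini-Hochberg step-up over all testable regions:
p(i) ← min over j ≥ i of m·p(j)/j, capped at 1, input order restored.
Untestable regions (a group with no non-missing values) are excluded from
m. Calling thresholds: `methods` mode p_adj ≤ 0.05 and |Δ median M| ≥ 1.4;
`results` mode p_adj ≤ 0.01 and |Δ median β| ≥ 0.25. The 25% criterion is
taken on the β scale (the natural "percent methylation" reading; recorded
in output metadata). Both parameterizations are exposed and deliberately
not reconciled.

**Calibration.** Pooling probes × samples makes values within a probe row
correlated (they share the probe's true methylation level); relative to
the iid null the realized U variance is smaller, so the test is
conservative — under a global null the fraction of regions at raw p ≤ 0.05
is far below nominal (measured ≈ 0.002 over 20 seeds × ~65 regions). The
null-calibration benchmark reports this raw-p false-call proportion;
BH-adjusted calls under the null are essentially zero.

## Genomic-class profiles

β histograms over ten bins of width 0.1 ([0.9, 1.0] closed at the top),
pooled over all samples of a group, genome-wide or per genomic class. The
default vocabulary is nine classes — TSS, 5'UTR, gene body, 3'UTR, LINE,
SINE, LTR, CGI, enhancer — with the finer promoter split (TSS1500, TSS200,
first exon) supported via configuration; `TSS` matches the union of the
fine promoter labels. A probe contributes to every class it belongs to.

## CNV calling

Total probe fluorescence (meth + unmeth, floored at 1 a.u.) scales with
copy number. Choices where the published pipeline is silent:

- **Bins** — equal-probe-count runs per chromosome (default 50 probes,
  ~8.9k bins at full 450k scale), remainder merged into the last bin;
  equal probe support equalizes median stability across bins. Autosomes +
  X only.
- **Library scaling** — each sample's median log₂ total is subtracted
  before binning, removing global intensity differences that would mimic
  whole-genome CNV.
- **Baseline** — per bin, the median and MAD across ≥ 3 copy-stable
  control samples (10 female blood-like controls in the benchmarks) of
  the per-sample median log₂ total over bin probes. "Median probe
  fluorescence" is read as the median of log totals (robust to outlier
  probes).
- **Significance** — |ratio| > k·max(MAD, mad_floor), k = 3,
  mad_floor = 0.05; small control cohorts make parametric tests fragile.
  The gain/loss track (+1/−1) is nonzero only for significant bins.
- **States** — the five published cutoffs are kept verbatim, including
  their coarseness: a uniform single-copy loss (expected ratio −1 ≤
  −0.96) lands in the homozygous-deletion state. This is preserved, not
  corrected; "correctly stated" in the benchmarks means a gain state with
  +1 for gains and a deletion state with −1 for losses.
- **chrX** — male samples against the all-female baseline get a +1 log₂
  shift on chrX before thresholding; with sex unspecified, chrX calls are
  suppressed with a warning.

## qPCR

Efficiency is 2^slope of log₂ fluorescence vs cycle over the best
contiguous window of 4–6 cycles, after excluding the saturated plateau
(≥ 90% of maximum) and the baseline below the noise floor (mean + 3 sd of
cycles 1–5) — each restriction applies only while enough candidate cycles
remain, and the window maximizing r² wins (fits with best r² < 0.99 are
flagged low-quality, not discarded). N0 = F/E^Cq with Cq interpolated
log-linearly at the threshold F; the default threshold is the geometric
midpoint of the fitted window, keeping the estimate threshold-invariant
(±5%) within the exponential phase. Replicates are aggregated as the mean
of per-replicate N0; reference normalization divides by the geometric
mean of the two reference genes (arithmetic mode available). An
undetected target yields N0 = 0 with a flag; an undetected reference
makes the ratio undefined.

## Sample-level summaries

Hierarchical clustering (average linkage, Euclidean distance on the top
5,000 most variable β probes by default) and PCA (on centered M values)
are fully deterministic; samples are canonicalized to lexicographic order
before linkage so results do not depend on input order. Distance, linkage,
probe subset and scale are exposed as parameters since none is canonical.
Gene-set enrichment is a one-sided hypergeometric tail with BH across
sets — generic plumbing, not a replica of any online annotation service.

## Synthetic cohorts: what they emulate

The generator's defaults are the benchmark study conditions: 23
chromosomes at 1/100 human genome length, ~20,000 CpG probes plus 100
negative controls; bimodal β (Beta(2,38) and Beta(38,2) modes, mean 0.05
and 0.95); tumor groups re-draw a configurable fraction (default 0.5) of
methylated-mode probes from the unmethylated mode, optionally sparing
promoter/CGI classes; β-scale measurement noise sd 0.02. Sample groups
follow the uncultured/cultured/seminoma/control design (4/4/3/10).

Total intensity is a per-probe lognormal "affinity" (log-sd 0.4) shared
across samples — as on real arrays, where probe brightness is
reproducible and cancels against the control baseline — times
per-(probe,sample) technical noise with log-sd 0.02, calibrated so the
per-bin copy-number noise floor reproduces the platform's detection limit
(aberrations under ~10% mosaic fraction are not called), times copy/2.
Channel decomposition is exact before noise (meth/(meth+unmeth) = true
β); β noise is applied afterwards at fixed total, keeping methylation and
copy number orthogonal by construction. Zero totals are floored at 1 a.u.
so homozygous deletions stay finite.

Planted DMRs are coherent: all probes of a planted region share one base
mode in every group (the mode the shift departs from), and the target
group's M is offset by delta_m — a methylation loss starts from the
methylated mode, a gain from the unmethylated mode, so the planted effect
is observable rather than saturating against the β boundaries. Planted
CNVs scale the total by the effective copy 2(1−f) + f·c for mosaic
fraction f; the control group is copy-2 everywhere by construction and
the configuration rejects CNVs planted in it.

**What passing benchmarks do not show.** The generator has no dye-channel
chemistry, bead-level replicates, batch effects, spatial artifacts, or
cell-type admixture; tumor purity is binary (a mosaic fraction per CNV,
no purity mixture for methylation, although real seminoma hypomethylation
depth tracks lymphocyte infiltration). Recovery rates measured here
therefore bound the method's behavior under clean conditions and say
nothing about batch-confounded or heavily admixed cohorts. Full-scale
probe counts (~485k) and the published bin count (8,949) are not
reproduced at desk scale; bins are ~400 at default size.

## Numerical details

- β clamp ε = 10⁻³ (|M| ≤ log₂ 999); missing values propagate, never
  imputed.
- Exact-test enumeration cap 2·10⁵ combinations; beyond it the corrected
  normal approximation is used even under n ≤ 30 with ties.
- BH uses a stable mergesort so equal p-values keep input order.
- Quantile maps use the midpoint convention ((i−½)/n positions) so
  identical distributions are fixed points exactly.
- CNV thresholds validate strict ordering at construction; every finite
  ratio maps to exactly one state.
- All randomness flows through numpy Generators seeded from the
  configuration; identical configuration and seed give byte-identical
  outputs.
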