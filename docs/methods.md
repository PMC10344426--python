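# Methods

This note documents the models and procedures `finemark` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Coordinate conventions and interval algebra

All coordinates are 0-based half-open; GFF3 input is converted on read and
1-based coordinates never appear internally. Overlap everywhere means
≥ 1 bp intersection and ignores strand (paired-end CUT&RUN fragments are
unstranded). Merging with a gap parameter `d` follows the `bedtools merge
-d` convention: two intervals merge iff the gap between them is ≤ `d`, so
bookended intervals merge at `d = 0`. Intervals crossing a chromosome end
are rejected rather than clipped — silent truncation hides generator and
parser bugs. Interval primitives are sorted-array sweeps; the overlap
count for a query [s, e) is `#{starts < e} − #{ends ≤ s}`, exact for any
interval multiset because the two excluded sets are disjoint when s < e.

## Synthetic data

The generator emulates the *structure* of a two-condition CUT&RUN study of
a repressive mark in a mutant losing a transcription factor: 2 conditions
× 2 replicates of histone-mark fragments, one deeply enriched TF sample
with sub-120-bp fragments, deliberate depth differences between samples,
and a DE gene table with planted classes.

**Model.** Fragment *start* counts per bp are negative binomial with mean
μ = background_rate × depth × ∏(enrichment × condition_fc) and variance
μ(1 + φμ); φ = 0 recovers Poisson. Lengths are uniform per target
(TF: 50–119 bp; histone: 150–400 bp); fragments that would overrun the
chromosome have their length redrawn (start resampled if no admissible
length exists). One seed governs an experiment; each sample uses a
substream keyed by a CRC32 hash of its sample id, so regenerating or
adding samples never perturbs the others.

**Planted truth.** Three region kinds, each serialized as BED + TSV:

- `tf_peak` — 500-bp sites at 25× enrichment in the TF sample, a
  configurable fraction (default 0.74) centred in the promoter windows of
  neuroblast-class genes;
- `low_level_mark` — histone-mark enrichment (default 3×) around a subset
  of TF peaks. The mark region is the peak extended by 750 bp per side
  (default): nucleosomal marks spread over flanking chromatin well beyond
  a factor footprint, and a mark region of roughly 2 kb makes the planted
  regional fold change observable at 500-bp window resolution instead of
  being diluted by within-window background. A configurable fraction
  (default 0.8) of these regions gets condition_fc = 0.4 in the mutant — a
  2.5-fold decrease;
- `broad_domain` — 5–50-kb domains at 8× enrichment, stable across
  conditions, placed ≥ 12 kb apart because domains closer than the 10-kb
  downstream merge are indistinguishable by construction.

**Default scale.** 2 chromosomes × 2.5 Mb at 0.02 fragments/bp and depth
multipliers (1.0, 1.3, 0.8, 1.15) — about 10⁵–2×10⁵ fragments per sample,
seconds to simulate, with enough counts per 500-bp window (~30–50) for the
differential test to have power. These sizes were chosen once as the
package's study conditions and are used by the tests and the acceptance
script.

**What the generator does not emulate**: sequence content, mappability
structure, GC bias, PCR duplicates, fragment-length/enrichment coupling,
and — important for interpretation — *replicate-level* biological
variability: the per-bp NB noise is independent across bp, so at 500-bp
window scale the effective dispersion is ≈ φ/width and window counts are
nearly Poisson. Window-level overdispersion is therefore exercised
directly with NB-simulated count matrices in the test suite rather than
through fragments. Passing tests show the pipeline's bookkeeping,
normalization and error control are correct under these idealized
conditions; they do not certify performance on real libraries with
correlated noise or mappability artifacts.

## Coverage and normalization

Raw binned coverage adds 1 to every bin a fragment overlaps; duplicates
(identical chrom/start/end) can be collapsed and long fragments excluded,
mirroring standard track generation for TF samples (≤ 120 bp). RPKM uses
each bin's true width (the terminal bin may be short). Replicate tracks
are merged by the per-bin arithmetic mean. Z-score tracks subtract the
genome-wide mean over all bins of all chromosomes and divide by the
population standard deviation; a zero-variance track z-scores to all
zeros with a warning rather than an error.

**TMM on reads-in-peaks.** The spike-in-free normalization for histone
marks: count fragments in mark-enriched regions, compute TMM factors on
the regions × samples matrix, and scale each sample's track by
1,000,000 / (tmm × reads_in_peaks). The TMM estimator follows the
published definition exactly (verified against the reference
implementation to 1e−6): reference column by library-scaled upper-quartile
proximity to the mean (ties to the lowest index); M and A over regions
positive in both samples; double-tailed trims of 30 % on M and 5 % on A by
average ranks; inverse delta-method variance weights; factors rescaled to
geometric mean 1. Degenerate inputs (< 2 usable regions) give factor 1
with a warning.

In the end-to-end pipeline the reads-in-peaks region set is the *filtered
broad domains* called on pooled control fragments, not all enriched
islands. TMM assumes most regions are unchanged between conditions; in
data where the changing compartment (low-level peak-local mark) can
dominate the region *count* while the stable domains dominate the read
*mass*, normalizing on all islands lets the trimmed mean land on the
changing regions and skews every scale factor. Counting in the broad
domains — which is also where a peak caller run on the control mark would
put its peaks, low-level enrichment being sub-threshold by definition —
keeps the majority-unchanged assumption true.

## Differential windows

Windows of 500 bp advance by 100 bp (a fixed, configurable step; 1/5 of
the window). Counting is ≥ 1 bp overlap. Windows whose pooled scaled
count is below `min_count = 10` are not tested. Sample exposures are
proportional to 1/scale_j (i.e. tmm_j × reads_in_peaks_j), normalized to
mean 1.

**Test.** An exact conditional NB test: under the null, modelling counts
with gamma shapes proportional to exposure, the pooled treatment count
given the window total is beta-binomial(total, e_t/φ, e_c/φ); at φ ≤ 1e−8
this is the exact binomial split. Two-sided p doubles the smaller tail
(capped at 1). The common dispersion φ is a method-of-moments estimate
pooled across all tested windows: φ = max(0, Σ(v − m·c̄)/Σ m²) with m, v
the within-condition mean and variance of exposure-normalized counts and
c̄ the mean inverse exposure. The exact conditional form was chosen over
a likelihood-ratio χ² because a genome-wide scan consumes the far tail of
the null distribution, where the χ² approximation at 2+2 replicates is
anti-conservative; the discrete exact test is slightly conservative there,
which is the right failure direction for FDR control (verified by null
simulation at 10⁴ windows × 100 repetitions).

BH correction runs over tested windows. Fold change is
log2((mean scaled treatment + 0.5)/(mean scaled control + 0.5)); the 0.5
pseudocount affects fold change only, never the test. Significant windows
are merged into maximal runs (gap 0) *before* kb accounting, so summaries
report region kb, as results in this field are quoted. A consequence of
testing raw counts with exposure offsets: duplicating every sample's
fragments k-fold leaves fold changes bit-identical but legitimately
increases power (q-values shrink) — a test on pre-scaled counts would be
depth-invariant only by double-counting evidence.

## Peak calling and post-processing

The narrow-peak caller is deliberately not a re-implementation of any
published caller: fixed 150-bp windows are tested against
λ = max(genome-wide, 1-kb-local, 10-kb-local) expected counts with a
Poisson upper tail, BH-corrected, and adjacent significant windows joined;
the summit is the maximum-coverage bp (leftmost on ties) and the score is
−log10 of the joined region's minimum q. The local expectations are
flanking means excluding the 5 windows centred on the tested one —
without the exclusion a narrow peak inflates its own background estimate
and caps its own significance; with it, broad elevated regions still
raise the local λ and are not shredded into spurious narrow peaks. The
genome-wide λ floors the estimate, keeping the null calibrated where the
flanks are noisy. Any deterministic caller with controlled false
discovery would do: downstream stages consume peak interval sets.

Post-processing: confidence filtering is strict (−log10 q > 100), the
fragment-size filter is strict (< 120 bp), replicate peak sets merge at
gap 0 with the merged peak taking the maximum constituent score and that
constituent's summit (a conservative convention), the heterochromatin
blacklist merges high-confidence H3K9me3 peaks at gap 3000 bp, and
blacklisting removes any peak with ≥ 1 bp overlap. Shuffled backgrounds
preserve the region count and per-region lengths exactly, forbid overlap
among themselves (otherwise "same number of bp" is not meaningful), allow
chromosome reassignment with probability proportional to chromosome
length, and are deterministic per seed with a 1000-retry placement cap.

## Annotation and gene classes

Peak categories are decided at the summit (midpoint fallback), by
precedence promoter > tts > exonic > intronic > intergenic. The promoter
window is (−1000, +100) bp around the TSS in gene orientation — the
conventional default — and the TTS window mirrors it at the transcript
end; both are configurable. Every peak is assigned the gene with the
nearest TSS on its chromosome. Gene classes follow the rule: DE iff
|FC| > 2 **and** padj < 0.05 (sign → neuroblast- vs immature-INP-
enriched), invariant iff |FC| < 2 regardless of p, otherwise unclassified
(including |FC| exactly 2). The overestimated-variance t-test divides the
comparison group's variance by the focal group's size, a deliberately
conservative marker-test convention; its null p-values are stochastically
larger than uniform, which the tests assert rather than uniformity.

## Broad domains and coverage ratio

Island calling: full 500-bp windows (a terminal partial window is not
tested), expected count λ = N·w/(egf·G) with egf = 0.7 the effective
genome fraction and G the total assembly length; a window is eligible iff
its count reaches the smallest integer whose Poisson upper tail is below
0.2; eligible windows with inter-window gaps ≤ 2 kb cluster; the island
score is Σ −ln P(count; λ) in nats over eligible windows; fragments are
counted at full extent with no shift. Domain filters are strict
(score > 500, length > 3000 bp) and applied *before* the 10-kb merge —
merging never rescues an island that is individually too short, and the
test suite pins this ordering. Region coverage is fragments ≥ 1 bp
overlap per region per replicate, divided by region length, averaged
across replicates; the domain:peak coverage ratio is the ratio of means,
with peaks overlapping any domain excluded first (an empty set after
exclusion is an error, not a ratio). Because overlap counting credits a
region with fragments that only partially overlap it, measured reads/bp
exceeds the local rate by ≈ mean_fragment_length/region_length; for
narrow peak regions against multi-kb domains this biases the measured
ratio a few percent below the planted enrichment ratio, which is inherent
to the reads/length computation and left uncorrected.

## Bin density

Both conditions are subsampled without replacement to exactly equal
fragment counts (depth matching is the point; unequal inputs are an
error). The default fragment→bin assignment is by midpoint, so totals are
conserved and per-bin distributions are comparable across conditions; the
≥ 1 bp any-overlap mode is available, under which the total can only
exceed n. Terminal short bins are kept in tables but excluded from
distribution summaries (width bias).

## Pipeline

`run_pipeline` is a pure function of (config, seed): every stage derives
its randomness from the config seed via stable label hashing, all
intermediates are serialized as BED/bedGraph/TSV, and two runs with the
same config are byte-identical (asserted in the tests). Stage errors
abort with the stage name; configs are YAML with unknown keys rejected.
Defaults: window 500 / step 100, q < 0.05, fold-change cut 2, peak
confidence 100, blacklist gap 3000, island w = 500 / g = 2000 /
egf = 0.7, domain filters 500 / 3000 / 10000, fragment cap 120. The
simulated study has no H3K9me3 sample by default, so the blacklist stage
runs with an empty set; supplying extra regions exercises it.

## Known limitations

- The substitute peak caller and the window test are documented
  replacements, not re-implementations, of MACS2 and diffReps; parameter
  estimates (φ, local λ) are plug-in, not profiled.
- The dispersion estimate is global; no per-window shrinkage.
- Real-data effects (mappability, duplicates, GC, correlated replicate
  noise) are out of the generator's scope, so recovery rates measured
  here are upper bounds on real-data performance.
- bigWig output is not produced; tracks are bedGraph.
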