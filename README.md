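# finemark

Quantification of **low-level histone-mark changes** from CUT&RUN fragment
data, without spike-in normalization.

CUT&RUN maps protein–DNA interactions by digesting chromatin around
antibody-tethered nuclease and sequencing the released fragments:
transcription-factor (TF) footprints release sub-120-bp fragments, while
histone marks release nucleosomal (150–400 bp) fragments. A recurring
analysis problem is detecting *modest* changes in a repressive mark such as
H3K27me3 at TF-bound sites — enrichment far below canonical Polycomb
domains, where peak callers are blind and naive depth normalization is
confounded by library composition. `finemark` implements that analysis as a
reusable, tested pipeline, exercisable end to end on synthetic fragment
data with planted, recorded ground truth:

- **TMM-in-peaks normalization.** Reads are counted in histone-mark-enriched
  regions, trimmed-mean-of-M-values (TMM) factors are computed per sample
  (M = log2 ratio of library-scaled counts vs a reference sample, double-tail
  trims of 30 % on M and 5 % on abundance, precision weights), and the final
  track scale is

  ```
  scale_j = 1,000,000 / (tmm_j × reads_in_peaks_j)
  ```

- **Sliding-window differential enrichment.** 500-bp windows advanced by
  100 bp; per-window counts are compared between conditions with an exact
  negative-binomial conditional test (beta-binomial split of the window
  total, exact binomial in the Poisson limit), with a method-of-moments
  common dispersion and BH correction genome-wide. Significant windows are
  merged into regions before any kb accounting, and summaries are stratified
  by TF-peak binding.
- **Broad-domain calling.** SICER-style islands: fixed 500-bp windows,
  Poisson eligibility against λ = N·w/(egf·G), clustering across gaps
  ≤ 2 kb, island score = Σ −ln P(count; λ). Polycomb-like domains are the
  islands with score > 500 and length > 3 kb, merged within 10 kb and
  between replicates; their reads/bp coverage is compared with TF peaks
  outside them.
- **Peak post-processing.** Strict sub-120-bp fragment filtering, a
  documented local-Poisson substitute peak caller, −log10(q) > 100
  confidence filtering, replicate merging, H3K9me3 blacklisting
  (merge gap 3000 bp), and matched shuffled backgrounds preserving region
  count and length multiset.
- **Annotation and expression classes.** HOMER-style summit categories
  (promoter > tts > exonic > intronic > intergenic, promoter window
  −1000/+100 bp), nearest-TSS gene assignment, and gene classes from a
  differential-expression table: DE iff |FC| > 2 and adjusted p < 0.05,
  invariant iff |FC| < 2.
- **Depth-matched bin density.** Exact subsampling to equal fragment
  counts, 500-bp genome bins, bound/unbound per-condition reads-per-bin
  distributions.

## Worked example

Run the whole synthetic pipeline from the shell:

```
$ finemark run --seed 1 --outdir out
report written to out/report.json
peaks: 100  domains: 12
```

or from Python:

```python
from finemark import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(outdir="out", seed=1))
```

With seed 1 the report contains (abridged):

```
n_tf_peaks                        100
n_pc_domains                      12
bound_gene_fraction   nb_enriched 71.4   (shuffled control: 33.3)
tmm_factors                       1.000, 1.003, 0.997, 1.000
coverage_ratio_domain_over_peak   2.48
diff_summary          frac_down2x 0.905  (bound stratum: 0.95)
```

Reading it: all 100 planted TF binding sites are recovered as
high-confidence peaks; 71.4 % of neuroblast-enriched genes have a bound
peak versus 33.3 % for the length-matched shuffled control. The TMM
factors sit at 1 because the planted composition differences are
concentrated in regions excluded from the normalization set, so the
reads-in-peaks scales absorb the (deliberate) 1.0–1.3× depth differences
between samples. 90.5 % of the significantly changed kb shows a >2-fold
decrease of the mark in the mutant, concentrated at bound regions — the
planted regime. Broad domains carry ~2.5× the reads/bp coverage of the
low-level peak-local mark in this configuration (planted 8× vs 3×
enrichment, measured at called peak intervals).

All intermediates are serialized next to the report: fragment BEDs, peak
and domain BEDs, the normalization table, the per-window differential
table, a volcano-plot TSV (significance line at −log10 0.05 = 1.301), and
bin-density tables. Individual stages are exposed as subcommands
(`simulate`, `coverage`, `normalize`, `callpeaks`, `diffwindows`,
`domains`, `density`, `annotate`) operating on BED/TSV files.

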