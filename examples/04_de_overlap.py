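"""Do the most differentially expressed genes sit in R-loop-prone regions?

Builds a DESeq-style ranked table whose top 100 genes overlap a
DRIPc-seq-like region set at rate 0.6 against a 0.35 background, runs the
permutation test, and summarises an up/down-regulated transcript count.
"""

from rloopkit import (
    de_peak_enrichment,
    de_summary,
    dripc_like_config,
    generate_annotation,
    generate_peaks,
    generate_ranked_table,
)

cfg = dripc_like_config(seed=21)
genes, truth = generate_annotation(cfg)
regions = generate_peaks(genes, truth, cfg)
table = generate_ranked_table(genes, regions, p_top=0.6, p_background=0.35, seed=22)

result = de_peak_enrichment(table, regions, n_top=100, n_perm=1000, seed=23)
print(f"top-100 genes overlapping a region : {result.observed_fraction:.0%}")
print(f"random-100 baseline (null mean)    : {result.null_mean:.1%}")
print(f"permutation p-value                : {result.p_value:.4g}"
      f"  (99% CI [{result.ci_low:.4g}, {result.ci_high:.4g}])")

s = de_summary([f"u{i}" for i in range(2578)], [f"d{i}" for i in range(2435)], 30_769)
print(f"\naltered transcripts: {s.altered} of {s.total_quantified}"
      f" (~{s.percent_altered_rounded}%)")
# The observed ~60% against a ~35% baseline mirrors a strongly R-loop-
# associated expression response; the summary line shows the altered-
# transcript bookkeeping used for whole-transcriptome statements.
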