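"""Permutation enrichment of ChIP-style peaks in highly transcribed genes.

Builds a synthetic study in which 70% of peaks are deliberately placed in
the top decile of transcribed genes, removes bead-control artifacts, and
asks whether the surviving peaks overlap the top-decile genes more than
count-matched random gene sets (1000 permutations, 99% CI).
"""

from rloopkit import (
    SyntheticConfig,
    enrich,
    filter_against_control,
    generate_annotation,
    generate_peaks,
    top_fraction_genes,
)

cfg = SyntheticConfig(seed=11, enrichment_theta=0.7)
genes, truth = generate_annotation(cfg)
peaks = generate_peaks(genes, truth, cfg)

# a small bead-control set: peaks overlapping it are artifacts
control_cfg = SyntheticConfig(seed=91, enrichment_theta=0.0, n_peaks=40)
control = generate_peaks(genes, truth, control_cfg)
clean = filter_against_control(peaks, control)
print(f"peaks: {len(peaks)} -> {len(clean)} after bead-control removal")

top = top_fraction_genes(genes, fraction=0.10)
result = enrich(clean, genes, top, n_perm=1000, seed=17)

print(f"observed overlap fraction : {result.observed_fraction:.3f}")
print(f"null mean +/- sd          : {result.null_mean:.3f} +/- {result.null_sd:.3f}")
print(f"permutation p-value       : {result.p_value:.4g}")
print(f"99% CI for the p-value    : [{result.ci_low:.4g}, {result.ci_high:.4g}]")
# With 70% of peaks targeted at the top decile the observed fraction sits
# far above the ~10% null rate, so p hits its floor 1/(n_perm+1).
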