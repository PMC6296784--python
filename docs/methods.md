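# Methods

## Interval model

All coordinates are 0-based half-open (`[start, end)`, BED convention).
Two intervals overlap iff they share at least one base; abutting intervals
do not overlap; strand is ignored throughout. Overlap queries run on a
per-chromosome interval tree; by construction (and by test) every query
agrees exactly with the naive pairwise definition, so the tree is purely
an acceleration.

Bead-control filtering removes a peak on *any* overlap with a control
interval — no reciprocal-fraction requirement. This is the strictest
literal reading of artifact removal against a no-antibody control; a
fraction-based rule would retain peaks that merely graze an artifact and
would need an extra parameter that nothing in the workflow constrains.

Top-fraction gene selection removes blacklisted genes (e.g. rDNA loci)
first, sorts by expression descending with ties broken by `gene_id`
ascending, and keeps `floor(fraction × n_remaining)` genes. `floor` rather
than rounding is a fixed, documented choice: published "top 10%" counts
depend on the exact source annotation and cannot disambiguate the rounding
rule, so determinism is preferred. Note the edge case: `floor` can return
an empty selection when `fraction × n < 1`.

## Permutation enrichment test

For query intervals `Q` and feature genes `F` within a universe `U`:

* observed statistic: `#{q ∈ Q : q overlaps ≥1 gene of F} / |Q|` (a query
  interval hitting several genes counts once);
* null: `n_perm` draws of `|F|` genes uniformly without replacement from
  `U`; each draw's overlap fraction is recorded. Sampled sets are matched
  in **count only** — not length- or chromosome-matched. This mirrors
  resampling "equal in number" gene sets; covariate-matched or
  rotation-based randomisations are deliberately out of scope;
* p-value: `(r + 1) / (n_perm + 1)` with `r` the number of null fractions
  at least as extreme as the observation. Ties count toward `r`. The
  add-one estimator guarantees `p > 0` and is the standard choice for
  resampling nulls; it can be disabled (`add_one=False`) for the raw
  proportion;
* confidence interval: the exact Clopper–Pearson binomial interval for
  `r / n_perm` at level 0.99 (default), pushed endpoint-wise through the
  same add-one map, so `ci_low ≤ p ≤ ci_high` always holds, including at
  `r = 0`. Clopper–Pearson is chosen for validity at extreme counts rather
  than tightness; the interval quantifies Monte-Carlo uncertainty of the
  permutation estimate, not sampling uncertainty of the experiment.

Internally the null is computed from a precomputed gene-by-peak boolean
overlap matrix (a draw's fraction is a row-union); a test verifies each
draw equals the direct per-draw evaluation, and a second test checks the
null mean against the closed-form hypergeometric expectation
`mean_q [1 − C(n−m_q, k)/C(n, k)]`.

**Conservativeness.** Overlap fractions live on a grid (multiples of
`1/|Q|`), so ties between observed and null values are common and the
tie-inclusive p-value is *super-uniform* under the null — stochastically
larger than uniform. Calibration is therefore checked one-sided: a KS
test against the conservative bound (rejecting only if p-values are
anti-conservative, i.e. too small too often). Users should expect the test
to lose a little power relative to a randomised (mid-p) rule and to never
overstate significance.

The DE front-end (`de_peak_enrichment`) swaps the roles: observed is the
fraction of the top-`n` genes (smallest DE p-values, boundary ties broken
by `gene_id`) overlapping a region set, and the null resamples `n`-gene
sets from the full tested table — not from a whole-genome annotation —
so the test conditions on the genes the DE model actually quantified.
Gene bodies are the overlap unit; promoter or window extensions can be
applied upstream by the caller.

## qPCR quantitation

All formulas assume perfect doubling per cycle (base 2); the dilution of
the measured template enters as `log2(dilution)`. Efficiency-corrected
(non-2 base) models and standard-curve fitting are out of scope.

* ChIP percent enrichment: `100·2^(Ct_in − Ct_IP − log2 d)` minus the same
  term with the mock-IP Ct when a mock was run. A negative mock-subtracted
  value is reported as-is with a `below_background` flag — clipping at zero
  would bias any later normalisation.
* DRIP fold over input: `2^(Ct_in − log2 d − Ct_DRIP)`; an empty-bead mock
  IP, when present, is subtracted on the fold scale (same flag rule).
* Comparative Ct: `2^−ΔΔCt` with `ΔCt = Ct_target − Ct_reference` per
  condition.
* Relative normalisation divides per-locus values by a designated
  reference sample (which becomes 1.0); a missing or non-positive
  reference raises, naming the locus.
* Linear-range dilution selection keeps, per (sample, locus, role), the
  well whose Ct lies inside a window (default 15–32 cycles, configurable —
  a conventional linear range, as instrument-specific limits vary), nearest
  the midpoint on ties; if none qualifies the nearest well is returned
  flagged `ct_out_of_linear_range`.

Replicates: Cts are averaged within (sample, locus, role) *before* formula
evaluation (the default; `average="value"` switches to averaging
replicate-wise derived values). The reported spread is the standard
deviation of replicate-wise derived values, replicates matched by id.
Both conventions occur in practice; Ct-averaging is the default because it
matches how plates are usually summarised and keeps the log2-scale
estimate unbiased under Gaussian Ct noise.

## Synthetic data

Generators are pure functions of `(config, seed)` (numpy PCG64 streams;
sub-stages use fixed offsets of the config seed) and every generated
artifact round-trips bit-exactly through the package's writers/readers
(floats serialised at `%.17g`, parsed with round-trip precision).

* **Annotation**: genes split round-robin across chromosomes; lengths
  drawn Normal(mean, mean/4) truncated at 100 bp; starts placed by
  distributing the leftover sequence uniformly among gaps (uniform
  non-overlapping arrangement; infeasible densities raise). Expression is
  log-normal(μ=2, σ=1 by default) and assigned independently of gene
  geometry — which makes the top decile an exchangeable random gene
  subset, the property that makes the calibration checks exact.
* **Peaks**: each peak independently lands, with probability
  `enrichment_theta`, uniformly inside a uniformly chosen top-fraction
  gene (overlap guaranteed; the top set is computed with the same floor
  rule as the analysis, so truth and analysis agree by construction), else
  uniformly on the genome. The realised in-top count is recorded.
* **Ct plates**: well Cts are obtained by inverting the quantitation
  formulas at the configured true folds, with independent Gaussian noise
  (sd 0.2 cycles by default — a typical technical-replicate spread) added
  to *every* well including inputs and references. At zero noise the
  pipeline inverts exactly; under noise `2^ε` is log-normal, so recovery
  is unbiased on the log2 scale (and tested there).
* **Ranked DE tables**: `n_top_true` top slots and `n_background`
  background slots are filled from the annotation, each slot taking a
  peak-overlapping gene with its configured probability (`p_top` /
  `p_background`). Slots are filled in *random order* so that, if an
  overlap pool runs dry, the shortfall hits top and background slots
  symmetrically — filling top slots first was observed (by the calibration
  suite) to bias the test anti-conservative at equal probabilities. Top
  slots get vanishing p-values and up/down directions at a configurable
  split; background slots are `unchanged` with p-values ≥ 0.01.

Default study conditions: 3 chromosomes × 300 kb, 600 genes (~800 bp),
150 peaks × 400 bp, top fraction 0.10, 1000 permutations — a compact
yeast-like genome on which every analysis completes in seconds while all
statistics stay away from degenerate regimes. The DE scenario uses
`dripc_like_config` (450 regions): maps of R-loop-prone regions are far
denser than point-source ChIP peaks, and with ~45% of genes inside a
region, top/background overlap rates of 0.6/0.35 are realisable without
pool saturation.

What the generators do **not** emulate: read-level noise, peak-calling
uncertainty, fragment-size effects, chromatin accessibility or sequence
composition, correlated expression structure, amplification-efficiency
drift, inter-plate batch effects. Passing tests therefore demonstrate the
*statistical machinery* — calibration, power at known effect sizes, exact
formula inversion, determinism — not robustness to those real-data
artifacts.

## Numerical and interface choices

* RNG: `numpy.random.default_rng` exclusively; seeds threaded explicitly;
  same seed ⇒ bitwise-identical results end to end (tested).
* Deterministic orderings everywhere: intervals by (chrom, start, end),
  gene selections by (expression desc, gene_id asc), DE ranks by
  (p-value, gene_id).
* Empty query sets make the overlap fraction undefined and raise rather
  than return 0 or NaN.
* The CLI is a thin layer over the library; each stage writes a JSON
  report (config echo, seed, package version, MD5 of inputs) sufficient to
  re-run it.

## Known limitations

* Count-matched (not length/GC/chromosome-matched) null gene sets: on
  genomes with strong covariate structure the null can be optimistic;
  rotation or covariate-matched randomisation would be the upgrade path.
* Tie-inclusive p-values are conservative on coarse grids (few query
  intervals); power suffers accordingly.
* qPCR modelling assumes perfect doubling and a single dilution per well
  group (mixed dilutions within a group raise; run the linear-range
  selector first).
* The altered-transcript summary treats the up/down sets as given; it does
  no thresholding of the DE table itself.
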