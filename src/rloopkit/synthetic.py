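"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the pipeline's real
inputs — a small yeast-like genome annotation with log-normal expression
levels, ChIP-style peak sets whose affinity for highly transcribed genes
is a single tunable probability, qPCR Ct plates produced by inverting the
quantitation formulas under Gaussian cycle noise, and DESeq-style ranked
tables with controlled peak-overlap structure.  Every generator is a pure
function of (config, seed), so any run is reproducible bit-for-bit.

Defaults describe a compact genome (3 chromosomes x 300 kb, 600 genes,
150 peaks of 400 bp) sized so that full analyses complete in seconds while
leaving every statistic well away from degenerate regimes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .de_overlap import RankedGene
from .intervals import GeneRecord, GenomicInterval, IntervalSet, top_fraction_genes
from .qpcr import CtRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "dripc_like_config",
    "generate_annotation",
    "generate_peaks",
    "simulate_ct",
    "generate_ranked_table",
]

#: Default true enrichment folds per qPCR locus (DRIP/ddCt designs) or
#: true percent-enrichment levels (ChIP design).
DEFAULT_TRUE_FOLDS = {"ADH1": 4.0, "PMA1": 8.0, "SNR13": 2.0}


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of the synthetic study.

    ``enrichment_theta`` is the probability that each peak is placed inside
    a uniformly chosen top-fraction gene rather than uniformly on the
    genome; 0 gives a null (unenriched) peak set, 1 a fully enriched one.
    ``ct_noise_sd`` is the Gaussian well-to-well noise on the Ct scale.
    """

    n_chroms: int = 3
    chrom_length: int = 300_000
    n_genes: int = 600
    gene_length_mean: int = 800
    expression_mu: float = 2.0
    expression_sigma: float = 1.0
    n_peaks: int = 150
    peak_length: int = 400
    enrichment_theta: float = 0.0
    top_fraction: float = 0.10
    ct_noise_sd: float = 0.2
    ct_input_baseline: float = 20.0
    dilution: float = 10.0
    n_replicates: int = 3
    mock_percent: float = 0.5
    true_folds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_FOLDS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_genes", "gene_length_mean",
                     "n_peaks", "peak_length", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.enrichment_theta <= 1.0):
            raise ValueError("enrichment_theta must be in [0, 1]")
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_folds"] = dict(d["true_folds"])
        return d


@dataclass
class SyntheticTruth:
    """What the generator actually did, kept for recovery tests."""

    config: SyntheticConfig
    top_gene_ids: tuple[str, ...] = ()
    true_folds: dict[str, float] = field(default_factory=dict)
    peak_in_top_count: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "top_gene_ids": list(self.top_gene_ids),
            "true_folds": self.true_folds,
            "peak_in_top_count": self.peak_in_top_count,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def dripc_like_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Study conditions for the DE-table scenario: a DRIPc-seq-style region set.

    Maps of R-loop-prone regions are far denser than point-source ChIP
    peaks — roughly a third of all tested genes overlap such a region even
    before any perturbation.  450 peaks on the default genome put about
    45% of genes inside a region, so ranked tables with top-gene overlap
    probability up to ~0.6 against a ~0.35 background are realisable
    without pool exhaustion.
    """
    params = dict(n_peaks=450, peak_length=400, enrichment_theta=0.0)
    params.update(overrides)
    return SyntheticConfig(seed=seed, **params)


def generate_annotation(
    config: SyntheticConfig,
) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Place non-overlapping genes uniformly; draw log-normal expression.

    Genes are split round-robin across chromosomes; per chromosome, gene
    lengths are drawn around ``gene_length_mean`` and starts are placed by
    distributing the leftover sequence uniformly among the gaps, which
    yields a uniform non-overlapping arrangement.  Raises if the requested
    gene density does not fit.
    """
    rng = np.random.default_rng(config.seed)
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    genes: list[GeneRecord] = []
    gene_idx = 0
    for c, n_c in enumerate(per_chrom):
        if n_c == 0:
            continue
        lengths = np.maximum(
            100,
            rng.normal(config.gene_length_mean, config.gene_length_mean / 4, n_c).astype(int),
        )
        total = int(lengths.sum())
        slack = config.chrom_length - total
        if slack < 0:
            raise ValueError(
                f"generate_annotation: genes do not fit on {_chrom_name(c)} "
                f"({total} bp of gene > {config.chrom_length} bp)"
            )
        # uniform gap allocation: sorted draws from the slack positions
        offsets = np.sort(rng.integers(0, slack + 1, size=n_c))
        starts = offsets + np.concatenate(([0], np.cumsum(lengths[:-1])))
        for s, length in zip(starts, lengths):
            genes.append(
                GeneRecord(
                    gene_id=f"g{gene_idx:04d}",
                    interval=GenomicInterval(_chrom_name(c), int(s), int(s + length)),
                    expression=0.0,
                )
            )
            gene_idx += 1

    # expression independent of geometry: assign after placement
    expr = rng.lognormal(config.expression_mu, config.expression_sigma, len(genes))
    genes = [dataclasses.replace(g, expression=float(e)) for g, e in zip(genes, expr)]

    top = top_fraction_genes(genes, config.top_fraction)
    truth = SyntheticTruth(
        config=config,
        top_gene_ids=tuple(g.gene_id for g in top),
        true_folds=dict(config.true_folds),
    )
    return genes, truth


def generate_peaks(
    annotation: Sequence[GeneRecord],
    truth: SyntheticTruth,
    config: SyntheticConfig | None = None,
) -> IntervalSet:
    """Place peaks with probability ``enrichment_theta`` inside top genes.

    Each peak independently either lands uniformly inside a uniformly
    chosen top-fraction gene (guaranteeing overlap) or uniformly on the
    genome.  The realised count of top-targeted peaks is recorded in
    ``truth.peak_in_top_count``.
    """
    cfg = config if config is not None else truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    top_ids = set(truth.top_gene_ids)
    top_genes = [g for g in annotation if g.gene_id in top_ids]
    if cfg.enrichment_theta > 0 and not top_genes:
        raise ValueError("generate_peaks: no top genes to target")
    chrom_names = [_chrom_name(i) for i in range(cfg.n_chroms)]
    peaks: list[GenomicInterval] = []
    in_top = 0
    for _ in range(cfg.n_peaks):
        if rng.random() < cfg.enrichment_theta:
            gene = top_genes[rng.integers(len(top_genes))]
            giv = gene.interval
            hi = max(giv.start, giv.end - cfg.peak_length)
            chrom = giv.chrom
            start = int(rng.integers(giv.start, hi + 1))
            in_top += 1
        else:
            chrom = chrom_names[rng.integers(cfg.n_chroms)]
            start = int(rng.integers(0, cfg.chrom_length - cfg.peak_length + 1))
        end = min(start + cfg.peak_length, cfg.chrom_length)
        peaks.append(GenomicInterval(chrom, start, end))
    truth.peak_in_top_count = in_top
    return IntervalSet(peaks, name="synthetic_peaks")


def simulate_ct(
    truth: SyntheticTruth,
    design: str = "drip",
    config: SyntheticConfig | None = None,
) -> list[CtRecord]:
    """Simulate a Ct plate by inverting the quantitation formulas.

    * ``drip``: ``Ct_drip = Ct_input - log2(dilution) - log2(F) + eps`` so
      the fold formula recovers F exactly at zero noise; an empty-bead mock
      with negligible material is not simulated (fold truths are post-mock).
    * ``chip``: the IP well carries the true percent level plus a mock
      level ``mock_percent``; the mock well carries ``mock_percent`` alone,
      so mock subtraction recovers the true percent.
    * ``ddct``: target Ct in the treated sample sits ``log2(F)`` cycles
      below the control sample's; reference-locus wells are level.

    Noise ``eps ~ Normal(0, ct_noise_sd)`` is added independently to every
    well, including input and reference wells.
    """
    cfg = config if config is not None else truth.config
    if design not in ("drip", "chip", "ddct"):
        raise ValueError(f"design must be drip|chip|ddct, got {design!r}")
    if not truth.true_folds:
        raise ValueError("simulate_ct: truth.true_folds is empty")
    rng = np.random.default_rng(cfg.seed + 2)
    log_d = math.log2(cfg.dilution)
    base = cfg.ct_input_baseline
    sd = cfg.ct_noise_sd
    records: list[CtRecord] = []

    def noisy(ct: float) -> float:
        return float(ct + rng.normal(0.0, sd)) if sd > 0 else float(ct)

    for locus, fold in sorted(truth.true_folds.items()):
        if fold <= 0:
            raise ValueError(f"simulate_ct: true fold for {locus} must be > 0")
        for rep in range(1, cfg.n_replicates + 1):
            if design == "drip":
                records.append(CtRecord("sim", locus, "input", cfg.dilution, noisy(base), rep))
                ct_drip = base - log_d - math.log2(fold)
                records.append(CtRecord("sim", locus, "drip", cfg.dilution, noisy(ct_drip), rep))
            elif design == "chip":
                # fold is interpreted as true percent enrichment over input
                records.append(CtRecord("sim", locus, "input", cfg.dilution, noisy(base), rep))
                ct_ip = base - log_d - math.log2((fold + cfg.mock_percent) / 100.0)
                ct_mock = base - log_d - math.log2(cfg.mock_percent / 100.0)
                records.append(CtRecord("sim", locus, "ip", cfg.dilution, noisy(ct_ip), rep))
                records.append(CtRecord("sim", locus, "mock", cfg.dilution, noisy(ct_mock), rep))
            else:  # ddct
                for sample, f in (("control", 1.0), ("treated", fold)):
                    ct_t = base - math.log2(f)
                    records.append(CtRecord(sample, locus, "ip", 1.0, noisy(ct_t), rep))
    if design == "ddct":
        for sample in ("control", "treated"):
            for rep in range(1, cfg.n_replicates + 1):
                records.append(CtRecord(sample, "REF", "reference", 1.0, noisy(base), rep))
    return records


def generate_ranked_table(
    annotation: Sequence[GeneRecord],
    peaks: IntervalSet,
    p_top: float,
    p_background: float,
    n_top_true: int = 100,
    n_background: int = 300,
    frac_up: float = 0.5,
    seed: int = 0,
) -> list[RankedGene]:
    """DESeq-style ranked table whose top genes hit peaks at a known rate.

    Genes are drawn from the annotation: each of the ``n_top_true`` top
    slots takes a peak-overlapping gene with probability ``p_top`` (else a
    non-overlapping one), background slots likewise at ``p_background``.
    Top genes receive vanishingly small p-values (up/down split at
    ``frac_up``); background genes receive larger ones and are
    ``unchanged``.  When the pools run dry the realised rate simply
    saturates at what the genome offers.
    """
    for name, p in (("p_top", p_top), ("p_background", p_background)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    if n_top_true + n_background > len(annotation):
        raise ValueError("generate_ranked_table: more table rows than annotation genes")
    rng = np.random.default_rng(seed)
    hit_pool = [g for g in annotation if peaks.overlaps_any(g.interval)]
    miss_pool = [g for g in annotation if not peaks.overlaps_any(g.interval)]
    hit_pool = [hit_pool[i] for i in rng.permutation(len(hit_pool))]
    miss_pool = [miss_pool[i] for i in rng.permutation(len(miss_pool))]

    def draw(p: float) -> GeneRecord:
        want_hit = rng.random() < p
        pool = hit_pool if want_hit else miss_pool
        if not pool:
            pool = miss_pool if want_hit else hit_pool
        return pool.pop()

    # Fill slots in random order so that, if a pool runs dry, the fallback
    # affects top and background slots symmetrically (otherwise equal
    # probabilities would not give an exchangeable, calibrated table).
    slots = ["top"] * n_top_true + ["bg"] * n_background
    chosen: dict[int, GeneRecord] = {}
    for slot_idx in rng.permutation(len(slots)):
        chosen[int(slot_idx)] = draw(p_top if slots[slot_idx] == "top" else p_background)

    table: list[RankedGene] = []
    for i in range(n_top_true):
        g = chosen[i]
        direction = "up" if rng.random() < frac_up else "down"
        table.append(
            RankedGene(g.gene_id, g.interval, p_value=float((i + 1) * 1e-9), direction=direction)
        )
    for j in range(n_background):
        g = chosen[n_top_true + j]
        table.append(
            RankedGene(
                g.gene_id,
                g.interval,
                p_value=float(0.01 + 0.99 * rng.random()),
                direction="unchanged",
            )
        )
    return table
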