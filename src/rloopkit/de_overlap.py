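"""Differential-expression front-end for the overlap-enrichment machinery.

Given a table of genes ranked by differential-expression p-value, the
question is whether the most strongly altered genes fall inside previously
mapped R-loop-prone regions (DRIPc-seq peaks) more often than randomly
chosen tested genes do.  The null resamples gene sets of the same size
from the *full tested table* — not from a whole-genome annotation — so the
test conditions on which genes the DE model actually quantified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .enrichment import EnrichmentResult, observed_overlap_fraction, permutation_test
from .intervals import GenomicInterval, GeneRecord, IntervalSet

__all__ = [
    "RankedGene",
    "DESummary",
    "read_ranked_table",
    "write_ranked_table",
    "top_ranked",
    "de_peak_enrichment",
    "de_summary",
]

DIRECTIONS = ("up", "down", "unchanged")


@dataclass(frozen=True)
class RankedGene:
    """One row of a DE result table: gene, its locus, p-value, direction."""

    gene_id: str
    interval: GenomicInterval
    p_value: float
    direction: str = "unchanged"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"gene {self.gene_id}: p_value must be in [0, 1]")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"gene {self.gene_id}: direction must be one of {DIRECTIONS}"
            )


@dataclass(frozen=True)
class DESummary:
    """Counts of transcripts altered by a perturbation."""

    n_up: int
    n_down: int
    total_quantified: int
    altered: int
    percent_altered: float
    percent_altered_rounded: int


_RANKED_COLS = ["gene_id", "chrom", "start", "end", "p_value", "direction"]


def read_ranked_table(path: str | Path) -> list[RankedGene]:
    """Read a ranked DE TSV (``gene_id chrom start end p_value direction``)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"gene_id": str, "chrom": str, "direction": str})
    missing = [c for c in _RANKED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: ranked table missing columns {missing}")
    table = [
        RankedGene(
            gene_id=row.gene_id,
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
            p_value=float(row.p_value),
            direction=row.direction,
        )
        for row in df.itertuples(index=False)
    ]
    ids = [g.gene_id for g in table]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate gene_id in ranked table")
    return table


def write_ranked_table(table: Sequence[RankedGene], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in table],
            "chrom": [g.interval.chrom for g in table],
            "start": [g.interval.start for g in table],
            "end": [g.interval.end for g in table],
            "p_value": [g.p_value for g in table],
            "direction": [g.direction for g in table],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def top_ranked(table: Sequence[RankedGene], n: int) -> list[RankedGene]:
    """The *n* genes with smallest DE p-value; boundary ties break by gene_id."""
    if not (1 <= n <= len(table)):
        raise ValueError(f"top_ranked: need 1 <= n <= |table| = {len(table)}, got {n}")
    return sorted(table, key=lambda g: (g.p_value, g.gene_id))[:n]


def de_peak_enrichment(
    table: Sequence[RankedGene],
    peaks: IntervalSet,
    n_top: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
    ci_level: float = 0.99,
) -> EnrichmentResult:
    """Enrichment of the top-*n_top* DE genes for overlap with peak regions.

    Observed statistic: the fraction of the top genes whose body overlaps
    at least one peak.  Null: ``n_perm`` draws of ``n_top`` genes uniformly
    without replacement from the full tested table, one-sided (greater)
    permutation p-value with a 99% Clopper-Pearson CI by default.
    """
    top = top_ranked(table, n_top)
    query = IntervalSet((g.interval for g in top), name="top_de_genes")
    observed = observed_overlap_fraction(query, peaks)
    # Each permutation draws n_top genes from the full tested table and
    # measures their peak-overlap rate (gene-side fraction).
    universe = [
        GeneRecord(gene_id=g.gene_id, interval=g.interval, expression=0.0) for g in table
    ]
    null = _gene_side_null(peaks, universe, k=n_top, n_perm=n_perm, seed=seed)
    return permutation_test(observed, null, tail="greater", ci_level=ci_level)


def _gene_side_null(
    peaks: IntervalSet,
    universe: Sequence[GeneRecord],
    k: int,
    n_perm: int,
    seed: int,
):
    """Null of gene-side overlap fractions: of k sampled genes, how many hit a peak."""
    import numpy as np

    from .enrichment import NullDistribution

    if not (1 <= k <= len(universe)):
        raise ValueError(f"need 1 <= k <= |universe|, got k={k}")
    rng = np.random.default_rng(seed)
    hit = np.array([peaks.overlaps_any(g.interval) for g in universe], dtype=bool)
    fractions = np.empty(n_perm)
    n_u = len(universe)
    for i in range(n_perm):
        idx = rng.choice(n_u, size=k, replace=False)
        fractions[i] = hit[idx].mean()
    return NullDistribution(tuple(float(f) for f in fractions), n_perm=n_perm, seed=seed)


def de_summary(
    up: Sequence[str],
    down: Sequence[str],
    total_quantified: int,
) -> DESummary:
    """Summarise how many quantified transcripts a perturbation altered.

    ``altered = |up| + |down|`` and ``percent_altered = 100 * altered /
    total_quantified`` (returned both exact and rounded to the nearest
    integer, the form such counts are quoted in).
    """
    up_set, down_set = set(up), set(down)
    both = up_set & down_set
    if both:
        raise ValueError(f"de_summary: genes in both up and down sets: {sorted(both)[:5]}")
    if total_quantified <= 0:
        raise ValueError("de_summary: total_quantified must be positive")
    altered = len(up_set) + len(down_set)
    if altered > total_quantified:
        raise ValueError("de_summary: more altered genes than quantified transcripts")
    percent = 100.0 * altered / total_quantified
    return DESummary(
        n_up=len(up_set),
        n_down=len(down_set),
        total_quantified=total_quantified,
        altered=altered,
        percent_altered=percent,
        percent_altered_rounded=round(percent),
    )
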