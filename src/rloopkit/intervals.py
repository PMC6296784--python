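"""Genomic interval primitives, BED I/O, overlap queries and gene selection.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  Two intervals overlap iff they share at least one base;
abutting intervals do not overlap.  Strand is ignored everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "IntervalSet",
    "BedParseError",
    "overlaps",
    "read_bed",
    "write_bed",
    "read_annotation",
    "write_annotation",
    "filter_against_control",
    "top_fraction_genes",
]


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; carries the 1-based line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on a named chromosome.

    Sorts by ``(chrom, start, end)``, which fixes the deterministic
    iteration order of every interval collection in this package.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:[{self.start},{self.end})"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff *a* and *b* share >= 1 base (same chromosome, any overlap)."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


@dataclass(frozen=True)
class GeneRecord:
    """A gene: an interval, a unique identifier, and an expression level."""

    gene_id: str
    interval: GenomicInterval
    expression: float

    def __post_init__(self) -> None:
        if not (self.expression >= 0):
            raise ValueError(f"gene {self.gene_id}: expression must be >= 0")


class IntervalSet:
    """An ordered, named collection of :class:`GenomicInterval`.

    Intervals are stored and iterated in ``(chrom, start, end)`` sort order.
    An interval-tree index per chromosome backs all overlap queries; query
    results are always identical to the naive pairwise definition.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), name: str = "") -> None:
        self.name = name
        self._intervals: tuple[GenomicInterval, ...] = tuple(sorted(intervals))
        self._trees: dict[str, IntervalTree] | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalSet(name={self.name!r}, n={len(self)})"

    # -- queries ------------------------------------------------------------
    def _index(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self._intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
            self._trees = trees
        return self._trees

    def overlaps_any(self, query: GenomicInterval) -> bool:
        """True iff *query* overlaps at least one interval of this set."""
        tree = self._index().get(query.chrom)
        return bool(tree is not None and tree.overlap(query.start, query.end))


# -- BED I/O ----------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path: str | Path, name: str | None = None) -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet`.

    Columns beyond the first three are ignored; ``track``/``browser``
    headers, comments and blank lines are skipped.  Malformed coordinates
    raise :class:`BedParseError` naming the offending line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate {s!r}/{e!r}"
                ) from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals, name=name if name is not None else path.stem)


def write_bed(interval_set: IntervalSet, path: str | Path) -> None:
    """Write sorted BED3 lines (tab-separated, no trailing whitespace)."""
    with open(path, "w") as fh:
        for iv in interval_set:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# -- gene annotation tables -------------------------------------------------

_ANNOT_COLS = ["gene_id", "chrom", "start", "end", "expression"]


def read_annotation(path: str | Path) -> list[GeneRecord]:
    """Read a gene annotation TSV (``gene_id chrom start end expression``)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation table missing columns {missing}")
    genes = [
        GeneRecord(
            gene_id=row.gene_id,
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
            expression=float(row.expression),
        )
        for row in df.itertuples(index=False)
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate gene_id in annotation")
    return genes


def write_annotation(genes: Sequence[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.interval.chrom for g in genes],
            "start": [g.interval.start for g in genes],
            "end": [g.interval.end for g in genes],
            "expression": [g.expression for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# -- peak filtering and gene selection --------------------------------------


def filter_against_control(peaks: IntervalSet, control: IntervalSet) -> IntervalSet:
    """Drop every peak that overlaps any control interval.

    This is the bead-control artifact filter: a single base of overlap with
    a no-antibody control peak removes the peak (no reciprocal-fraction
    requirement).  Surviving peaks keep their order.
    """
    survivors = [p for p in peaks if not control.overlaps_any(p)]
    return IntervalSet(survivors, name=peaks.name)


def top_fraction_genes(
    genes: Sequence[GeneRecord],
    fraction: float,
    blacklist: Iterable[str] = (),
) -> list[GeneRecord]:
    """Select the most highly expressed ``floor(fraction * n)`` genes.

    Blacklisted gene ids (e.g. rDNA loci) are removed *before* the cutoff is
    computed, so ``n`` is the count of non-blacklisted genes.  Sorting is by
    expression descending with ties broken by ``gene_id`` ascending, which
    makes the selection deterministic.
    """
    if not genes:
        raise ValueError("top_fraction_genes: empty gene collection")
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    black = set(blacklist)
    eligible = [g for g in genes if g.gene_id not in black]
    eligible.sort(key=lambda g: (-g.expression, g.gene_id))
    k = math.floor(fraction * len(eligible))
    return eligible[:k]
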