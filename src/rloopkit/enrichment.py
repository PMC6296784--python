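"""Permutation-resampling overlap enrichment of an interval set against gene sets.

The test asks whether a set of query intervals (ChIP-seq peaks, say)
overlaps a feature gene set (e.g. the top 10% of transcribed genes) more
often than it overlaps randomly chosen gene sets of the same size.  The
null distribution is built by repeatedly sampling ``k`` genes without
replacement from the universe and recording the fraction of query
intervals that hit at least one sampled gene.

The permutation p-value uses the add-one estimator ``(r + 1) / (n + 1)``
with ties counted as exceedances, and carries an exact Clopper-Pearson
binomial confidence interval (default level 0.99) for the Monte-Carlo
uncertainty of the exceedance proportion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, GeneRecord, IntervalSet

__all__ = [
    "NullDistribution",
    "EnrichmentResult",
    "observed_overlap_fraction",
    "gene_overlap_matrix",
    "sample_null",
    "permutation_test",
    "enrich",
]


@dataclass(frozen=True)
class NullDistribution:
    """Resampled overlap fractions: one entry per permutation."""

    fractions: tuple[float, ...]
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.fractions) != self.n_perm:
            raise ValueError("NullDistribution: |fractions| != n_perm")
        if any(not (0.0 <= f <= 1.0) for f in self.fractions):
            raise ValueError("NullDistribution: fractions must lie in [0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed overlap fraction with its permutation-null summary.

    ``ci_low <= p_value <= ci_high`` holds by construction: the confidence
    interval is the exact binomial interval for the exceedance proportion,
    pushed endpoint-wise through the same add-one map as the p-value.
    """

    observed_fraction: float
    null_mean: float
    null_sd: float
    p_value: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_perm: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def observed_overlap_fraction(query: IntervalSet, targets: IntervalSet) -> float:
    """Fraction of query intervals overlapping at least one target interval.

    A query interval hitting several targets still counts once.  Undefined
    (raises) for an empty query set.
    """
    if len(query) == 0:
        raise ValueError("observed_overlap_fraction: empty query set")
    hits = sum(1 for q in query if targets.overlaps_any(q))
    return hits / len(query)


def gene_overlap_matrix(
    query: IntervalSet, universe: Sequence[GeneRecord]
) -> np.ndarray:
    """Boolean matrix ``M[i, j]``: does universe gene *i* overlap query interval *j*.

    The row-wise union over a sampled gene subset reproduces
    :func:`observed_overlap_fraction` of the query against that subset; the
    matrix is precomputed once so thousands of permutations are cheap.
    """
    n_q = len(query)
    mat = np.zeros((len(universe), n_q), dtype=bool)
    # index query intervals by chromosome once
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(query):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    from intervaltree import IntervalTree

    trees = {
        chrom: IntervalTree.from_tuples((s, e, j) for s, e, j in items)
        for chrom, items in by_chrom.items()
    }
    for i, gene in enumerate(universe):
        tree = trees.get(gene.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(gene.interval.start, gene.interval.end):
            mat[i, hit.data] = True
    return mat


def sample_null(
    query: IntervalSet,
    universe: Sequence[GeneRecord],
    k: int,
    n_perm: int,
    seed: int,
) -> NullDistribution:
    """Null overlap fractions from ``n_perm`` random gene sets of size ``k``.

    Each permutation draws ``k`` distinct genes uniformly without
    replacement from the universe (count-matched only: sampled sets are not
    length- or chromosome-matched) and records the fraction of query
    intervals overlapping the sampled genes.  Fully reproducible given
    ``seed``.
    """
    if len(query) == 0:
        raise ValueError("sample_null: empty query set")
    if not (1 <= k <= len(universe)):
        raise ValueError(f"sample_null: need 1 <= k <= |universe|, got k={k}")
    if n_perm < 1:
        raise ValueError("sample_null: n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    mat = gene_overlap_matrix(query, universe)
    n_u = len(universe)
    fractions = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n_u, size=k, replace=False)
        fractions[i] = mat[idx].any(axis=0).mean()
    return NullDistribution(tuple(float(f) for f in fractions), n_perm=n_perm, seed=seed)


def _clopper_pearson(r: int, n: int, level: float) -> tuple[float, float]:
    """Exact binomial CI for a proportion r/n (valid at r = 0 and r = n)."""
    alpha = 1.0 - level
    lo = 0.0 if r == 0 else float(stats.beta.ppf(alpha / 2, r, n - r + 1))
    hi = 1.0 if r == n else float(stats.beta.ppf(1 - alpha / 2, r + 1, n - r))
    return lo, hi


def permutation_test(
    observed: float,
    null: NullDistribution,
    tail: str = "greater",
    ci_level: float = 0.99,
    add_one: bool = True,
) -> EnrichmentResult:
    """Permutation p-value of *observed* against a resampled null.

    ``r`` counts null fractions at least as extreme as the observation
    (``>=`` for tail="greater", ``<=`` for tail="less"; ties count, which is
    conservative).  The p-value is ``(r + 1) / (n_perm + 1)`` (or ``r /
    n_perm`` with ``add_one=False``), and the confidence interval is the
    exact Clopper-Pearson interval for ``r / n_perm`` mapped endpoint-wise
    through the same estimator.
    """
    if null.n_perm == 0:
        raise ValueError("permutation_test: empty null distribution")
    if tail not in ("greater", "less"):
        raise ValueError(f"tail must be 'greater' or 'less', got {tail!r}")
    if not (0.0 < ci_level < 1.0):
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    fr = np.asarray(null.fractions)
    n = null.n_perm
    r = int((fr >= observed).sum()) if tail == "greater" else int((fr <= observed).sum())

    def estimator(prop: float) -> float:
        return (prop * n + 1) / (n + 1) if add_one else prop

    p_value = estimator(r / n)
    lo, hi = _clopper_pearson(r, n, ci_level)
    return EnrichmentResult(
        observed_fraction=float(observed),
        null_mean=float(fr.mean()),
        null_sd=float(fr.std(ddof=1)) if n > 1 else 0.0,
        p_value=float(p_value),
        ci_low=float(estimator(lo)),
        ci_high=float(estimator(hi)),
        ci_level=ci_level,
        n_perm=n,
        seed=null.seed,
    )


def enrich(
    query: IntervalSet,
    universe: Sequence[GeneRecord],
    feature_set: Sequence[GeneRecord],
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "greater",
    ci_level: float = 0.99,
) -> EnrichmentResult:
    """Full enrichment test of *query* intervals against a feature gene set.

    Computes the observed fraction of query intervals overlapping the
    feature genes, builds a count-matched null via :func:`sample_null` with
    ``k = |feature_set|``, and returns the one-sided permutation test
    (default 1000 permutations, 99% confidence interval).
    """
    universe_ids = {g.gene_id for g in universe}
    missing = [g.gene_id for g in feature_set if g.gene_id not in universe_ids]
    if missing:
        raise ValueError(
            f"enrich: feature_set genes not in universe: {missing[:5]}..."
            if len(missing) > 5
            else f"enrich: feature_set genes not in universe: {missing}"
        )
    targets = IntervalSet((g.interval for g in feature_set), name="feature_set")
    observed = observed_overlap_fraction(query, targets)
    null = sample_null(query, universe, k=len(feature_set), n_perm=n_perm, seed=seed)
    return permutation_test(observed, null, tail=tail, ci_level=ci_level)
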