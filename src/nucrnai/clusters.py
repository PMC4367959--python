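"""Locus clustering, proximity statistics, and the binomial placement null.

Called 1-kb loci are merged into clusters with a 5-kb proximity rule; the
GRH<->GRTS relationship is summarised as the fraction of query loci within a
distance cutoff of the reference set, compared against an exact binomial
null in which a 1-kb query is placed uniformly among all valid start
positions on the genome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .calls import RegionCall
from .genome import (
    GenomeModel,
    GenomicInterval,
    merge_within,
    nearest_distances,
)

FEATURE_CLASSES = (
    "LTR_retrotransposon",
    "LINE",
    "DNA_transposon",
    "other_repeat",
    "gene",
)


@dataclass
class Annotation:
    feature_class: str
    name: str
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")


@dataclass
class Cluster:
    """A merged run of called loci with optional feature annotations."""

    interval: GenomicInterval
    members: list[RegionCall] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)

    @property
    def length_kb(self) -> float:
        return self.interval.width / 1000.0

    @property
    def n_members(self) -> int:
        return len(self.members)

    def has_class(self, feature_class: str) -> bool:
        return any(a.feature_class == feature_class for a in self.annotations)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_clusters: int
    n_loci: int
    n_loci_in_multi: int
    clustered_fraction: float
    n_large: int
    large_threshold_bp: int


def cluster_calls(
    calls: Sequence[RegionCall],
    max_gap: int = 5000,
    large_threshold_bp: int = 10000,
) -> ClusterResult:
    """Merge called bins within ``max_gap`` bp into clusters.

    ``clustered_fraction`` is the fraction of loci falling in clusters with
    at least two members (the "in proximity to each other" statistic);
    ``n_large`` counts clusters at least ``large_threshold_bp`` long.
    """
    intervals = [c.interval for c in calls]
    merged = merge_within(intervals, max_gap)
    clusters = [Cluster(interval=iv) for iv in merged]
    by_chrom: dict[str, list[Cluster]] = {}
    for cl in clusters:
        by_chrom.setdefault(cl.interval.chrom, []).append(cl)
    for call in calls:
        for cl in by_chrom.get(call.bin.chrom, ()):
            if cl.interval.overlaps(call.interval):
                cl.members.append(call)
                break
    n_loci = len(calls)
    n_multi = sum(cl.n_members for cl in clusters if cl.n_members >= 2)
    return ClusterResult(
        clusters=clusters,
        n_clusters=len(clusters),
        n_loci=n_loci,
        n_loci_in_multi=n_multi,
        clustered_fraction=(n_multi / n_loci) if n_loci else 0.0,
        n_large=sum(1 for cl in clusters if cl.interval.width >= large_threshold_bp),
        large_threshold_bp=large_threshold_bp,
    )


def proximity_fraction(
    query: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
    cutoff: float,
) -> float:
    """Fraction of query intervals within ``cutoff`` bp of the reference set.

    Overlap or abutment counts as distance 0.  Non-decreasing in cutoff.
    """
    if len(query) == 0:
        raise ValueError("empty query")
    if len(reference) == 0:
        warnings.warn("empty reference set; proximity fraction is 0", stacklevel=2)
        return 0.0
    d = nearest_distances(query, reference)
    return float(np.mean(d <= cutoff))


@dataclass
class BinomialNull:
    """Uniform-placement null for query proximity to a reference set."""

    p_hit: float
    min_fraction_to_reject: float
    min_count_to_reject: int
    n_query: int
    cutoff: int
    alpha: float


def _hit_start_span(
    reference: Sequence[GenomicInterval],
    genome: GenomeModel,
    cutoff: int,
    query_width: int,
    chromosomes: Sequence[str] | None = None,
) -> tuple[int, int]:
    """Exact count of (hit starts, valid starts) for a uniformly placed query.

    A query of width ``w`` starting at ``s`` is a hit for reference ``[a, b)``
    iff ``distance([s, s+w), [a, b)) <= cutoff``, i.e. ``s`` lies in the
    closed integer range ``[a - w - cutoff, b + cutoff]`` (abutment counts as
    distance 0).  Hit ranges are clipped to valid starts, merged across the
    reference set, and summed.
    """
    names = list(chromosomes) if chromosomes is not None else genome.names
    valid = 0
    hits = 0
    ref_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in reference:
        ref_by_chrom.setdefault(iv.chrom, []).append(iv)
    for name in names:
        length = genome.lengths[name]
        n_valid = length - query_width + 1
        if n_valid <= 0:
            continue
        valid += n_valid
        ranges = []
        for iv in ref_by_chrom.get(name, ()):
            lo = max(0, iv.start - query_width - cutoff)
            hi = min(n_valid, iv.end + cutoff + 1)  # half-open on start grid
            if hi > lo:
                ranges.append((lo, hi))
        ranges.sort()
        cur_lo = cur_hi = None
        for lo, hi in ranges:
            if cur_hi is not None and lo <= cur_hi:
                cur_hi = max(cur_hi, hi)
            else:
                if cur_hi is not None:
                    hits += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
        if cur_hi is not None:
            hits += cur_hi - cur_lo
    return hits, valid


def binomial_proximity_null(
    n_query: int,
    reference: Sequence[GenomicInterval],
    genome: GenomeModel,
    cutoff: int,
    alpha: float,
    query_width: int = 1000,
    chromosomes: Sequence[str] | None = None,
) -> BinomialNull:
    """Binomial null for ``n_query`` independent uniform 1-kb placements.

    ``p_hit`` is the exact probability that one placement lands within
    ``cutoff`` of the reference set; ``min_fraction_to_reject`` is the
    smallest ``k/n_query`` whose upper binomial tail
    ``P(X >= k | n_query, p_hit)`` is <= ``alpha``.  ``chromosomes``
    restricts the placement universe (e.g. autosome-only nulls).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_query < 1:
        raise ValueError("n_query must be >= 1")
    hits, valid = _hit_start_span(reference, genome, cutoff, query_width, chromosomes)
    if valid == 0:
        raise ValueError("no valid query placements on the genome")
    p_hit = hits / valid
    # smallest k with upper tail <= alpha; sf(k-1) = P(X >= k)
    ks = np.arange(n_query + 1)
    tails = stats.binom.sf(ks - 1, n_query, p_hit)
    ok = np.flatnonzero(tails <= alpha)
    k_min = int(ok[0]) if ok.size else n_query + 1
    return BinomialNull(
        p_hit=float(p_hit),
        min_fraction_to_reject=min(k_min / n_query, 1.0 + 1.0 / n_query),
        min_count_to_reject=k_min,
        n_query=n_query,
        cutoff=int(cutoff),
        alpha=alpha,
    )


def binomial_proximity_pvalue(
    observed_count: int, n_query: int, p_hit: float
) -> float:
    """Upper binomial tail P(X >= observed) under the placement null."""
    return float(stats.binom.sf(observed_count - 1, n_query, p_hit))


@dataclass
class ProximityCurve:
    """Observed proximity fraction vs the binomial rejection threshold."""

    cutoffs: np.ndarray
    observed_fraction: np.ndarray
    null_threshold_fraction: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=np.int64)
        if np.any(np.diff(self.cutoffs) <= 0):
            raise ValueError("cutoffs must be increasing")
        if np.any(np.diff(self.observed_fraction) < 0):
            raise ValueError("observed fraction must be non-decreasing in cutoff")


def proximity_curve(
    query: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
    genome: GenomeModel,
    cutoffs: Sequence[int] | None = None,
    alpha: float = 1e-12,
    query_width: int = 1000,
    chromosomes: Sequence[str] | None = None,
) -> ProximityCurve:
    """Observed GRH->GRTS-style proximity curve with its binomial null.

    Defaults: cutoffs 0..50 kb in 1-kb steps and alpha 1e-12 (the p-value
    scale at which the observed curve is compared with the null threshold).
    """
    if cutoffs is None:
        cutoffs = list(range(0, 50001, 1000))
    d = nearest_distances(query, reference)
    observed = np.array([float(np.mean(d <= c)) for c in cutoffs])
    thresholds = np.array(
        [
            binomial_proximity_null(
                len(query), reference, genome, c, alpha, query_width, chromosomes
            ).min_fraction_to_reject
            for c in cutoffs
        ]
    )
    return ProximityCurve(
        cutoffs=np.asarray(cutoffs),
        observed_fraction=observed,
        null_threshold_fraction=thresholds,
        alpha=alpha,
    )


def annotate_clusters(
    clusters: Sequence[Cluster],
    features: Sequence[tuple[GenomicInterval, str, str]],
) -> list[Cluster]:
    """Fill cluster annotations from classed features.

    ``features`` are ``(interval, feature_class, name)`` triples; every
    feature sharing >= 1 bp with a cluster is recorded with its overlap.
    Annotations are replaced, clusters returned sorted by descending length
    so a "top N largest" listing is a prefix.
    """
    for cl in clusters:
        cl.annotations = []
        for iv, fclass, name in features:
            if cl.interval.overlaps(iv):
                overlap = min(cl.interval.end, iv.end) - max(cl.interval.start, iv.start)
                cl.annotations.append(Annotation(fclass, name, overlap))
    return sorted(clusters, key=lambda c: (-c.interval.width, c.interval))
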