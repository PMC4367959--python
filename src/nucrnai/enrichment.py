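"""Monte Carlo significance tests for region-set statistics.

Two nulls are provided: length-matched uniform placement of clusters (for
annotation enrichment, e.g. LTR retrotransposons in GRTS clusters) and
uniform re-draws of same-size bin sets (for fold-increase fraction
statistics).  p-values use the add-one estimator
``(1 + #{null >= observed}) / (1 + n_iter)`` and therefore never reach 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clusters import Cluster
from .genome import GenomeModel, GenomicInterval, merge_within


@dataclass
class EnrichmentResult:
    """Observed statistic, its Monte Carlo null sample, and add-one p."""

    observed: float
    null_samples: np.ndarray
    p_value: float
    seed: int
    n_iter: int
    label: str = ""

    def __post_init__(self) -> None:
        self.null_samples = np.asarray(self.null_samples, dtype=float)
        if len(self.null_samples) != self.n_iter:
            raise ValueError("null sample length != n_iter")
        expect = (1 + int(np.sum(self.null_samples >= self.observed))) / (1 + self.n_iter)
        if not np.isclose(self.p_value, expect):
            raise ValueError("p_value inconsistent with add-one estimator")


def _add_one_p(observed: float, null: np.ndarray) -> float:
    return (1 + int(np.sum(null >= observed))) / (1 + len(null))


class _MergedFeatures:
    """Merged, per-chromosome sorted feature spans for O(log n) overlap tests."""

    def __init__(self, features: Sequence[GenomicInterval]) -> None:
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        merged = merge_within(features, 0)
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        for iv in merged:
            starts.setdefault(iv.chrom, []).append(iv.start)
            ends.setdefault(iv.chrom, []).append(iv.end)
        for c in starts:
            self.by_chrom[c] = (np.asarray(starts[c]), np.asarray(ends[c]))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self.by_chrom:
            return False
        starts, ends = self.by_chrom[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        return i < len(starts) and starts[i] < end


def _cluster_intervals(
    clusters: Sequence[Cluster] | Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    return [c.interval if isinstance(c, Cluster) else c for c in clusters]


def mc_cluster_annotation_enrichment(
    clusters: Sequence[Cluster] | Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    genome: GenomeModel,
    n_iter: int = 10000,
    seed: int = 0,
    per_chromosome: bool = False,
    max_tries: int = 1000,
) -> EnrichmentResult:
    """How many clusters overlap >= 1 feature vs length-matched random placement.

    Each null iteration re-places every cluster (its length preserved)
    uniformly at random on the genome, non-overlapping, and recounts
    feature-bearing clusters.  ``per_chromosome=True`` restricts each
    placement to its original chromosome.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    ivs = _cluster_intervals(clusters)
    feats = _MergedFeatures(features)
    observed = sum(1 for iv in ivs if feats.overlaps(iv.chrom, iv.start, iv.end))
    for iv in ivs:
        homes = [iv.chrom] if per_chromosome else genome.names
        if not any(genome.lengths[c] >= iv.width for c in homes):
            raise ValueError(
                f"cluster of length {iv.width} exceeds every placement chromosome"
            )
    rng = np.random.default_rng(seed)
    names = genome.names
    # per-cluster placement universe, precomputed once
    placement: list[tuple[list[str], np.ndarray, np.ndarray]] = []
    for iv in ivs:
        homes = [iv.chrom] if per_chromosome else names
        caps = np.array(
            [max(0, genome.lengths[c] - iv.width + 1) for c in homes], dtype=float
        )
        placement.append((homes, caps, np.cumsum(caps / caps.sum())))
    null = np.empty(n_iter)
    for it in range(n_iter):
        placed: dict[str, list[tuple[int, int]]] = {}
        count = 0
        for iv, (homes, caps, cum) in zip(ivs, placement):
            for _ in range(max_tries):
                ci = int(np.searchsorted(cum, rng.random(), side="right"))
                chrom = homes[ci]
                s = int(rng.integers(0, int(caps[ci])))
                e = s + iv.width
                clash = any(s < pe and ps < e for ps, pe in placed.get(chrom, ()))
                if not clash:
                    placed.setdefault(chrom, []).append((s, e))
                    count += feats.overlaps(chrom, s, e)
                    break
            else:
                raise RuntimeError("could not place cluster without overlap")
        null[it] = count
    return EnrichmentResult(
        observed=float(observed),
        null_samples=null,
        p_value=_add_one_p(observed, null),
        seed=seed,
        n_iter=n_iter,
        label="cluster_annotation_overlap",
    )


def mc_fraction_significance(
    base_bin_indices: Sequence[int],
    fc_vector: np.ndarray,
    thresholds: Sequence[float],
    n_iter: int = 10000,
    seed: int = 0,
    analyzable: Sequence[int] | None = None,
) -> list[EnrichmentResult]:
    """Fraction of base bins with FC >= threshold vs random same-size bin sets.

    One result per threshold; null draws are without replacement from
    ``analyzable`` bin indices (default: every bin of ``fc_vector``).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    fc = np.asarray(fc_vector, dtype=float)
    base = np.asarray(base_bin_indices, dtype=np.int64)
    pool = (
        np.arange(len(fc), dtype=np.int64)
        if analyzable is None
        else np.asarray(analyzable, dtype=np.int64)
    )
    if len(base) > len(pool):
        raise ValueError("base region set larger than the analyzable bin universe")
    thresholds = [float(t) for t in thresholds]
    if any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(base)
    base_fc = fc[base]
    # one matrix of null draws shared across thresholds
    null_fc = np.empty((n_iter, k))
    for it in range(n_iter):
        null_fc[it] = fc[rng.choice(pool, size=k, replace=False)]
    results = []
    for t in thresholds:
        observed = float(np.mean(base_fc >= t))
        null = (null_fc >= t).mean(axis=1)
        results.append(
            EnrichmentResult(
                observed=observed,
                null_samples=null,
                p_value=_add_one_p(observed, null),
                seed=seed,
                n_iter=n_iter,
                label=f"fraction_fc_ge_{t:g}",
            )
        )
    return results
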