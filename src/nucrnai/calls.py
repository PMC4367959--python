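"""Per-bin fold changes and tiered region calling (GRTS / GRH / desilenced).

GRTS (germline nuclear RNAi-dependent transcriptional silencing) bins show a
consistent mutant/wild-type Pol II increase across all three CTD antibodies
(8WG16, S2, S5); GRH (heterochromatic) bins show a wild-type/mutant H3K9me3
decrease in every supplied nuclear-RNAi mutant.  Tiers 3 / 2 / 1.5 record the
largest cutoff a bin satisfies in every required assay, so calls nest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome import Bin, GenomeBins, GenomeModel, GenomicInterval
from .tracks import BinnedTrack, POLII_ASSAYS

TIERS = (3.0, 2.0, 1.5)

CALL_TYPES = ("GRTS", "GRH", "POLII_DECREASED", "HRDE1_TARGET")


@dataclass(frozen=True)
class RegionCall:
    """A called 1-kb bin with its per-assay fold changes."""

    bin: Bin
    call_type: str
    tier: float
    per_assay_fc: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.call_type not in CALL_TYPES:
            raise ValueError(f"unknown call type {self.call_type!r}")

    @property
    def interval(self) -> GenomicInterval:
        return self.bin.interval

    @property
    def min_fc(self) -> float:
        return min(self.per_assay_fc.values())


@dataclass
class FoldChangeTable:
    """Fold-change vectors over the bin universe, one per assay pair."""

    bins: GenomeBins
    fc: dict[str, np.ndarray]
    epsilon: float

    def __post_init__(self) -> None:
        for assay, vec in self.fc.items():
            if len(vec) != self.bins.n_bins:
                raise ValueError(f"fold-change vector for {assay} has wrong length")
            if not np.all(np.isfinite(vec)) or (np.asarray(vec) <= 0).any():
                raise ValueError(f"fold changes for {assay} must be positive finite")


def default_epsilon(mutant: BinnedTrack, wildtype: BinnedTrack) -> float:
    """Pseudocount: the per-million equivalent of one read in the smaller library.

    For raw tracks (depth_factor 1) this degrades to 1 read.
    """
    return float(max(mutant.depth_factor, wildtype.depth_factor))


def fold_change_values(
    mutant: np.ndarray, wildtype: np.ndarray, epsilon: float
) -> np.ndarray:
    """Element-wise pseudocounted ratio (m + eps) / (w + eps)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    m = np.asarray(mutant, dtype=float)
    w = np.asarray(wildtype, dtype=float)
    if m.shape != w.shape:
        raise ValueError("mismatched bin universes")
    return (m + epsilon) / (w + epsilon)


def fold_change(
    mutant: BinnedTrack, wildtype: BinnedTrack, epsilon: float | None = None
) -> np.ndarray:
    """Per-bin (mutant + eps) / (wildtype + eps) on identical bin universes."""
    if mutant.bins.n_bins != wildtype.bins.n_bins or (
        mutant.bins.genome.names != wildtype.bins.genome.names
    ):
        raise ValueError("mismatched bin universes")
    if epsilon is None:
        epsilon = default_epsilon(mutant, wildtype)
    return fold_change_values(mutant.values, wildtype.values, epsilon)


def _tier_for(min_fc: np.ndarray) -> np.ndarray:
    """Highest tier in (3, 2, 1.5) satisfied by every assay, else 0."""
    tier = np.zeros(len(min_fc))
    for t in sorted(TIERS):
        tier[min_fc >= t] = t
    return tier


def call_grts(
    polII_fc: Mapping[str, np.ndarray],
    bins: GenomeBins,
    cutoff: float = 3.0,
    mutant_signal: Mapping[str, np.ndarray] | None = None,
    min_signal: float = 0.0,
) -> list[RegionCall]:
    """Bins with fold change >= cutoff in ALL three Pol II assay pairs.

    ``mutant_signal`` (per-million mutant tracks, same keys) enables the
    optional minimum-signal filter: an increase-type call additionally needs
    mutant signal >= ``min_signal`` in every assay.
    """
    missing = [a for a in POLII_ASSAYS if a not in polII_fc]
    if missing or len(polII_fc) < 3:
        raise ValueError(f"need all three Pol II assay pairs; missing {missing}")
    return _call_consistent(
        {a: polII_fc[a] for a in POLII_ASSAYS},
        bins,
        cutoff,
        "GRTS",
        signal=mutant_signal,
        min_signal=min_signal,
    )


def call_polII_decreased(
    polII_fc: Mapping[str, np.ndarray],
    bins: GenomeBins,
    cutoff: float = 3.0,
) -> list[RegionCall]:
    """Bins with Pol II *decreased* >= cutoff-fold in all three assay pairs.

    Reported for completeness (the mutant shows only a handful, not analysed
    further); implemented as the same consistency rule on inverted ratios.
    """
    inverted = {a: 1.0 / np.asarray(v, dtype=float) for a, v in polII_fc.items()}
    missing = [a for a in POLII_ASSAYS if a not in inverted]
    if missing:
        raise ValueError(f"need all three Pol II assay pairs; missing {missing}")
    return _call_consistent(
        {a: inverted[a] for a in POLII_ASSAYS}, bins, cutoff, "POLII_DECREASED"
    )


def _call_consistent(
    fc: Mapping[str, np.ndarray],
    bins: GenomeBins,
    cutoff: float,
    call_type: str,
    signal: Mapping[str, np.ndarray] | None = None,
    min_signal: float = 0.0,
) -> list[RegionCall]:
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    mat = np.vstack([np.asarray(fc[a], dtype=float) for a in fc])
    min_fc = mat.min(axis=0)
    ok = min_fc >= cutoff
    if signal is not None and min_signal > 0:
        sig = np.vstack([np.asarray(signal[a], dtype=float) for a in fc])
        ok &= sig.min(axis=0) >= min_signal
    tiers = _tier_for(min_fc)
    assays = list(fc)
    all_bins = bins.bins
    return [
        RegionCall(
            bin=all_bins[i],
            call_type=call_type,
            tier=float(tiers[i]) if tiers[i] > 0 else float(cutoff),
            per_assay_fc={a: float(mat[k, i]) for k, a in enumerate(assays)},
        )
        for i in np.flatnonzero(ok)
    ]


@dataclass
class GrhResult:
    """GRH calls plus the fraction retained within reference regions."""

    calls: list[RegionCall]
    retained: list[RegionCall] | None = None
    retained_fraction: float | None = None


def call_grh(
    h3k9me3_fc: Mapping[str, np.ndarray],
    bins: GenomeBins,
    cutoff: float = 3.0,
    reference_regions: Sequence[GenomicInterval] | None = None,
) -> GrhResult:
    """Bins with H3K9me3 decreased >= cutoff-fold in EVERY supplied mutant.

    Fold decreases are wild-type-over-mutant oriented, ``(wt+eps)/(mut+eps)``.
    With ``reference_regions`` (e.g. a previously published H3K9me3-dependent
    region set), calls are intersected with them and the retained fraction of
    reference regions reported.
    """
    if not h3k9me3_fc:
        raise ValueError("empty mutant set")
    calls = _call_consistent(dict(h3k9me3_fc), bins, cutoff, "GRH")
    if reference_regions is None:
        return GrhResult(calls=calls)
    if len(reference_regions) == 0:
        raise ValueError("reference_regions is empty")
    retained = [
        c
        for c in calls
        if any(c.interval.overlaps(r) for r in reference_regions)
    ]
    # fraction of reference regions containing at least one call
    hit = sum(
        1
        for r in reference_regions
        if any(c.interval.overlaps(r) for c in calls)
    )
    return GrhResult(
        calls=calls,
        retained=retained,
        retained_fraction=hit / len(reference_regions),
    )


@dataclass
class DesilencedResult:
    calls: list[RegionCall]
    fraction: float


def call_desilenced(
    mrna_fc: np.ndarray,
    bins: GenomeBins,
    base_regions: Sequence[GenomicInterval],
    cutoff: float = 3.0,
) -> DesilencedResult:
    """Subset of ``base_regions`` whose bin fold change reaches ``cutoff``.

    Used both to define exemplary targets (GRTS+GRH regions with >= 3-fold
    mRNA increase in the mutant) and to score other mutants against them.
    A multi-bin region counts as desilenced when its maximal bin fold change
    reaches the cutoff.
    """
    if len(base_regions) == 0:
        raise ValueError("base_regions is empty")
    vec = np.asarray(mrna_fc, dtype=float)
    all_bins = bins.bins
    calls: list[RegionCall] = []
    for region in base_regions:
        r = bins.bins_overlapping(region)
        sub = vec[r.start : r.stop]
        i_best = r.start + int(np.argmax(sub))
        if sub.max() >= cutoff:
            calls.append(
                RegionCall(
                    bin=all_bins[i_best],
                    call_type="HRDE1_TARGET",
                    tier=float(_tier_for(np.array([sub.max()]))[0] or cutoff),
                    per_assay_fc={"mRNA": float(sub.max())},
                )
            )
    return DesilencedResult(calls=calls, fraction=len(calls) / len(base_regions))


@dataclass
class CallSummary:
    """Per-assay medians and chromosome distribution of a call set."""

    n_calls: int
    median_fc: dict[str, float]
    per_chromosome: dict[str, int]
    per_chromosome_fraction: dict[str, float]
    sex_chromosome_fraction: float


def summarize_calls(
    calls: Sequence[RegionCall],
    genome: GenomeModel,
    fc_table: FoldChangeTable | None = None,
) -> CallSummary:
    """Median fold change per assay over called bins + chromosome tabulation.

    Medians come from the calls' own ``per_assay_fc`` unless a full
    ``fc_table`` is supplied (then its vectors are indexed at call bins).
    """
    counts = {name: 0 for name in genome.names}
    for c in calls:
        counts[c.bin.chrom] += 1
    n = len(calls)
    if n == 0:
        return CallSummary(
            n_calls=0,
            median_fc={},
            per_chromosome=counts,
            per_chromosome_fraction={k: 0.0 for k in counts},
            sex_chromosome_fraction=0.0,
        )
    if fc_table is not None:
        idx = np.array([c.bin.index for c in calls])
        medians = {
            assay: float(np.median(np.asarray(vec)[idx]))
            for assay, vec in fc_table.fc.items()
        }
    else:
        assays = sorted({a for c in calls for a in c.per_assay_fc})
        medians = {
            a: float(
                np.median([c.per_assay_fc[a] for c in calls if a in c.per_assay_fc])
            )
            for a in assays
        }
    sex = sum(counts[name] for name in counts if genome.is_sex_chromosome(name))
    return CallSummary(
        n_calls=n,
        median_fc=medians,
        per_chromosome=counts,
        per_chromosome_fraction={k: v / n for k, v in counts.items()},
        sex_chromosome_fraction=sex / n,
    )
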