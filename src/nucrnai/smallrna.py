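"""Small-RNA signatures and per-region abundance comparisons.

The 22G endo-siRNA class is recognised by its length x 5'-nucleotide
signature (predominantly 21-22 nt, 5' G, antisense to the target
transcript); per-region fold changes between genotypes classify loci whose
siRNA pool depends on a given pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignments import AlignmentTable
from .calls import fold_change_values
from .genome import GenomicInterval
from .tracks import BinnedTrack, region_signal

LENGTH_RANGE = range(18, 31)
BASES = ("A", "C", "G", "T")


@dataclass
class SmallRnaSignature:
    """Weighted length x 5'-base matrix for reads within a region set."""

    matrix: pd.DataFrame  # index: read length (nt); columns: A C G T
    total_weight: float
    region_label: str = ""
    unassigned_weight: float = 0.0  # reads with 5' base N (not in the matrix)

    def __post_init__(self) -> None:
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("negative signature counts")
        if not np.isclose(self.matrix.to_numpy().sum(), self.total_weight):
            raise ValueError("matrix sum != total_weight")

    @property
    def modal_length(self) -> int | None:
        if self.total_weight == 0:
            return None
        return int(self.matrix.sum(axis=1).idxmax())

    @property
    def modal_base(self) -> str | None:
        if self.total_weight == 0:
            return None
        return str(self.matrix.sum(axis=0).idxmax())

    def base_fraction(self, base: str) -> float:
        if self.total_weight == 0:
            return 0.0
        return float(self.matrix[base].sum() / self.total_weight)

    def to_tsv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="length")


def signature(
    alignments: AlignmentTable,
    regions: Sequence[GenomicInterval],
    lengths: range = LENGTH_RANGE,
    region_label: str = "",
) -> SmallRnaSignature:
    """Weighted length x 5'-base matrix over reads with midpoint in ``regions``.

    Reads whose 5' base is unavailable (``N``, e.g. BED input without
    sequence) are excluded from the matrix and reported as
    ``unassigned_weight``.
    """
    mat = pd.DataFrame(
        0.0, index=list(lengths), columns=list(BASES), dtype=float
    )
    unassigned = 0.0
    mid = alignments.midpoints()
    chroms = alignments.df["chrom"].to_numpy()
    in_any = np.zeros(len(alignments), dtype=bool)
    for region in regions:
        in_any |= (
            (chroms == region.chrom)
            & (mid >= region.start)
            & (mid < region.end)
        )
    sub = alignments.df[in_any]
    for length, base, w in zip(
        sub["read_length"].to_numpy(),
        sub["five_prime_base"].to_numpy(),
        sub["weight"].to_numpy(),
    ):
        if base not in BASES:
            unassigned += w
        elif length in mat.index:
            mat.loc[length, base] += w
        else:
            unassigned += w
    return SmallRnaSignature(
        matrix=mat,
        total_weight=float(mat.to_numpy().sum()),
        region_label=region_label,
        unassigned_weight=float(unassigned),
    )


@dataclass
class AbundanceComparison:
    """Per-region fold changes of track A over track B, with the fraction
    of regions reduced at least ``reduced_cutoff``-fold in B."""

    regions: list[GenomicInterval]
    fold_change: np.ndarray  # (A + eps) / (B + eps) per region
    fraction_reduced: float
    reduced_cutoff: float
    epsilon: float


def region_abundance_compare(
    track_a: BinnedTrack,
    track_b: BinnedTrack,
    regions: Sequence[GenomicInterval],
    reduced_cutoff: float = 3.0,
    epsilon: float | None = None,
) -> AbundanceComparison:
    """Compare per-region signal between two depth-normalised tracks.

    ``fraction_reduced`` is the fraction of regions whose signal drops at
    least ``reduced_cutoff``-fold in ``track_b`` relative to ``track_a``
    (the "siRNA levels reduced in the mutant" statistic).
    """
    if track_a.bins.n_bins != track_b.bins.n_bins:
        raise ValueError("mismatched bin universes")
    if len(regions) == 0:
        raise ValueError("empty region set")
    if epsilon is None:
        epsilon = float(max(track_a.depth_factor, track_b.depth_factor))
    a = region_signal(track_a, regions)
    b = region_signal(track_b, regions)
    fc = fold_change_values(a, b, epsilon)
    return AbundanceComparison(
        regions=list(regions),
        fold_change=fc,
        fraction_reduced=float(np.mean(fc >= reduced_cutoff)),
        reduced_cutoff=reduced_cutoff,
        epsilon=epsilon,
    )
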