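"""Per-bin signal tracks and anchored metagene profiles.

Each placement contributes its multi-mapper weight to the single 1-kb bin
containing its midpoint; per-million normalisation rescales by
``1e6 / total library weight`` so genotype comparisons of like assays are
depth-matched.  ChIP input is kept as its own track, never subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignments import AlignmentTable
from .genome import Bin, GenomeBins, GenomeModel, GenomicInterval

ASSAYS = (
    "polII_8WG16",
    "polII_S2",
    "polII_S5",
    "H3K9me3",
    "input",
    "pre_mRNA",
    "mRNA",
    "smallRNA",
)

POLII_ASSAYS = ("polII_8WG16", "polII_S2", "polII_S5")


@dataclass
class BinnedTrack:
    """Weighted, optionally depth-normalised per-bin signal for one library."""

    library_id: str
    genotype: str
    assay: str
    values: np.ndarray
    bins: GenomeBins
    depth_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.bins.n_bins:
            raise ValueError(
                f"track length {len(self.values)} != bin count {self.bins.n_bins}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")
        if (self.values < 0).any():
            raise ValueError("track values must be non-negative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def to_tsv(self, path: str | Path) -> None:
        """Write chrom/start/end/value TSV (one row per bin)."""
        b = self.bins
        names = np.asarray(b.genome.names, dtype=object)[b.bin_chrom_codes]
        pd.DataFrame(
            {
                "chrom": names,
                "start": b.bin_starts,
                "end": b.bin_ends,
                "value": self.values,
            }
        ).to_csv(path, sep="\t", index=False)


def _as_genome_bins(bins: GenomeBins | Sequence[Bin]) -> GenomeBins:
    if isinstance(bins, GenomeBins):
        return bins
    return GenomeBins.from_bins(list(bins))


def bin_signal(
    alignments: AlignmentTable,
    bins: GenomeBins | Sequence[Bin],
    normalize: str = "raw",
    *,
    library_id: str = "",
    genotype: str = "",
    assay: str = "input",
) -> BinnedTrack:
    """Sum placement weights into the bin containing each midpoint.

    ``normalize='per_million'`` rescales all bins by ``1e6 / total weight``
    (recorded as ``depth_factor``); ``'raw'`` leaves weighted counts, whose
    genome-wide total equals the number of distinct reads.
    """
    if normalize not in ("raw", "per_million"):
        raise ValueError("normalize must be 'raw' or 'per_million'")
    gb = _as_genome_bins(bins)
    values = np.zeros(gb.n_bins)
    if len(alignments):
        idx = gb.bin_indices(
            alignments.df["chrom"].to_numpy(), alignments.midpoints()
        )
        np.add.at(values, idx, alignments.df["weight"].to_numpy())
    depth_factor = 1.0
    if normalize == "per_million":
        total = values.sum()
        if total > 0:
            depth_factor = 1e6 / total
            values = values * depth_factor
    return BinnedTrack(
        library_id=library_id,
        genotype=genotype,
        assay=assay,
        values=values,
        bins=gb,
        depth_factor=depth_factor,
    )


def region_signal(
    track: BinnedTrack, regions: Sequence[GenomicInterval]
) -> np.ndarray:
    """Summed track signal over the bins each region overlaps."""
    out = np.empty(len(regions))
    for i, region in enumerate(regions):
        r = track.bins.bins_overlapping(region)
        out[i] = track.values[r.start : r.stop].sum()
    return out


# ---------------------------------------------------------------------------
# Metagene profiles


@dataclass
class AnchorSet:
    """Single-bp anchors (e.g. plus-one nucleosome dyads, 3' UTR ends)."""

    anchors: list[tuple[str, int, str]]
    label: str = ""

    def __post_init__(self) -> None:
        for chrom, pos, strand in self.anchors:
            if strand not in ("+", "-", "."):
                raise ValueError(f"invalid anchor strand {strand!r}")
            if pos < 0:
                raise ValueError(f"negative anchor position on {chrom}")

    @classmethod
    def from_bed(cls, path: str | Path, label: str = "") -> "AnchorSet":
        from .genome import read_bed

        ivs = read_bed(path)
        return cls([(iv.chrom, iv.start, iv.strand) for iv in ivs], label=label)

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class MetageneProfile:
    """Strand-oriented mean coverage around a set of anchors."""

    offsets: np.ndarray
    mean_signal: np.ndarray
    n_anchors: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.mean_signal = np.asarray(self.mean_signal, dtype=float)
        if len(self.offsets) != len(self.mean_signal):
            raise ValueError("offset/signal length mismatch")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")

    @property
    def peak_offset(self) -> int:
        return int(self.offsets[int(np.argmax(self.mean_signal))])


def coverage_arrays(
    alignments: AlignmentTable, genome: GenomeModel
) -> dict[str, np.ndarray]:
    """Weighted per-base read coverage, one float array per chromosome."""
    cov = {name: np.zeros(length) for name, length in genome.chromosomes}
    df = alignments.df
    for name in cov:
        m = df["chrom"].to_numpy() == name
        if not m.any():
            continue
        starts = np.clip(df["start"].to_numpy()[m], 0, len(cov[name]))
        ends = np.clip(df["end"].to_numpy()[m], 0, len(cov[name]))
        w = df["weight"].to_numpy()[m]
        diff = np.zeros(len(cov[name]) + 1)
        np.add.at(diff, starts, w)
        np.add.at(diff, ends, -w)
        cov[name] = np.cumsum(diff[:-1])
    return cov


def metagene(
    source: AlignmentTable | dict[str, np.ndarray],
    anchors: AnchorSet,
    flank: int,
    step: int = 10,
    genome: GenomeModel | None = None,
) -> MetageneProfile:
    """Mean strand-oriented coverage at offsets in [-flank, +flank].

    ``source`` is either an alignment table (coverage is computed with
    multi-mapper weights) or precomputed per-chromosome coverage arrays.
    Anchors whose window runs off the chromosome are dropped and counted.
    Offsets are 5'->3' relative to each anchor's strand; unstranded anchors
    are treated as '+'.
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    if flank < step:
        raise ValueError("flank must be >= step")
    if isinstance(source, AlignmentTable):
        if genome is None:
            raise ValueError("genome required to build coverage from alignments")
        cov = coverage_arrays(source, genome)
    else:
        cov = source
    offsets = np.arange(-flank, flank + 1, step, dtype=np.int64)
    acc = np.zeros(len(offsets))
    used = 0
    dropped = 0
    for chrom, pos, strand in anchors.anchors:
        if chrom not in cov:
            dropped += 1
            continue
        arr = cov[chrom]
        signed = -offsets if strand == "-" else offsets
        idx = pos + signed
        if idx.min() < 0 or idx.max() >= len(arr):
            dropped += 1
            continue
        acc += arr[idx]
        used += 1
    if used == 0:
        raise ValueError("all anchors dropped (windows exceed chromosome bounds)")
    return MetageneProfile(offsets, acc / used, n_anchors=used, n_dropped=dropped)
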