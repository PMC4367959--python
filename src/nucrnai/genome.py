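"""Genome model, 1-kb bin tiling, and interval algebra.

Coordinates are 0-based half-open throughout (BED convention).  The 1-kb bin
is the unit of every downstream analysis: the genome is tiled chromosome by
chromosome, the last bin per chromosome may be shorter, and bins carry a
stable genome-wide index so signal tracks are plain NumPy vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

DEFAULT_SEX_CHROMOSOMES = frozenset({"chrX", "X"})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap between two intervals in bp.

    0 when the intervals overlap or abut on the same chromosome, the gap
    length otherwise, and ``math.inf`` when the chromosomes differ.
    """
    if a.chrom != b.chrom:
        return math.inf
    return float(max(0, a.start - b.end, b.start - a.end))


class GenomeModel:
    """Ordered chromosomes with lengths; defines the bin universe.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs.  Order is preserved and defines
        bin indexing for the whole run.
    sex_chromosome_names
        Names treated as the sex chromosome for per-chromosome summaries.
    """

    def __init__(
        self,
        chromosomes: Sequence[tuple[str, int]],
        sex_chromosome_names: Iterable[str] = DEFAULT_SEX_CHROMOSOMES,
    ) -> None:
        chroms = [(str(n), int(l)) for n, l in chromosomes]
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for n, l in chroms:
            if l < 1:
                raise ValueError(f"chromosome {n} has non-positive length {l}")
        self.chromosomes: list[tuple[str, int]] = chroms
        self.lengths: dict[str, int] = dict(chroms)
        self.names: list[str] = names
        self.sex_chromosome_names = frozenset(sex_chromosome_names)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def is_sex_chromosome(self, chrom: str) -> bool:
        return chrom in self.sex_chromosome_names

    def autosomes(self) -> list[str]:
        return [n for n in self.names if not self.is_sex_chromosome(n)]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __len__(self) -> int:
        return len(self.chromosomes)

    @classmethod
    def from_chrom_sizes(
        cls,
        path: str | Path,
        sex_chromosome_names: Iterable[str] = DEFAULT_SEX_CHROMOSOMES,
    ) -> "GenomeModel":
        """Read a UCSC-dialect chrom.sizes file (name<TAB>length)."""
        chroms: list[tuple[str, int]] = []
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {i}: expected 'name length'")
            try:
                chroms.append((parts[0], int(parts[1])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {i}: bad length {parts[1]!r}") from exc
        return cls(chroms, sex_chromosome_names)

    def to_chrom_sizes(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{n}\t{l}\n" for n, l in self.chromosomes)
        )


@dataclass(frozen=True)
class Bin:
    """One tile of the genome; ``index`` is its genome-wide ordinal."""

    interval: GenomicInterval
    index: int

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def width(self) -> int:
        return self.interval.width


class GenomeBins:
    """Vectorised companion to a tiled genome.

    Holds the per-chromosome offsets so that positions map to bin indices in
    O(1) and signal tracks are flat vectors of length ``n_bins``.
    """

    def __init__(self, genome: GenomeModel, bin_size: int = 1000) -> None:
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if len(genome) == 0:
            raise ValueError("no chromosomes")
        self.genome = genome
        self.bin_size = int(bin_size)
        self.offsets: dict[str, int] = {}
        self.n_per_chrom: dict[str, int] = {}
        off = 0
        for name, length in genome.chromosomes:
            self.offsets[name] = off
            n = -(-length // bin_size)  # ceil division
            self.n_per_chrom[name] = n
            off += n
        self.n_bins = off
        self._bins: list[Bin] | None = None
        # flat arrays for vectorised work
        self.bin_chrom_codes = np.empty(self.n_bins, dtype=np.int32)
        self.bin_starts = np.empty(self.n_bins, dtype=np.int64)
        self.bin_ends = np.empty(self.n_bins, dtype=np.int64)
        for ci, (name, length) in enumerate(genome.chromosomes):
            o, n = self.offsets[name], self.n_per_chrom[name]
            starts = np.arange(n, dtype=np.int64) * bin_size
            self.bin_chrom_codes[o : o + n] = ci
            self.bin_starts[o : o + n] = starts
            self.bin_ends[o : o + n] = np.minimum(starts + bin_size, length)
        self.bin_widths = self.bin_ends - self.bin_starts

    @property
    def bins(self) -> list[Bin]:
        if self._bins is None:
            names = self.genome.names
            self._bins = [
                Bin(
                    GenomicInterval(
                        names[self.bin_chrom_codes[i]],
                        int(self.bin_starts[i]),
                        int(self.bin_ends[i]),
                    ),
                    i,
                )
                for i in range(self.n_bins)
            ]
        return self._bins

    def bin_index(self, chrom: str, pos: int) -> int:
        if chrom not in self.offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.genome.lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self.offsets[chrom] + pos // self.bin_size

    def bin_indices(self, chroms: Sequence[str], positions: np.ndarray) -> np.ndarray:
        """Vectorised position -> bin index (chroms may repeat)."""
        chrom_arr = np.asarray(chroms)
        pos = np.asarray(positions, dtype=np.int64)
        out = np.empty(len(pos), dtype=np.int64)
        for name in np.unique(chrom_arr):
            if name not in self.offsets:
                raise KeyError(f"unknown chromosome {name!r}")
            m = chrom_arr == name
            out[m] = self.offsets[name] + pos[m] // self.bin_size
        return out

    def bins_overlapping(self, interval: GenomicInterval) -> range:
        """Range of bin indices overlapping ``interval``."""
        if interval.chrom not in self.offsets:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        o = self.offsets[interval.chrom]
        first = o + interval.start // self.bin_size
        last = o + (interval.end - 1) // self.bin_size
        last = min(last, o + self.n_per_chrom[interval.chrom] - 1)
        return range(first, last + 1)

    def bin_interval(self, index: int) -> GenomicInterval:
        return GenomicInterval(
            self.genome.names[self.bin_chrom_codes[index]],
            int(self.bin_starts[index]),
            int(self.bin_ends[index]),
        )

    @classmethod
    def from_bins(cls, bins: Sequence[Bin]) -> "GenomeBins":
        """Rebuild the universe from an ordered, gapless bin list."""
        if not bins:
            raise ValueError("no bins")
        chrom_lengths: dict[str, int] = {}
        width = max(b.width for b in bins)
        for b in bins:
            chrom_lengths[b.chrom] = max(chrom_lengths.get(b.chrom, 0), b.end)
        return cls(GenomeModel(list(chrom_lengths.items())), width)


def tile_genome(genome: GenomeModel, bin_size: int = 1000) -> list[Bin]:
    """Tile every chromosome into consecutive bins of ``bin_size`` bp.

    The final bin of each chromosome may be shorter.  Bin indices run 0..N-1
    in chromosome order.
    """
    return GenomeBins(genome, bin_size).bins


def merge_within(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals connected by chains of pairwise distances <= max_gap.

    Output is sorted and non-overlapping; strand is dropped.  Idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= max_gap
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def nearest_distances(
    query: Sequence[GenomicInterval], reference: Sequence[GenomicInterval]
) -> np.ndarray:
    """Distance from each query interval to its nearest reference interval.

    Overlap or abutment gives 0; queries on chromosomes with no reference
    get ``inf``.
    """
    ref = merge_within(reference, 0)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in ref:
        by_chrom.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
    starts_tmp: dict[str, list[int]] = {}
    ends_tmp: dict[str, list[int]] = {}
    for iv in ref:
        starts_tmp.setdefault(iv.chrom, []).append(iv.start)
        ends_tmp.setdefault(iv.chrom, []).append(iv.end)
    by_chrom = {
        c: (np.asarray(starts_tmp[c]), np.asarray(ends_tmp[c])) for c in starts_tmp
    }
    out = np.full(len(query), np.inf)
    for qi, q in enumerate(query):
        if q.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[q.chrom]
        i = int(np.searchsorted(starts, q.start))
        best = math.inf
        for k in (i - 1, i):
            if 0 <= k < len(starts):
                best = min(best, max(0, starts[k] - q.end, q.start - ends[k]))
        out[qi] = best
    return out


# ---------------------------------------------------------------------------
# BED I/O (BED3/BED6, 0-based half-open; writer emits sorted records)

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into intervals (strand kept when present)."""
    out: list[GenomicInterval] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) == 1:
            f = line.split()
        if len(f) < 3:
            raise ValueError(f"{path}: line {i}: fewer than 3 BED columns")
        strand = f[5] if len(f) >= 6 and f[5] in STRANDS else "."
        try:
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write sorted BED6 (name/score default to '.'/0)."""
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start))
    with open(path, "w") as fh:
        for i in order:
            iv = intervals[i]
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
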