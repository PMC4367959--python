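"""Aligned-read containers with multi-mapper weighting.

A read mapping to ``k`` genomic positions contributes one placement record
per position, each carrying ``hit_count = k`` and ``weight = 1/k``, so the
total weight over all placements of one read is exactly 1 and total binned
signal conserves read counts.

The canonical in-memory container is :class:`AlignmentTable`, a thin wrapper
around a pandas DataFrame so that binning, subsetting and signature counting
stay vectorised; :class:`WeightedAlignment` is the single-record view used
in small examples and tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeModel, GenomicInterval, STRANDS

COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "hit_count",
    "weight",
    "read_length",
    "five_prime_base",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class WeightedAlignment:
    """One genomic placement of a read, weighted by its multiplicity."""

    interval: GenomicInterval
    hit_count: int = 1
    read_length: int | None = None
    five_prime_base: str = "N"

    def __post_init__(self) -> None:
        if self.hit_count < 1:
            raise ValueError("hit_count must be >= 1")
        if self.five_prime_base not in ("A", "C", "G", "T", "N"):
            raise ValueError(f"invalid 5' base {self.five_prime_base!r}")

    @property
    def weight(self) -> float:
        return 1.0 / self.hit_count

    @property
    def length(self) -> int:
        return (
            self.read_length
            if self.read_length is not None
            else self.interval.width
        )


class AlignmentTable:
    """Vectorised table of weighted read placements."""

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"alignment table missing columns {missing}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_placements(self) -> int:
        return len(self.df)

    @property
    def total_weight(self) -> float:
        """Sum of placement weights; equals the number of distinct reads."""
        return float(self.df["weight"].sum())

    def midpoints(self) -> np.ndarray:
        return ((self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2).astype(
            np.int64
        )

    def subset(self, interval: GenomicInterval) -> "AlignmentTable":
        """Placements whose midpoint lies inside ``interval``."""
        mid = self.midpoints()
        m = (
            (self.df["chrom"].to_numpy() == interval.chrom)
            & (mid >= interval.start)
            & (mid < interval.end)
        )
        return AlignmentTable(self.df[m])

    def to_records(self) -> list[WeightedAlignment]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                WeightedAlignment(
                    GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                    hit_count=int(row.hit_count),
                    read_length=int(row.read_length),
                    five_prime_base=row.five_prime_base,
                )
            )
        return out

    @classmethod
    def from_records(cls, records: Iterable[WeightedAlignment]) -> "AlignmentTable":
        rows = [
            (
                r.interval.chrom,
                r.interval.start,
                r.interval.end,
                r.interval.strand,
                r.hit_count,
                r.weight,
                r.length,
                r.five_prime_base,
            )
            for r in records
        ]
        df = pd.DataFrame(rows, columns=COLUMNS)
        if df.empty:
            df = _empty_frame()
        return cls(df)

    @classmethod
    def from_arrays(
        cls,
        chrom: Sequence[str] | pd.Categorical,
        start: np.ndarray,
        end: np.ndarray,
        strand: Sequence[str],
        hit_count: np.ndarray | None = None,
        read_length: np.ndarray | None = None,
        five_prime_base: Sequence[str] | None = None,
    ) -> "AlignmentTable":
        n = len(start)
        hc = np.ones(n, dtype=np.int64) if hit_count is None else np.asarray(hit_count)
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.asarray(start, dtype=np.int64),
                "end": np.asarray(end, dtype=np.int64),
                "strand": strand,
                "hit_count": hc,
                "weight": 1.0 / hc,
                "read_length": (
                    np.asarray(end, dtype=np.int64) - np.asarray(start, dtype=np.int64)
                    if read_length is None
                    else np.asarray(read_length, dtype=np.int64)
                ),
                "five_prime_base": (
                    ["N"] * n if five_prime_base is None else five_prime_base
                ),
            }
        )
        return cls(df)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=object),
            "hit_count": pd.Series(dtype=np.int64),
            "weight": pd.Series(dtype=float),
            "read_length": pd.Series(dtype=np.int64),
            "five_prime_base": pd.Series(dtype=object),
        }
    )


def _check_chromosomes(chroms: np.ndarray, genome: GenomeModel, path: str) -> None:
    unknown = set(np.unique(chroms)) - set(genome.names)
    if unknown:
        name = sorted(unknown)[0]
        raise ValueError(f"{path}: unknown chromosome {name!r}")


def load_bed(path: str | Path, genome: GenomeModel | None = None) -> AlignmentTable:
    """Load BED6 placements.

    Optional columns beyond the canonical six: column 7 is the placement
    multiplicity (``hit_count``), column 8 the strand-corrected 5' base
    (small-RNA libraries).  Unknown-chromosome and malformed records raise
    with the offending name or line number.
    """
    path = str(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype={0: str},
        )
    except pd.errors.EmptyDataError:
        return AlignmentTable(_empty_frame())
    except Exception:
        _scan_bed_for_error(path)
        raise
    if df.shape[1] < 6:
        _scan_bed_for_error(path, min_cols=6)
        raise ValueError(f"{path}: expected >= 6 BED columns")
    try:
        start = df[1].to_numpy(dtype=np.int64)
        end = df[2].to_numpy(dtype=np.int64)
    except (ValueError, TypeError):
        _scan_bed_for_error(path, min_cols=6)
        raise
    bad = np.flatnonzero((start < 0) | (end <= start))
    if bad.size:
        raise ValueError(f"{path}: line {bad[0] + 1}: empty or inverted interval")
    strand = df[5].astype(str).to_numpy()
    bad_strand = np.flatnonzero(~np.isin(strand, STRANDS))
    if bad_strand.size:
        raise ValueError(f"{path}: line {bad_strand[0] + 1}: invalid strand")
    hit = (
        df[6].to_numpy(dtype=np.int64)
        if df.shape[1] >= 7
        else np.ones(len(df), dtype=np.int64)
    )
    if (hit < 1).any():
        line = int(np.flatnonzero(hit < 1)[0]) + 1
        raise ValueError(f"{path}: line {line}: hit_count must be >= 1")
    base = (
        df[7].astype(str).to_numpy() if df.shape[1] >= 8 else ["N"] * len(df)
    )
    chroms = df[0].to_numpy()
    if genome is not None:
        _check_chromosomes(chroms, genome, path)
    return AlignmentTable.from_arrays(
        chroms, start, end, strand, hit_count=hit, five_prime_base=list(base)
    )


def _scan_bed_for_error(path: str, min_cols: int = 3) -> None:
    """Line-by-line pass to attribute a parse failure to a line number."""
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < min_cols:
            raise ValueError(f"{path}: line {i}: fewer than {min_cols} columns")
        try:
            int(f[1]), int(f[2])
        except ValueError:
            raise ValueError(f"{path}: line {i}: non-integer coordinates") from None


def load_sam(path: str | Path, genome: GenomeModel | None = None) -> AlignmentTable:
    """Load SAM/BAM placements via pysam.

    ``hit_count`` is taken from the NH tag when present; otherwise the number
    of records sharing the read name.  The 5' base is the strand-corrected
    first base of the original read (complement of the last stored base for
    reverse-strand records).
    """
    path = str(path)
    records = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            records.append(rec)
    name_counts = Counter(r.query_name for r in records)
    rows = []
    for rec in records:
        chrom = rec.reference_name
        if genome is not None and chrom not in genome:
            raise ValueError(f"{path}: unknown chromosome {chrom!r}")
        nh = rec.get_tag("NH") if rec.has_tag("NH") else name_counts[rec.query_name]
        seq = rec.query_sequence or ""
        if seq:
            base = _COMPLEMENT.get(seq[-1], "N") if rec.is_reverse else seq[0]
        else:
            base = "N"
        rows.append(
            (
                chrom,
                rec.reference_start,
                rec.reference_end,
                "-" if rec.is_reverse else "+",
                int(nh),
                1.0 / int(nh),
                rec.query_length or (rec.reference_end - rec.reference_start),
                base,
            )
        )
    df = pd.DataFrame(rows, columns=COLUMNS) if rows else _empty_frame()
    return AlignmentTable(df)


def load_alignments(
    path: str | Path,
    format: str | None = None,
    genome: GenomeModel | None = None,
) -> AlignmentTable:
    """Load an alignment file (``BED6`` or ``SAM``; inferred from suffix)."""
    if format is None:
        suffix = Path(path).suffix.lower()
        format = {".bed": "BED6", ".sam": "SAM", ".bam": "SAM"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer alignment format from {path}")
    fmt = format.upper()
    if fmt == "BED6":
        return load_bed(path, genome)
    if fmt in ("SAM", "BAM"):
        return load_sam(path, genome)
    raise ValueError(f"unsupported alignment format {format!r}")
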