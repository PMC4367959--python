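"""Exon/intron read classification and pre-mRNA enrichment metrics.

Reads are classified by midpoint against transcript models (exon wins when
overlapping genes disagree); the intron/exon tag ratio of a nascent-RNA
library relative to a matched mRNA library quantifies how strongly the
protocol enriches unspliced transcripts.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignments import AlignmentTable
from .genome import GenomicInterval


@dataclass
class TranscriptModel:
    """A gene as sorted exons; introns are the inter-exon gaps."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


def transcripts_from_gff(path: str | Path) -> list[TranscriptModel]:
    """Read gene/exon models from GFF3 (via gffutils; introns derived)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
            for e in db.children(gene, featuretype="exon", order_by="start")
        ]
        if not exons:
            continue
        gid = gene.attributes.get("ID", [gene.id])[0]
        models.append(TranscriptModel(gid, gene.seqid, gene.strand, exons))
    return models


@dataclass
class ExonIntronSummary:
    """Weighted percentage breakdown of a library's tags by gene structure."""

    library_id: str
    pct_exonic: float
    pct_intronic: float
    pct_other: float

    def __post_init__(self) -> None:
        total = self.pct_exonic + self.pct_intronic + self.pct_other
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"percentages sum to {total}, not 100")

    @property
    def intron_exon_ratio(self) -> float:
        if self.pct_exonic == 0:
            raise ZeroDivisionError("no exonic tags; ratio undefined")
        return self.pct_intronic / self.pct_exonic


class _IntervalLookup:
    """Per-chromosome sorted half-open spans for vectorised point queries."""

    def __init__(self, intervals: Sequence[GenomicInterval]) -> None:
        from .genome import merge_within

        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        for iv in merge_within(intervals, 0):
            starts.setdefault(iv.chrom, []).append(iv.start)
            ends.setdefault(iv.chrom, []).append(iv.end)
        for c in starts:
            self.by_chrom[c] = (np.asarray(starts[c]), np.asarray(ends[c]))

    def contains(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        out = np.zeros(len(positions), dtype=bool)
        for c, (starts, ends) in self.by_chrom.items():
            m = chroms == c
            if not m.any():
                continue
            pos = positions[m]
            i = np.searchsorted(starts, pos, side="right") - 1
            ok = i >= 0
            hit = np.zeros(len(pos), dtype=bool)
            hit[ok] = pos[ok] < ends[i[ok]]
            out[m] = hit
        return out


def classify_reads(
    alignments: AlignmentTable,
    models: Sequence[TranscriptModel],
    library_id: str = "",
    weighted: bool = True,
) -> ExonIntronSummary:
    """Classify each placement's midpoint as exonic, intronic, or other.

    Percentages are weight-conserving: with ``weighted=False`` every
    placement counts 1 instead of its multi-mapper weight.
    """
    if not models:
        raise ValueError("no transcript models")
    exons = _IntervalLookup([e for m in models for e in m.exons])
    introns = _IntervalLookup([i for m in models for i in m.introns])
    chroms = alignments.df["chrom"].to_numpy()
    mid = alignments.midpoints()
    w = (
        alignments.df["weight"].to_numpy()
        if weighted
        else np.ones(len(alignments))
    )
    total = w.sum()
    if total == 0:
        raise ValueError("no reads to classify")
    in_exon = exons.contains(chroms, mid)
    in_intron = introns.contains(chroms, mid) & ~in_exon  # exon takes priority
    pe = 100.0 * w[in_exon].sum() / total
    pi = 100.0 * w[in_intron].sum() / total
    return ExonIntronSummary(
        library_id=library_id,
        pct_exonic=pe,
        pct_intronic=pi,
        pct_other=100.0 - pe - pi,
    )


def premrna_enrichment_factor(
    pre: ExonIntronSummary, mrna: ExonIntronSummary
) -> float:
    """[intron/exon] ratio of the nascent library over the mRNA library."""
    if mrna.pct_intronic == 0:
        raise ZeroDivisionError(
            "mRNA library has no intronic tags; add a pseudocount to the "
            "summary (e.g. classify with a small spike) before comparing"
        )
    return pre.intron_exon_ratio / mrna.intron_exon_ratio


def region_strand_bias(
    alignments: AlignmentTable,
    region: GenomicInterval,
    reference_strand: str,
) -> float:
    """Weighted fraction of in-region reads on ``reference_strand``.

    ~1.0 for sense-dominated transcription (e.g. desilenced retrotransposon
    pre-mRNA), ~0.0 for antisense-dominated signal (e.g. 22G siRNAs scored
    against the transcript strand).
    """
    if reference_strand not in ("+", "-"):
        raise ValueError("reference_strand must be '+' or '-'")
    sub = alignments.subset(region)
    total = sub.total_weight
    if total == 0:
        raise ValueError(f"no coverage in {region}")
    on = sub.df["strand"].to_numpy() == reference_strand
    return float(sub.df["weight"].to_numpy()[on].sum() / total)
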