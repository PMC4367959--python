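"""Packaged reference data.

The one bundled dataset is the catalogue of the sixteen largest GRTS
clusters in the C. elegans genome (WS190 coordinates) with their printed
repeat-element annotations and gene lists.  Region boundaries are 1-kb
multiples and are interpreted as 0-based half-open, bin-aligned intervals.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .genome import GenomicInterval

ANNOTATION_COLUMNS = ("ltr_retrotransposon", "line", "dna_transposon", "other_repeat")


def load_top_grts_clusters() -> pd.DataFrame:
    """The sixteen largest GRTS clusters with their annotations.

    Columns: chrom, start, end, length_kb, the four repeat annotation
    classes ('-' where absent), comma-separated gene lists, and whether the
    cluster overlaps a GRH cluster.
    """
    with resources.files("nucrnai.data").joinpath("grts_top_clusters.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def cluster_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def annotation_class_counts(df: pd.DataFrame) -> dict[str, int]:
    """Number of clusters carrying each repeat annotation class."""
    return {
        col: int((df[col].astype(str) != "-").sum()) for col in ANNOTATION_COLUMNS
    }


def computed_lengths_kb(df: pd.DataFrame) -> np.ndarray:
    """Cluster lengths recomputed from the printed interval boundaries."""
    return ((df["end"] - df["start"]) / 1000.0).to_numpy()
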