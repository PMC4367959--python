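"""Synthetic genome, annotations, and read libraries with planted truth.

The generator emulates the statistical structure the analysis assumes:
per-bin Poisson read counts with genotype-specific fold effects in planted
regions (Pol II / pre-mRNA / mRNA up and H3K9me3 down in the "mutant"),
duplicated repeat blocks that yield multi-mapping reads (hit_count = number
of copies, weight 1/copies), exon/intron-structured transcripts with
library-specific intronic fractions, and antisense 21-22-nt 5'-G small RNAs
concentrated at planted targets.  Everything is deterministic given the
seed, and a :class:`TruthRecord` exposes the planted regions so every
pipeline stage can be scored against ground truth.

Gene structure is deliberately simple: each full 1-kb bin carries one gene
with exons [0, 600) and [900, 1000) and an intron [600, 900), so intronic
placement probabilities translate directly into tag percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import AlignmentTable
from .genome import Bin, GenomeBins, GenomeModel, GenomicInterval
from .rna import TranscriptModel
from .tracks import ASSAYS, POLII_ASSAYS

GENOTYPES = ("wildtype", "mutant")

_EXON1_END = 600
_INTRON_END = 900

# spacing (in bins) kept between planted features so that 5-kb clustering
# never merges two distinct planted regions
_PLANT_MARGIN_BINS = 8


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the real study's conditions at desk scale: a six-
    chromosome genome (five autosomes plus chrX, planted targets
    autosome-only), ~20 background reads per 1-kb bin (the real libraries
    average ~21), Pol II and H3K9me3 effects near the reported median folds,
    pre-mRNA desilencing on the 10-50-fold scale, 16 target clusters with
    LTR-like elements planted in 10 of them, and 21-22-nt 5'-G siRNAs.
    """

    seed: int = 0
    chromosome_lengths: tuple[tuple[str, int], ...] = (
        ("chrI", 1_000_000),
        ("chrII", 1_000_000),
        ("chrIII", 1_000_000),
        ("chrIV", 1_000_000),
        ("chrV", 1_000_000),
        ("chrX", 1_000_000),
    )
    bin_size: int = 1000
    n_grts_regions: int = 16
    n_grh_regions: int = 22
    n_overlap_regions: int = 8
    grts_len_bins: int = 3
    grh_len_bins: int = 1
    grts_polII_fold: float = 6.0
    grh_h3k9_fold: float = 6.0
    premrna_fold: float = 50.0
    mrna_fold: float = 5.0
    desilenced_fraction: float = 0.7
    sirna_target_fold: float = 10.0
    sirna_fold: float = 1.0
    sirna_reduced_fraction: float = 0.0
    background_reads_per_bin: float = 20.0
    intronic_fraction_pre: float = 0.2
    intronic_fraction_mrna: float = 0.01
    repeat_copies: int = 4
    repeat_block_bins: int = 2
    ltr_in_grts_fraction: float = 0.625
    n_background_ltr: int = 5
    n_dna_transposon: int = 1
    read_length: int = 50
    sirna_len_probs: tuple[tuple[int, float], ...] = (
        (20, 0.10),
        (21, 0.35),
        (22, 0.45),
        (23, 0.10),
    )
    sirna_5g_prob: float = 0.75
    x_chromosome_excluded: bool = True

    def __post_init__(self) -> None:
        # normalise sequence fields (e.g. parsed from YAML lists) to tuples
        # so configurations stay hashable for plan caching
        object.__setattr__(
            self,
            "chromosome_lengths",
            tuple((str(n), int(l)) for n, l in self.chromosome_lengths),
        )
        object.__setattr__(
            self,
            "sirna_len_probs",
            tuple((int(k), float(p)) for k, p in self.sirna_len_probs),
        )
        for name in (
            "grts_polII_fold",
            "grh_h3k9_fold",
            "premrna_fold",
            "mrna_fold",
            "sirna_target_fold",
            "sirna_fold",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("intronic_fraction_pre", "intronic_fraction_mrna"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.background_reads_per_bin <= 0:
            raise ValueError("background_reads_per_bin must be positive")
        if self.repeat_copies < 2:
            raise ValueError("repeat_copies must be >= 2")
        if self.n_overlap_regions > min(self.n_grts_regions, self.n_grh_regions):
            raise ValueError("n_overlap_regions exceeds the planted region counts")
        probs = dict(self.sirna_len_probs)
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("sirna_len_probs must sum to 1")

    def genome(self) -> GenomeModel:
        return GenomeModel(self.chromosome_lengths)


@dataclass(frozen=True)
class PlantedRegion:
    """One planted locus with its class and per-assay effects."""

    interval: GenomicInterval
    region_class: str  # GRTS | GRH | both
    gene_strand: str = "+"
    has_ltr: bool = False
    ltr: GenomicInterval | None = None
    desilenced: bool = False
    sirna_reduced: bool = False

    @property
    def is_grts(self) -> bool:
        return self.region_class in ("GRTS", "both")

    @property
    def is_grh(self) -> bool:
        return self.region_class in ("GRH", "both")


@dataclass
class TruthRecord:
    """Planted ground truth: regions, repeats, and annotation features."""

    regions: list[PlantedRegion]
    repeat_copies: list[GenomicInterval]
    background_ltrs: list[GenomicInterval]
    dna_transposons: list[GenomicInterval]

    def grts_regions(self) -> list[PlantedRegion]:
        return [r for r in self.regions if r.is_grts]

    def grh_regions(self) -> list[PlantedRegion]:
        return [r for r in self.regions if r.is_grh]

    def bin_indices(self, bins: GenomeBins, which: str = "GRTS") -> np.ndarray:
        sel = {
            "GRTS": lambda r: r.is_grts,
            "GRH": lambda r: r.is_grh,
            "any": lambda r: True,
        }[which]
        idx: list[int] = []
        for r in self.regions:
            if sel(r):
                idx.extend(bins.bins_overlapping(r.interval))
        return np.array(sorted(set(idx)), dtype=np.int64)

    def ltr_features(self) -> list[tuple[GenomicInterval, str, str]]:
        feats = []
        k = 0
        for r in self.regions:
            if r.ltr is not None:
                feats.append((r.ltr, "LTR_retrotransposon", f"CerSim-{k}"))
                k += 1
        for i, iv in enumerate(self.background_ltrs):
            feats.append((iv, "LTR_retrotransposon", f"CerSim-bg-{i}"))
        return feats

    def all_features(self) -> list[tuple[GenomicInterval, str, str]]:
        feats = self.ltr_features()
        feats += [
            (iv, "DNA_transposon", f"TcSim-{i}")
            for i, iv in enumerate(self.dna_transposons)
        ]
        feats += [
            (iv, "other_repeat", f"repeat-copy-{i}")
            for i, iv in enumerate(self.repeat_copies)
        ]
        return feats

    def to_dict(self) -> dict:
        def iv(x: GenomicInterval | None):
            return None if x is None else [x.chrom, x.start, x.end, x.strand]

        return {
            "regions": [
                {
                    "interval": iv(r.interval),
                    "class": r.region_class,
                    "gene_strand": r.gene_strand,
                    "has_ltr": r.has_ltr,
                    "ltr": iv(r.ltr),
                    "desilenced": r.desilenced,
                    "sirna_reduced": r.sirna_reduced,
                }
                for r in self.regions
            ],
            "repeat_copies": [iv(x) for x in self.repeat_copies],
            "background_ltrs": [iv(x) for x in self.background_ltrs],
            "dna_transposons": [iv(x) for x in self.dna_transposons],
        }


class _BinAllocator:
    """Places non-overlapping bin runs with a safety margin, autosome-first."""

    def __init__(self, gb: GenomeBins, rng: np.random.Generator, allowed: np.ndarray):
        self.gb = gb
        self.rng = rng
        self.free = np.zeros(gb.n_bins, dtype=bool)
        self.free[allowed] = True
        # never plant in the last (possibly partial) bin of a chromosome
        for name in gb.genome.names:
            o, n = gb.offsets[name], gb.n_per_chrom[name]
            self.free[o + n - 1] = False

    def take(self, k: int) -> int:
        """Return the first bin index of a free run of k bins (one chromosome)."""
        codes = self.gb.bin_chrom_codes
        for _ in range(10000):
            cand = np.flatnonzero(self.free)
            if cand.size == 0:
                break
            s = int(self.rng.choice(cand))
            if s + k > self.gb.n_bins:
                continue
            if not self.free[s : s + k].all():
                continue
            if codes[s] != codes[s + k - 1]:
                continue
            lo = max(0, s - _PLANT_MARGIN_BINS)
            self.free[lo : s + k + _PLANT_MARGIN_BINS] = False
            return s
        raise ValueError("planted regions exceed chromosome capacity")


def _plan_cached(config: SimulationConfig) -> TruthRecord:
    gb = GenomeBins(config.genome(), config.bin_size)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    genome = gb.genome
    allowed_chroms = (
        genome.autosomes() if config.x_chromosome_excluded else genome.names
    )
    allowed = np.flatnonzero(
        np.isin(
            gb.bin_chrom_codes,
            [genome.names.index(c) for c in allowed_chroms],
        )
    )
    alloc = _BinAllocator(gb, rng, allowed)

    def region_at(start_bin: int, k: int) -> GenomicInterval:
        return GenomicInterval(
            genome.names[gb.bin_chrom_codes[start_bin]],
            int(gb.bin_starts[start_bin]),
            int(gb.bin_ends[start_bin + k - 1]),
        )

    n_grts = config.n_grts_regions
    n_overlap = config.n_overlap_regions
    n_grh_only = config.n_grh_regions - n_overlap

    grts_ivs = [region_at(alloc.take(config.grts_len_bins), config.grts_len_bins)
                for _ in range(n_grts)]
    grh_ivs = [region_at(alloc.take(config.grh_len_bins), config.grh_len_bins)
               for _ in range(n_grh_only)]

    n_ltr = int(round(config.ltr_in_grts_fraction * n_grts))
    ltr_pick = set(rng.choice(n_grts, size=n_ltr, replace=False).tolist())
    n_des = int(round(config.desilenced_fraction * n_grts))
    des_pick = set(rng.choice(n_grts, size=n_des, replace=False).tolist())

    regions: list[PlantedRegion] = []
    dna_transposons: list[GenomicInterval] = []
    for i, iv in enumerate(grts_ivs):
        ltr = None
        if i in ltr_pick:
            ltr = GenomicInterval(iv.chrom, iv.start + 100, iv.start + 900)
        regions.append(
            PlantedRegion(
                interval=iv,
                region_class="both" if i < n_overlap else "GRTS",
                has_ltr=ltr is not None,
                ltr=ltr,
                desilenced=i in des_pick,
            )
        )
    # a DNA transposon embedded in the first LTR-bearing region, if any
    ltr_regions = [r for r in regions if r.has_ltr]
    for j in range(min(config.n_dna_transposon, len(ltr_regions))):
        host = ltr_regions[j].ltr
        assert host is not None
        dna_transposons.append(
            GenomicInterval(host.chrom, host.start + 200, host.start + 500)
        )
    for iv in grh_ivs:
        regions.append(PlantedRegion(interval=iv, region_class="GRH"))

    # siRNA-reduced subset among all planted target regions
    n_red = int(round(config.sirna_reduced_fraction * len(regions)))
    red_pick = set(rng.choice(len(regions), size=n_red, replace=False).tolist())
    regions = [
        PlantedRegion(
            interval=r.interval,
            region_class=r.region_class,
            gene_strand=r.gene_strand,
            has_ltr=r.has_ltr,
            ltr=r.ltr,
            desilenced=r.desilenced,
            sirna_reduced=(i in red_pick),
        )
        for i, r in enumerate(regions)
    ]

    repeat_copies = [
        region_at(alloc.take(config.repeat_block_bins), config.repeat_block_bins)
        for _ in range(config.repeat_copies if config.repeat_block_bins else 0)
    ]
    background_ltrs = []
    for _ in range(config.n_background_ltr):
        s = alloc.take(1)
        background_ltrs.append(
            GenomicInterval(
                genome.names[gb.bin_chrom_codes[s]],
                int(gb.bin_starts[s]) + 100,
                int(gb.bin_starts[s]) + 900,
            )
        )
    return TruthRecord(
        regions=regions,
        repeat_copies=repeat_copies,
        background_ltrs=background_ltrs,
        dna_transposons=dna_transposons,
    )


@lru_cache(maxsize=16)
def _plan(config: SimulationConfig) -> TruthRecord:
    return _plan_cached(config)


def plan(config: SimulationConfig) -> TruthRecord:
    """Deterministic planted-truth layout for a configuration."""
    return _plan(config)


def _gene_strand_codes(config: SimulationConfig, gb: GenomeBins, truth: TruthRecord) -> np.ndarray:
    """Per-bin gene strand (0='+', 1='-'): alternating, '+' forced at targets."""
    codes = (np.arange(gb.n_bins) % 2).astype(np.int8)
    for r in truth.regions:
        rr = gb.bins_overlapping(r.interval)
        codes[rr.start : rr.stop] = 0 if r.gene_strand == "+" else 1
    return codes


def mean_vector(
    config: SimulationConfig, assay: str, genotype: str
) -> np.ndarray:
    """Analytic Poisson mean per bin for one library (the simulator's truth)."""
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}")
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    gb = GenomeBins(config.genome(), config.bin_size)
    truth = plan(config)
    mean = np.full(gb.n_bins, float(config.background_reads_per_bin))
    for r in truth.regions:
        rr = gb.bins_overlapping(r.interval)
        sl = slice(rr.start, rr.stop)
        if assay in POLII_ASSAYS and genotype == "mutant" and r.is_grts:
            mean[sl] *= config.grts_polII_fold
        elif assay == "H3K9me3" and genotype == "wildtype" and r.is_grh:
            mean[sl] *= config.grh_h3k9_fold
        elif assay == "pre_mRNA" and genotype == "mutant" and r.is_grts:
            mean[sl] *= config.premrna_fold
        elif assay == "mRNA" and genotype == "mutant" and r.is_grts and r.desilenced:
            mean[sl] *= config.mrna_fold
        elif assay == "smallRNA":
            level = config.sirna_target_fold
            if genotype == "mutant" and r.sirna_reduced:
                level /= config.sirna_fold
            mean[sl] *= level
    return mean


def expected_bin_mean(
    config: SimulationConfig, bin: Bin | int, assay: str, genotype: str
) -> float:
    """Closed-form Poisson mean used by :func:`simulate` for one bin/library."""
    idx = bin.index if isinstance(bin, Bin) else int(bin)
    vec = mean_vector(config, assay, genotype)
    if not 0 <= idx < len(vec):
        raise ValueError(f"bin index {idx} outside genome")
    return float(vec[idx])


def _simulate_library(
    config: SimulationConfig, assay: str, genotype: str
) -> AlignmentTable:
    gb = GenomeBins(config.genome(), config.bin_size)
    truth = plan(config)
    lib_index = ASSAYS.index(assay) * len(GENOTYPES) + GENOTYPES.index(genotype)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1, lib_index))
    )
    means = mean_vector(config, assay, genotype)
    counts = rng.poisson(means)
    bin_idx = np.repeat(np.arange(gb.n_bins), counts)
    n = len(bin_idx)
    chrom_codes = gb.bin_chrom_codes[bin_idx]
    widths = gb.bin_widths[bin_idx]
    bstarts = gb.bin_starts[bin_idx]
    chrom_lens = np.array([l for _, l in config.chromosome_lengths], dtype=np.int64)

    # midpoint offset within the bin
    u = rng.random(n)
    if assay in ("pre_mRNA", "mRNA"):
        f = (
            config.intronic_fraction_pre
            if assay == "pre_mRNA"
            else config.intronic_fraction_mrna
        )
        intronic = rng.random(n) < f
        off = np.empty(n)
        off[intronic] = _EXON1_END + u[intronic] * (_INTRON_END - _EXON1_END)
        e = u[~intronic] * 700.0
        off[~intronic] = np.where(e < _EXON1_END, e, e + 300.0)
        partial = widths < config.bin_size
        off[partial] = u[partial] * widths[partial]
    else:
        off = u * widths
    mid = bstarts + off.astype(np.int64)

    gene_codes = _gene_strand_codes(config, gb, truth)[bin_idx]
    if assay == "smallRNA":
        target_mask = np.zeros(gb.n_bins, dtype=bool)
        for r in truth.regions:
            rr = gb.bins_overlapping(r.interval)
            target_mask[rr.start : rr.stop] = True
        is_target = target_mask[bin_idx]
        lens = rng.integers(18, 31, size=n).astype(np.int64)
        sl, sp = zip(*config.sirna_len_probs)
        lens[is_target] = rng.choice(sl, size=int(is_target.sum()), p=sp)
        # strand: antisense to the gene at targets, random elsewhere
        strand_codes = (rng.random(n) < 0.5).astype(np.int8)
        strand_codes[is_target] = 1 - gene_codes[is_target]
        bases = np.array(["A", "C", "G", "T"], dtype=object)[
            rng.integers(0, 4, size=n)
        ]
        is_g = rng.random(n) < config.sirna_5g_prob
        alt = np.array(["A", "C", "T"], dtype=object)[rng.integers(0, 3, size=n)]
        bases[is_target] = np.where(is_g[is_target], "G", alt[is_target])
        read_len = lens
    else:
        read_len = np.full(n, config.read_length, dtype=np.int64)
        if assay in ("pre_mRNA", "mRNA"):
            strand_codes = gene_codes.copy()
        else:
            strand_codes = (rng.random(n) < 0.5).astype(np.int8)
        bases = np.full(n, "N", dtype=object)

    starts = mid - read_len // 2
    max_start = chrom_lens[chrom_codes] - read_len
    starts = np.clip(starts, 0, np.maximum(max_start, 0))
    ends = starts + read_len
    hit = np.ones(n, dtype=np.int64)

    # duplicated repeat blocks -> multi-mapped placements at every copy
    copies = truth.repeat_copies
    if copies:
        k = len(copies)
        copy_codes = np.array(
            [gb.genome.names.index(c.chrom) for c in copies], dtype=np.int64
        )
        copy_starts = np.array([c.start for c in copies], dtype=np.int64)
        copy_ends = np.array([c.end for c in copies], dtype=np.int64)
        in_copy = np.full(n, -1, dtype=np.int64)
        for j in range(k):
            m = (
                (chrom_codes == copy_codes[j])
                & (mid >= copy_starts[j])
                & (mid < copy_ends[j])
            )
            in_copy[m] = j
        multi = in_copy >= 0
        if multi.any():
            offs = mid[multi] - copy_starts[in_copy[multi]]
            nm = int(multi.sum())
            # one row per (multi read, copy)
            rep_mid = (copy_starts[None, :] + offs[:, None]).ravel()
            rep_codes = np.broadcast_to(copy_codes, (nm, k)).ravel()
            rep_len = np.repeat(read_len[multi], k)
            rep_strand = np.repeat(strand_codes[multi], k)
            rep_bases = np.repeat(bases[multi], k)
            rep_starts = rep_mid - rep_len // 2
            rep_max = chrom_lens[rep_codes] - rep_len
            rep_starts = np.clip(rep_starts, 0, np.maximum(rep_max, 0))
            rep_ends = rep_starts + rep_len
            keep = ~multi
            chrom_codes = np.concatenate([chrom_codes[keep], rep_codes])
            starts = np.concatenate([starts[keep], rep_starts])
            ends = np.concatenate([ends[keep], rep_ends])
            strand_codes = np.concatenate([strand_codes[keep], rep_strand])
            bases = np.concatenate([bases[keep], rep_bases])
            read_len = np.concatenate([read_len[keep], rep_len])
            hit = np.concatenate(
                [hit[keep], np.full(nm * k, k, dtype=np.int64)]
            )

    chroms = pd.Categorical.from_codes(
        chrom_codes.astype(np.int64), categories=gb.genome.names
    ).astype(object)
    strands = np.where(strand_codes == 0, "+", "-")
    return AlignmentTable.from_arrays(
        chroms,
        starts,
        ends,
        list(strands),
        hit_count=hit,
        read_length=read_len,
        five_prime_base=list(bases),
    )


def build_transcript_models(
    config: SimulationConfig,
) -> list[TranscriptModel]:
    """The generator's gene models (one two-exon gene per full bin)."""
    gb = GenomeBins(config.genome(), config.bin_size)
    truth = plan(config)
    strands = _gene_strand_codes(config, gb, truth)
    models = []
    for i in range(gb.n_bins):
        chrom = gb.genome.names[gb.bin_chrom_codes[i]]
        s = int(gb.bin_starts[i])
        e = int(gb.bin_ends[i])
        strand = "+" if strands[i] == 0 else "-"
        if e - s == config.bin_size and config.bin_size == 1000:
            exons = [
                GenomicInterval(chrom, s, s + _EXON1_END, strand),
                GenomicInterval(chrom, s + _INTRON_END, e, strand),
            ]
        else:
            exons = [GenomicInterval(chrom, s, e, strand)]
        models.append(TranscriptModel(f"g{i:06d}", chrom, strand, exons))
    return models


@dataclass
class SimulationResult:
    """All in-memory outputs of one simulation run."""

    config: SimulationConfig
    genome: GenomeModel
    bins: GenomeBins
    truth: TruthRecord
    libraries: dict[tuple[str, str], AlignmentTable]
    paths: dict[str, Path] = field(default_factory=dict)

    def library(self, assay: str, genotype: str) -> AlignmentTable:
        return self.libraries[(assay, genotype)]

    def transcript_models(self) -> list[TranscriptModel]:
        return build_transcript_models(self.config)

    def features(self) -> list[tuple[GenomicInterval, str, str]]:
        return self.truth.all_features()


def simulate(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    assays: Sequence[str] | None = None,
    genotypes: Sequence[str] = GENOTYPES,
) -> SimulationResult:
    """Generate libraries (and optionally write all files) for a configuration.

    Each library's read stream is seeded independently from ``config.seed``,
    so generating a subset of libraries yields byte-identical content to a
    full run.  When ``outdir`` is given, writes chrom.sizes, a gene GFF3,
    classed feature BED, per-library BED6 alignments (column 7 = hit count,
    column 8 = 5' base), and truth.json.
    """
    use_assays = tuple(assays) if assays is not None else ASSAYS
    for a in use_assays:
        if a not in ASSAYS:
            raise ValueError(f"unknown assay {a!r}")
    genome = config.genome()
    gb = GenomeBins(genome, config.bin_size)
    truth = plan(config)
    libraries = {
        (a, g): _simulate_library(config, a, g)
        for a in use_assays
        for g in genotypes
    }
    result = SimulationResult(
        config=config, genome=genome, bins=gb, truth=truth, libraries=libraries
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        genome.to_chrom_sizes(out / "genome.chrom.sizes")
        result.paths["chrom_sizes"] = out / "genome.chrom.sizes"
        _write_gff(build_transcript_models(config), out / "genes.gff3")
        result.paths["genes_gff"] = out / "genes.gff3"
        _write_features(truth.all_features(), out / "features.bed")
        result.paths["features_bed"] = out / "features.bed"
        (out / "truth.json").write_text(
            json.dumps(truth.to_dict(), indent=1, sort_keys=True)
        )
        result.paths["truth"] = out / "truth.json"
        for (a, g), table in libraries.items():
            p = out / f"{a}_{g}.bed"
            _write_library_bed(table, p)
            result.paths[f"{a}_{g}"] = p
    return result


def _write_library_bed(table: AlignmentTable, path: Path) -> None:
    df = table.df
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples(index=False)):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\tr{i:07d}\t0\t{row.strand}"
                f"\t{row.hit_count}\t{row.five_prime_base}\n"
            )


def _write_gff(models: Sequence[TranscriptModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            fh.write(
                f"{m.chrom}\tsim\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            for j, e in enumerate(m.exons):
                fh.write(
                    f"{m.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{m.strand}\t.\tID={m.gene_id}.e{j};Parent={m.gene_id}\n"
                )


def _write_features(
    features: Sequence[tuple[GenomicInterval, str, str]], path: Path
) -> None:
    with open(path, "w") as fh:
        for iv, fclass, name in sorted(
            features, key=lambda t: (t[0].chrom, t[0].start)
        ):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fclass}|{name}\t0\t{iv.strand}\n"
            )
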