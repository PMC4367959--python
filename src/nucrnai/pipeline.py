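"""End-to-end orchestration: from aligned libraries to a target-calling report.

Stages: per-bin weighted tracks -> genotype fold changes -> tiered GRTS/GRH
calls -> 5-kb clusters with annotations -> proximity curve + binomial null
-> Monte Carlo enrichment -> RNA metrics -> small-RNA signatures.  Each
stochastic step records its seed; the report is deterministic given config
and seed (the timestamp is isolated to one header field of the Markdown).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import calls as _calls
from . import clusters as _clusters
from . import enrichment as _enrichment
from . import rna as _rna
from . import smallrna as _smallrna
from .alignments import AlignmentTable, load_alignments
from .genome import GenomeModel, GenomeBins, GenomicInterval, read_bed, write_bed
from .tracks import ASSAYS, POLII_ASSAYS, BinnedTrack, bin_signal


class PipelineError(RuntimeError):
    """A requested stage cannot run (typically a missing library)."""


#: libraries each explicitly requested stage needs
STAGE_REQUIREMENTS: dict[str, tuple[tuple[str, str], ...]] = {
    "grts": tuple(
        (a, g) for a in ("polII_8WG16", "polII_S2", "polII_S5")
        for g in ("wildtype", "mutant")
    ),
    "grh": (("H3K9me3", "wildtype"), ("H3K9me3", "mutant")),
    "premrna": (("pre_mRNA", "wildtype"), ("pre_mRNA", "mutant")),
    "rna": (("pre_mRNA", "wildtype"), ("mRNA", "wildtype")),
    "smallrna": (("smallRNA", "wildtype"),),
}


@dataclass
class LibrarySpec:
    assay: str
    genotype: str
    path: str
    format: str | None = None


@dataclass
class RunConfig:
    """Paths, libraries, and thresholds for one pipeline run."""

    genome: str
    outdir: str
    libraries: list[LibrarySpec]
    genes_gff: str | None = None
    features_bed: str | None = None
    seed: int = 0
    grts_cutoff: float = 3.0
    grh_cutoff: float = 3.0
    desilence_cutoff: float = 3.0
    epsilon: float | None = None
    min_signal_reads: float = 5.0
    cluster_gap: int = 5000
    large_cluster_bp: int = 10000
    proximity_max: int = 50000
    proximity_step: int = 1000
    alpha: float = 1e-12
    mc_iterations: int = 2000
    fraction_thresholds: tuple[float, ...] = (10.0, 50.0, 200.0)
    top_clusters: int = 16
    reduced_sirna_cutoff: float = 3.0
    stages: tuple[str, ...] | None = None  # None: run whatever libraries allow

    def __post_init__(self) -> None:
        for name in ("grts_cutoff", "grh_cutoff", "cluster_gap", "mc_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        libs = [LibrarySpec(**d) for d in raw.pop("libraries", [])]
        ann = raw.pop("annotations", {}) or {}
        params = raw.pop("parameters", {}) or {}
        return cls(
            genome=raw.pop("genome"),
            outdir=raw.pop("outdir", "results"),
            libraries=libs,
            genes_gff=ann.get("genes_gff"),
            features_bed=ann.get("features_bed"),
            seed=int(raw.pop("seed", 0)),
            **params,
        )


def _require(
    tracks: dict[tuple[str, str], BinnedTrack], stage: str, assay: str, genotype: str
) -> BinnedTrack:
    key = (assay, genotype)
    if key not in tracks:
        raise PipelineError(
            f"stage {stage!r} requires library assay={assay} genotype={genotype}"
        )
    return tracks[key]


def _load_features(path: str) -> list[tuple[GenomicInterval, str, str]]:
    """BED whose name column is 'feature_class|name'."""
    feats = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise ValueError(f"{path}: line {i}: need 4+ columns with classed names")
        fclass, _, name = f[3].partition("|")
        feats.append((GenomicInterval(f[0], int(f[1]), int(f[2])), fclass, name or f[3]))
    return feats


def _calls_table(calllist: Sequence[_calls.RegionCall]) -> list[dict[str, Any]]:
    return [
        {
            "chrom": c.bin.chrom,
            "start": c.bin.start,
            "end": c.bin.end,
            "call_type": c.call_type,
            "tier": c.tier,
            **{f"fc_{a}": round(v, 4) for a, v in c.per_assay_fc.items()},
        }
        for c in calllist
    ]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage the configured libraries support; return the report.

    Writes tracks, calls, clusters, and the JSON/Markdown report under
    ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = GenomeModel.from_chrom_sizes(config.genome)
    gb = GenomeBins(genome)
    report: dict[str, Any] = {
        "config": {
            "seed": config.seed,
            "grts_cutoff": config.grts_cutoff,
            "grh_cutoff": config.grh_cutoff,
            "cluster_gap": config.cluster_gap,
            "alpha": config.alpha,
            "mc_iterations": config.mc_iterations,
            "min_signal_reads": config.min_signal_reads,
            "epsilon": config.epsilon,
        },
        "genome": {"n_chromosomes": len(genome), "n_bins": gb.n_bins},
    }

    tables: dict[tuple[str, str], AlignmentTable] = {}
    tracks: dict[tuple[str, str], BinnedTrack] = {}
    for spec in config.libraries:
        table = load_alignments(spec.path, spec.format, genome=genome)
        key = (spec.assay, spec.genotype)
        tables[key] = table
        tracks[key] = bin_signal(
            table,
            gb,
            normalize="per_million",
            library_id=f"{spec.assay}_{spec.genotype}",
            genotype=spec.genotype,
            assay=spec.assay,
        )
    if config.stages:
        for stage in config.stages:
            if stage not in STAGE_REQUIREMENTS:
                raise PipelineError(f"unknown stage {stage!r}")
            for assay, genotype in STAGE_REQUIREMENTS[stage]:
                if (assay, genotype) not in tracks:
                    raise PipelineError(
                        f"stage {stage!r} requires library assay={assay} "
                        f"genotype={genotype}"
                    )
    report["libraries"] = {
        f"{a}_{g}": {
            "n_placements": len(tables[(a, g)]),
            "n_reads": round(tables[(a, g)].total_weight, 3),
        }
        for (a, g) in sorted(tracks)
    }

    # ---- GRTS calling -----------------------------------------------------
    grts_calls: list[_calls.RegionCall] = []
    grts_regions: list[GenomicInterval] = []
    have_polII = all(
        (a, g) in tracks for a in POLII_ASSAYS for g in ("wildtype", "mutant")
    )
    if have_polII:
        fc = {}
        mut_signal_reads = {}
        for a in POLII_ASSAYS:
            mut = _require(tracks, "grts", a, "mutant")
            wt = _require(tracks, "grts", a, "wildtype")
            eps = config.epsilon or _calls.default_epsilon(mut, wt)
            fc[a] = _calls.fold_change(mut, wt, eps)
            mut_signal_reads[a] = mut.values / mut.depth_factor
        grts_calls = _calls.call_grts(
            fc,
            gb,
            cutoff=config.grts_cutoff,
            mutant_signal=mut_signal_reads,
            min_signal=config.min_signal_reads,
        )
        grts_regions = [c.interval for c in grts_calls]
        summary = _calls.summarize_calls(grts_calls, genome)
        report["grts"] = {
            "n_calls": summary.n_calls,
            "median_fc": summary.median_fc,
            "per_chromosome": summary.per_chromosome,
            "sex_chromosome_fraction": summary.sex_chromosome_fraction,
        }
        decreased = _calls.call_polII_decreased(fc, gb, cutoff=config.grts_cutoff)
        report["polII_decreased"] = {"n_calls": len(decreased)}
        write_bed([c.interval for c in grts_calls], out / "grts_calls.bed")
        _write_tsv(_calls_table(grts_calls), out / "grts_calls.tsv")

    # ---- GRH calling ------------------------------------------------------
    grh_calls: list[_calls.RegionCall] = []
    grh_regions: list[GenomicInterval] = []
    if ("H3K9me3", "mutant") in tracks and ("H3K9me3", "wildtype") in tracks:
        wt = tracks[("H3K9me3", "wildtype")]
        mut = tracks[("H3K9me3", "mutant")]
        eps = config.epsilon or _calls.default_epsilon(mut, wt)
        grh_fc = {"mutant": _calls.fold_change_values(wt.values, mut.values, eps)}
        grh_calls = _calls.call_grh(grh_fc, gb, cutoff=config.grh_cutoff).calls
        grh_regions = [c.interval for c in grh_calls]
        summary = _calls.summarize_calls(grh_calls, genome)
        report["grh"] = {
            "n_calls": summary.n_calls,
            "median_fc": summary.median_fc,
            "per_chromosome": summary.per_chromosome,
            "sex_chromosome_fraction": summary.sex_chromosome_fraction,
        }
        write_bed(grh_regions, out / "grh_calls.bed")
        _write_tsv(_calls_table(grh_calls), out / "grh_calls.tsv")

    # ---- clustering + proximity ------------------------------------------
    clusters = []
    if grts_calls:
        cres = _clusters.cluster_calls(
            grts_calls, max_gap=config.cluster_gap,
            large_threshold_bp=config.large_cluster_bp,
        )
        clusters = cres.clusters
        report["grts_clusters"] = {
            "n_clusters": cres.n_clusters,
            "clustered_fraction": cres.clustered_fraction,
            "n_large": cres.n_large,
        }
        if config.features_bed:
            feats = _load_features(config.features_bed)
            clusters = _clusters.annotate_clusters(clusters, feats)
            top = clusters[: config.top_clusters]
            report["cluster_annotation"] = {
                "n_top": len(top),
                "ltr_bearing": sum(
                    1 for c in top if c.has_class("LTR_retrotransposon")
                ),
                "dna_transposon_bearing": sum(
                    1 for c in top if c.has_class("DNA_transposon")
                ),
            }
            ltr = [iv for iv, fc_, _ in feats if fc_ == "LTR_retrotransposon"]
            if ltr and top:
                enr = _enrichment.mc_cluster_annotation_enrichment(
                    top, ltr, genome, n_iter=config.mc_iterations, seed=config.seed
                )
                report["ltr_enrichment"] = {
                    "observed": enr.observed,
                    "p_value": enr.p_value,
                    "n_iter": enr.n_iter,
                    "seed": enr.seed,
                }
        _write_tsv(
            [
                {
                    "chrom": c.interval.chrom,
                    "start": c.interval.start,
                    "end": c.interval.end,
                    "length_kb": c.length_kb,
                    "n_members": c.n_members,
                    "annotations": ";".join(
                        f"{a.feature_class}|{a.name}|{a.overlap_bp}"
                        for a in c.annotations
                    ),
                }
                for c in clusters
            ],
            out / "grts_clusters.tsv",
        )
    if grts_calls and grh_calls:
        curve = _clusters.proximity_curve(
            grh_regions,
            grts_regions,
            genome,
            cutoffs=list(range(0, config.proximity_max + 1, config.proximity_step)),
            alpha=config.alpha,
        )
        report["proximity"] = {
            "cutoffs": curve.cutoffs.tolist(),
            "observed_fraction": np.round(curve.observed_fraction, 4).tolist(),
            "null_threshold_fraction": np.round(
                curve.null_threshold_fraction, 4
            ).tolist(),
            "alpha": curve.alpha,
            "fraction_within_10kb": float(
                _clusters.proximity_fraction(grh_regions, grts_regions, 10000)
            ),
        }

    # ---- pre-mRNA fraction statistics -------------------------------------
    if (
        grts_calls
        and ("pre_mRNA", "mutant") in tracks
        and ("pre_mRNA", "wildtype") in tracks
    ):
        mut = tracks[("pre_mRNA", "mutant")]
        wt = tracks[("pre_mRNA", "wildtype")]
        eps = config.epsilon or _calls.default_epsilon(mut, wt)
        pre_fc = _calls.fold_change(mut, wt, eps)
        idx = [c.bin.index for c in grts_calls]
        results = _enrichment.mc_fraction_significance(
            idx,
            pre_fc,
            thresholds=config.fraction_thresholds,
            n_iter=config.mc_iterations,
            seed=config.seed,
        )
        report["premrna_fractions"] = [
            {
                "threshold": t,
                "fraction": r.observed,
                "p_value": r.p_value,
                "seed": r.seed,
            }
            for t, r in zip(config.fraction_thresholds, results)
        ]

    # ---- RNA metrics ------------------------------------------------------
    if config.genes_gff and ("mRNA", "wildtype") in tables:
        models = _rna.transcripts_from_gff(config.genes_gff)
        rna_report = {}
        for (a, g), table in sorted(tables.items()):
            if a not in ("pre_mRNA", "mRNA"):
                continue
            s = _rna.classify_reads(table, models, library_id=f"{a}_{g}")
            rna_report[f"{a}_{g}"] = {
                "pct_exonic": round(s.pct_exonic, 3),
                "pct_intronic": round(s.pct_intronic, 3),
                "intron_exon_ratio": round(s.intron_exon_ratio, 5),
            }
        for g in ("wildtype", "mutant"):
            if f"pre_mRNA_{g}" in rna_report and f"mRNA_{g}" in rna_report:
                rna_report[f"enrichment_factor_{g}"] = round(
                    rna_report[f"pre_mRNA_{g}"]["intron_exon_ratio"]
                    / rna_report[f"mRNA_{g}"]["intron_exon_ratio"],
                    3,
                )
        report["rna_metrics"] = rna_report

    # ---- small RNA --------------------------------------------------------
    if ("smallRNA", "wildtype") in tables:
        target_regions = grts_regions + grh_regions
        if target_regions:
            sig = _smallrna.signature(
                tables[("smallRNA", "wildtype")], target_regions, region_label="targets"
            )
            report["smallrna_signature"] = {
                "modal_length": sig.modal_length,
                "modal_base": sig.modal_base,
                "g_fraction": round(sig.base_fraction("G"), 4),
                "total_weight": round(sig.total_weight, 3),
            }
            sig.to_tsv(out / "smallrna_signature.tsv")
            if ("smallRNA", "mutant") in tracks:
                cmp = _smallrna.region_abundance_compare(
                    tracks[("smallRNA", "wildtype")],
                    tracks[("smallRNA", "mutant")],
                    target_regions,
                    reduced_cutoff=config.reduced_sirna_cutoff,
                )
                report["smallrna_compare"] = {
                    "fraction_reduced": cmp.fraction_reduced,
                    "median_fc": float(np.median(cmp.fold_change)),
                }

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    _write_markdown(report, out / "report.md")
    return report


def _write_tsv(rows: list[dict[str, Any]], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_markdown(report: dict[str, Any], path: Path) -> None:
    lines = ["# Germline nuclear RNAi target-calling report", ""]
    lines.append(f"Generated: {time.strftime('%Y-%m-%d %H:%M:%S')}")
    lines.append("")
    for section, payload in sorted(report.items()):
        lines.append(f"## {section}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(payload, indent=1, sort_keys=True, default=str))
        lines.append("```")
        lines.append("")
    Path(path).write_text("\n".join(lines))
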