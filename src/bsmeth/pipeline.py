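"""Pipeline orchestration: simulate -> call -> profile -> integrate.

Each stage reads and writes plain-text files (FASTA/FASTQ/BED/TSV/JSON) so
runs are fully reproducible from the configuration echoed into the run
report. The CLI in ``bsmeth.cli`` is a thin wrapper over these functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, reference
from .calling import call_methylation, estimate_error_rate
from .config import SimConfig
from .integrate import (
    classify_deg_table,
    cross_tabulate,
    filter_marker_genes,
    gene_methylation_direction,
    hypomethylated_markers,
    incidence_summary,
)
from .profiles import (
    bimodal_fractions,
    density_methylation_heatmap,
    global_levels,
    metagene_profile,
)
from .qc import build_pileup, filter_reads, remove_duplicates
from .simulate import (
    plant_gene_body_deltas,
    simulate_bisulfite_reads,
    simulate_deg_table,
    simulate_genome,
    simulate_methylome,
)

logger = logging.getLogger(__name__)

#: tumor-library methylation shift planted on the CG-down marker genes
PLANTED_MARKER_DELTA = -0.3


@dataclass
class PipelineConfig:
    """All stage parameters plus paths; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "bsmeth_out"
    simulate: SimConfig = field(default_factory=SimConfig)
    paired_libraries: bool = True
    embed_marker_genes: bool = True
    # call stage
    adaptor: str = ""
    min_base_quality: int = 20
    q_threshold: float = 0.01
    min_level_depth: int = 4
    # profile stage
    min_per_strand_depth: int = 10
    window: int = 200
    n_level_bins: int = 20
    flank: int = 2000
    # integrate stage
    min_abs_delta: float = 0.1
    deg_preset: str = "figure"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "simulate" in d:
            d["simulate"] = SimConfig.from_dict(d["simulate"])
        cfg = cls(**d)
        cfg.simulate.seed = cfg.seed if "simulate" not in (d or {}) else cfg.simulate.seed
        cfg.simulate.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def echo(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        mix = d["simulate"].pop("cg_mixture")
        d["simulate"]["cg_mixture"] = {k: list(v) if isinstance(v, tuple) else v for k, v in mix.items()}
        return d


def run_simulate(config: PipelineConfig) -> dict[str, str]:
    """Write the synthetic study fixture directory; returns the manifest."""
    out = Path(config.out_dir) / "sim"
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    genome, genes, repeats = simulate_genome(sim)

    marker_tab = reference.marker_table()
    if config.embed_marker_genes and len(genes) >= len(marker_tab):
        # name the first genes after the candidate markers so the simulated
        # DEG table and methylome tell one coherent story
        for gene, symbol in zip(genes, marker_tab["symbol"]):
            gene.gene_id = symbol

    methylome = simulate_methylome(genome, genes, sim)
    reads, truth = simulate_bisulfite_reads(genome, methylome, sim)

    io.write_fasta(genome, out / "genome.fa")
    io.write_genes_bed(genes, out / "genes.bed")
    io.write_exons_bed(genes, out / "exons.bed")
    io.write_repeats_bed(repeats, out / "repeats.bed")
    io.write_gene_table(genes, out / "genes.tsv")
    io.write_fastq(reads, out / "reads.fastq")
    io.write_tsv(truth, out / "truth.tsv")
    io.write_tsv(methylome.to_frame(), out / "methylome.tsv")

    gene_ids = {g.gene_id for g in genes}
    markers = [
        {"gene_id": s, "log2fc": f, "pvalue": p, "fdr": p}
        for s, f, p in zip(marker_tab["symbol"], marker_tab["log2fc"], marker_tab["pvalue"])
        if s in gene_ids
    ]
    n_deg = max(len(genes), len(markers))
    deg = simulate_deg_table(n_deg, embedded_markers=markers or None, seed=sim.seed)
    # make the non-marker simulated genes addressable in the DEG table
    other = sorted(gene_ids - {m["gene_id"] for m in markers})
    bg_rows = deg.index[~deg["gene_id"].isin({m["gene_id"] for m in markers})]
    for idx, gid in zip(bg_rows, other):
        deg.loc[idx, "gene_id"] = gid
    io.write_tsv(deg, out / "deg.tsv")
    io.write_tsv(reference.marker_reference(), out / "markers.tsv")
    io.write_tsv(reference.tumor_incidence(), out / "cohorts.tsv")

    manifest = {
        p.name: str(p)
        for p in sorted(out.iterdir())
    }
    if config.paired_libraries:
        down_ids = set(marker_tab.loc[marker_tab["cg_down"], "symbol"]) & gene_ids
        tumor_meth = plant_gene_body_deltas(methylome, genes, down_ids, PLANTED_MARKER_DELTA)
        tumor_sim = SimConfig(**{**{f.name: getattr(sim, f.name) for f in fields(SimConfig)},
                                 "seed": sim.seed + 1})
        t_reads, t_truth = simulate_bisulfite_reads(genome, tumor_meth, tumor_sim)
        io.write_fastq(t_reads, out / "reads_tumor.fastq")
        io.write_tsv(t_truth, out / "truth_tumor.tsv")
        io.write_tsv(tumor_meth.to_frame(), out / "methylome_tumor.tsv")
        manifest = {p.name: str(p) for p in sorted(out.iterdir())}
    return manifest


def call_library(
    reads, genome, config: PipelineConfig, library_id: str
) -> tuple[pd.DataFrame, object, dict]:
    """QC chain -> pileup -> error estimate -> methylation calls."""
    kept, filter_counts = filter_reads(reads, adaptor=config.adaptor)
    deduped = remove_duplicates(kept)
    pileup = build_pileup(deduped, genome, min_base_quality=config.min_base_quality)
    control = estimate_error_rate(pileup, genome.control_contig, library_id=library_id)
    calls = call_methylation(
        pileup,
        control,
        q_threshold=config.q_threshold,
        min_level_depth=config.min_level_depth,
        control_contig=genome.control_contig,
    )
    stage_counts = {
        "reads_in": len(reads),
        "reads_after_filter": len(kept),
        "filter_removed": {k: v for k, v in filter_counts.items() if k != "kept"},
        "reads_after_dedup": len(deduped),
        "duplicates_removed": len(kept) - len(deduped),
        "sites_tested": int((calls["depth"] >= 1).sum()),
        "sites_called_methylated": int(calls["is_methylated"].sum()),
    }
    return calls, control, stage_counts


def run_call(config: PipelineConfig, library: str = "wt") -> dict:
    """Run QC + calling for one simulated library; writes TSV/JSON outputs."""
    out = Path(config.out_dir)
    sim_dir = out / "sim"
    suffix = "" if library == "wt" else f"_{library}"
    genome = io.read_fasta(sim_dir / "genome.fa")
    reads = io.read_fastq_with_truth(
        sim_dir / f"reads{suffix}.fastq", sim_dir / f"truth{suffix}.tsv"
    )
    if not reads:
        logger.error("no reads in library %s", library)
    calls, control, counts = call_library(reads, genome, config, library)
    call_dir = out / "call"
    call_dir.mkdir(parents=True, exist_ok=True)
    io.write_calls_tsv(calls, call_dir / f"calls_{library}.tsv")
    io.write_json(
        {
            "library_id": control.library_id,
            "error_rate": control.error_rate,
            "total_c_observed": control.total_c_observed,
            "total_depth": control.total_depth,
        },
        call_dir / f"control_{library}.json",
    )
    return {"library": library, "error_rate": control.error_rate, "counts": counts}


def run_profile(config: PipelineConfig, library: str = "wt") -> dict:
    """Global levels, bimodal summary, per-feature heatmaps, metagene profile."""
    out = Path(config.out_dir)
    calls = io.read_calls_tsv(out / "call" / f"calls_{library}.tsv")
    genome = io.read_fasta(out / "sim" / "genome.fa")
    genes = io.read_gene_table(out / "sim" / "genes.tsv")
    repeats = io.read_bed(out / "sim" / "repeats.bed")

    feature_sets: dict[str, list[tuple[str, int, int]]] = {
        "whole_genome": [
            (name, 0, len(seq)) for name, seq in genome.main_contigs().items()
        ],
        "exons": [(g.contig, s, e) for g in genes for s, e in g.exons],
        "genes": [(g.contig, g.tx_start, g.tx_end) for g in genes],
        "repeats": [
            (r.contig, int(r.start), int(r.end)) for r in repeats.itertuples()
        ],
    }
    heatmaps = {}
    for label, feats in feature_sets.items():
        if not feats:
            continue
        hm = density_methylation_heatmap(
            calls,
            genome,
            feats,
            feature_label=label,
            min_per_strand_depth=config.min_per_strand_depth,
            window=config.window,
            n_level_bins=config.n_level_bins,
        )
        heatmaps[label] = hm.to_dict()

    bim = bimodal_fractions(calls)
    meta = metagene_profile(calls, genes, flank=config.flank)
    report = {
        "library": library,
        "global_levels_site_mean": global_levels(calls, "site_mean"),
        "global_levels_pooled": global_levels(calls, "pooled"),
        "bimodal": {
            "context": bim.context,
            "frac_hypo": bim.frac_hypo,
            "frac_mid": bim.frac_mid,
            "frac_hyper": bim.frac_hyper,
            "n_sites": bim.n_sites,
        },
        "metagene": meta.to_dict(orient="records"),
        "heatmaps": heatmaps,
    }
    prof_dir = out / "profile"
    prof_dir.mkdir(parents=True, exist_ok=True)
    io.write_json(report, prof_dir / f"profiles_{library}.json")
    return report


def run_integrate(config: PipelineConfig) -> dict:
    """Methylome-transcriptome integration on the two called libraries."""
    out = Path(config.out_dir)
    calls_wt = io.read_calls_tsv(out / "call" / "calls_wt.tsv")
    calls_tumor = io.read_calls_tsv(out / "call" / "calls_tumor.tsv")
    genes = io.read_gene_table(out / "sim" / "genes.tsv")
    deg = io.read_tsv(out / "sim" / "deg.tsv")
    marker_ref = io.read_tsv(out / "sim" / "markers.tsv")
    cohorts = io.read_tsv(out / "sim" / "cohorts.tsv")

    regions = pd.DataFrame(
        [(g.gene_id, g.contig, g.tx_start, g.tx_end) for g in genes],
        columns=["gene_id", "contig", "start", "end"],
    )
    deltas, n_excluded = gene_methylation_direction(
        calls_wt, calls_tumor, regions, min_abs_delta=config.min_abs_delta
    )
    deg = classify_deg_table(deg, preset=config.deg_preset)
    xtab = cross_tabulate(deltas, deg)
    markers = filter_marker_genes(deg, marker_ref)
    hypo = hypomethylated_markers(markers, deltas)
    incidence = incidence_summary(cohorts)

    report = {
        "deltas_defined": len(deltas),
        "deltas_excluded_undefined": n_excluded,
        "integration_table": xtab.to_dict(),
        "marker_genes": markers["gene_id"].tolist(),
        "marker_count": len(markers),
        "hypomethylated_markers": hypo["gene_id"].tolist(),
        "hypomethylated_count": len(hypo),
        "incidence": incidence.drop(columns=["percentage"])
        .assign(percentage=incidence["percentage"])
        .to_dict(orient="records"),
    }
    int_dir = out / "integrate"
    int_dir.mkdir(parents=True, exist_ok=True)
    io.write_json(report, int_dir / "integration.json")
    io.write_tsv(deltas, int_dir / "deltas.tsv")
    return report


def run_all(config: PipelineConfig) -> dict:
    """Full pipeline; returns (and writes) the run report."""
    manifest = run_simulate(config)
    call_wt = run_call(config, "wt")
    report = {
        "version": __version__,
        "config": config.echo(),
        "sim_manifest": sorted(manifest),
        "call_wt": call_wt,
    }
    if config.paired_libraries:
        report["call_tumor"] = run_call(config, "tumor")
    report["profile_wt"] = {
        k: v
        for k, v in run_profile(config, "wt").items()
        if k in ("global_levels_site_mean", "global_levels_pooled", "bimodal")
    }
    if config.paired_libraries:
        report["integration"] = run_integrate(config)
    io.write_json(report, Path(config.out_dir) / "report.json")
    return report
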