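"""Parameter-recovery experiments on synthetic data.

Each function runs one self-contained study at its documented problem
size, using the package's own generator and analysis chain, and returns
the measured quantities together with the configured truth. They back
both the validation test suite and ``scripts/acceptance.py``; problem
sizes are chosen so every study completes in minutes on one core while
keeping Monte-Carlo error well inside the documented tolerances.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import ConversionControl, call_methylation, estimate_error_rate
from .config import BetaMixture, SimConfig
from .integrate import cross_tabulate, gene_methylation_direction
from .pipeline import PipelineConfig, call_library, run_all
from .profiles import bimodal_fractions, global_levels
from .simulate import (
    plant_gene_body_deltas,
    simulate_bisulfite_reads,
    simulate_deg_table,
    simulate_genome,
    simulate_methylome,
    simulate_site_counts,
)


def _expected_error_rate(cfg: SimConfig) -> float:
    """P(C observation) at a truly unmethylated cytosine under the generator."""
    cf, e = cfg.conversion_failure_rate, cfg.sequencing_error_rate
    return cf * (1 - e) + (1 - cf) * e


def error_rate_recovery(seed: int = 0) -> dict:
    """Full-chain spike-in error estimation on a lambda-rich library.

    ~30 kb main contig plus a 30 kb control contig at 35% of reads gives
    well over 150,000 post-deduplication base observations on control
    cytosines.
    """
    cfg = SimConfig(
        seed=seed,
        genome_length=30_000,
        n_genes=10,
        n_repeats=5,
        target_depth=30,
        lambda_length=30_000,
        lambda_fraction=0.35,
    )
    genome, genes, _ = simulate_genome(cfg)
    methylome = simulate_methylome(genome, genes, cfg)
    reads, _ = simulate_bisulfite_reads(genome, methylome, cfg)
    _, control, _ = call_library(reads, genome, PipelineConfig(simulate=cfg), "err")
    return {
        "error_rate": control.error_rate,
        "expected_error_rate": _expected_error_rate(cfg),
        "lambda_observations": control.total_depth,
    }


def global_level_recovery(seed: int = 0) -> dict:
    """Full-chain recovery of the configured global CG mean at 30x depth.

    A 150 kb genome yields >10,000 CG strand-sites; the recovered
    site-mean CG level is compared with the analytic mixture mean, and the
    non-CG levels with the true non-CG mean plus the error floor.
    """
    cfg = SimConfig(seed=seed, genome_length=150_000, n_genes=50, target_depth=30,
                    lambda_length=10_000, lambda_fraction=0.05)
    genome, genes, _ = simulate_genome(cfg)
    methylome = simulate_methylome(genome, genes, cfg)
    reads, _ = simulate_bisulfite_reads(genome, methylome, cfg)
    calls, control, _ = call_library(reads, genome, PipelineConfig(simulate=cfg), "glob")
    lv = global_levels(calls, "site_mean")
    n_cg = int(((calls["context"] == "CG") & calls["level"].notna()).sum())
    return {
        "cg_level": lv["CG"],
        "chg_level": lv.get("CHG", float("nan")),
        "chh_level": lv.get("CHH", float("nan")),
        "configured_cg_mean": cfg.cg_mixture.mean,
        "error_rate": control.error_rate,
        "n_cg_sites": n_cg,
    }


def bimodal_recovery(seed: int = 0) -> dict:
    """Recovery of the hypo/hyper mixture weights from observed levels.

    Uses the per-cytosine count-report path at an exact mean depth of 50
    over a 120 kb genome (~10,000 CG strand-sites), where binomial
    sampling noise around the 0.2/0.8 boundaries is small.
    """
    cfg = SimConfig(seed=seed, genome_length=120_000, n_genes=40, lambda_length=5_000)
    genome, genes, _ = simulate_genome(cfg)
    methylome = simulate_methylome(genome, genes, cfg)
    pileup = simulate_site_counts(
        methylome, genome, mean_depth=50,
        conversion_failure_rate=cfg.conversion_failure_rate,
        sequencing_error_rate=cfg.sequencing_error_rate,
        seed=seed,
    )
    control = estimate_error_rate(pileup, genome.control_contig)
    calls = call_methylation(pileup, control, control_contig=genome.control_contig)
    bim = bimodal_fractions(calls)
    return {
        "frac_hypo": bim.frac_hypo,
        "frac_hyper": bim.frac_hyper,
        "weight_hypo": cfg.cg_mixture.weight_hypo,
        "weight_hyper": cfg.cg_mixture.weight_hyper,
        "n_sites": bim.n_sites,
    }


def fdr_null_calibration(seed: int = 0, n_seeds: int = 10) -> dict:
    """Fraction of truly unmethylated sites called methylated.

    Each replicate draws ~20,000 all-null sites (true level 0, known
    error rate 0.005, depth 20) and runs the binomial caller with BH
    control at q < 0.01; the mean called fraction over replicates
    measures false-positive control under the null.
    """
    cfg = SimConfig(
        seed=seed,
        genome_length=40_000,
        n_genes=0,
        n_repeats=0,
        cg_mixture=BetaMixture(point_mass=0.0),
        non_cg_mean=0.0,
        conversion_failure_rate=0.005,
        sequencing_error_rate=0.0,
        lambda_length=5_000,
    )
    genome, genes, _ = simulate_genome(cfg)
    methylome = simulate_methylome(genome, genes, cfg)
    fractions = []
    n_total = 0
    for k in range(n_seeds):
        pileup = simulate_site_counts(
            methylome, genome, mean_depth=20,
            conversion_failure_rate=0.005, sequencing_error_rate=0.0,
            seed=seed * n_seeds + k + 1,
        )
        pileup = pileup[pileup["contig"] != genome.control_contig]
        ctrl = ConversionControl("null", 0.005, 0, 1)
        calls = call_methylation(pileup, ctrl)
        tested = calls["depth"] >= 1
        n_total += int(tested.sum())
        fractions.append(calls.loc[tested, "is_methylated"].mean())
    return {"mean_called_fraction": float(np.mean(fractions)), "n_sites_total": n_total}


def planted_delta_recovery(seed: int = 0) -> dict:
    """Detection of engineered gene-body hypomethylation.

    220 genes on a 132 kb genome; 20 genes receive a -0.3 gene-body CG
    shift in the tumor methylome. Both libraries are sampled at 30x via
    the count-report path, called, and per-gene directions derived with
    the default |delta| >= 0.1 rule. Reports the planted-gene recall, the
    false-down rate among null genes, and the inputs for cross-tabulation
    checks.
    """
    cfg = SimConfig(seed=seed, genome_length=132_000, n_genes=220, n_repeats=0,
                    lambda_length=5_000)
    genome, genes, _ = simulate_genome(cfg)
    meth_wt = simulate_methylome(genome, genes, cfg)
    rng = np.random.default_rng([seed, 7])
    planted = sorted(rng.choice([g.gene_id for g in genes], size=20, replace=False))
    meth_tumor = plant_gene_body_deltas(meth_wt, genes, planted, -0.3)

    kwargs = dict(
        mean_depth=30,
        conversion_failure_rate=cfg.conversion_failure_rate,
        sequencing_error_rate=cfg.sequencing_error_rate,
    )
    pile_wt = simulate_site_counts(meth_wt, genome, seed=seed * 2 + 100, **kwargs)
    pile_tu = simulate_site_counts(meth_tumor, genome, seed=seed * 2 + 101, **kwargs)
    ctrl_wt = estimate_error_rate(pile_wt, genome.control_contig)
    ctrl_tu = estimate_error_rate(pile_tu, genome.control_contig)
    calls_wt = call_methylation(pile_wt, ctrl_wt, control_contig=genome.control_contig)
    calls_tu = call_methylation(pile_tu, ctrl_tu, control_contig=genome.control_contig)

    regions = pd.DataFrame(
        [(g.gene_id, g.contig, g.tx_start, g.tx_end) for g in genes],
        columns=["gene_id", "contig", "start", "end"],
    )
    deltas, n_excluded = gene_methylation_direction(calls_wt, calls_tu, regions)
    down = set(deltas.loc[deltas["direction"] == "down", "gene_id"])
    planted_set = set(planted)
    nulls = set(deltas["gene_id"]) - planted_set
    recall = len(down & planted_set) / len(planted_set)
    false_down = len(down & nulls) / len(nulls) if nulls else 0.0

    deg = simulate_deg_table(
        len(genes),
        embedded_markers=[
            {"gene_id": g, "log2fc": 2.0 if i % 2 == 0 else -2.0, "pvalue": 1e-6, "fdr": 1e-5}
            for i, g in enumerate(planted)
        ],
        seed=seed,
    )
    # rename background rows onto the remaining simulated genes
    others = sorted({g.gene_id for g in genes} - planted_set)
    bg_rows = deg.index[~deg["gene_id"].isin(planted_set)]
    for idx, gid in zip(bg_rows, others):
        deg.loc[idx, "gene_id"] = gid
    xtab = cross_tabulate(deltas, deg)
    return {
        "recall": recall,
        "false_down_rate": false_down,
        "n_planted": len(planted_set),
        "n_null_genes": len(nulls),
        "n_excluded": n_excluded,
        "deltas": deltas,
        "deg": deg,
        "integration_table": xtab,
    }


def determinism_check(seed: int, workdir) -> dict:
    """Two full pipeline runs with one seed must be byte-identical."""
    workdir = Path(workdir)
    outputs = []
    for name in ("run_a", "run_b"):
        cfg = PipelineConfig.from_dict(
            {
                "seed": seed,
                "out_dir": str(workdir / name),
                "simulate": {
                    "seed": seed,
                    "genome_length": 30_000,
                    "n_genes": 12,
                    "n_repeats": 6,
                    "target_depth": 10,
                    "lambda_length": 5_000,
                },
            }
        )
        run_all(cfg)
        outputs.append(Path(cfg.out_dir))
    compared = [
        "call/calls_wt.tsv",
        "call/calls_tumor.tsv",
        "call/control_wt.json",
        "sim/reads.fastq",
        "sim/truth.tsv",
        "sim/deg.tsv",
    ]
    identical = all(
        filecmp.cmp(outputs[0] / rel, outputs[1] / rel, shallow=False) for rel in compared
    )
    # the run report embeds the (necessarily different) output paths in its
    # config echo; normalise them before comparing the rest byte-for-byte
    import json

    reports = []
    for out in outputs:
        rep = json.loads((out / "report.json").read_text())
        rep["config"]["out_dir"] = "<out>"
        reports.append(json.dumps(rep, sort_keys=True))
    identical = identical and reports[0] == reports[1]
    n_bytes = sum((outputs[0] / rel).stat().st_size for rel in compared) + len(reports[0])
    return {"identical": identical, "n_bytes_compared": n_bytes}
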