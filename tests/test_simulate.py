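"""Generator correctness: determinism, invariants, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from bsmeth.config import BetaMixture, SimConfig
from bsmeth.qc import build_pileup, remove_duplicates
from bsmeth.simulate import (
    LAMBDA_CONTIG,
    Genome,
    plant_gene_body_deltas,
    simulate_bisulfite_reads,
    simulate_deg_table,
    simulate_genome,
    simulate_methylome,
    simulate_site_counts,
)


def test_genome_deterministic_under_fixed_seed(small_config):
    g1, genes1, reps1 = simulate_genome(small_config)
    g2, genes2, reps2 = simulate_genome(small_config)
    assert g1.contigs == g2.contigs
    assert genes1 == genes2 and reps1 == reps2


def test_genome_changes_with_seed(small_config):
    cfg2 = SimConfig(**{**small_config.__dict__, "seed": small_config.seed + 1})
    g1, _, _ = simulate_genome(small_config)
    g2, _, _ = simulate_genome(cfg2)
    assert g1.contigs["chr1"] != g2.contigs["chr1"]


def test_zero_genes_is_degenerate_but_valid():
    cfg = SimConfig(seed=3, genome_length=5_000, n_genes=0, n_repeats=0, lambda_length=2_000)
    genome, genes, repeats = simulate_genome(cfg)
    assert genes == [] and repeats == []
    assert len(genome.contigs["chr1"]) == 5_000


def test_exons_contained_in_gene_span_by_enumeration():
    cfg = SimConfig(seed=11, genome_length=50_000, n_genes=20, lambda_length=2_000)
    _, genes, _ = simulate_genome(cfg)
    assert len(genes) == 20
    for gene in genes:
        assert len(gene.exons) >= 2
        prev_end = gene.tx_start
        for s, e in gene.exons:
            assert gene.tx_start <= s < e <= gene.tx_end
            assert s >= prev_end  # sorted, non-overlapping
            prev_end = e


def test_invalid_config_rejected_with_field_name():
    with pytest.raises(ValueError, match="target_depth"):
        SimConfig(target_depth=-1).validate()
    with pytest.raises(ValueError, match="lambda_fraction"):
        SimConfig(lambda_fraction=1.0).validate()
    with pytest.raises(ValueError, match="weight_hypo"):
        BetaMixture(weight_hypo=1.5).validate()


def test_genome_alphabet_and_control_invariants():
    with pytest.raises(ValueError, match="empty"):
        Genome({"chr1": ""})
    with pytest.raises(ValueError, match="ACGTN"):
        Genome({"chr1": "ACGU"})
    with pytest.raises(ValueError, match="control_contig"):
        Genome({"chr1": "ACGT"}, control_contig="missing")


class TestMethylome:
    def test_point_mass_mixture_sets_every_cg_site(self, small_config):
        cfg = SimConfig(**{**small_config.__dict__, "cg_mixture": BetaMixture(point_mass=1.0)})
        genome, genes, _ = simulate_genome(cfg)
        meth = simulate_methylome(genome, genes, cfg)
        for strand in "+-":
            key = ("chr1", strand)
            cg = meth.contexts[key] == 1
            assert np.all(meth.levels[key][cg] == 1.0)

    def test_lambda_spikein_is_fully_unmethylated(self, small_study):
        meth = small_study["methylome"]
        for strand in "+-":
            lv = meth.levels[(LAMBDA_CONTIG, strand)]
            assert np.all(lv[~np.isnan(lv)] == 0.0)

    def test_every_cytosine_has_exactly_one_entry(self, small_study):
        genome, meth = small_study["genome"], small_study["methylome"]
        for contig, seq in genome.contigs.items():
            n_c = seq.count("C")
            n_g = seq.count("G")
            plus = meth.levels[(contig, "+")]
            minus = meth.levels[(contig, "-")]
            assert int(np.sum(~np.isnan(plus))) == n_c
            assert int(np.sum(~np.isnan(minus))) == n_g

    def test_cg_mixture_fractions_within_3_se_of_weights(self):
        cfg = SimConfig(seed=5, genome_length=120_000, n_genes=40, lambda_length=2_000)
        genome, genes, _ = simulate_genome(cfg)
        meth = simulate_methylome(genome, genes, cfg)
        lv = np.concatenate(
            [
                meth.levels[("chr1", s)][meth.contexts[("chr1", s)] == 1]
                for s in "+-"
            ]
        )
        lv = lv[~np.isnan(lv)]
        assert lv.size >= 10_000
        for frac, weight in (
            ((lv < 0.2).mean(), cfg.cg_mixture.weight_hypo),
            ((lv > 0.8).mean(), cfg.cg_mixture.weight_hyper),
        ):
            se = np.sqrt(weight * (1 - weight) / lv.size)
            # beta tails leak slightly past the thresholds, so allow the
            # analytic tail mass as well as 3 sampling standard errors
            assert abs(frac - weight) <= 3 * se + 0.01

    def test_symmetric_cpg_pairs_identical_by_default(self, small_study):
        meth = small_study["methylome"]
        plus = meth.levels[("chr1", "+")]
        minus = meth.levels[("chr1", "-")]
        dyads = np.nonzero(meth.contexts[("chr1", "+")] == 1)[0]
        assert np.allclose(plus[dyads], minus[dyads + 1])


class TestReads:
    def _flat_methylome(self, genome, genes, cfg, level):
        cfg = SimConfig(**{**cfg.__dict__, "cg_mixture": BetaMixture(point_mass=level),
                           "non_cg_mean": 0.0})
        meth = simulate_methylome(genome, genes, cfg)
        if level > 0:
            for key, lv in meth.levels.items():
                if key[0] != LAMBDA_CONTIG:
                    lv[~np.isnan(lv)] = level
        return cfg, meth

    def test_complete_conversion_leaves_no_c_at_cytosines(self, small_config):
        genome, genes, _ = simulate_genome(small_config)
        cfg, meth = self._flat_methylome(genome, genes, small_config, 0.0)
        cfg = SimConfig(**{**cfg.__dict__, "conversion_failure_rate": 0.0,
                           "sequencing_error_rate": 0.0})
        reads, _ = simulate_bisulfite_reads(genome, meth, cfg)
        pileup = build_pileup(reads, genome)
        assert int(pileup["meth_count"].sum()) == 0
        assert int(pileup["unmeth_count"].sum()) > 0

    def test_full_methylation_leaves_no_t_at_cytosines(self, small_config):
        genome, genes, _ = simulate_genome(small_config)
        cfg, meth = self._flat_methylome(genome, genes, small_config, 1.0)
        cfg = SimConfig(**{**cfg.__dict__, "conversion_failure_rate": 0.0,
                           "sequencing_error_rate": 0.0, "lambda_fraction": 0.0})
        reads, _ = simulate_bisulfite_reads(genome, meth, cfg)
        pileup = build_pileup(reads, genome)
        main = pileup[pileup["contig"] == "chr1"]
        assert int(main["unmeth_count"].sum()) == 0
        assert int(main["meth_count"].sum()) > 0

    def test_read_count_matches_truth_table(self, small_study):
        reads, truth = small_study["reads"], small_study["truth"]
        assert len(reads) == len(truth)
        assert sorted(r.read_id for r in reads) == sorted(truth["read_id"])

    def test_lambda_read_fraction_matches_configuration(self, small_study):
        truth, cfg = small_study["truth"], small_study["config"]
        frac = (truth["contig"] == LAMBDA_CONTIG).mean()
        assert frac == pytest.approx(cfg.lambda_fraction, abs=0.01)

    def test_reads_are_position_sorted_and_deterministic(self, small_study):
        reads, cfg = small_study["reads"], small_study["config"]
        keys = [(r.contig, r.start) for r in reads]
        assert keys == sorted(keys)
        again, _ = simulate_bisulfite_reads(
            small_study["genome"], small_study["methylome"], cfg
        )
        assert [r.sequence for r in again] == [r.sequence for r in reads]

    def test_paired_end_changes_only_fragment_sampling(self, small_config):
        cfg = SimConfig(**{**small_config.__dict__, "paired_end": True,
                           "fragment_length": 200})
        genome, genes, _ = simulate_genome(cfg)
        meth = simulate_methylome(genome, genes, cfg)
        reads, truth = simulate_bisulfite_reads(genome, meth, cfg)
        # mates sit at both ends of a fragment_length insert on one strand
        offset = cfg.fragment_length - cfg.read_length
        for (_, _), grp in truth.groupby(["contig", "strand"]):
            starts = grp["start"].tolist()
            mates = {s + offset for s in starts}
            assert sum(s in mates for s in starts) >= len(starts) * 0.5
        # mean per-strand depth on the main contig stays on the configured scale
        main = truth[truth["contig"] == "chr1"]
        depth = len(main) * cfg.read_length / (2 * cfg.genome_length)
        assert depth == pytest.approx(cfg.target_depth, rel=0.15)
        assert len(reads) == len(truth)

    def test_noise_free_pileup_recovers_truth_against_coverage_oracle(self):
        cfg = SimConfig(seed=9, genome_length=4_000, n_genes=2, n_repeats=0,
                        target_depth=20, lambda_fraction=0.0, lambda_length=500,
                        cg_mixture=BetaMixture(point_mass=1.0), non_cg_mean=0.0)
        genome, genes, _ = simulate_genome(cfg)
        meth = simulate_methylome(genome, genes, cfg)
        for key, lv in meth.levels.items():
            if key[0] != LAMBDA_CONTIG:
                lv[~np.isnan(lv)] = 1.0
        cfg = SimConfig(**{**cfg.__dict__, "conversion_failure_rate": 0.0,
                           "sequencing_error_rate": 0.0})
        reads, _ = simulate_bisulfite_reads(genome, meth, cfg)
        deduped = remove_duplicates(reads)
        pileup = build_pileup(deduped, genome)
        main = pileup[pileup["contig"] == "chr1"]
        # brute-force per-read interval coverage oracle
        seq = genome.contigs["chr1"]
        for row in main.sample(n=min(len(main), 120), random_state=0).itertuples():
            cover = sum(
                1
                for r in deduped
                if r.contig == "chr1"
                and r.strand == row.strand
                and r.start <= row.pos < r.start + len(r.sequence)
            )
            assert row.meth_count == cover
            assert row.unmeth_count == 0


class TestDegTable:
    MARKERS = [
        {"gene_id": "agr2", "log2fc": 3.89, "pvalue": 3.28e-20, "fdr": 3.28e-20},
        {"gene_id": "spint2", "log2fc": 1.98, "pvalue": 4.05e-91, "fdr": 4.05e-91},
    ]

    def test_embedded_markers_appear_verbatim(self):
        deg = simulate_deg_table(100, embedded_markers=self.MARKERS, seed=1)
        assert len(deg) == 100
        row = deg.set_index("gene_id").loc["agr2"]
        assert row["log2fc"] == 3.89 and row["pvalue"] == 3.28e-20

    def test_empty_table(self):
        assert simulate_deg_table(0).empty

    def test_duplicate_marker_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            simulate_deg_table(10, embedded_markers=self.MARKERS + self.MARKERS[:1])

    def test_null_false_positive_count_within_3_se(self):
        from scipy.stats import norm

        sd = 0.5
        deg = simulate_deg_table(1_000, seed=2, null_log2fc_sd=sd)
        hits = ((deg["log2fc"] >= 1.0) & (deg["pvalue"] <= 0.05)).sum()
        tail = norm.sf(1.0 / sd) * 0.05  # independent null log2fc and p
        expected = 1_000 * tail
        se = np.sqrt(1_000 * tail * (1 - tail))
        assert abs(hits - expected) <= 3 * se + 1

    def test_deterministic(self):
        a = simulate_deg_table(50, seed=4)
        b = simulate_deg_table(50, seed=4)
        pd.testing.assert_frame_equal(a, b)


def test_site_counts_report_recovers_levels_in_expectation():
    cfg = SimConfig(seed=13, genome_length=30_000, n_genes=10, lambda_length=2_000)
    genome, genes, _ = simulate_genome(cfg)
    meth = simulate_methylome(genome, genes, cfg)
    pileup = simulate_site_counts(meth, genome, mean_depth=30,
                                  conversion_failure_rate=0.0,
                                  sequencing_error_rate=0.0, seed=13)
    main = pileup[(pileup["contig"] == "chr1") & (pileup["context"] == "CG")]
    depth = main["meth_count"] + main["unmeth_count"]
    obs = (main["meth_count"][depth > 0] / depth[depth > 0]).mean()
    truth = np.concatenate(
        [meth.levels[("chr1", s)][meth.contexts[("chr1", s)] == 1] for s in "+-"]
    )
    assert obs == pytest.approx(np.nanmean(truth), abs=0.01)


def test_planted_deltas_shift_only_selected_gene_bodies(small_study):
    genome, genes, meth = small_study["genome"], small_study["genes"], small_study["methylome"]
    target = genes[0]
    shifted = plant_gene_body_deltas(meth, genes, [target.gene_id], -0.3)
    for strand in "+-":
        key = ("chr1", strand)
        inside = np.zeros(len(genome.contigs["chr1"]), dtype=bool)
        inside[target.tx_start : target.tx_end] = True
        cg = (meth.contexts[key] == 1) & ~np.isnan(meth.levels[key])
        changed = meth.levels[key] != shifted.levels[key]
        changed &= cg
        assert not np.any(changed & ~inside)
        body = cg & inside
        expected = np.clip(meth.levels[key][body] - 0.3, 0, 1)
        assert np.allclose(shifted.levels[key][body], expected)
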