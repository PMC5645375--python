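"""Read filtering, deduplication, context classification and pileups."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bsmeth.qc import (
    Read,
    build_pileup,
    classify_context,
    context_arrays,
    filter_reads,
    mask_low_quality,
    remove_duplicates,
    revcomp,
    trinucleotide,
)
from bsmeth.simulate import Genome


def mk_read(seq, quals=None, read_id="r1", contig="chr1", start=0, strand="+"):
    if quals is None:
        quals = np.full(len(seq), 40, dtype=np.int16)
    elif np.isscalar(quals):
        quals = np.full(len(seq), quals, dtype=np.int16)
    else:
        quals = np.asarray(quals, dtype=np.int16)
    return Read(read_id, contig, start, strand, seq, quals)


class TestFilterReads:
    def test_n_fraction_strictly_above_threshold_removed(self):
        # 10 N in 90 bases = 11.1% > 10% -> removed; 9 N = 10% exactly -> kept
        removed = mk_read("N" * 10 + "A" * 80)
        kept = mk_read("N" * 9 + "A" * 81, read_id="r2")
        out, counts = filter_reads([removed, kept])
        assert [r.read_id for r in out] == ["r2"]
        assert counts["n_fraction"] == 1

    def test_clean_high_quality_read_kept(self):
        out, counts = filter_reads([mk_read("ACGT" * 20, quals=40)], adaptor="TTTTTT")
        assert len(out) == 1 and counts["kept"] == 1

    @pytest.mark.parametrize("n_low,expect_kept", [(50, True), (51, False)])
    def test_low_quality_fraction_boundary(self, n_low, expect_kept):
        quals = [5] * n_low + [40] * (100 - n_low)
        out, counts = filter_reads([mk_read("A" * 100, quals=quals)])
        assert bool(out) is expect_kept
        assert counts["low_quality"] == (0 if expect_kept else 1)

    def test_adaptor_exact_substring_removed(self):
        adaptor = "AGATCGGAAGAGC"
        bad = mk_read("C" * 10 + adaptor + "C" * 10)
        good = mk_read("C" * 33, read_id="r2")
        out, counts = filter_reads([bad, good], adaptor=adaptor)
        assert [r.read_id for r in out] == ["r2"]
        assert counts["adaptor"] == 1

    def test_empty_adaptor_disables_rule(self):
        out, counts = filter_reads([mk_read("ACGT" * 10)], adaptor="")
        assert len(out) == 1 and counts["adaptor"] == 0

    def test_removal_counts_account_for_all_drops(self, small_study):
        reads = small_study["reads"]
        out, counts = filter_reads(reads)
        assert len(reads) - len(out) == (
            counts["adaptor"] + counts["n_fraction"] + counts["low_quality"]
        )


class TestRemoveDuplicates:
    def test_one_read_kept_per_position(self):
        reads = [mk_read("ACGT", read_id=f"r{i}", start=100) for i in range(3)]
        out = remove_duplicates(reads)
        assert len(out) == 1

    def test_distinct_positions_untouched(self):
        reads = [mk_read("ACGT", read_id=f"r{i}", start=i * 10) for i in range(5)]
        assert len(remove_duplicates(reads)) == 5

    def test_kept_count_equals_distinct_keys_by_enumeration(self, rng):
        reads = []
        for i in range(10):
            start = int(rng.choice([0, 5, 9, 20]))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(mk_read("ACGTA", read_id=f"r{i}", start=start, strand=strand))
        keys = {(r.contig, r.start, r.strand) for r in reads}
        assert len(remove_duplicates(reads)) == len(keys)

    def test_highest_mean_quality_then_lexicographic_id_wins(self):
        a = mk_read("ACGT", quals=30, read_id="b")
        b = mk_read("ACGT", quals=35, read_id="z")
        c = mk_read("ACGT", quals=35, read_id="a")
        (kept,) = remove_duplicates([a, b, c])
        assert kept.read_id == "a"


class TestMaskLowQuality:
    def test_boundary_is_strict(self):
        read = mk_read("CCC", quals=[19, 20, 21])
        assert mask_low_quality(read).tolist() == [False, True, True]

    def test_all_q0_contributes_nothing(self):
        genome = Genome({"chr1": "CCCC"})
        pileup = build_pileup([mk_read("CCCC", quals=0)], genome)
        assert int((pileup["meth_count"] + pileup["unmeth_count"]).sum()) == 0
        assert int(pileup["other_count"].sum()) > 0


class TestClassifyContext:
    def test_cg_definition(self):
        genome = Genome({"chr1": "ACGT"})
        assert classify_context(genome, "chr1", 1, "+") == "CG"

    def test_chg_definition(self):
        genome = Genome({"chr1": "ACAGT"})
        assert classify_context(genome, "chr1", 1, "+") == "CHG"

    def test_chh_definition(self):
        genome = Genome({"chr1": "ACAAT"})
        assert classify_context(genome, "chr1", 1, "+") == "CHH"

    def test_non_cytosine_raises_with_coordinate(self):
        genome = Genome({"chr1": "ACGT"})
        with pytest.raises(ValueError, match="chr1:0"):
            classify_context(genome, "chr1", 0, "+")

    def test_minus_strand_cg_on_acgt(self):
        # plus-strand G at index 2 is C on the minus strand, followed (on the
        # minus strand) by the complement of index 1's C, i.e. G -> CG
        genome = Genome({"chr1": "ACGT"})
        assert classify_context(genome, "chr1", 2, "-") == "CG"

    def test_minus_strand_by_exhaustive_revcomp_enumeration(self):
        # oracle: classify on the reverse complement with the plus-strand rule
        bases = "ACGT"
        for b1 in bases:
            for b2 in bases:
                for b3 in bases:
                    seq = b1 + b2 + b3 + "G"  # G at index 3 = minus-strand C
                    rc = revcomp(seq)
                    expected = classify_context(Genome({"c": rc}), "c", 0, "+")
                    got = classify_context(Genome({"c": seq}), "c", 3, "-")
                    assert got == expected, seq

    def test_contig_end_uses_n_as_h(self):
        genome = Genome({"chr1": "AAC"})
        assert classify_context(genome, "chr1", 2, "+") == "CHH"
        genome = Genome({"chr1": "AACA"})  # +2 missing G
        assert classify_context(genome, "chr1", 2, "+") == "CHH"

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=40))
    def test_context_arrays_match_scalar_rule(self, seq):
        plus, minus = context_arrays(seq)
        padded = seq + "NN"
        for i, b in enumerate(seq):
            if b == "C":
                if padded[i + 1] == "G":
                    expect = 1
                elif padded[i + 2] == "G":
                    expect = 2
                else:
                    expect = 3
                assert plus[i] == expect
            else:
                assert plus[i] == 0
            if b == "G":
                prev1 = seq[i - 1] if i >= 1 else "N"
                prev2 = seq[i - 2] if i >= 2 else "N"
                if prev1 == "C":
                    expect = 1
                elif prev2 == "C":
                    expect = 2
                else:
                    expect = 3
                assert minus[i] == expect
            else:
                assert minus[i] == 0


def test_trinucleotide_is_strand_oriented():
    seq = "TACGA"
    assert trinucleotide(seq, 2, "+") == "CGA"
    assert trinucleotide(seq, 3, "-") == "CGT"  # revcomp of ACG
    assert trinucleotide("C", 0, "+") == "CNN"  # padded at the contig end
    assert trinucleotide("GA", 0, "-") == "CNN"


class TestBuildPileup:
    def test_single_c_observation(self):
        genome = Genome({"chr1": "ACGT"})
        pileup = build_pileup([mk_read("ACGT")], genome)
        row = pileup[(pileup["pos"] == 1) & (pileup["strand"] == "+")].iloc[0]
        assert row["meth_count"] == 1 and row["unmeth_count"] == 0
        assert row["context"] == "CG"

    def test_converted_t_counts_as_unmethylated(self):
        genome = Genome({"chr1": "ACGT"})
        pileup = build_pileup([mk_read("ATGT")], genome)
        row = pileup[(pileup["pos"] == 1) & (pileup["strand"] == "+")].iloc[0]
        assert row["unmeth_count"] == 1 and row["meth_count"] == 0

    def test_non_cytosine_positions_have_no_entry(self):
        genome = Genome({"chr1": "ATTA"})
        pileup = build_pileup([mk_read("ATTA")], genome)
        assert pileup.empty

    def test_minus_strand_read_counts_minus_sites(self):
        # minus-strand cytosine at plus G (index 2); a fully methylated
        # minus read over ACGT reads revcomp = ACGT
        genome = Genome({"chr1": "ACGT"})
        pileup = build_pileup([mk_read("ACGT", strand="-")], genome)
        minus = pileup[pileup["strand"] == "-"]
        row = minus[minus["pos"] == 2].iloc[0]
        assert row["meth_count"] == 1
        plus = pileup[pileup["strand"] == "+"]
        assert int((plus["meth_count"] + plus["unmeth_count"]).sum()) == 0

    def test_out_of_bounds_read_rejected_with_count(self):
        genome = Genome({"chr1": "ACGT"})
        pileup = build_pileup([mk_read("ACGTACGT", start=2)], genome)
        assert pileup.attrs["stats"]["reads_rejected_out_of_bounds"] == 1
        assert int((pileup["meth_count"] + pileup["unmeth_count"]).sum()) == 0

    def test_permutation_invariance(self, small_study):
        reads = small_study["reads"][:400]
        genome = small_study["genome"]
        a = build_pileup(reads, genome)
        b = build_pileup(list(reversed(reads)), genome)
        a.attrs = b.attrs = {}
        assert a.equals(b)

    def test_strand_separation(self, small_study):
        genome = small_study["genome"]
        reads = small_study["reads"][:400]
        base = build_pileup(reads, genome)
        mutated = [
            Read(r.read_id, r.contig, r.start, r.strand, "A" * len(r.sequence), r.qualities)
            if r.strand == "-"
            else r
            for r in reads
        ]
        alt = build_pileup(mutated, genome)
        cols = ["meth_count", "unmeth_count", "other_count"]
        assert base[base["strand"] == "+"][cols].equals(alt[alt["strand"] == "+"][cols])

    def test_counts_sum_to_overlapping_strand_matched_reads(self, small_study):
        genome = small_study["genome"]
        reads = remove_duplicates(small_study["reads"][:300])
        pileup = build_pileup(reads, genome)
        covered = pileup[(pileup["meth_count"] + pileup["unmeth_count"]) > 0]
        for row in covered.sample(n=min(len(covered), 60), random_state=1).itertuples():
            overlap = sum(
                1
                for r in reads
                if r.contig == row.contig
                and r.strand == row.strand
                and r.start <= row.pos < r.start + len(r.sequence)
            )
            assert row.meth_count + row.unmeth_count + row.other_count == overlap
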