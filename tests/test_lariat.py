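import numpy as np
import pandas as pd
import pytest

from lariatools.lariat import (
    AlignPenalties,
    UsageTable,
    align_branch_read,
    build_lariat_reference,
    compare_bin_fractions,
    compare_usage,
    merge_pairs,
    placement_cost,
    qc_filter_read,
    quantify_usage,
)
from lariatools.seqio import IntronModel, QualRead
from lariatools.study_data import HUMAN_DBP_BINS, human_usage_table


def make_read(seq: str, q: int = 36, rid: str = "r") -> QualRead:
    return QualRead(rid, seq, np.full(len(seq), q))


class TestQcFilter:
    def test_eight_low_quality_bases_rejected(self):
        r = make_read("A" * 50)
        r.phred[:8] = 9
        assert not qc_filter_read(r)

    def test_seven_low_quality_bases_accepted(self):
        r = make_read("A" * 50)
        r.phred[:7] = 9
        assert qc_filter_read(r)

    def test_high_quality_read_accepted(self):
        assert qc_filter_read(make_read("A" * 50, q=30))


class TestMergePairs:
    @staticmethod
    def _pair_from_fragment(frag: str, read_len: int):
        r1 = make_read(frag[:read_len], rid="p/1")
        r2_seq = frag[-read_len:][::-1].translate(str.maketrans("ACGT", "TGCA"))
        return r1, make_read(r2_seq, rid="p/2")

    @staticmethod
    def _random_fragment(n, seed=0):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_hundred_nt_overlap_reconstructs_fragment(self):
        frag = self._random_fragment(200, seed=1)
        r1, r2 = self._pair_from_fragment(frag, 150)
        merged = merge_pairs(r1, r2, min_merged_len=195)
        assert merged is not None and merged.seq == frag  # 150+150-100

    def test_short_merge_discarded(self):
        frag = self._random_fragment(170, seed=2)  # 130-nt overlap
        r1, r2 = self._pair_from_fragment(frag, 150)
        assert merge_pairs(r1, r2, min_merged_len=195) is None

    def test_overlap_boundary_at_minimum(self):
        # a perfect 19-nt overlap is below the minimum and must not merge;
        # a perfect 20-nt overlap is exactly at the minimum and must merge.
        # The mismatch cap is tightened so no longer, noisier overlap can
        # be accepted by chance on random sequence.
        for true_ov, expected_merge in ((19, False), (20, True)):
            frag = self._random_fragment(300 - true_ov, seed=3)
            r1, r2 = self._pair_from_fragment(frag, 150)
            merged = merge_pairs(r1, r2, max_mismatch=3, min_merged_len=100)
            if expected_merge:
                assert merged is not None and merged.seq == frag
            else:
                assert merged is None

    def test_disagreement_resolved_to_higher_quality_base(self):
        frag = self._random_fragment(120, seed=4)
        r1, r2 = self._pair_from_fragment(frag, 80)  # 40-nt overlap
        seq = list(r1.seq)
        seq[100 - 40] = "A" if seq[100 - 40] != "A" else "C"  # corrupt r1 in overlap
        r1 = QualRead(r1.id, "".join(seq), np.full(80, 20))  # r2 wins on quality
        merged = merge_pairs(r1, r2, min_merged_len=100)
        assert merged is not None and merged.seq == frag


class TestLariatReference:
    def test_junction_joins_bp_to_intron_start(self):
        intron = IntronModel("GTAAGTCCCTAACCCCAG")
        ref = build_lariat_reference(intron, bp_pos=12, up_len=4, down_len=6)
        assert ref.seq == "CTAAGTAAGT"
        assert ref.junction_index == 4
        assert ref.seq[ref.junction_index - 1] == intron.seq[11]

    def test_single_base_upstream_flank(self):
        intron = IntronModel("GTAAGTCCCTAACCCCAG")
        ref = build_lariat_reference(intron, bp_pos=12, up_len=1, down_len=3)
        assert ref.seq == "AGTA" and ref.junction_index == 1

    def test_flank_overrun_raises(self):
        intron = IntronModel("GTAAGTCCCTAACCCCAG")
        with pytest.raises(ValueError):
            build_lariat_reference(intron, bp_pos=3, up_len=4, down_len=6)
        with pytest.raises(ValueError):
            build_lariat_reference(intron, bp_pos=12, up_len=4, down_len=100)


def _reference_panel():
    """Two references over a 60-nt intron, shared 12/30 flanks."""
    rng = np.random.default_rng(99)
    seq = list("GT" + "".join(rng.choice(list("ACGT"), size=56)) + "AG")
    seq[18:21] = "TAA"
    seq[28:31] = "TAA"
    intron = IntronModel("".join(seq), permissive=True)
    return [build_lariat_reference(intron, b, 12, 30) for b in (21, 31)]


class TestAlignment:
    def test_identical_read_costs_zero(self):
        refs = _reference_panel()
        aln = align_branch_read(make_read(refs[0].seq), refs)
        assert aln.cost == 0 and aln.branch_event == "match" and aln.bp_pos == 21

    def test_single_mismatch_costs_four(self):
        refs = _reference_panel()
        seq = list(refs[1].seq)
        seq[30] = "A" if seq[30] != "A" else "C"
        aln = align_branch_read(make_read("".join(seq)), refs)
        assert aln.cost == 4 and aln.bp_pos == 31

    def test_one_nt_insertion_costs_fifteen(self):
        refs = _reference_panel()
        seq = refs[0].seq[:20] + "T" + refs[0].seq[20:]
        if placement_cost(seq, refs[0].seq) != 15:  # guard: unambiguous site
            seq = refs[0].seq[:25] + "T" + refs[0].seq[25:]
        aln = align_branch_read(make_read(seq), refs)
        assert aln.cost == 15 and aln.indel is not None

    def test_at_substitution_at_junction_classified(self):
        refs = _reference_panel()
        seq = list(refs[0].seq)
        assert seq[refs[0].junction_index - 1] == "A"
        seq[refs[0].junction_index - 1] = "T"
        aln = align_branch_read(make_read("".join(seq)), refs)
        assert aln.branch_event == "A>T" and aln.cost == 4

    def test_junction_coverage_rule(self):
        refs = _reference_panel()
        # a read entirely downstream of the junction has no left flank
        tail = refs[0].seq[refs[0].junction_index :]
        assert align_branch_read(make_read(tail), refs) is None

    def test_cost_tie_breaks_to_smallest_bp(self):
        intron = IntronModel("GT" + "C" * 40 + "AG", permissive=True)
        refs = [build_lariat_reference(intron, b, 8, 20) for b in (15, 25)]
        assert refs[0].seq == refs[1].seq  # all-C upstream: indistinguishable
        aln = align_branch_read(make_read(refs[0].seq), refs)
        assert aln.bp_pos == 15


def oracle_cost(read: str, ref: str, pen: AlignPenalties):
    """Exhaustive enumeration of every <=1-interior-indel placement."""
    m, n = len(read), len(ref)

    def mm(a, b):
        return sum(x != y for x, y in zip(a, b))

    best = None
    for s in range(n - m + 1):
        c = pen.mismatch * mm(read, ref[s : s + m])
        best = c if best is None or c < best else best
    for k in range(1, n - m + 1):  # deletion: read skips k reference bases
        gap = pen.gap_open + pen.gap_ext * k
        for s in range(n - m - k + 1):
            for i in range(1, m):
                c = gap + pen.mismatch * (
                    mm(read[:i], ref[s : s + i]) + mm(read[i:], ref[s + i + k : s + m + k])
                )
                best = c if best is None or c < best else best
    for k in range(1, m - 1):  # insertion: k read bases unaligned
        gap = pen.gap_open + pen.gap_ext * k
        span = m - k
        if span > n:
            continue
        for s in range(n - span + 1):
            for i in range(1, span):
                c = gap + pen.mismatch * (
                    mm(read[:i], ref[s : s + i]) + mm(read[i + k :], ref[s + i : s + span])
                )
                best = c if best is None or c < best else best
    return best


class TestAlignmentOracle:
    def test_cost_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(31)
        pen = AlignPenalties()
        for case in range(40):
            n = int(rng.integers(12, 40))
            m = int(rng.integers(8, n + 1))
            ref = "".join(rng.choice(list("ACGT"), size=n))
            kind = case % 4
            if kind == 0:  # unrelated read
                read = "".join(rng.choice(list("ACGT"), size=m))
            else:  # mutated substring of the reference
                s = int(rng.integers(0, n - m + 1))
                read = list(ref[s : s + m])
                for _ in range(int(rng.integers(0, 3))):
                    j = int(rng.integers(0, len(read)))
                    read[j] = "ACGT"[int(rng.integers(0, 4))]
                if kind == 2 and len(read) > 3:
                    del read[int(rng.integers(1, len(read) - 1))]
                if kind == 3 and len(read) > 3:
                    j = int(rng.integers(1, len(read) - 1))
                    read.insert(j, "ACGT"[int(rng.integers(0, 4))])
                read = "".join(read)
            assert placement_cost(read, ref, pen) == oracle_cost(read, ref, pen), (
                read,
                ref,
            )


class TestUsageTable:
    def test_published_control_fractions(self):
        table = human_usage_table()
        frac = table.fractions().loc["control"]
        assert frac.round(2).tolist() == [0.28, 0.46, 0.24, 0.02]

    def test_single_bin_fraction_one(self):
        aln = align_branch_read(make_read(_reference_panel()[0].seq), _reference_panel())
        table = quantify_usage({"c": [aln, aln, None]}, [21, 31])
        assert table.fractions().loc["c", 21] == 1.0
        assert table.counts.loc["c"].sum() == 2  # None excluded

    def test_unknown_bin_raises(self):
        aln = align_branch_read(make_read(_reference_panel()[0].seq), _reference_panel())
        with pytest.raises(ValueError):
            quantify_usage({"c": [aln]}, [31])

    def test_tsv_roundtrip(self, tmp_path):
        table = human_usage_table()
        table.to_tsv(tmp_path / "u.tsv")
        assert UsageTable.from_tsv(tmp_path / "u.tsv") == table


class TestCompareUsage:
    def test_uniform_table_has_zero_statistic(self):
        t = UsageTable(pd.DataFrame([[10, 10], [10, 10]], columns=[1, 2]))
        chi2, df, p = compare_usage(t)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0) and df == 1

    def test_zero_column_raises(self):
        t = UsageTable(pd.DataFrame([[10, 0], [10, 0]], columns=[1, 2]))
        with pytest.raises(ValueError):
            compare_usage(t)

    def test_pooling_merges_counts(self):
        pooled = human_usage_table().pool({41: 36})
        assert pooled.counts.shape == (3, 3)
        assert pooled.counts.loc["TIA1/TIAR depleted", 36] == 13


class TestCompareBinFractions:
    def test_identical_groups(self):
        t, df, p = compare_bin_fractions([0.3, 0.3], [0.3, 0.3])
        assert t == 0.0 and p == 1.0

    def test_separated_groups_significant(self):
        t, df, p = compare_bin_fractions([0.1, 0.2], [0.8, 0.9], welch=False)
        assert p < 0.05

    def test_welch_df_below_pooled_when_variances_differ(self):
        a = [0.1, 0.11, 0.09, 0.1]
        b = [0.5, 0.9, 0.1, 1.3]  # ~100x the variance
        _, df_w, _ = compare_bin_fractions(a, b, welch=True)
        _, df_p, _ = compare_bin_fractions(a, b, welch=False)
        assert df_w < df_p == 6
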