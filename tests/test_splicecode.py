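import numpy as np
import pandas as pd
import pytest

from lariatools.splicecode import (
    ALL_CODONS,
    ALL_HEXAMERS,
    IRVING_WILLIAMS_SERIES,
    CodonCountTable,
    HexamerScoreTable,
    MetalResidueFrequencies,
    aa_log_ratio,
    codon_counts,
    fold_excess,
    metal_gradient,
    preference_index,
    rank_codons,
    standard_genetic_code,
    window_score,
)
from lariatools.study_data import de_codon_count_tables


class TestCodonCounts:
    def test_homopolymer_hexamer(self):
        table = codon_counts({"AAAAAA"})
        assert table.counts["AAA"] == 4 and table.total == 4

    def test_four_windows_enumerated(self):
        table = codon_counts({"GAAGAA"})
        assert table.counts["GAA"] == 2
        assert table.counts["AAG"] == 1
        assert table.counts["AGA"] == 1
        assert table.total == 4

    def test_non_hexamer_rejected(self):
        with pytest.raises(ValueError):
            codon_counts({"GAAGA"})

    def test_conservation_total_is_four_per_hexamer(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            size = int(rng.integers(1, 400))
            hexset = set(rng.choice(ALL_HEXAMERS, size=size, replace=False))
            table = codon_counts(hexset)
            assert sum(table.counts.values()) == table.total == 4 * len(hexset)


class TestFoldExcess:
    def test_published_de_codon_folds(self):
        ese, ess = de_codon_count_tables()
        fx = fold_excess(ese, ess)
        assert fx.loc["GAA", "fold"] == pytest.approx(13.5, abs=0.05)
        assert fx.loc["GAC", "fold"] == pytest.approx(23.3, abs=0.05)
        assert fx.loc["GAT", "fold"] == pytest.approx(4.5, abs=0.05)

    def test_equal_counts_equal_totals_give_unity(self):
        a = CodonCountTable({"GAA": 5}, total=100)
        b = CodonCountTable({"GAA": 5}, total=100)
        fx = fold_excess(a, b)
        assert fx.loc["GAA", "fold"] == 1.0 and fx.loc["GAA", "log_ratio"] == 0.0

    def test_zero_ess_count_flagged_and_pseudocounted(self):
        a = CodonCountTable({"GAA": 5}, total=100)
        b = CodonCountTable({"GAC": 5}, total=100)
        fx = fold_excess(a, b)
        assert np.isinf(fx.loc["GAA", "fold"])
        assert fx.loc["GAA", "pseudocounted"]
        assert fx.loc["GAA", "log_ratio"] == pytest.approx(np.log(5.5 / 0.5))

    def test_monotonicity_in_ese_count(self):
        b = CodonCountTable({"GAA": 5}, total=100)
        folds = [
            fold_excess(CodonCountTable({"GAA": n}, total=100), b).loc["GAA", "fold"]
            for n in (1, 3, 9)
        ]
        assert folds[0] < folds[1] < folds[2]


class TestRankCodons:
    @staticmethod
    def _uniform_ratios(value=0.0):
        return {c: value for c in ALL_CODONS}

    def test_planted_top_codon_ranks_first(self):
        ratios = self._uniform_ratios()
        ratios["GAC"] = 2.0
        ranked = rank_codons(ratios)
        assert ranked.iloc[0]["codon"] == "GAC"

    def test_all_equal_is_alphabetical(self):
        ranked = rank_codons(self._uniform_ratios())
        assert list(ranked["codon"]) == sorted(ALL_CODONS)

    def test_stop_codons_flagged(self):
        ranked = rank_codons(self._uniform_ratios())
        stops = set(ranked.loc[ranked["is_stop"], "codon"])
        assert stops == {"TAA", "TAG", "TGA"}

    def test_incomplete_input_rejected(self):
        with pytest.raises(ValueError):
            rank_codons({"GAC": 1.0})


class TestAminoAcidRatios:
    def test_single_codon_residue_equals_codon_ratio(self):
        ese = CodonCountTable({"ATG": 8}, total=100)
        ess = CodonCountTable({"ATG": 2}, total=100)
        assert aa_log_ratio(ese, ess).loc["M", "ratio"] == pytest.approx(4.0)

    def test_aspartate_from_published_counts(self):
        ese, ess = de_codon_count_tables()
        assert aa_log_ratio(ese, ess).loc["D", "ratio"] == pytest.approx(8.91, abs=0.005)

    def test_uniform_counts_log_ratio_zero(self):
        uniform = {c: 2 for c in ALL_CODONS}
        a = CodonCountTable(uniform, total=128)
        b = CodonCountTable(uniform, total=128)
        table = aa_log_ratio(a, b)
        assert np.allclose(table["log_ratio"], 0.0)
        assert "*" not in table.index


class TestMetalGradient:
    def test_uniform_frequencies_give_identical_averages(self):
        aas = list("DEHC")
        freqs = MetalResidueFrequencies(
            {m: {aa: 1.0 for aa in aas} for m in IRVING_WILLIAMS_SERIES}
        )
        ratios = {"D": 1.0, "E": 0.5, "H": -1.0, "C": -0.5}
        res = metal_gradient(ratios, freqs)
        assert np.allclose(res.averages, res.averages.iloc[0])

    def test_toy_two_metal_weighting(self):
        freqs = MetalResidueFrequencies({"A": {"D": 1.0}, "B": {"H": 1.0}})
        res = metal_gradient({"D": 1.0, "H": -1.0}, freqs, series_order=("A", "B"))
        assert res.averages["A"] == pytest.approx(1.0)
        assert res.averages["B"] == pytest.approx(-1.0)

    def test_weights_renormalised_over_overlap(self):
        freqs = MetalResidueFrequencies({"A": {"D": 0.5, "X": 0.5}})
        res = metal_gradient({"D": 2.0}, freqs, series_order=("A",))
        assert res.averages["A"] == pytest.approx(2.0)  # X absent -> D weight 1

    def test_empty_overlap_raises(self):
        freqs = MetalResidueFrequencies({"A": {"X": 1.0}})
        with pytest.raises(ValueError):
            metal_gradient({"D": 1.0}, freqs, series_order=("A",))


class TestPreferenceIndex:
    @staticmethod
    def _usage():
        code = standard_genetic_code()
        sense = [c for c in ALL_CODONS if code[c] != "*"]
        return {c: 1.0 / len(sense) for c in sense}

    def test_null_draw_has_moderate_indices(self):
        rng = np.random.default_rng(3)
        pool = list(ALL_HEXAMERS)
        code = standard_genetic_code()
        ok = [h for h in pool if code[h[:3]] != "*" and code[h[3:]] != "*"]
        tested = list(rng.choice(ok, size=120, replace=False))
        idx = preference_index(tested, pool, self._usage(), n_random=300, seed=11)
        finite = idx["index"].dropna()
        assert (finite.abs() < 4).all()

    def test_planted_aspartate_enrichment_detected(self):
        rng = np.random.default_rng(4)
        gay = [h for h in ALL_HEXAMERS if h[:3] in ("GAC", "GAT") and h[3:6] not in ("TAA", "TAG", "TGA")]
        other = [h for h in ALL_HEXAMERS if h[:3] not in ("GAC", "GAT", "TAA", "TAG", "TGA")]
        tested = list(rng.choice(gay, size=60, replace=False)) + list(
            rng.choice(other, size=60, replace=False)
        )
        idx = preference_index(tested, list(ALL_HEXAMERS), self._usage(), n_random=300, seed=12)
        assert idx.loc["D", "index"] > 3

    def test_single_randomisation_rejected(self):
        with pytest.raises(ValueError):
            preference_index(["AAAAAA"], list(ALL_HEXAMERS), self._usage(), n_random=1)


def uniform_score_table(ese=2.0, ess=1.0) -> HexamerScoreTable:
    return HexamerScoreTable(
        pd.DataFrame(
            {
                "hexamer": ALL_HEXAMERS,
                "ese_score": ese,
                "ess_score": ess,
                "label": "neutral",
            }
        )
    )


class TestWindowScore:
    def test_full_window_scores_twenty_hexamers(self):
        table = uniform_score_table()
        seq = "A" * 60
        # uniform table: the mean equals the constant ratio regardless of count
        assert window_score(seq, 30, 34, table) == pytest.approx(2.0)

    def test_planted_hexamer_shifts_mean_by_delta_over_twenty(self):
        df = uniform_score_table().df.copy()
        seq = "A" * 60
        # centre a distinctive hexamer inside the 25-nt window around 28..32
        seq = seq[:27] + "GACGTC" + seq[33:]
        delta = 10.0
        df.loc[df["hexamer"] == "GACGTC", "ese_score"] = 2.0 + delta
        table = HexamerScoreTable(df)
        base = window_score("A" * 60, 28, 32, uniform_score_table())
        shifted = window_score(seq, 28, 32, table)
        assert shifted - base == pytest.approx(delta / 1.0 / 20)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            window_score("ACGTA", 2, 3, uniform_score_table())
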