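"""Normalisation, fold changes, effect sizes, recall AUC, positional bias."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from trnaduo import screen_stats as ss
from trnaduo.libdesign import GuidePairRecord, LibraryManifest
from conftest import unique_spacers


def two_rep_design():
    return ss.ScreenDesign(
        [
            ss.SampleSpec("d3_1", "day3", "1"),
            ss.SampleSpec("d3_2", "day3", "2"),
            ss.SampleSpec("d14_1", "day14", "1"),
            ss.SampleSpec("d14_2", "day14", "2"),
        ]
    )


class TestScreenDesign:
    def test_paired_replicates(self):
        d = two_rep_design()
        assert d.paired_replicates() == [
            ("1", "d14_1", "d3_1"), ("2", "d14_2", "d3_2")
        ]

    def test_missing_compared_role_rejected(self):
        with pytest.raises(ValueError, match="day14"):
            ss.ScreenDesign([ss.SampleSpec("a", "day3", "1")])

    def test_duplicate_replicate_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate replicate"):
            ss.ScreenDesign(
                [
                    ss.SampleSpec("a", "day3", "1"),
                    ss.SampleSpec("b", "day3", "1"),
                    ss.SampleSpec("c", "day14", "1"),
                ]
            )

    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "design.yaml"
        cfg.write_text(
            "samples:\n"
            "  - {name: p1, role: plasmid, replicate: 1}\n"
            "  - {name: d14, role: day14, replicate: 1}\n"
            "comparison: {treatment: day14, control: plasmid}\n"
        )
        d = ss.ScreenDesign.from_yaml(cfg)
        assert d.control_role == "plasmid"
        assert d.paired_replicates() == [("1", "d14", "p1")]


class TestNormaliseCounts:
    def test_proportional_scaling(self):
        counts = pd.DataFrame({"s": [10, 30, 60]})
        norm = ss.normalise_counts(counts, scale=1e7)
        assert np.allclose(norm["s"], [1e6, 3e6, 6e6])

    def test_scalar_multiple_samples_identical(self):
        counts = pd.DataFrame({"a": [1, 2, 3], "b": [10, 20, 30]})
        norm = ss.normalise_counts(counts)
        assert np.allclose(norm["a"], norm["b"])

    def test_zero_sum_sample_rejected(self):
        with pytest.raises(ValueError, match="zero-sum"):
            ss.normalise_counts(pd.DataFrame({"s": [0, 0]}))


class TestLog2FoldChange:
    def lfc_for(self, treat, ctrl, pc):
        counts = pd.DataFrame(
            {"d3_1": [ctrl, 100], "d3_2": [ctrl, 100],
             "d14_1": [treat, 100], "d14_2": [treat, 100]},
            index=pd.Index(["v0", "v1"], name="vector_id"),
        )
        # already-normalised columns: equal sums not required for this test
        return ss.log2_fold_change(counts, two_rep_design(), pc)

    def test_doubling_is_one(self):
        eff = self.lfc_for(200, 100, 0.0)
        assert eff.lfc.loc["v0", "1"] == pytest.approx(1.0)

    def test_pseudocount_example(self):
        eff = self.lfc_for(200, 100, 0.5)
        assert eff.lfc.loc["v0", "1"] == pytest.approx(
            math.log2(200.5 / 100.5)
        )

    def test_zero_with_pseudocount_finite(self):
        eff = self.lfc_for(0, 100, 0.5)
        assert eff.lfc.loc["v0", "1"] == pytest.approx(math.log2(0.5 / 100.5))

    def test_zero_without_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            self.lfc_for(0, 100, 0.0)

    def test_depth_invariance(self, rng):
        raw = pd.DataFrame(
            rng.integers(1, 1000, size=(20, 4)),
            columns=["d3_1", "d3_2", "d14_1", "d14_2"],
        )
        scaled = raw.copy()
        scaled["d14_1"] *= 13  # sequencing depth changes one sample
        d = two_rep_design()
        lfc_a = ss.log2_fold_change(ss.normalise_counts(raw), d)
        lfc_b = ss.log2_fold_change(ss.normalise_counts(scaled), d)
        assert np.allclose(lfc_a.lfc, lfc_b.lfc)


class TestAggregateGene:
    def make_inputs(self, rng, lfc_rows):
        sp1 = unique_spacers(rng, len(lfc_rows))
        sp2 = unique_spacers(rng, len(lfc_rows))
        recs = [
            GuidePairRecord(f"v{i}", "GENE_A", sp1[i], "WT", "CTRL",
                            sp2[i], "singleton")
            for i in range(len(lfc_rows))
        ]
        lfc = pd.DataFrame(
            lfc_rows, index=pd.Index([f"v{i}" for i in range(len(lfc_rows))],
                                     name="vector_id"),
        )
        return ss.EffectTable(lfc), LibraryManifest(recs)

    def test_mean_over_vectors(self, rng):
        eff, man = self.make_inputs(rng, [[-1.0], [-3.0]])
        out = ss.aggregate_gene(eff, man, "gene")
        assert out.loc["GENE_A", "lfc"] == pytest.approx(-2.0)
        assert out.loc["GENE_A", "n_vectors"] == 2

    def test_replicates_averaged_before_vectors(self, rng):
        eff, man = self.make_inputs(rng, [[-1.0, -2.0, -3.0]])
        out = ss.aggregate_gene(eff, man, "gene")
        assert out.loc["GENE_A", "lfc"] == pytest.approx(-2.0)

    def test_gene_pair_key_is_order_free(self, rng):
        sp = unique_spacers(rng, 4)
        recs = [
            GuidePairRecord("v0", "A", sp[0], "WT", "B", sp[1], "double_ko"),
            GuidePairRecord("v1", "B", sp[2], "WT", "A", sp[3], "double_ko"),
        ]
        lfc = pd.DataFrame({"r1": [-2.0, -4.0]},
                           index=pd.Index(["v0", "v1"], name="vector_id"))
        out = ss.aggregate_gene(ss.EffectTable(lfc), LibraryManifest(recs),
                                "gene_pair")
        assert out.loc[("A", "B"), "lfc"] == pytest.approx(-3.0)

    def test_unannotated_vector_rejected(self, rng):
        eff, man = self.make_inputs(rng, [[-1.0]])
        eff.lfc.loc["ghost"] = [0.0]
        with pytest.raises(ValueError, match="not in manifest"):
            ss.aggregate_gene(eff, man, "gene")


class TestCohensD:
    def test_equal_groups(self):
        out = ss.cohens_d_ttest([1, 2, 3], [1, 2, 3])
        assert out.cohens_d == pytest.approx(0.0)
        assert out.p_value == pytest.approx(1.0)

    def test_hand_computed_d_of_three(self):
        # pooled sd = 1 exactly, mean difference 3
        out = ss.cohens_d_ttest([4, 5, 6], [1, 2, 3])
        assert out.cohens_d == pytest.approx(3.0, abs=1e-12)

    def test_welch_p_matches_scipy(self):
        from scipy import stats

        x, y = [4.0, 5.5, 6.1, 4.4], [1.2, 2.3, 3.3]
        out = ss.cohens_d_ttest(x, y)
        assert out.p_value == pytest.approx(
            stats.ttest_ind(x, y, equal_var=False).pvalue, abs=1e-12
        )

    def test_sign_flips_on_group_exchange(self):
        a = ss.cohens_d_ttest([4, 5, 6], [1, 2, 3])
        b = ss.cohens_d_ttest([1, 2, 3], [4, 5, 6])
        assert a.cohens_d == pytest.approx(-b.cohens_d)

    def test_degenerate_unequal_groups_rejected(self):
        with pytest.raises(ValueError, match="zero pooled variance"):
            ss.cohens_d_ttest([1, 1], [2, 2])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ss.cohens_d_ttest([1], [2, 3])


def oracle_auc(ranks, n, n_pos):
    """Closed-form trapezoid AUC from 1-based positive ranks."""
    return sum(n - r + 1 for r in ranks) / (n * n_pos) - 1 / (2 * n)


class TestRecallAUC:
    def scores(self, n):
        return pd.Series(np.arange(n, dtype=float),
                         index=[f"g{i}" for i in range(n)])

    def test_positives_ranked_first(self):
        res = ss.recall_auc(self.scores(10), {"g0", "g1"})
        assert res.auc == pytest.approx(0.9)

    def test_positives_ranked_last(self):
        res = ss.recall_auc(self.scores(10), {"g8", "g9"})
        assert res.auc == pytest.approx(0.1)

    def test_all_items_positive(self):
        res = ss.recall_auc(self.scores(10), {f"g{i}" for i in range(10)})
        assert res.auc == pytest.approx(0.5)

    def test_matches_rank_enumeration_oracle_exhaustively(self):
        """Every positive-set placement for n <= 6 against the closed form."""
        for n in range(2, 7):
            scores = self.scores(n)
            for k in range(1, n + 1):
                for pos in itertools.combinations(range(n), k):
                    ids = {f"g{i}" for i in pos}
                    expected = oracle_auc([p + 1 for p in pos], n, k)
                    assert ss.recall_auc(scores, ids).auc == pytest.approx(
                        expected
                    ), (n, pos)

    def test_ties_broken_by_stable_id_order(self):
        scores = pd.Series([0.0, 0.0, 0.0], index=["a", "b", "c"])
        res = ss.recall_auc(scores, {"a"})
        assert res.auc == pytest.approx(oracle_auc([1], 3, 1))

    def test_curve_ends_at_full_recall(self):
        res = ss.recall_auc(self.scores(8), {"g3", "g5"})
        assert res.curve[-1, 1] == pytest.approx(1.0)
        assert (np.diff(res.curve[:, 1]) >= 0).all()

    def test_empty_positive_set_rejected(self):
        with pytest.raises(ValueError, match="empty positive"):
            ss.recall_auc(self.scores(4), set())

    def test_unscored_positive_rejected(self):
        with pytest.raises(ValueError, match="not scored"):
            ss.recall_auc(self.scores(4), {"nope"})


class TestPositionBias:
    def make_mirrored(self, rng, pos1_lfc, pos2_lfc):
        """Guides g0..g{n-1} each measured in both cassette positions."""
        n = len(pos1_lfc)
        guides = unique_spacers(rng, n)
        # distinct partners per orientation so only g0..g{n-1} appear in
        # both positions
        partner_f, partner_r = unique_spacers(rng, 2)
        recs, rows = [], {}
        for i, g in enumerate(guides):
            recs.append(GuidePairRecord(f"f{i}", f"g{i}", g, "WT", "PF",
                                        partner_f, "double_ko"))
            rows[f"f{i}"] = pos1_lfc[i]
            recs.append(GuidePairRecord(f"r{i}", "PR", partner_r, "WT",
                                        f"g{i}", g, "double_ko"))
            rows[f"r{i}"] = pos2_lfc[i]
        lfc = pd.DataFrame({"rep1": rows}).rename_axis("vector_id")
        return ss.EffectTable(lfc), LibraryManifest(recs)

    def test_identical_means_give_unit_slope(self, rng):
        eff, man = self.make_mirrored(rng, [-1.0, 0.0, 2.0, 1.0],
                                      [-1.0, 0.0, 2.0, 1.0])
        out = ss.position_bias(eff, man)
        assert out.pearson_r == pytest.approx(1.0)
        assert out.slope == pytest.approx(1.0)

    def test_doubled_means_give_slope_two(self, rng):
        eff, man = self.make_mirrored(rng, [-1.0, 0.0, 2.0],
                                      [-2.0, 0.0, 4.0])
        out = ss.position_bias(eff, man)
        assert out.slope == pytest.approx(2.0)
        assert out.pearson_r == pytest.approx(1.0)

    def test_four_point_closed_form(self, rng):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 1.5, 2.5, 4.0])
        eff, man = self.make_mirrored(rng, list(x), list(y))
        out = ss.position_bias(eff, man)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        syy = ((y - y.mean()) ** 2).sum()
        assert out.slope == pytest.approx(sxy / sxx)
        assert out.pearson_r == pytest.approx(sxy / math.sqrt(sxx * syy))
        assert out.n_guides == 4

    def test_too_few_shared_guides_rejected(self, rng):
        eff, man = self.make_mirrored(rng, [0.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValueError, match="need >= 3"):
            ss.position_bias(eff, man)
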