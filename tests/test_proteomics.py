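"""Adaptive differential-abundance statistics and gene-set enrichment."""

import numpy as np
import pandas as pd
import pytest

from lymphomorph import proteomics as prot


@pytest.fixture(scope="module")
def toy_dataset():
    return prot.simulate_abundances(
        120, 10,
        effects={"site": {"P00000": 1.79, "P00001": 2.5},
                 "age_both": {"P00002": 1.5, "P00003": 2.0}},
        seed=42)


class TestSimulate:
    def test_determinism(self):
        a, _, _ = prot.simulate_abundances(30, 4, seed=9)
        b, _, _ = prot.simulate_abundances(30, 4, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_no_effects_truth_all_null(self):
        _, _, truth = prot.simulate_abundances(20, 4, seed=1)
        assert truth["is_null"].all()

    def test_site_effect_expected_log2fc(self, toy_dataset):
        mat, design, truth = toy_dataset
        lfc = prot.group_log2fc(mat, design, "mand_vs_sub_mean")
        assert lfc["P00000"] == pytest.approx(1.79, abs=0.5)
        assert truth.loc["P00000", "site"] == 1.79

    def test_degenerate_sizes_raise(self):
        with pytest.raises(ValueError):
            prot.simulate_abundances(10, 1)


class TestLog2fc:
    def test_identical_groups_zero(self):
        mat = pd.DataFrame(np.ones((5, 8)),
                           columns=[f"s{i}" for i in range(8)],
                           index=[f"P{i}" for i in range(5)])
        design = pd.DataFrame({
            "site": ["mandibular"] * 4 + ["subiliac"] * 4,
            "age": ["young", "young", "old", "old"] * 2,
            "mouse_id": list("aabb") * 2,
        }, index=mat.columns)
        lfc = prot.group_log2fc(mat, design, "mand_vs_sub_mean")
        assert np.allclose(lfc, 0.0)

    def test_hand_arithmetic_log_scale(self):
        # log2 means 3 vs 1 -> log2fc 2 (linear 8 vs 2)
        mat = pd.DataFrame([[3.0] * 4 + [1.0] * 4],
                           columns=[f"s{i}" for i in range(8)], index=["P0"])
        design = pd.DataFrame({
            "site": ["mandibular"] * 4 + ["subiliac"] * 4,
            "age": ["young", "young", "old", "old"] * 2,
            "mouse_id": list("aabb") * 2,
        }, index=mat.columns)
        assert prot.group_log2fc(mat, design, "mand_vs_sub_mean")["P0"] == 2.0

    def test_fold_change_report_value(self):
        assert round(2 ** 1.79, 2) == 3.46

    def test_unknown_contrast_raises(self, toy_dataset):
        mat, design, _ = toy_dataset
        with pytest.raises(KeyError):
            prot.group_log2fc(mat, design, "left_vs_right")


class TestAdaptiveTest:
    def test_null_type_one_error_rate(self):
        mat, design, _ = prot.simulate_abundances(1000, 10, seed=3)
        res = prot.adaptive_test(mat, design, "mand_vs_sub_mean")
        rate = float((res["p"] <= 0.05).mean())
        assert rate == pytest.approx(0.05, abs=0.015)

    def test_identical_groups_p_one(self):
        cols = [f"s{i}" for i in range(8)]
        design = pd.DataFrame({
            "site": ["mandibular"] * 4 + ["subiliac"] * 4,
            "age": ["young", "young", "old", "old"] * 2,
            "mouse_id": list("aabb") * 2,
        }, index=cols)
        mat = pd.DataFrame([[1.0, 2.0, 3.0, 4.0] * 2], columns=cols,
                           index=["P0"])
        res = prot.adaptive_test(mat, design, "mand_vs_sub_mean")
        assert res.loc["P0", "p"] == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_routes_to_wilcoxon(self):
        cols = [f"s{i}" for i in range(12)]
        design = pd.DataFrame({
            "site": ["mandibular"] * 6 + ["subiliac"] * 6,
            "age": ["young"] * 3 + ["old"] * 3 + ["young"] * 3 + ["old"] * 3,
            "mouse_id": list("abcabc") * 2,
        }, index=cols)
        mat = pd.DataFrame([[5.0] * 6 + [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
                           columns=cols, index=["P0"])
        res = prot.adaptive_test(mat, design, "mand_vs_sub_mean")
        assert res.loc["P0", "test_used"] == "wilcoxon"
        assert not res.loc["P0", "normal_all_groups"]

    def test_small_groups_raise(self):
        mat, design, _ = prot.simulate_abundances(5, 2, seed=0)
        with pytest.raises(ValueError):
            prot.adaptive_test(mat, design, "mand_vs_sub_young")

    def test_power_for_large_site_effects(self):
        effects = {"site": {f"P{i:05d}": 1.5 for i in range(60)}}
        mat, design, truth = prot.simulate_abundances(600, 10, effects=effects,
                                                      seed=7)
        res = prot.adaptive_test(mat, design, "mand_vs_sub_mean")
        hits = res.index[(res["q"] <= 0.05)]
        true_set = set(truth.index[truth["site"] > 0])
        power = len(set(hits) & true_set) / len(true_set)
        fdr = (len(set(hits) - true_set) / max(len(hits), 1))
        assert power > 0.8
        assert fdr <= 0.10


class TestBH:
    def test_hand_step_up(self):
        np.testing.assert_allclose(prot.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert prot.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(prot.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_q_at_least_p_and_order_invariant(self, rng):
        p = rng.random(50)
        q = prot.bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)
        perm = rng.permutation(50)
        np.testing.assert_allclose(prot.bh_adjust(p[perm]), q[perm])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            prot.bh_adjust([0.5, 1.5])


class TestAgeIndependentFilter:
    @staticmethod
    def _rows(index, lfc, q):
        return pd.DataFrame({"log2fc": lfc, "p": q, "q": q}, index=index)

    def test_no_joint_age_up_keeps_everything(self):
        idx = [f"P{i}" for i in range(5)]
        site = self._rows(idx, [1.0] * 5, [0.01] * 5)
        age_m = self._rows(idx, [1.0] * 5, [0.5] * 5)
        age_s = self._rows(idx, [1.0] * 5, [0.01] * 5)
        out, removed = prot.age_independent_filter(site, age_m, age_s)
        assert removed == [] and len(out) == 5

    def test_all_age_up_removes_everything(self):
        idx = [f"P{i}" for i in range(4)]
        rows = self._rows(idx, [1.0] * 4, [0.01] * 4)
        out, removed = prot.age_independent_filter(rows, rows, rows)
        assert len(out) == 0 and set(removed) == set(idx)

    def test_toy_intersection_by_hand(self):
        idx = [f"P{i}" for i in range(5)]
        site = self._rows(idx, [1.0] * 5, [0.01] * 5)
        age_m = self._rows(idx, [1.0, 1.0, -1.0, 1.0, 1.0],
                           [0.01, 0.01, 0.01, 0.5, 0.01])
        age_s = self._rows(idx, [1.0, -1.0, 1.0, 1.0, 1.0],
                           [0.01, 0.01, 0.01, 0.01, 0.5])
        out, removed = prot.age_independent_filter(site, age_m, age_s)
        assert removed == ["P0"]
        assert len(out) == 4

    def test_mismatched_universe_raises(self):
        a = self._rows(["P0"], [1.0], [0.01])
        b = self._rows(["P1"], [1.0], [0.01])
        with pytest.raises(ValueError):
            prot.age_independent_filter(a, a, b)


class TestVolcano:
    def test_categories(self):
        rows = pd.DataFrame({
            "log2fc": [1.79, np.log2(1.7), np.log2(3.0), 0.1],
            "p": [0.01, 0.01, 0.2, 0.9],
            "q": [0.01, 0.01, 0.2, 0.9],
        }, index=["strong", "moderate", "notsig", "small"])
        out = prot.volcano_table(rows)
        assert out.loc["strong", "category"] == "strong"
        assert out.loc["moderate", "category"] == "moderate"
        assert out.loc["notsig", "category"] == "none"
        assert out.loc["small", "category"] == "none"


class TestSsgsea:
    def test_hand_oracle_five_proteins(self):
        mat = pd.DataFrame({"s1": [5.0, 4.0, 3.0, 2.0, 1.0]},
                           index=list("ABCDE"))
        scores, _ = prot.ssgsea_scores(mat, {"top": ["A", "B"]})
        w = np.arange(5, 0, -1) ** 0.25
        m = np.array([1, 1, 0, 0, 0], dtype=bool)
        p_in = np.cumsum(np.where(m, w, 0)) / w[m].sum()
        p_out = np.cumsum(~m) / 3
        assert scores.loc["top", "s1"] == pytest.approx(float(np.sum(p_in - p_out)),
                                                        abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self, rng):
        mat = pd.DataFrame(rng.normal(size=(30, 4)),
                           index=[f"P{i}" for i in range(30)],
                           columns=list("wxyz"))
        sets = {"s": [f"P{i}" for i in range(0, 9, 2)]}
        base, _ = prot.ssgsea_scores(mat, sets)
        warped = mat.copy()
        warped["w"] = np.exp(mat["w"] * 2.0) + 5.0  # strictly monotone
        after, _ = prot.ssgsea_scores(warped, sets)
        pd.testing.assert_frame_equal(base, after)

    def test_top_set_outscores_bottom_set(self, rng):
        vals = np.sort(rng.normal(size=(20, 3)), axis=0)[::-1]
        mat = pd.DataFrame(vals, index=[f"P{i}" for i in range(20)],
                           columns=list("abc"))
        scores, _ = prot.ssgsea_scores(
            mat, {"top": ["P0", "P1", "P2"], "bottom": ["P17", "P18", "P19"]})
        assert (scores.loc["top"] > scores.loc["bottom"]).all()

    def test_empty_intersection_raises(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 2)),
                           index=list("ABCDE"), columns=["s1", "s2"])
        with pytest.raises(ValueError):
            prot.ssgsea_scores(mat, {"s": ["Z1", "Z2"]})


class TestPrerankedGsea:
    def test_full_universe_es_zero(self):
        t = pd.Series([3.0, 2.0, 1.0], index=list("ABC"))
        res = prot.preranked_gsea(t, {"all": list("ABC")}, nperm=100, seed=0)
        assert res.loc["all", "ES"] == 0.0

    def test_top_ranks_closed_form(self):
        t = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("ABCDE"))
        res = prot.preranked_gsea(t, {"top2": ["A", "B"]}, nperm=100, seed=0)
        # P_hit reaches 1 after the top two while P_miss is still 0
        assert res.loc["top2", "ES"] == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        t = pd.Series(rng.normal(size=40), index=[f"P{i}" for i in range(40)])
        sets = {"s": [f"P{i}" for i in range(0, 12)]}
        a = prot.preranked_gsea(t, sets, nperm=200, seed=3)
        b = prot.preranked_gsea(t, sets, nperm=200, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_set_raises(self):
        t = pd.Series([1.0, 2.0], index=list("AB"))
        with pytest.raises(ValueError):
            prot.preranked_gsea(t, {"s": list("ABCD")}, nperm=100)


class TestGroupTestScores:
    def test_separated_scores_exact_p(self, toy_dataset):
        _, design, _ = toy_dataset
        sub = design.iloc[list(range(3)) + list(range(20, 23))]
        scores = pd.DataFrame(
            [[1.0, 2.0, 3.0, 10.0, 11.0, 12.0]], index=["s"],
            columns=sub.index)
        res = prot.group_test_scores(scores, sub, "site")
        assert res.loc["s", "p"] == pytest.approx(0.1)

    def test_q_at_least_p(self, toy_dataset):
        mat, design, _ = toy_dataset
        sets = {"a": [f"P{i:05d}" for i in range(10)],
                "b": [f"P{i:05d}" for i in range(20, 40)]}
        scores, _ = prot.ssgsea_scores(mat, sets)
        res = prot.group_test_scores(scores, design, "site")
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_single_level_factor_raises(self, toy_dataset):
        mat, design, _ = toy_dataset
        scores = pd.DataFrame(np.ones((1, len(design))), index=["s"],
                              columns=design.index)
        mono = design.copy()
        mono["site"] = "mandibular"
        with pytest.raises(ValueError):
            prot.group_test_scores(scores, mono, "site")


class TestGmtRoundtrip:
    def test_write_then_read(self, tmp_path):
        sets = {"a": ["P1", "P2"], "b": ["P3", "P4", "P5"]}
        path = tmp_path / "sets.gmt"
        prot.write_gmt(sets, path)
        assert prot.read_gmt(path) == sets


class TestOverrepresentation:
    def test_enriched_set_detected(self):
        universe = [f"P{i}" for i in range(100)]
        sets = {"hit_set": universe[:10], "other": universe[50:70]}
        res = prot.overrepresentation(universe[:8], universe, sets)
        assert res.loc["hit_set", "p"] < 1e-6
        assert res.loc["other", "p"] > 0.5
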