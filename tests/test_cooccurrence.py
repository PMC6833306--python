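import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway
from statsmodels.stats.multitest import multipletests

from zetascape import CommunityMatrix, c_score, nodf, perm_anova, range_stats, vif_screen
from zetascape.cooccurrence import _holm

from _oracles import c_score_brute, nodf_brute
from conftest import random_community


class TestRangeStats:
    def test_toy_values(self, toy_matrix, toy_sites):
        df = range_stats(toy_matrix, toy_sites)
        # sp1 occupies all sites (elev 100, 300, 600)
        row = df.loc["sp1"]
        assert row["mean_elevation"] == pytest.approx(1000.0 / 3.0)
        assert row["min_elevation"] == 100.0
        assert row["max_elevation"] == 600.0
        assert row["elevation_range"] == 500.0
        assert row["range_ratio"] == pytest.approx(1.0)
        assert df.loc["sp3", "range_ratio"] == pytest.approx(1.0 / 3.0)
        assert df.loc["sp3", "elevation_range"] == 0.0
        assert df["category"].tolist() == ["NON_E", "NE", "PE"]

    def test_zero_occupancy_species(self, toy_sites):
        cm = CommunityMatrix(
            ["A", "B", "C"], ["u", "v"], np.array([[1, 0], [1, 0], [0, 0]])
        )
        df = range_stats(cm, toy_sites)
        assert np.isnan(df.loc["v", "mean_elevation"])
        assert df.loc["v", "range_ratio"] == 0.0


class TestPermAnova:
    def test_f_matches_scipy(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            groups = np.repeat(["a", "b", "c"], [12, 9, 7])
            values = rng.normal(size=len(groups)) + (groups == "b") * rng.normal()
            res = perm_anova(values, groups, n_perm=99, seed=1, posthoc=False)
            blocks = [values[groups == g] for g in ("a", "b", "c")]
            assert res.f_statistic == pytest.approx(f_oneway(*blocks).statistic)

    def test_extreme_separation_floor_p(self):
        values = np.concatenate([np.zeros(10), np.full(10, 100.0)])
        groups = np.repeat(["lo", "hi"], 10)
        res = perm_anova(values, groups, n_perm=499, seed=0, posthoc=False)
        assert res.p_value == pytest.approx(1.0 / 500.0)

    def test_null_p_not_small(self):
        rng = np.random.default_rng(100)
        values = rng.normal(size=40)
        groups = np.repeat(["a", "b"], 20)
        res = perm_anova(values, groups, n_perm=999, seed=2, posthoc=False)
        assert res.p_value > 0.05

    def test_small_group_excluded_with_warning(self):
        values = np.arange(11, dtype=float)
        groups = np.array(["a"] * 5 + ["b"] * 5 + ["c"])
        with pytest.warns(UserWarning, match="excluded"):
            res = perm_anova(values, groups, n_perm=99, seed=0, posthoc=False)
        assert res.excluded == ["c"]
        assert res.groups == ["a", "b"]

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="2 groups"):
            perm_anova(np.arange(5.0), np.array(["a"] * 5), n_perm=9)

    def test_nan_values_dropped(self):
        values = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0, 8.0])
        groups = np.repeat(["a", "b"], 4)
        res = perm_anova(values, groups, n_perm=99, seed=0, posthoc=False)
        clean = perm_anova(
            np.array([1.0, 2.0, 4.0, 5.0, 6.0, 7.0, 8.0]),
            np.array(["a", "a", "a", "b", "b", "b", "b"]),
            n_perm=99,
            seed=0,
            posthoc=False,
        )
        assert res.f_statistic == pytest.approx(clean.f_statistic)

    def test_posthoc_pairs_and_adjustment(self):
        rng = np.random.default_rng(21)
        groups = np.repeat(["a", "b", "c"], 15)
        values = rng.normal(size=45) + (groups == "c") * 3.0
        res = perm_anova(values, groups, n_perm=499, seed=3)
        ph = res.posthoc
        assert sorted(zip(ph["group_a"], ph["group_b"])) == [
            ("a", "b"),
            ("a", "c"),
            ("b", "c"),
        ]
        assert (ph["p_adjusted"] >= ph["p_raw"] - 1e-12).all()
        assert (ph["p_adjusted"] <= 1.0).all()
        # the separated group's comparisons are significant, the other is not
        sig = ph.set_index(["group_a", "group_b"])["p_adjusted"]
        assert sig[("a", "c")] < 0.05 and sig[("b", "c")] < 0.05
        assert sig[("a", "b")] > 0.05

    def test_deterministic(self):
        rng = np.random.default_rng(50)
        values = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        r1 = perm_anova(values, groups, n_perm=199, seed=11)
        r2 = perm_anova(values, groups, n_perm=199, seed=11)
        assert r1.p_value == r2.p_value
        pd.testing.assert_frame_equal(r1.posthoc, r2.posthoc)


class TestHolm:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            p = rng.random(rng.integers(2, 8))
            expected = multipletests(p, method="holm")[1]
            assert np.allclose(_holm(p), expected)


class TestCScore:
    def test_checkerboard_is_one(self):
        inc = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        cm = CommunityMatrix(list("abcd"), ["x", "y"], inc)
        assert c_score(cm) == pytest.approx(1.0)

    def test_identical_distributions_zero(self):
        inc = np.array([[1, 1], [1, 1], [0, 0]])
        cm = CommunityMatrix(list("abc"), ["x", "y"], inc)
        assert c_score(cm) == pytest.approx(0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(71)
        for _ in range(25):
            cm = random_community(rng, 6, 6, p_low=0.3, p_high=0.7)
            if (cm.occupancy() > 0).sum() < 2:
                continue
            assert c_score(cm) == pytest.approx(c_score_brute(cm.incidence))

    def test_single_species_raises(self):
        cm = CommunityMatrix(["a", "b"], ["x"], np.array([[1], [0]]))
        with pytest.raises(ValueError, match="2 species"):
            c_score(cm)


class TestNODF:
    def test_triangular_is_100(self):
        inc = np.tril(np.ones((5, 5), dtype=int))
        cm = CommunityMatrix(
            [f"s{i}" for i in range(5)], [f"x{j}" for j in range(5)], inc
        )
        assert nodf(cm) == pytest.approx(100.0)

    def test_checkerboard_is_zero(self):
        inc = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        cm = CommunityMatrix(list("abcd"), ["x", "y"], inc)
        assert nodf(cm) == pytest.approx(0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(72)
        for _ in range(25):
            cm = random_community(rng, 5, 6, p_low=0.2, p_high=0.8)
            assert nodf(cm) == pytest.approx(nodf_brute(cm.incidence))

    def test_too_small_raises(self):
        cm = CommunityMatrix(["a"], ["x", "y"], np.array([[1, 0]]))
        with pytest.raises(ValueError, match="at least 2"):
            nodf(cm)


class TestVIF:
    def _frame(self, n=60, seed=6):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        return pd.DataFrame({"a": a, "b": b}), rng

    def test_independent_covariates_retained(self):
        df, _ = self._frame()
        retained, dropped = vif_screen(df, ["a", "b"])
        assert retained == ["a", "b"] and dropped == []

    def test_exact_duplicate_dropped_first(self):
        df, _ = self._frame()
        df["a_copy"] = df["a"]
        retained, dropped = vif_screen(df, ["a", "b", "a_copy"])
        assert len(retained) == 2 and "b" in retained
        assert dropped[0][1] == np.inf

    def test_constructed_vif_threshold(self):
        # x3 = x1 + noise with R^2 ~ 0.95 -> VIF ~ 20: dropped at threshold
        # 10, retained at threshold 30
        rng = np.random.default_rng(9)
        a = rng.normal(size=400)
        b = rng.normal(size=400)
        c = a + np.sqrt(1 / 19) * rng.normal(size=400)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        retained_10, dropped_10 = vif_screen(df, ["a", "b", "c"], threshold=10)
        assert len(retained_10) == 2 and "b" in retained_10
        assert dropped_10[0][1] == pytest.approx(20.0, rel=0.5)
        retained_30, _ = vif_screen(df, ["a", "b", "c"], threshold=30)
        assert retained_30 == ["a", "b", "c"]

    def test_input_order_preserved(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {"z": rng.normal(size=50), "m": rng.normal(size=50), "k": rng.normal(size=50)}
        )
        retained, _ = vif_screen(df, ["z", "m", "k"])
        assert retained == ["z", "m", "k"]

    def test_validation(self):
        df, _ = self._frame(n=2)
        with pytest.raises(ValueError, match="2 candidate"):
            vif_screen(df, ["a"])
        with pytest.raises(ValueError, match="more sites"):
            vif_screen(df, ["a", "b"])
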