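import numpy as np
import pandas as pd
import pytest

from zetascape import (
    ISplineBasis,
    build_design,
    fit_msgdm,
    ispline_transform,
    run_model_suite,
)
from zetascape.msgdm import MSGDMDesign, _mean_pairwise
from zetascape.zeta import records_for_combinations, sample_combinations

from conftest import random_community


class TestISpline:
    def test_closed_form_values(self):
        """Order-2 I-splines with one interior knot at 0.5 have simple
        piecewise-quadratic closed forms; check against hand-derived values."""
        basis = ISplineBasis(order=2, n_basis=3)
        x = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        got = basis.transform(x)
        # I1 = 4x(1-x) on [0,.5] then 1; I2 = 2x^2 then 1-2(1-x)^2;
        # I3 = 0 then (2x-1)^2
        expected = np.array(
            [
                [0.0, 0.0, 0.0],
                [0.75, 0.125, 0.0],
                [1.0, 0.5, 0.0],
                [1.0, 0.875, 0.25],
                [1.0, 1.0, 1.0],
            ]
        )
        assert np.allclose(got, expected)

    def test_boundary_and_monotone(self):
        basis = ISplineBasis()
        grid = np.linspace(0, 1, 101)
        vals = basis.transform(grid)
        assert np.allclose(vals[0], 0.0)
        assert np.allclose(vals[-1], 1.0)
        assert (np.diff(vals, axis=0) >= -1e-12).all()

    def test_more_basis_functions(self):
        basis = ISplineBasis(order=2, n_basis=5)
        vals = basis.transform(np.linspace(0, 1, 51))
        assert vals.shape == (51, 5)
        assert np.allclose(vals[0], 0.0) and np.allclose(vals[-1], 1.0)
        assert (np.diff(vals, axis=0) >= -1e-12).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match="rescale"):
            ISplineBasis().transform(np.array([-0.1]))

    def test_invalid_config_raises(self):
        with pytest.raises(ValueError, match="n_basis"):
            ISplineBasis(order=3, n_basis=2)

    def test_functional_wrapper(self):
        x = np.array([0.3, 0.6])
        assert np.allclose(ispline_transform(x), ISplineBasis().transform(x))


class TestBuildDesign:
    def test_toy_columns(self, toy_matrix, toy_sites):
        combos = np.array([[0, 1], [0, 2], [1, 2]])
        recs = records_for_combinations(toy_matrix, combos)
        d = build_design(toy_matrix, toy_sites, 2, recs, ["elevation"])
        # responses: Sorensen zeta of pairs (A,B), (A,C), (B,C)
        assert d.response == pytest.approx([0.8, 0.5, 2.0 / 3.0])
        # |elevation diffs| = 200, 500, 300 -> min-max scaled
        assert d.predictors["elevation"].to_numpy() == pytest.approx(
            [0.0, 1.0, 1.0 / 3.0]
        )
        # distances: 10, 10, 10*sqrt(2) -> scaled 0, 0, 1
        assert d.predictors["distance"].to_numpy() == pytest.approx([0.0, 0.0, 1.0])

    def test_max_summary(self, toy_matrix, toy_sites):
        combos = np.array([[0, 1], [0, 2]])
        recs = records_for_combinations(toy_matrix, combos)
        d = build_design(toy_matrix, toy_sites, 2, recs, ["elevation"], summary="max")
        # max pairwise diff equals the pair diff here: 200, 500 -> scaled 0, 1
        assert d.predictors["elevation"].to_numpy() == pytest.approx([0.0, 1.0])

    def test_mean_pairwise_triplet(self):
        vals = np.array([0.0, 2.0, 6.0])
        combos = np.array([[0, 1, 2]])
        # pairwise |diffs| 2, 6, 4 -> mean 4
        assert _mean_pairwise(vals, combos)[0] == pytest.approx(4.0)

    def test_constant_covariate_dropped(self, toy_matrix, toy_sites):
        st = toy_sites
        st.data["flat"] = 7.0
        combos = np.array([[0, 1], [1, 2]])
        recs = records_for_combinations(toy_matrix, combos)
        with pytest.warns(UserWarning, match="flat"):
            d = build_design(toy_matrix, st, 2, recs, ["flat", "elevation"])
        assert d.dropped == ["flat"]
        assert "flat" not in d.predictors.columns

    def test_unknown_covariate_raises(self, toy_matrix, toy_sites):
        combos = np.array([[0, 1]])
        recs = records_for_combinations(toy_matrix, combos)
        with pytest.raises(KeyError, match="humidity"):
            build_design(toy_matrix, toy_sites, 2, recs, ["humidity"])

    def test_wrong_order_raises(self, toy_matrix, toy_sites):
        recs = records_for_combinations(toy_matrix, np.array([[0, 1]]))
        with pytest.raises(ValueError, match="order"):
            build_design(toy_matrix, toy_sites, 3, recs, ["elevation"])

    def test_biotic_column_tracks_other_category(self, toy_sites):
        rng = np.random.default_rng(31)
        cm = random_community(rng, 3, 20)
        st = type(toy_sites)(toy_sites.data.set_axis(cm.sites))
        combos = np.array([[0, 1], [0, 2], [1, 2]])
        recs = records_for_combinations(cm, combos)
        d = build_design(
            cm, st, 2, recs, ["elevation"], biotic_cm=cm, biotic_name="self"
        )
        # the biotic matrix is the focal matrix itself: its dissimilarity is
        # exactly 1 - response, so after min-max scaling the column must be
        # perfectly anticorrelated with the response
        r = np.corrcoef(d.response, d.predictors["self"])[0, 1]
        assert r == pytest.approx(-1.0)

    def test_biotic_site_mismatch_raises(self, toy_matrix, toy_sites):
        rng = np.random.default_rng(1)
        other = random_community(rng, 4, 5)
        recs = records_for_combinations(toy_matrix, np.array([[0, 1]]))
        with pytest.raises(ValueError, match="site set"):
            build_design(
                toy_matrix, toy_sites, 2, recs, ["elevation"], biotic_cm=other
            )


class TestFitMSGDM:
    def _signal_design(self, n=600, seed=42, n_noise=3):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({f"p{j}": rng.random(n) for j in range(1 + n_noise)})
        response = 1.0 - (0.1 + 0.8 * X["p0"] ** 1.5)  # similarity falls with p0
        return MSGDMDesign(
            response=response.to_numpy(), predictors=X, order=2, scheme="sorensen"
        )

    def test_signal_recovery(self):
        fit = fit_msgdm(self._signal_design())
        assert fit.variance_explained > 0.99
        imps = fit.importance
        assert max(imps, key=imps.get) == "p0"
        assert all(imps[k] < 0.1 * imps["p0"] for k in imps if k != "p0")

    def test_importance_is_coefficient_sum(self):
        fit = fit_msgdm(self._signal_design())
        for name, coefs in fit.coefficients.items():
            assert fit.importance[name] == pytest.approx(coefs.sum())
            assert (coefs >= 0).all()

    def test_predictions_monotone_in_each_predictor(self):
        fit = fit_msgdm(self._signal_design())
        rng = np.random.default_rng(0)
        base = pd.DataFrame(
            {name: rng.random(20) for name in fit.predictor_names}
        )
        for name in fit.predictor_names:
            prev = None
            for v in np.linspace(0, 1, 11):
                cur = base.copy()
                cur[name] = v
                pred = fit.predict_dissimilarity(cur)
                if prev is not None:
                    assert (pred >= prev - 1e-9).all()
                prev = pred

    def test_noise_response_unexplained(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({f"p{j}": rng.random(1000) for j in range(4)})
        d = MSGDMDesign(response=rng.random(1000), predictors=X, order=2, scheme="sorensen")
        assert fit_msgdm(d).variance_explained < 0.05

    def test_duplicate_predictor_flagged(self):
        rng = np.random.default_rng(5)
        x = rng.random(200)
        X = pd.DataFrame({"a": x, "b": x})
        d = MSGDMDesign(response=1 - x, predictors=X, order=2, scheme="sorensen")
        fit = fit_msgdm(d)
        assert set(fit.flagged) == {"a", "b"}
        # the joint surface is still recovered even if attribution is split
        assert fit.variance_explained > 0.99

    def test_small_design_warns(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.random(20)})
        d = MSGDMDesign(response=rng.random(20), predictors=X, order=2, scheme="sorensen")
        with pytest.warns(UserWarning, match="10 records"):
            fit_msgdm(d)

    def test_deterministic(self):
        d = self._signal_design()
        f1, f2 = fit_msgdm(d), fit_msgdm(d)
        assert f1.intercept == f2.intercept
        for name in f1.predictor_names:
            assert np.array_equal(f1.coefficients[name], f2.coefficients[name])


class TestModelSuite:
    def _study(self, seed=13, n_sites=30):
        rng = np.random.default_rng(seed)
        parts = []
        species, category = [], {}
        for label, count in (("NON_E", 120), ("NE", 30), ("PE", 25)):
            inc = (rng.random((n_sites, count)) < 0.25).astype(np.int8)
            names = [f"{label}_{j}" for j in range(count)]
            species += names
            category.update({n: label for n in names})
            parts.append(inc)
        from zetascape import CommunityMatrix, SiteTable

        cm = CommunityMatrix(
            [f"s{i}" for i in range(n_sites)], species, np.hstack(parts), category
        )
        st = SiteTable(
            pd.DataFrame(
                {
                    "x": rng.uniform(0, 50, n_sites),
                    "y": rng.uniform(0, 50, n_sites),
                    "elevation": rng.uniform(0, 2000, n_sites),
                },
                index=cm.sites,
            )
        )
        return cm, st

    def test_structure_and_determinism(self):
        cm, st = self._study()
        fits = run_model_suite(cm, st, "NE", [2, 3], n_samples=150, seed=5)
        assert set(fits) == {2, 3}
        assert set(fits[2]) == {"abiotic", "biotic1", "biotic2"}
        again = run_model_suite(cm, st, "NE", [2, 3], n_samples=150, seed=5)
        for o in (2, 3):
            for m in fits[o]:
                assert fits[o][m].variance_explained == again[o][m].variance_explained

    def test_biotic1_undefined_for_non_endemics(self):
        cm, st = self._study()
        with pytest.raises(ValueError, match="non-endemic"):
            run_model_suite(cm, st, "NON_E", [2], n_samples=50)
        fits = run_model_suite(
            cm, st, "NON_E", [2], n_samples=100, seed=3, models=("abiotic",)
        )
        assert set(fits[2]) == {"abiotic"}

    def test_biotic_models_add_one_predictor(self):
        cm, st = self._study()
        fits = run_model_suite(cm, st, "PE", [2], n_samples=150, seed=9)
        names_a = set(fits[2]["abiotic"].predictor_names)
        names_b1 = set(fits[2]["biotic1"].predictor_names)
        names_b2 = set(fits[2]["biotic2"].predictor_names)
        assert names_b1 - names_a == {"zeta_NON_E"}
        assert names_b2 - names_a == {"zeta_NE"}
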