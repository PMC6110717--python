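import inspect

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from conflictscope import (EnsembleModel, auc, crossval_auc,
                           extract_covariates, fit_ensemble,
                           make_pseudoabsences, predict_surface,
                           screen_collinearity, tss, variable_importance)
from conflictscope.errors import ValidationError
from conflictscope.raster import RasterGrid
from conflictscope.riskmap import _vifs, default_members
from conflictscope.synthgen import LandscapeBundle


class FixedProbability(BaseEstimator, ClassifierMixin):
    """Stub member whose probability is a fixed function of the features."""

    def __init__(self, fn=None):
        self.fn = fn

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p = np.clip(self.fn(np.asarray(X)), 1e-9, 1 - 1e-9)
        return np.column_stack([1 - p, p])


def make_bundle(**named_values):
    rasters = {name: RasterGrid(values=np.asarray(vals, dtype=float),
                                origin=(0.0, 0.0), cell_size=1.0)
               for name, vals in named_values.items()}
    ref = next(iter(rasters.values()))
    return LandscapeBundle(rasters=rasters, extent=(ref.shape[1], ref.shape[0]),
                           cell_size=1.0, seed=0)


class TestExtraction:
    def test_constant_raster_extracts_constant(self):
        bundle = make_bundle(flat=np.full((6, 6), 5.0))
        pts = pd.DataFrame({"x": [1.2, 4.9], "y": [3.3, 0.1]})
        table = extract_covariates(pts, bundle, radius=1.5)
        assert (table["flat"] == 5.0).all()

    def test_plus_shaped_buffer_mean(self):
        # 3x3 grid; radius 1 around the centre reaches the 4-neighbourhood
        vals = np.arange(9, dtype=float).reshape(3, 3)
        bundle = make_bundle(v=vals)
        pts = pd.DataFrame({"x": [1.5], "y": [1.5]})
        table = extract_covariates(pts, bundle, radius=1.0)
        expected = np.mean([vals[1, 1], vals[0, 1], vals[2, 1], vals[1, 0], vals[1, 2]])
        assert table["v"].iloc[0] == pytest.approx(expected)

    def test_default_radius_is_village_scale(self):
        assert inspect.signature(extract_covariates).parameters["radius"].default == 3.25

    def test_empty_buffer_flagged(self):
        vals = np.full((4, 4), -9999.0)
        vals[3, 3] = 1.0
        bundle = make_bundle(v=vals)
        with pytest.warns(UserWarning, match="empty buffers"):
            table = extract_covariates(pd.DataFrame({"x": [0.5], "y": [0.5]}),
                                       bundle, radius=0.6)
        assert np.isnan(table["v"].iloc[0])


class TestScreening:
    def test_duplicated_column_drops_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        table = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=200)})
        kept, report = screen_collinearity(table)
        assert kept.shape[1] == 2 and "c" in kept.columns
        assert len(report) == 1

    def test_orthogonal_columns_kept(self):
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.normal(size=(100, 3)))
        table = pd.DataFrame(q, columns=["a", "b", "c"])
        kept, report = screen_collinearity(table)
        assert list(kept.columns) == ["a", "b", "c"]
        assert report.empty

    def test_linear_combination_dropped_and_vif_oracle(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=500)
        x2 = rng.normal(size=500)
        x3 = x1 + x2 + rng.normal(scale=0.05, size=500)
        table = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        vifs = _vifs(table)
        # oracle: VIF_j = 1 / (1 - R^2_j) via direct OLS
        z = (table - table.mean()) / table.std(ddof=0)
        for j, name in enumerate(table.columns):
            others = z.drop(columns=[name]).to_numpy()
            coef, *_ = np.linalg.lstsq(others, z[name].to_numpy(), rcond=None)
            r2 = 1 - np.var(z[name].to_numpy() - others @ coef) / np.var(z[name])
            assert vifs[name] == pytest.approx(1 / (1 - r2), rel=1e-6)
        kept, report = screen_collinearity(table)
        assert report.iloc[0]["column"] == vifs.idxmax()
        assert kept.shape[1] == 2

    def test_constant_column_dropped_with_warning(self):
        table = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
        with pytest.warns(UserWarning, match="constant"):
            kept, report = screen_collinearity(table)
        assert list(kept.columns) == ["b"]


class TestPseudoAbsences:
    def test_points_fall_inside_mask(self, landscape):
        pts = make_pseudoabsences(landscape, n=500, seed=3)
        fc = landscape.rasters["for_cov"]
        vals = fc.value_at(pts["x"].to_numpy(), pts["y"].to_numpy())
        assert (vals < 0.5).all()

    def test_default_background_size(self):
        assert inspect.signature(make_pseudoabsences).parameters["n"].default == 10_000

    def test_uniform_over_mask_cells(self):
        mask = RasterGrid(values=np.ones((10, 10)), origin=(0.0, 0.0), cell_size=1.0)
        bundle = make_bundle(for_cov=np.zeros((10, 10)))
        with pytest.warns(UserWarning, match="replacement"):
            pts = make_pseudoabsences(bundle, mask=mask, n=50_000, seed=4)
        rows, cols = mask.cell_of(pts["x"].to_numpy(), pts["y"].to_numpy())
        counts = np.bincount(rows * 10 + cols, minlength=100)
        from scipy.stats import chisquare
        stat, p = chisquare(counts)
        assert p > 0.01

    def test_oversampling_warns(self):
        bundle = make_bundle(for_cov=np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="replacement"):
            make_pseudoabsences(bundle, n=100, seed=5)


class TestScores:
    def test_auc_trivials_and_example(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5
        assert auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(6)
        s = rng.uniform(size=80).round(1)  # coarse scores force ties
        y = rng.integers(0, 2, 80)
        assert auc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_tss_trivials_and_example(self):
        assert tss([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert tss([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.0
        assert tss([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc([0.1, 0.2], [1, 1])
        with pytest.raises(ValidationError):
            tss([0.1, 0.2], [0, 0])


class TestCrossval:
    def test_separable_data_scores_one(self):
        x = pd.DataFrame({"a": np.r_[np.zeros(50), np.ones(50)]})
        y = np.r_[np.zeros(50), np.ones(50)]
        member = default_members(0)["glm"]
        assert crossval_auc(member, x, y, seed=7) == 1.0

    def test_null_features_score_half(self):
        rng = np.random.default_rng(8)
        x = pd.DataFrame({"a": rng.normal(size=2000), "b": rng.normal(size=2000)})
        y = rng.integers(0, 2, 2000)
        member = default_members(0)["glm"]
        assert 0.45 <= crossval_auc(member, x, y, seed=8) <= 0.55

    def test_protocol_defaults(self):
        sig = inspect.signature(crossval_auc)
        assert sig.parameters["reps"].default == 10
        assert sig.parameters["train_frac"].default == 0.7


class TestEnsemble:
    @staticmethod
    def _toy_data(n=300, seed=9):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        p = 1 / (1 + np.exp(-(2.5 * x["a"])))
        y = (rng.uniform(size=n) < p).astype(int)
        return x, y.to_numpy()

    def test_single_passing_member_is_the_ensemble(self):
        x, y = self._toy_data()
        members = {"glm": default_members(0)["glm"]}
        ens = fit_ensemble(x, y, members=members, seed=9, reps=3)
        np.testing.assert_allclose(ens.predict(x),
                                   ens.member_predictions(x)["glm"])

    def test_known_tss_gives_known_weights(self):
        x, y = self._toy_data()
        members = {
            "m1": FixedProbability(lambda X: 1 / (1 + np.exp(-3 * X[:, 0]))),
            "m2": FixedProbability(lambda X: 1 / (1 + np.exp(-1.2 * X[:, 0]))),
        }
        ens = fit_ensemble(x, y, members=members, seed=10, reps=3)
        t1, t2 = ens.tss_raw["m1"], ens.tss_raw["m2"]
        assert ens.tss_weight["m1"] == pytest.approx(t1 / (t1 + t2))
        # weighted-mean oracle on fixed prediction vectors
        preds = ens.member_predictions(x)
        expected = (preds["m1"] * ens.tss_weight["m1"]
                    + preds["m2"] * ens.tss_weight["m2"])
        np.testing.assert_allclose(ens.predict(x), expected)

    def test_weight_arithmetic(self):
        # TSS 0.6 and 0.2 renormalise to 0.75 / 0.25
        t = {"a": 0.6, "b": 0.2}
        total = sum(t.values())
        assert t["a"] / total == pytest.approx(0.75)
        assert t["b"] / total == pytest.approx(0.25)

    def test_ensemble_is_convex_combination(self):
        x, y = self._toy_data(seed=11)
        members = {k: v for k, v in default_members(0).items() if k in ("glm", "gbm")}
        ens = fit_ensemble(x, y, members=members, seed=11, reps=3)
        preds = ens.member_predictions(x)
        combo = ens.predict(x)
        assert (combo >= preds.min(axis=1) - 1e-12).all()
        assert (combo <= preds.max(axis=1) + 1e-12).all()

    def test_no_passing_member_errors_with_values(self):
        rng = np.random.default_rng(12)
        x = pd.DataFrame({"a": rng.normal(size=300)})
        y = rng.integers(0, 2, 300)
        with pytest.raises(ValidationError, match="AUC"):
            fit_ensemble(x, y, members={"glm": default_members(0)["glm"]},
                         seed=12, reps=3)

    def test_cv_auc_tracks_bayes_auc_on_known_logistic_risk(self):
        # ensemble members should approach the Bayes AUC implied by the
        # true success probabilities
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            n = 2000
            x = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
            p = 1 / (1 + np.exp(-(1.5 * x["a"] - 1.0 * x["b"])))
            y = (rng.uniform(size=n) < p).astype(int).to_numpy()
            bayes = auc(p, y)
            members = {"glm": default_members(seed)["glm"]}
            ens = fit_ensemble(x, y, members=members, seed=seed, reps=5)
            assert abs(ens.cv_auc["glm"] - bayes) < 0.05


class TestSurfaceAndImportance:
    def test_flat_member_gives_flat_surface(self):
        bundle = make_bundle(a=np.random.default_rng(13).uniform(size=(8, 8)))
        x = pd.DataFrame({"a": np.linspace(-1, 1, 100)})
        y = np.r_[np.zeros(50), np.ones(50)]
        const = FixedProbability(lambda X: np.full(len(X), 0.37))
        ens = EnsembleModel(members={"c": const.fit(x, y)},
                            cv_auc={"c": 1.0}, tss_weight={"c": 1.0},
                            tss_raw={"c": 0.0},
                            scaler_mean=x.mean(), scaler_sd=x.std(ddof=0),
                            columns=("a",))
        surf = predict_surface(ens, bundle)
        np.testing.assert_allclose(surf.valid_values(), 0.37)

    def test_surface_matches_point_predictions_at_cell_centres(self):
        rng = np.random.default_rng(14)
        bundle = make_bundle(a=rng.uniform(size=(10, 10)),
                             b=rng.uniform(size=(10, 10)))
        cx, cy = bundle.grid.cell_centers()
        pts = pd.DataFrame({"x": cx.ravel()[:40], "y": cy.ravel()[:40]})
        table = extract_covariates(pts, bundle, radius=0.4)  # buffer = own cell
        y = rng.integers(0, 2, 40)
        y[:3] = 1
        y[3:6] = 0
        ens = fit_ensemble(table, y, members={"glm": default_members(0)["glm"]},
                           seed=14, reps=2, auc_min=-1.0)
        surf = predict_surface(ens, bundle)
        rows, cols = bundle.grid.cell_of(pts["x"].to_numpy(), pts["y"].to_numpy())
        np.testing.assert_allclose(surf.values[rows, cols], ens.predict(table),
                                   atol=1e-6)

    def test_surface_bounded_probabilities(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            bundle = make_bundle(a=rng.uniform(size=(8, 8)),
                                 b=rng.uniform(size=(8, 8)))
            x, y = TestEnsemble._toy_data(seed=seed)
            x.columns = ["a", "b"]
            ens = fit_ensemble(x, y, members={"glm": default_members(0)["glm"]},
                               seed=seed, reps=2)
            v = predict_surface(ens, bundle).valid_values()
            assert v.min() >= 0 and v.max() <= 1

    def test_inert_variable_has_r_near_one(self):
        rng = np.random.default_rng(15)
        n = 400
        x = pd.DataFrame({"a": rng.normal(size=n), "junk": rng.normal(size=n)})
        member = FixedProbability(lambda X: 1 / (1 + np.exp(-2 * X[:, 0])))
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-2 * x["a"]))).astype(int)
        ens = fit_ensemble(x, y.to_numpy(), members={"m": member}, seed=15, reps=2)
        imp = variable_importance(ens, x, perms=5, seed=15)
        assert imp["junk"] == pytest.approx(1.0, abs=1e-9)
        assert imp["a"] < 0.5  # the sole informative variable
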