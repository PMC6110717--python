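import numpy as np
import pandas as pd
import pytest

from conflictscope import (TruthParams, aicc, attach_risk_covariates,
                           compare_models, cronbach_alpha, evidence_ratio,
                           fit_multinomial, gen_survey, prepare_responses,
                           scale_diagnostics)
from conflictscope.errors import ValidationError
from conflictscope.raster import RasterGrid
from conflictscope.tolerance import (MultinomialFit, all_subsets,
                                     fitted_probabilities, standard_model_set)


def make_survey(n, villages, seed=0, **truth_kwargs):
    truth = TruthParams(**truth_kwargs)
    return gen_survey(villages, None, truth, n, seed=seed)


def stub_fit(ll, K, n, terms=(), name=""):
    empty = pd.DataFrame(np.zeros((1, 2)), index=["Intercept"],
                         columns=["same", "increase"])
    ses = pd.DataFrame(np.ones((1, 2)), index=["Intercept"],
                       columns=["same", "increase"])
    return MultinomialFit(coefficients=empty, standard_errors=ses,
                          log_likelihood=ll, K=K, n=n, terms=tuple(terms),
                          name=name)


class TestPrepare:
    def test_exclusion_counts(self, villages):
        sv = make_survey(2386, villages, seed=1, dontknow_rate=0.0, missing_rate=0.0)
        sv.loc[sv.index[:107], "tolerance"] = "dont_know"
        sv.loc[sv.index[107:137], "tolerance"] = "missing"
        table, report = prepare_responses(sv)
        assert report == {"n_input": 2386, "n_dont_know": 107,
                          "n_missing": 30, "n_retained": 2249}
        assert len(table) == 2249

    def test_no_exclusions_keeps_all_rows(self, villages):
        sv = make_survey(200, villages, seed=2, dontknow_rate=0.0, missing_rate=0.0)
        table, report = prepare_responses(sv)
        assert len(table) == 200 and report["n_retained"] == 200

    def test_scenario_mean_after_orientation(self, villages):
        sv = make_survey(10, villages, seed=3, dontknow_rate=0.0, missing_rate=0.0)
        sv[["ScenA", "ScenB", "ScenC", "ScenD"]] = [1, 2, 3, 4]
        table, _ = prepare_responses(sv, standardize=False)
        assert (table["Scenario"] == 2.5).all()

    def test_reverse_keyed_items_reoriented(self, villages):
        sv = make_survey(500, villages, seed=4, dontknow_rate=0.0, missing_rate=0.0)
        table, _ = prepare_responses(sv, standardize=False)
        # after orientation all items share the pro-conservation direction
        assert table["Kill_tiger"].corr(table["Protect_tiger"]) > 0

    def test_all_excluded_errors(self, villages):
        sv = make_survey(20, villages, seed=5)
        sv["tolerance"] = "dont_know"
        with pytest.raises(ValidationError):
            prepare_responses(sv)


class TestScaleDiagnostics:
    def test_alpha_of_perfectly_correlated_pair(self):
        x = np.random.default_rng(0).normal(size=300)
        assert cronbach_alpha(pd.DataFrame({"a": x, "b": x})) == pytest.approx(1.0)

    def test_alpha_closed_form_two_items(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        y = 0.6 * x + 0.8 * rng.normal(size=2000)
        df = pd.DataFrame({"a": x, "b": y})
        df = (df - df.mean()) / df.std(ddof=1)  # equal unit variances
        r = df["a"].corr(df["b"])
        assert cronbach_alpha(df) == pytest.approx(2 * r / (1 + r), abs=1e-10)

    def test_one_factor_items_pass_adequacy(self, villages):
        sv = make_survey(2000, villages, seed=6)
        diag = scale_diagnostics(sv[["ScenA", "ScenB", "ScenC", "ScenD"]])
        assert 0 < diag["cronbach_alpha"] <= 1
        assert diag["kmo_overall"] > 0.6
        assert all(v > 0.6 for v in diag["kmo_per_item"].values())
        assert diag["first_factor_variance_pct"] > 25.0  # dominant factor
        # stronger scenarios load harder, mirroring attack > sighting items
        assert diag["loadings"]["ScenC"] > diag["loadings"]["ScenA"]

    def test_zero_variance_item_named(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [2, 2, 2, 2]})
        with pytest.raises(ValidationError, match="b"):
            scale_diagnostics(df)


class TestMultinomialFit:
    def test_intercept_only_matches_closed_form(self, villages):
        sv = make_survey(900, villages, seed=7, dontknow_rate=0.0, missing_rate=0.0)
        table, _ = prepare_responses(sv)
        fit = fit_multinomial(table, terms=[])
        counts = table["tolerance"].value_counts()
        n = len(table)
        ll_oracle = sum(c * np.log(c / n) for c in counts)
        assert fit.log_likelihood == pytest.approx(ll_oracle, abs=1e-6)
        probs = fitted_probabilities(fit, table).iloc[0]
        for level in ("reduce_eradicate", "same", "increase"):
            assert probs[level] == pytest.approx(counts[level] / n, abs=1e-6)
        assert fit.K == 2  # two intercepts

    def test_parameter_count_contract(self, villages):
        sv = make_survey(500, villages, seed=8, dontknow_rate=0.0, missing_rate=0.0)
        table, _ = prepare_responses(sv)
        fit = fit_multinomial(table, ["Protect_tiger", "BadGood", "sex"])
        # 2 outcomes x (intercept + 2 numeric + 1 dummy)
        assert fit.K == 2 * 4

    def test_null_predictor_rarely_significant(self, villages):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sv = make_survey(1000, villages, seed=seed,
                             dontknow_rate=0.0, missing_rate=0.0)
            table, _ = prepare_responses(sv)
            table["noise"] = rng.normal(size=len(table))
            fit = fit_multinomial(table, ["noise"])
            z = fit.z_values().loc["noise"].abs()
            hits += int((z < 3).all())
        assert hits >= 19  # |z| < 3 in >= 95% of replicates

    def test_reference_relabelling_preserves_likelihood(self, villages):
        sv = make_survey(600, villages, seed=9, dontknow_rate=0.0, missing_rate=0.0)
        table, _ = prepare_responses(sv)
        a = fit_multinomial(table, ["Protect_tiger"])
        b = fit_multinomial(table, ["Protect_tiger"], ref="same")
        assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-6)

    def test_rank_deficiency_names_aliased_terms(self, villages):
        sv = make_survey(300, villages, seed=10, dontknow_rate=0.0, missing_rate=0.0)
        table, _ = prepare_responses(sv)
        table["dup"] = table["Protect_tiger"]
        with pytest.raises(ValidationError, match="dup"):
            fit_multinomial(table, ["Protect_tiger", "dup"])

    def test_wrong_category_set_rejected(self, villages):
        sv = make_survey(300, villages, seed=11, dontknow_rate=0.0, missing_rate=0.0)
        table, _ = prepare_responses(sv)
        table = table[table["tolerance"] != "increase"]
        with pytest.raises(ValidationError):
            fit_multinomial(table, [])


class TestAICc:
    def test_limit_of_perfect_fit(self):
        assert aicc(stub_fit(0.0, 1, 10_000_000)) == pytest.approx(2.0, abs=1e-3)

    def test_formula_oracle(self):
        fit = stub_fit(-123.456, 7, 250)
        k, n = 7, 250
        expected = -2 * -123.456 + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert aicc(fit) == pytest.approx(expected, abs=1e-10)
        assert aicc(fit, correction=False) == pytest.approx(-2 * -123.456 + 2 * k,
                                                            abs=1e-10)

    def test_small_sample_guard(self):
        with pytest.raises(ValidationError):
            aicc(stub_fit(-10.0, 10, 11))


class TestComparison:
    def test_tied_models_split_importance(self):
        fits = {"with_a": stub_fit(-100.0, 4, 500, terms=("a", "b")),
                "without_a": stub_fit(-100.0, 4, 500, terms=("b",))}
        comp = compare_models(fits)
        assert comp.importance["a"] == pytest.approx(0.5)
        assert comp.importance["b"] == pytest.approx(1.0)
        assert comp.table["weight"].sum() == pytest.approx(1.0)

    def test_evidence_ratio_identity_and_published_deltas(self):
        assert evidence_ratio(100.0, 100.0) == 1.0
        assert round(evidence_ratio(0.0, 6.96)) == 32
        assert round(evidence_ratio(0.0, 6.38)) == 24

    def test_weights_invariant_to_constant_shift(self):
        base = {"a": stub_fit(-100.0, 4, 500, ("x",)),
                "b": stub_fit(-103.0, 4, 500, ("y",))}
        shifted = {k: stub_fit(v.log_likelihood - 50.0, v.K, v.n, v.terms)
                   for k, v in base.items()}
        ca, cb = compare_models(base), compare_models(shifted)
        np.testing.assert_allclose(ca.table["weight"], cb.table["weight"])
        np.testing.assert_allclose(ca.table["delta"], cb.table["delta"])
        assert ca.evidence_ratio("a", "b") == pytest.approx(cb.evidence_ratio("a", "b"))

    def test_single_fit_degenerate(self):
        comp = compare_models({"only": stub_fit(-10.0, 2, 100, ("x",))})
        assert comp.table["weight"].iloc[0] == 1.0
        assert comp.confidence_set == ("only",)

    def test_different_row_counts_rejected(self):
        with pytest.raises(ValidationError):
            compare_models({"a": stub_fit(-1.0, 2, 100),
                            "b": stub_fit(-1.0, 2, 101)})

    def test_all_subsets_cap(self):
        assert len(all_subsets(["a", "b", "c"])) == 8
        from conflictscope.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            all_subsets([f"t{i}" for i in range(20)], cap=4096)

    def test_standard_roster(self):
        roster = standard_model_set(["A", "B"], ["dis_riv"])
        assert set(roster) == {"social", "social+gp", "social+prob",
                               "social+landscape"}
        assert roster["social+gp"] == ("A", "B", "GP")


class TestRiskCovariates:
    def test_village_level_assignment_is_constant_within_village(self, villages):
        rng = np.random.default_rng(12)
        sv = make_survey(400, villages, seed=12, dontknow_rate=0.0, missing_rate=0.0)
        table, _ = prepare_responses(sv)
        surf = RasterGrid(values=rng.uniform(size=(50, 50)),
                          origin=(0.0, 0.0), cell_size=2.0)
        out = attach_risk_covariates(table, villages, geoprofile=surf)
        assert (out.groupby("village_id")["GP"].nunique() <= 1).all()

    def test_flat_surface_dropped_with_warning(self, villages):
        sv = make_survey(100, villages, seed=13, dontknow_rate=0.0, missing_rate=0.0)
        table, _ = prepare_responses(sv)
        flat = RasterGrid(values=np.full((50, 50), 0.4),
                          origin=(0.0, 0.0), cell_size=2.0)
        with pytest.warns(UserWarning, match="constant"):
            out = attach_risk_covariates(table, villages, geoprofile=flat)
        assert "GP" not in out.columns

    def test_gp_model_wins_four_model_comparison(self, landscape, villages, truth):
        """With a true geographic-profile effect in the generating model,
        the social+GP variant attains the minimum AICc in >= 90% of
        replicates at the study sample size."""
        from conflictscope import true_intensity
        from conflictscope.synthgen import ITEM_COLUMNS
        gp_surf = true_intensity(landscape, truth)
        # covariate-only risk (no source clusters) stands in for the
        # ensemble probability surface
        prob_surf = true_intensity(landscape,
                                   TruthParams(source_centres=()))
        social = [*ITEM_COLUMNS, "Scenario", "Age", "sex", "ethnicity"]
        wins = 0
        reps = 12
        for rep in range(reps):
            sv = gen_survey(villages, gp_surf, truth, 2386, seed=200 + rep)
            table, _ = prepare_responses(sv)
            table = attach_risk_covariates(table, villages,
                                           risk_surface=prob_surf,
                                           geoprofile=gp_surf,
                                           landscape=landscape)
            roster = standard_model_set(
                social, [n for n in landscape.rasters if n in table.columns])
            fits = {k: fit_multinomial(table, v, name=k)
                    for k, v in roster.items()}
            comp = compare_models(fits)
            wins += int(comp.table.index[0] == "social+gp")
        assert wins >= 0.9 * reps

    def test_negative_gp_effect_recovered(self, landscape, villages, truth):
        from conflictscope import true_intensity
        surf = true_intensity(landscape, truth)
        sv = gen_survey(villages, surf, truth, 5000, seed=14)
        table, _ = prepare_responses(sv)
        out = attach_risk_covariates(table, villages, geoprofile=surf)
        fit = fit_multinomial(out, ["Protect_tiger", "Kill_tiger", "BadGood",
                                    "Spirit", "Scenario", "GP"])
        for outcome in ("same", "increase"):
            beta = fit.coefficients.loc["GP", outcome]
            se = fit.standard_errors.loc["GP", outcome]
            assert beta < 0
            assert abs(beta - truth.tolerance_beta[outcome]["GP"]) < 3 * se
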