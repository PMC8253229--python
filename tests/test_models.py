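"""Published model presets, probability formulas, ML fitting, stepwise."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.miscmodels.ordinal_model import OrderedModel

import canopywilt as cw
from canopywilt.errors import FitError, InputError

ZERO_INDICES = {name: 0.0 for name in cw.INDEX_COLUMNS}


class TestRegistry:
    def test_model1_printed_constants(self):
        m = cw.get_model("model1")
        assert list(m.thresholds) == [-11.75, -7.19, -4.28]
        assert m.coefficients == {"u_star": 1.70, "a_star": -1.77, "csi": -0.15}
        assert m.levels == (0, 1, 2, 3)

    def test_model2_printed_constants(self):
        m = cw.get_model("model2")
        assert list(m.thresholds) == [25.93, 27.54, 29.61, 31.04, 33.07]
        assert m.coefficients == {
            "intensity": 78.45, "saturation": 6.96, "lightness": -1.08,
            "a_star": -2.62, "u_star": 1.44, "gga": -45.09, "csi": -0.34,
        }
        assert m.levels == (0, 1, 2, 3, 4, 5)

    def test_binary_model_printed_constants(self):
        m3, m4 = cw.get_model("model3"), cw.get_model("model4")
        assert m3.intercept == -0.43
        assert m3.coefficients == {"saturation": 11.70, "csi": -0.07}
        assert m4.intercept == -31.74
        assert m4.coefficients == {
            "lightness": -0.21, "a_star": -0.65, "gga": -37.90, "csi": -0.28,
        }


class TestLinearPredictor:
    def test_zero_input_gives_zero(self):
        assert cw.linear_predictor(cw.get_model("model1"), ZERO_INDICES) == 0.0

    def test_unit_weights_sum_printed_coefficients(self):
        iv = dict(ZERO_INDICES, u_star=1.0, a_star=1.0, csi=1.0)
        eps = cw.linear_predictor(cw.get_model("model1"), iv)
        assert eps == pytest.approx(1.70 - 1.77 - 0.15)

    def test_matches_term_by_term_sum(self, rng):
        m = cw.get_model("model2")
        iv = {name: rng.normal() for name in cw.INDEX_COLUMNS}
        expected = sum(w * iv[name] for name, w in m.coefficients.items())
        assert cw.linear_predictor(m, iv) == pytest.approx(expected)

    def test_missing_index_named_in_error(self):
        with pytest.raises(InputError, match="u_star"):
            cw.linear_predictor(cw.get_model("model1"), {"a_star": 1.0, "csi": 0.0})

    def test_non_finite_index_named_in_error(self):
        iv = dict(ZERO_INDICES, csi=float("nan"))
        with pytest.raises(InputError, match="csi"):
            cw.linear_predictor(cw.get_model("model1"), iv)


class TestPredictOrdinal:
    def test_zero_predictor_matches_direct_formula_evaluation(self):
        """Spreadsheet-style evaluation of the printed telescoping formulas."""
        p = cw.predict_ordinal(cw.get_model("model1"), ZERO_INDICES)
        c0, c1, c2 = (1 / (1 + math.exp(t)) for t in (11.75, 7.19, 4.28))
        expected = [c0, c1 - c0, c2 - c1, 1 - c2]
        assert p.probabilities == pytest.approx(expected, abs=1e-12)
        assert p.probabilities[0] == pytest.approx(7.9e-6, rel=0.02)

    @pytest.mark.parametrize("name", ["model1", "model2"])
    def test_probabilities_normalize_on_random_inputs(self, name, rng):
        m = cw.get_model(name)
        for _ in range(200):
            iv = {k: rng.normal(scale=5) for k in cw.INDEX_COLUMNS}
            p = cw.predict_ordinal(m, iv).probabilities
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert (p >= -1e-12).all()

    def test_extreme_predictor_concentrates_on_lowest_level(self):
        iv = dict(ZERO_INDICES, u_star=1000.0)
        p = cw.predict_ordinal(cw.get_model("model1"), iv)
        assert p.probabilities[0] == pytest.approx(1.0)
        assert p.top_score == 0

    def test_two_level_ordinal_collapses_to_binary(self):
        ordinal = cw.OrdinalLogisticModel(
            thresholds=[-0.43], coefficients={"saturation": 11.70, "csi": -0.07},
            levels=("turgid", "wilted"),
        )
        binary = cw.get_model("model3")
        iv = dict(ZERO_INDICES, saturation=0.3, csi=12.0)
        p_ord = cw.predict_ordinal(ordinal, iv).probabilities
        pt, pw = cw.predict_binary(binary, iv)
        assert p_ord == pytest.approx([pt, pw])


class TestPredictBinary:
    def test_zero_input_matches_printed_intercept(self):
        pt, pw = cw.predict_binary(cw.get_model("model3"), ZERO_INDICES)
        assert pt == pytest.approx(expit(-0.43))
        assert pt == pytest.approx(0.394, abs=5e-4)
        assert pt + pw == pytest.approx(1.0)

    def test_full_saturation_is_confidently_turgid(self):
        iv = dict(ZERO_INDICES, saturation=1.0)
        pt, _ = cw.predict_binary(cw.get_model("model3"), iv)
        assert pt == pytest.approx(expit(11.70 - 0.43))
        assert pt > 0.99


class TestClassify:
    def test_argmax_and_second(self):
        p = cw.WiltingPrediction((0, 1, 2, 3), [0.1, 0.5, 0.4, 0.0])
        assert cw.classify(p, "first") == 1
        assert cw.classify(p, "second") == (1, 2)

    def test_tie_breaks_toward_lower_score(self):
        p = cw.WiltingPrediction((0, 1), [0.5, 0.5])
        assert cw.classify(p, "first") == 0

    def test_close_race_keeps_both_scores(self):
        p = cw.WiltingPrediction((0, 1, 2, 3), [0.18, 0.35, 0.37, 0.10])
        assert cw.classify(p, "second") == (2, 1)


class TestBinarizeScore:
    @pytest.mark.parametrize("score, expected", [(0, "turgid"), (1, "turgid"),
                                                 (2, "wilted"), (5, "wilted")])
    def test_threshold_at_two(self, score, expected):
        assert cw.binarize_score(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            cw.binarize_score(6)


class TestInformationCriteria:
    def test_zero_case(self):
        assert cw.information_criteria(0.0, 0, 5) == (0.0, 0.0)

    def test_aic_sc_cross_at_n_e_squared(self):
        aic, sc = cw.information_criteria(-100.0, 3, round(math.exp(2)))
        assert aic == pytest.approx(206.0)
        assert sc == pytest.approx(206.0, abs=0.2)  # n rounded to integer


def _simulate_binary(rng, n=500):
    X = pd.DataFrame({
        "saturation": rng.normal(0.5, 0.2, n),
        "csi": rng.normal(40, 15, n),
    })
    eta = 8.0 * X["saturation"] - 0.05 * X["csi"] - 1.0
    y = rng.random(n) < expit(eta)
    X["status"] = np.where(y, "turgid", "wilted")
    return X


class TestFitBinary:
    def test_uninformative_predictor_recovers_base_rate(self, rng):
        n = 400
        X = pd.DataFrame({"hue": rng.normal(size=n),
                          "status": ["turgid"] * 240 + ["wilted"] * 160})
        m = cw.fit_binary(X, ["hue"])
        assert m.coefficients["hue"] == pytest.approx(0.0, abs=0.25)
        assert m.intercept == pytest.approx(math.log(240 / 160), abs=0.25)

    def test_recovers_known_coefficients_within_three_se(self, rng):
        X = _simulate_binary(rng)
        m = cw.fit_binary(X, ["saturation", "csi"])
        oracle = sm.Logit(
            (X["status"] == "turgid").astype(int),
            sm.add_constant(X[["saturation", "csi"]]),
        ).fit(disp=False)
        for name, truth in [("saturation", 8.0), ("csi", -0.05)]:
            se = oracle.bse[name]
            assert abs(m.coefficients[name] - truth) < 3 * se
            assert m.coefficients[name] == pytest.approx(oracle.params[name], abs=1e-3)

    def test_deviance_matches_hand_computed_likelihood(self):
        X = pd.DataFrame({"csi": [10.0, 20.0, 30.0, 40.0],
                          "status": ["turgid", "turgid", "wilted", "wilted"]})
        m = cw.fit_binary(X, ["csi"], positive_label="turgid")
        ll = 0.0
        for _, row in X.iterrows():
            pt = expit(m.intercept + m.coefficients["csi"] * row["csi"])
            ll += math.log(pt if row["status"] == "turgid" else 1 - pt)
        assert m.diagnostics["loglik"] == pytest.approx(ll, abs=1e-6)

    def test_single_class_outcome_is_a_fit_error(self, rng):
        X = pd.DataFrame({"csi": rng.normal(size=10), "status": ["wilted"] * 10})
        with pytest.raises(FitError):
            cw.fit_binary(X, ["csi"])


class TestFitOrdinal:
    def test_recovers_known_two_predictor_model_within_three_se(self):
        table = cw.simulate_index_table(cw.FieldSimConfig(n_plots=500, seed=21))
        preds = ["csi", "a_star", "ga"]
        m = cw.fit_ordinal(table, preds)
        oracle = OrderedModel(
            pd.Categorical(table["score"], categories=[0, 1, 2, 3, 4, 5], ordered=True),
            table[preds], distr="logit",
        ).fit(method="bfgs", disp=False)
        truth = cw.synth.DEFAULT_GENERATING_MODEL.coefficients
        for i, name in enumerate(preds):
            se = oracle.bse.iloc[i]
            assert abs(m.coefficients[name] - truth[name]) < 3 * se

    def test_two_level_fit_reduces_to_binary_logistic(self, rng):
        X = _simulate_binary(rng, n=300)
        X["score"] = (X["status"] == "wilted").astype(int)  # 0 = turgid (lower)
        ordinal = cw.fit_ordinal(X, ["saturation", "csi"])
        binary = cw.fit_binary(X, ["saturation", "csi"])
        for name in ("saturation", "csi"):
            assert ordinal.coefficients[name] == pytest.approx(
                binary.coefficients[name], abs=1e-3
            )
        assert ordinal.thresholds[0] == pytest.approx(binary.intercept, abs=1e-3)

    def test_loglik_matches_brute_force_cumulative_logit(self):
        table = pd.DataFrame({
            "csi": [5.0, 15.0, 25.0, 35.0, 45.0, 55.0],
            "ga": [0.9, 0.8, 0.6, 0.5, 0.3, 0.2],
            "score": [0, 0, 1, 1, 2, 2],
        })
        m = cw.fit_ordinal(table, ["csi"])
        ll = 0.0
        for _, row in table.iterrows():
            p = cw.predict_ordinal(m, dict(row)).probabilities
            ll += math.log(p[list(m.levels).index(row["score"])])
        assert m.diagnostics["loglik"] == pytest.approx(ll, abs=1e-6)

    def test_prediction_levels_limited_to_training_levels(self):
        m = cw.get_model("model1")
        p = cw.predict_ordinal(m, ZERO_INDICES)
        assert p.levels == (0, 1, 2, 3)


class TestStepwise:
    def test_single_informative_predictor_selected_with_aic_ordering(self):
        rng = np.random.default_rng(3)
        n = 400
        X = pd.DataFrame({c: rng.normal(size=n)
                          for c in ["intensity", "hue", "saturation", "a_star", "ga"]})
        X["status"] = np.where(
            rng.random(n) < expit(2.0 * X["a_star"] + 0.3), "turgid", "wilted"
        )
        res = cw.stepwise_select(
            X, "binary", candidates=["intensity", "hue", "saturation", "a_star", "ga"]
        )
        assert res.predictors == ["a_star"]
        assert (res.report.loc["selected", "AIC"] < res.report.loc["full", "AIC"]
                < res.report.loc["null", "AIC"])

    def test_pure_noise_returns_null_model(self):
        rng = np.random.default_rng(2)
        n = 200
        X = pd.DataFrame({c: rng.normal(size=n) for c in ["hue", "ga", "csi"]})
        X["status"] = np.where(rng.random(n) < 0.5, "turgid", "wilted")
        res = cw.stepwise_select(X, "binary", candidates=["hue", "ga", "csi"])
        assert res.predictors == []
        assert res.model.coefficients == {}

    def test_duplicated_predictor_enters_only_once(self, rng):
        n = 300
        base = rng.normal(size=n)
        X = pd.DataFrame({"ga": base, "gga": base, "hue": rng.normal(size=n)})
        X["status"] = np.where(rng.random(n) < expit(2 * base), "turgid", "wilted")
        res = cw.stepwise_select(X, "binary", candidates=["ga", "gga", "hue"])
        assert ("ga" in res.predictors) ^ ("gga" in res.predictors)


class TestModelFiles:
    def test_ordinal_round_trip(self, tmp_path):
        m = cw.get_model("model2")
        path = tmp_path / "model2.txt"
        cw.save_model(m, path)
        loaded = cw.load_model(path)
        assert loaded.coefficients == m.coefficients
        np.testing.assert_allclose(loaded.thresholds, m.thresholds)
        assert loaded.levels == m.levels

    def test_binary_round_trip(self, tmp_path):
        m = cw.get_model("model4")
        path = tmp_path / "model4.txt"
        cw.save_model(m, path)
        loaded = cw.load_model(path)
        assert loaded.intercept == m.intercept
        assert loaded.coefficients == m.coefficients
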