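"""Design encoding and IRLS logistic fitting."""

import math

import numpy as np
import pandas as pd
import pytest

from pvsignal.errors import RankDeficiencyError
from pvsignal.regress import (AGE_EDGES, Covariate, DesignSpec, encode_design,
                              fit_logistic, or_table, standard_design)


class TestEncodeDesign:
    def test_sex_reference_female_single_dummy(self):
        df = pd.DataFrame({"sex": ["F", "M", "F"], "event": [0, 1, 0]})
        spec = DesignSpec([Covariate("sex", "categorical", reference="F")])
        X, y = encode_design(df, spec)
        assert list(X.columns) == ["intercept", "sex:M"]
        assert X["sex:M"].tolist() == [0.0, 1.0, 0.0]

    def test_age_preset_bins(self):
        df = pd.DataFrame({"age": [30, 48, 55, 65, 80], "event": [0] * 5})
        spec = DesignSpec([Covariate("age", "quartile", edges=AGE_EDGES)])
        X, _ = encode_design(df, spec)
        assert set(X.columns) == {"intercept", "age:48-61", "age:61-71",
                                  "age:>71"}
        # 30 -> reference bin (<48); boundary 48 falls in the lower bin
        assert X.loc[0].drop("intercept").sum() == 0
        assert X.loc[2, "age:48-61"] == 1.0
        assert X.loc[3, "age:61-71"] == 1.0
        assert X.loc[4, "age:>71"] == 1.0

    def test_all_reference_row_is_intercept_only(self):
        df = pd.DataFrame({"sex": ["F"], "age": [30.0], "event": [0]})
        spec = DesignSpec([Covariate("sex", reference="F"),
                           Covariate("age", "quartile", edges=AGE_EDGES)])
        X, _ = encode_design(df, spec)
        assert X.loc[0].drop("intercept").sum() == 0

    def test_listwise_deletion_reported(self):
        df = pd.DataFrame({"sex": ["F", None, "M"], "event": [0, 1, 1]})
        spec = DesignSpec([Covariate("sex", reference="F")])
        X, y = encode_design(df, spec)
        assert len(X) == 2 and X.attrs["n_dropped"] == 1
        assert X.attrs["missingness"]["sex"] == 1

    def test_empty_after_deletion_raises_with_report(self):
        df = pd.DataFrame({"sex": [None, None], "event": [0, 1]})
        spec = DesignSpec([Covariate("sex", reference="F")])
        with pytest.raises(ValueError, match="missing"):
            encode_design(df, spec)


class TestFitLogistic:
    def test_single_covariate_reproduces_cross_product_or(self):
        # 2x2 table a=20 b=10 c=5 d=40 -> OR = 16
        X = np.array([[1.0, 1], [1, 1], [1, 0], [1, 0]])
        y = np.array([1.0, 0, 1, 0])
        w = np.array([20.0, 10, 5, 40])
        fit = fit_logistic(X, y, sample_weight=w)
        assert math.exp(fit.params.iloc[1]) == pytest.approx(16.0, rel=1e-9)

    def test_random_tables_match_cross_product(self, rng):
        X = np.array([[1.0, 1], [1, 1], [1, 0], [1, 0]])
        y = np.array([1.0, 0, 1, 0])
        for _ in range(100):
            a, b, c, d = rng.integers(1, 16, 4)
            fit = fit_logistic(X, y, sample_weight=np.array(
                [a, b, c, d], dtype=float))
            assert math.exp(fit.params.iloc[1]) == pytest.approx(
                a * d / (b * c), rel=1e-8)

    def test_null_response_small_coefficients(self):
        rng = np.random.default_rng(2)
        n = 10_000
        X = pd.DataFrame({"intercept": 1.0,
                          "x1": rng.normal(size=n),
                          "x2": rng.integers(0, 2, n).astype(float)})
        y = rng.integers(0, 2, n).astype(float)
        fit = fit_logistic(X, y)
        ors = np.exp(fit.params.drop("intercept"))
        assert np.all(np.abs(np.log(ors)) < 0.1)

    def test_known_or_recovered_with_coverage(self):
        rng = np.random.default_rng(3)
        n = 50_000
        drug = rng.integers(0, 2, n).astype(float)
        age = rng.normal(0, 1, n)
        eta = -3.0 + math.log(2.0) * drug + 0.3 * age
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = pd.DataFrame({"intercept": 1.0, "drug": drug, "age": age})
        fit = fit_logistic(X, y)
        tab = or_table(fit)
        assert tab.loc["drug", "or_low"] < 2.0 < tab.loc["drug", "or_high"]

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 2000
        X = pd.DataFrame({"intercept": 1.0,
                          "x1": rng.normal(size=n),
                          "x2": rng.integers(0, 2, n).astype(float)})
        eta = -1.0 + 0.8 * X["x1"] - 0.5 * X["x2"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        oracle = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(),
                                   oracle.params.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(fit.se.to_numpy(),
                                   oracle.bse.to_numpy(), rtol=1e-4)

    def test_deviance_monotone_nonincreasing(self, rng):
        for _ in range(5):
            n = 500
            X = pd.DataFrame({"intercept": 1.0,
                              "x1": rng.normal(size=n),
                              "x2": rng.normal(size=n)})
            eta = 0.5 * X["x1"] - 1.0 * X["x2"]
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = fit_logistic(X, y)
            assert np.all(np.diff(fit.deviance_path) <= 1e-9)

    def test_separation_flagged_not_silent(self):
        X = pd.DataFrame({"intercept": 1.0,
                          "x": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20), np.ones(20)]
        fit = fit_logistic(X, y)
        assert fit.separation

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        X = pd.DataFrame({"intercept": 1.0, "x": x, "x_copy": x})
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(RankDeficiencyError) as exc:
            fit_logistic(X, y)
        assert "x_copy" in exc.value.columns or "x" in exc.value.columns

    def test_ridge_stabilizes_separation(self):
        X = pd.DataFrame({"intercept": 1.0,
                          "x": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20), np.ones(20)]
        fit = fit_logistic(X, y, ridge=1.0)
        assert np.max(np.abs(fit.params)) < 15


class TestORTable:
    def test_wald_interval_arithmetic(self):
        # coef 0, se 0.1 -> OR 1.00 (0.82-1.22)
        fit_params = pd.Series([0.0, 0.0], index=["intercept", "x"])
        cov = pd.DataFrame(np.diag([0.01, 0.01]),
                           index=fit_params.index, columns=fit_params.index)
        from pvsignal.regress import LogisticFit
        fit = LogisticFit(fit_params, cov, 0.0, [0.0], 1, True, False, 100)
        tab = or_table(fit)
        assert tab.loc["x", "or"] == pytest.approx(1.0)
        assert tab.loc["x", "or_low"] == pytest.approx(0.822, abs=1e-3)
        assert tab.loc["x", "or_high"] == pytest.approx(1.217, abs=1e-3)

    def test_degenerate_zero_se_flagged(self):
        from pvsignal.regress import LogisticFit
        params = pd.Series([0.0, math.log(2)], index=["intercept", "x"])
        cov = pd.DataFrame(np.zeros((2, 2)), index=params.index,
                           columns=params.index)
        tab = or_table(LogisticFit(params, cov, 0.0, [0.0], 1, True, False, 10))
        assert tab.loc["x", "degenerate"]
        assert tab.loc["x", "or"] == pytest.approx(2.0)
        assert tab.loc["x", "or_low"] == tab.loc["x", "or_high"]

    def test_p_symmetric_in_sign(self):
        from pvsignal.regress import LogisticFit
        for sgn in (+1, -1):
            params = pd.Series([0.0, sgn * 0.4], index=["intercept", "x"])
            cov = pd.DataFrame(np.diag([0.01, 0.04]), index=params.index,
                               columns=params.index)
            tab = or_table(LogisticFit(params, cov, 0.0, [0.0], 1, True,
                                       False, 10))
            if sgn == 1:
                p_plus = tab.loc["x", "p"]
            else:
                assert tab.loc["x", "p"] == pytest.approx(p_plus)


def test_standard_design_covers_covariates(study_bundle):
    _, _, _, db = study_bundle
    cov = db.case_covariates()
    spec = standard_design([c for c in cov.columns if c.startswith("drug:")])
    X, y = encode_design(cov, spec)
    assert "age:61-71" in X.columns
    assert "wt:57.14-69" in X.columns
    assert any(c.startswith("drug:") for c in X.columns)
    assert set(np.unique(y)) <= {0.0, 1.0}
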