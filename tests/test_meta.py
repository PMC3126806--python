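"""DerSimonian-Laird meta-regression: moment estimator, WLS reductions,
independent cross-checks, and the relative-increase report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import twinvar as tv
from twinvar.errors import ConfigError, DataError
from twinvar.meta import _reml_tau_squared
from twinvar.types import MetaDataset


def intercept_only(y, v):
    return MetaDataset(y=np.asarray(y, float), v=np.asarray(v, float),
                       X=np.ones((len(y), 1)), columns=["intercept"])


class TestDLTauSquared:
    def test_exact_linear_data_gives_zero(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        y = 2.0 + 0.5 * np.arange(5.0)
        assert tv.dl_tau_squared(y, np.full(5, 0.3), X) == 0.0

    def test_hand_worked_three_studies_truncated(self):
        # Q = (1-2)^2 + 0 + (3-2)^2 = 2 = k - p -> tau2 truncates to 0
        assert tv.dl_tau_squared([1, 2, 3], [1, 1, 1], np.ones((3, 1))) == 0.0

    def test_hand_worked_three_studies_positive(self):
        # Q = 9 + 0 + 9 = 18; denominator = sum(w) - tr((X'WX)^-1 X'W^2 X) = 3 - 1 = 2
        # tau2 = (18 - (3 - 1)) / 2 = 8
        assert tv.dl_tau_squared([0, 3, 6], [1, 1, 1], np.ones((3, 1))) == pytest.approx(8.0)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(DataError):
            tv.dl_tau_squared([1, 2, 3], [1, 0, 1], np.ones((3, 1)))

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=12),
           st.lists(st.floats(0.01, 2.0), min_size=4, max_size=12))
    def test_always_nonnegative(self, y, v):
        k = min(len(y), len(v))
        assert tv.dl_tau_squared(y[:k], v[:k], np.ones((k, 1))) >= 0.0


class TestFitRemr:
    def test_matches_metafor_on_frozen_fixture(self):
        """Cross-validated against R metafor rma(..., method="DL", test="z")."""
        y = np.array([1.9002, 2.4292, 2.8556, 2.9468, 2.359, 2.9431,
                      3.0317, 2.5289, 3.2818, 3.095, 3.0838, 3.2962])
        v = np.array([0.02141, 0.01101, 0.01352, 0.05694, 0.02935, 0.08261,
                      0.00772, 0.0392, 0.00797, 0.03072, 0.04289, 0.00665])
        x1 = np.array([1.096, 3.278, 4.112, 5.843, 5.961, 7.468,
                       8.859, 9.417, 11.464, 9.846, 13.384, 15.009])
        x2 = np.array([35.335, 28.87, 36.889, 30.608, 26.88, 41.539,
                       28.375, 35.786, 26.883, 33.335, 26.177, 28.703])
        ds = MetaDataset(y=y, v=v, X=np.column_stack([np.ones(12), x1, x2]),
                         columns=["intercept", "x1", "x2"])
        r = tv.fit_remr(ds)
        assert r.tau2 == pytest.approx(0.0472298711, abs=1e-9)
        np.testing.assert_allclose(r.beta, [1.9529773942, 0.0847697000, 0.0060410595],
                                   atol=1e-9)
        np.testing.assert_allclose(r.se_beta, [0.7087550326, 0.0204098618, 0.0198609161],
                                   atol=1e-9)
        np.testing.assert_allclose(r.p_value, [0.00586017711, 3.276148929e-05,
                                               0.7609997347], rtol=1e-7)

    def test_tau2_zero_equal_v_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        beta_true = np.array([1.0, 0.4])
        y = X @ beta_true  # exactly linear -> tau2 = 0
        ds = MetaDataset(y=y, v=np.full(20, 0.25), X=X, columns=["intercept", "x"])
        r = tv.fit_remr(ds)
        assert r.tau2 == 0.0
        ols_beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(r.beta, ols_beta, atol=1e-12)

    def test_matches_statsmodels_wls_betas(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(30), rng.normal(size=30), rng.normal(size=30)])
        y = X @ [2.0, 0.3, -0.1] + rng.normal(0, 0.4, 30)
        v = rng.uniform(0.05, 0.4, 30)
        ds = MetaDataset(y=y, v=v, X=X, columns=["intercept", "a", "b"])
        r = tv.fit_remr(ds)
        w = 1.0 / (v + r.tau2)
        sm_fit = sm.WLS(y, X, weights=w).fit()
        np.testing.assert_allclose(r.beta, sm_fit.params, atol=1e-10)

    def test_constant_outcome_gives_zero_slope(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        ds = MetaDataset(y=np.full(10, 2.5), v=np.full(10, 0.1), X=X,
                         columns=["intercept", "proxy"])
        r = tv.fit_remr(ds)
        assert r.coef("proxy") == pytest.approx(0.0, abs=1e-12)
        assert r.coef("intercept") == pytest.approx(2.5)

    def test_weights_positive_and_decreasing_in_v(self):
        y = [1.0, 1.5, 2.0, 2.5]
        v = [0.1, 0.2, 0.4, 0.8]
        r = tv.fit_remr(intercept_only(y, v))
        assert np.all(r.weights > 0)
        assert np.all(np.diff(r.weights) < 0)
        np.testing.assert_allclose(r.weights, 1.0 / (np.array(v) + r.tau2))

    def test_collinear_design_names_columns(self):
        X = np.column_stack([np.ones(8), np.arange(8.0), 2 * np.arange(8.0)])
        ds = MetaDataset(y=np.arange(8.0), v=np.full(8, 0.1), X=X,
                         columns=["intercept", "age", "age_copy"])
        with pytest.raises(DataError, match="age"):
            tv.fit_remr(ds)

    def test_reml_alternative_runs(self):
        rng = np.random.default_rng(8)
        y = rng.normal(2, 0.6, 25)
        v = rng.uniform(0.02, 0.1, 25)
        ds = intercept_only(y, v)
        r = tv.fit_remr(ds, tau2_method="REML")
        assert r.tau2 >= 0.0
        assert _reml_tau_squared(y, v, ds.X) == pytest.approx(r.tau2)

    def test_knapp_hartung_widens_small_sample_p(self):
        rng = np.random.default_rng(9)
        y = rng.normal(1, 0.8, 8)
        v = rng.uniform(0.05, 0.2, 8)
        ds = intercept_only(y, v)
        plain = tv.fit_remr(ds)
        kh = tv.fit_remr(ds, knapp_hartung=True)
        assert kh.method.startswith("KH")
        assert kh.p_value[0] >= plain.p_value[0] - 1e-12


class TestBuildMetaDataset:
    @pytest.fixture
    def table(self):
        rng = np.random.default_rng(10)
        k = 24
        return pd.DataFrame({
            "survey_year": [1994] * 12 + [2002] * 12,
            "sex": (["M"] * 6 + ["F"] * 6) * 2,
            "birth_year": list(range(1950, 1956)) * 4,
            "obesity_pct": rng.uniform(1, 12, k),
            "overweight_pct": rng.uniform(10, 40, k),
            "mean_bmi": rng.uniform(21, 26, k),
            "agsd": rng.uniform(2.5, 3.6, k),
            "agsd_se": rng.uniform(0.08, 0.2, k),
            "esd": rng.uniform(1.4, 2.0, k),
            "esd_se": rng.uniform(0.05, 0.15, k),
            "fit_valid": [True] * 23 + [False],
        })

    def test_design_layout(self, table):
        ds, dropped = tv.build_meta_dataset(table, "obesity_pct", "A")
        assert ds.k == 23 and ds.p == 6
        assert ds.columns == ["intercept", "proxy", "sex", "age", "sex_x_proxy", "survey"]
        assert len(dropped) == 1
        np.testing.assert_allclose(
            ds.X[:, 1], table.loc[table.fit_valid, "obesity_pct"])
        # sex x proxy column is elementwise product
        np.testing.assert_allclose(ds.X[:, 4], ds.X[:, 2] * ds.X[:, 1])

    def test_e_outcome_uses_esd(self, table):
        ds, _ = tv.build_meta_dataset(table, "mean_bmi", "E")
        np.testing.assert_allclose(ds.y, table.loc[table.fit_valid, "esd"])

    def test_unknown_proxy_rejected(self, table):
        with pytest.raises(ConfigError):
            tv.build_meta_dataset(table, "height", "A")

    def test_too_few_strata_rejected(self, table):
        # three strata cannot support even the reduced 3-column design
        with pytest.raises(DataError):
            tv.build_meta_dataset(table.iloc[:3], "obesity_pct", "A")


def _result_with_proxy(beta):
    from twinvar.types import MetaRegressionResult

    b = np.array([2.0, beta])
    return MetaRegressionResult(
        columns=["intercept", "proxy"], beta=b, se_beta=np.full(2, 0.1),
        z=b / 0.1, p_value=np.full(2, 0.5), tau2=0.0, q_residual=0.0,
        weights=np.ones(2))


class TestRelativeIncrease:
    def test_printed_discussion_numbers(self):
        rel = tv.report_relative_increase(_result_with_proxy(0.1), mean_agsd=3.0)
        assert round(rel["pct_per_unit"], 1) == 3.3
        assert round(rel["pct_per_10_units"], 1) == 33.3

    @pytest.mark.parametrize("beta,mean,unit,ten", [(0.0, 3.0, 0.0, 0.0),
                                                    (0.3, 3.0, 10.0, 100.0)])
    def test_linear_scaling(self, beta, mean, unit, ten):
        rel = tv.report_relative_increase(_result_with_proxy(beta), mean)
        assert rel["pct_per_unit"] == pytest.approx(unit)
        assert rel["pct_per_10_units"] == pytest.approx(ten)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ConfigError):
            tv.report_relative_increase(_result_with_proxy(0.1), 0.0)


class TestRecoveryAcrossSlopes:
    def test_generating_slopes_recovered_without_systematic_bias(self):
        """Meta-level: estimates regressed on truth lie on the identity."""
        rng = np.random.default_rng(12)
        k = 80
        x = rng.uniform(0, 15, k)
        v = rng.uniform(0.01, 0.04, k)
        truths = np.linspace(-0.1, 0.25, 8)
        est = []
        for bt in truths:
            means = []
            for _ in range(40):
                y = 2.0 + bt * x + rng.normal(0, np.sqrt(v + 0.01))
                ds = MetaDataset(y=y, v=v, X=np.column_stack([np.ones(k), x]),
                                 columns=["intercept", "proxy"])
                means.append(tv.fit_remr(ds).coef("proxy"))
            est.append(np.mean(means))
        slope, intercept = np.polyfit(truths, est, 1)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert intercept == pytest.approx(0.0, abs=0.01)
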