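"""Twin-model likelihood, fitting, standard errors, and model selection.

Oracles used here are independent of the package's closed-form
sufficient-statistic likelihood: per-pair density summation through
scipy.stats, and exhaustive grid search over the parameter space.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import twinvar as tv
from twinvar.errors import ConfigError
from twinvar.twin_model import ZygosityData, fit_all_models

from conftest import draw_ae_pairs


def oracle_loglik(mu, params, model, mz_pairs, dz_pairs, mz_singles=(), dz_singles=()):
    """Per-pair scipy density summation (independent of the suff-stat path)."""
    ll = 0.0
    for zyg, pairs, singles in (("MZ", mz_pairs, mz_singles), ("DZ", dz_pairs, dz_singles)):
        cov = tv.pair_covariance(model, zyg, params)
        mvn = stats.multivariate_normal(mean=[mu, mu], cov=cov)
        for x1, x2 in pairs:
            ll += mvn.logpdf([x1, x2])
        for x in singles:
            ll += stats.norm.logpdf(x, loc=mu, scale=math.sqrt(cov[0, 0]))
    return ll


class TestPairCovariance:
    def test_ae_structure(self):
        p = {"var_a": 9.0, "var_e": 3.0}
        mz = tv.pair_covariance("AE", "MZ", p)
        dz = tv.pair_covariance("AE", "DZ", p)
        assert mz[0, 0] == 12.0 and mz[0, 1] == 9.0
        assert dz[0, 0] == 12.0 and dz[0, 1] == 4.5  # the 0.5 additive share

    def test_e_only_no_covariance(self):
        c = tv.pair_covariance("E", "MZ", {"var_e": 3.0})
        assert c[0, 0] == 3.0 and c[0, 1] == 0.0

    def test_dominance_quarter_share(self):
        p = {"var_a": 4.0, "var_d": 2.0, "var_e": 1.0}
        dz = tv.pair_covariance("ADE", "DZ", p)
        assert dz[0, 1] == pytest.approx(0.5 * 4.0 + 0.25 * 2.0)

    def test_unknown_model_errors(self):
        with pytest.raises(ConfigError):
            tv.pair_covariance("AED", "MZ", {})


class TestLoglik:
    def test_single_mz_pair_at_mean(self):
        # density of (22, 22) under mean (22, 22), Sigma=[[2,1],[1,2]]
        mz = ZygosityData.from_arrays([22.0], [22.0])
        dz = ZygosityData()
        ll = tv.loglik_stratum(mz, dz, "AE", 22.0, {"var_a": 1.0, "var_e": 1.0})
        assert ll == pytest.approx(-math.log(2 * math.pi) - 0.5 * math.log(3.0), abs=1e-12)

    @pytest.mark.parametrize("model,params", [
        ("AE", {"var_a": 7.0, "var_e": 2.5}),
        ("ACE", {"var_a": 5.0, "var_c": 2.0, "var_e": 2.5}),
        ("ADE", {"var_a": 5.0, "var_d": 2.0, "var_e": 2.5}),
        ("E", {"var_e": 9.0}),
    ])
    def test_matches_per_pair_density_oracle(self, model, params):
        rng = np.random.default_rng(2)
        x1, x2 = draw_ae_pairs(rng, 6, 23.0, 8.0, 3.0, 1.0)
        y1, y2 = draw_ae_pairs(rng, 4, 23.0, 8.0, 3.0, 0.5)
        singles = [21.0, 25.5]
        mz = ZygosityData.from_arrays(x1, x2, singles=singles)
        dz = ZygosityData.from_arrays(y1, y2)
        got = tv.loglik_stratum(mz, dz, model, 22.7, params)
        want = oracle_loglik(22.7, params, model, zip(x1, x2), zip(y1, y2),
                             mz_singles=singles)
        assert got == pytest.approx(want, abs=1e-10)

    def test_singleton_handling_is_noop_without_singletons(self, ae_dataset):
        mz, dz, _ = ae_dataset(10, 10, seed=4)
        base = tv.loglik_stratum(mz, dz, "AE", 22.0, {"var_a": 9.0, "var_e": 3.0})
        mz2 = ZygosityData(**{**mz.__dict__})
        assert tv.loglik_stratum(mz2, dz, "AE", 22.0, {"var_a": 9.0, "var_e": 3.0}) == base


class TestFit:
    def test_matches_grid_search_oracle_on_20_pairs(self, ae_dataset):
        mz, dz, _ = ae_dataset(10, 10, seed=7)
        fit = tv.fit_variance_model(mz, dz, "AE")
        step = 0.01
        m, var, _ = mz.pair_covariance_moments()
        mus = np.arange(m - 0.8, m + 0.8, step)
        aa = np.arange(step, 4.5, step)
        ee = np.arange(0.3, 3.5, step)
        A, E = np.meshgrid(aa, ee, indexing="ij")
        V = A**2 + E**2
        best = (-np.inf, None)
        x1 = np.array([22.0])  # placeholder; replaced below per pair
        for mu in mus:
            ll = np.zeros_like(V)
            for share, z in ((1.0, mz), (0.5, dz)):
                C = share * A**2
                det = V * V - C * C
                n = z.n_pairs
                qd = z.sum_sq - 2 * mu * z.sum_pair + 2 * n * mu * mu
                qc = z.sum_cross - mu * z.sum_pair + n * mu * mu
                ll += -n * np.log(2 * np.pi) - 0.5 * n * np.log(det) \
                    - 0.5 * (V * qd - 2 * C * qc) / det
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            if ll[i, j] > best[0]:
                best = (ll[i, j], (mu, aa[i], ee[j]))
        _, (gmu, ga, ge) = best
        assert abs(fit.mu - gmu) <= 1.5 * step
        assert abs(fit.agsd - ga) <= 1.5 * step
        assert abs(fit.esd - ge) <= 1.5 * step
        assert fit.loglik >= best[0] - 1e-6  # ML at least as good as the grid

    def test_parameter_recovery_large_n(self, ae_dataset):
        mz, dz, _ = ae_dataset(2000, 2000, mu=22.0, var_a=9.0, var_e=3.0, seed=11)
        fit = tv.fit_variance_model(mz, dz, "AE")
        assert fit.converged and fit.se_valid
        assert abs(fit.agsd - 3.0) <= 3 * fit.agsd_se
        assert abs(fit.esd - math.sqrt(3.0)) <= 3 * fit.esd_se
        assert abs(fit.mu - 22.0) <= 3 * math.sqrt(12.0 / 8000)

    def test_perfect_heritability_boundary(self):
        rng = np.random.default_rng(1)
        g = rng.standard_normal(120) * 3
        mz = ZygosityData.from_arrays(22 + g, 22 + g)  # exact duplicates
        zg = rng.standard_normal(120)
        a1 = math.sqrt(4.5) * (zg + rng.standard_normal(120))
        a2 = math.sqrt(4.5) * (zg + rng.standard_normal(120))
        dz = ZygosityData.from_arrays(22 + a1, 22 + a2)
        fit = tv.fit_variance_model(mz, dz, "AE")
        assert fit.var_e < 1e-4 * fit.var_a  # E driven to the boundary

    def test_location_invariance(self, ae_dataset):
        mz, dz, (x1, x2, y1, y2) = ae_dataset(150, 150, seed=3)
        base = tv.fit_variance_model(mz, dz, "AE")
        shift = 7.0
        mzs = ZygosityData.from_arrays(x1 + shift, x2 + shift)
        dzs = ZygosityData.from_arrays(y1 + shift, y2 + shift)
        moved = tv.fit_variance_model(mzs, dzs, "AE")
        assert moved.mu == pytest.approx(base.mu + shift, abs=1e-5)
        assert moved.var_a == pytest.approx(base.var_a, abs=1e-6)
        assert moved.var_e == pytest.approx(base.var_e, abs=1e-6)

    @given(st.floats(0.5, 3.0))
    @settings(max_examples=8)
    def test_scale_equivariance(self, c):
        from twinvar.twin_model import ZygosityData as ZD
        rng = np.random.default_rng(9)
        x1, x2 = draw_ae_pairs(rng, 150, 22.0, 9.0, 3.0, 1.0)
        y1, y2 = draw_ae_pairs(rng, 150, 22.0, 9.0, 3.0, 0.5)
        base = tv.fit_variance_model(ZD.from_arrays(x1, x2), ZD.from_arrays(y1, y2), "AE")
        scaled = tv.fit_variance_model(
            ZD.from_arrays(c * x1, c * x2), ZD.from_arrays(c * y1, c * y2), "AE")
        assert scaled.agsd == pytest.approx(c * base.agsd, rel=1e-4)
        assert scaled.esd == pytest.approx(c * base.esd, rel=1e-4)

    def test_nesting_of_logliks(self, ae_dataset):
        mz, dz, _ = ae_dataset(60, 60, seed=21)
        fits = fit_all_models(mz, dz)
        assert fits["E"].loglik <= fits["AE"].loglik + 1e-7
        assert fits["AE"].loglik <= fits["ACE"].loglik + 1e-7
        assert fits["AE"].loglik <= fits["ADE"].loglik + 1e-7

    def test_moment_sanity_on_large_balanced_data(self, ae_dataset):
        mz, dz, _ = ae_dataset(5000, 5000, var_a=9.0, var_e=3.0, seed=13)
        fit = tv.fit_variance_model(mz, dz, "AE")
        _, _, cov_mz = mz.pair_covariance_moments()
        _, _, cov_dz = dz.pair_covariance_moments()
        assert fit.var_a == pytest.approx(2 * (cov_mz - cov_dz), abs=0.45)

    def test_too_few_pairs_flagged_invalid(self):
        mz = ZygosityData.from_arrays([22.0], [23.0])
        dz = ZygosityData.from_arrays([21.0], [24.0])
        fit = tv.fit_variance_model(mz, dz, "AE")
        assert not fit.converged and not fit.valid


class TestStandardErrors:
    def test_doubling_data_shrinks_se_by_sqrt2(self, ae_dataset):
        mz, dz, _ = ae_dataset(400, 400, seed=17)
        fit1 = tv.fit_variance_model(mz, dz, "AE")
        double = lambda z: ZygosityData(
            n_pairs=2 * z.n_pairs, sum_pair=2 * z.sum_pair, sum_sq=2 * z.sum_sq,
            sum_cross=2 * z.sum_cross)
        fit2 = tv.fit_variance_model(double(mz), double(dz), "AE")
        assert fit2.agsd_se / fit1.agsd_se == pytest.approx(1 / math.sqrt(2), rel=1e-3)

    def test_se_calibrated_against_empirical_sd(self):
        rng = np.random.default_rng(23)
        est, ses = [], []
        for _ in range(500):
            x1, x2 = draw_ae_pairs(rng, 250, 22.0, 9.0, 3.0, 1.0)
            y1, y2 = draw_ae_pairs(rng, 250, 22.0, 9.0, 3.0, 0.5)
            fit = tv.fit_variance_model(
                ZygosityData.from_arrays(x1, x2), ZygosityData.from_arrays(y1, y2), "AE")
            est.append(fit.agsd)
            ses.append(fit.agsd_se)
        assert np.mean(ses) == pytest.approx(np.std(est, ddof=1), rel=0.15)

    def test_boundary_fit_se_flagged(self):
        rng = np.random.default_rng(29)
        e1 = rng.standard_normal(200)
        e2 = rng.standard_normal(200)
        mz = ZygosityData.from_arrays(22 + e1, 22 + e2)  # no genetic variance
        dz = ZygosityData.from_arrays(22 + rng.standard_normal(200),
                                      22 + rng.standard_normal(200))
        fit = tv.fit_variance_model(mz, dz, "AE")
        if fit.boundary:
            assert not fit.se_valid
            with pytest.raises(Exception):
                tv.agsd_standard_error(fit)

    def test_agsd_standard_error_accessor(self, ae_dataset):
        mz, dz, _ = ae_dataset(300, 300, seed=31)
        fit = tv.fit_variance_model(mz, dz, "AE")
        assert tv.agsd_standard_error(fit) == fit.agsd_se > 0


class TestModelSelection:
    def test_ae_selected_on_ae_data(self, ae_dataset):
        picks = []
        for seed in range(40):
            mz, dz, _ = ae_dataset(1000, 1000, seed=100 + seed)
            picks.append(tv.select_model(fit_all_models(mz, dz)))
        assert np.mean([p == "AE" for p in picks]) >= 0.9

    def test_zero_c_gives_identical_loglik_and_ae(self, ae_dataset):
        mz, dz, _ = ae_dataset(500, 500, seed=41)
        fits = fit_all_models(mz, dz)
        if fits["ACE"].var_c < 1e-6:
            assert fits["ACE"].loglik == pytest.approx(fits["AE"].loglik, abs=1e-5)
        assert tv.select_model(fits) in ("AE", "E")

    def test_forced_ae(self, ae_dataset):
        mz, dz, _ = ae_dataset(50, 50, seed=43)
        assert tv.select_model(fit_all_models(mz, dz), force="AE") == "AE"

    def test_missing_fit_errors(self):
        with pytest.raises(ConfigError):
            tv.select_model({"AE": None})


class TestHeritability:
    def test_examples(self, ae_dataset):
        from twinvar.types import VarianceFit
        fit = VarianceFit(model="AE", mu=22, var_a=9, var_c=0, var_d=0, var_e=3,
                          agsd=3, agsd_se=0.1, esd=math.sqrt(3), esd_se=0.1,
                          loglik=0.0, n_pairs_mz=10, n_pairs_dz=10)
        assert tv.heritability(fit) == pytest.approx(0.75)
        fit.var_a = 0
        assert tv.heritability(fit) == 0.0
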