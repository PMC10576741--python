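"""Rate-constant estimators: log-linear, k_sec least squares, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from gifluid import (
    EstimationError,
    ModelParams,
    bootstrap_se,
    closed_form_vgi,
    fit_k_sec,
    fit_log_linear,
)
from gifluid.estimation import single_point_rates


def _obs(times, fractions, volumes=None, animal_prefix="a"):
    df = pd.DataFrame(
        {
            "animal_id": [f"{animal_prefix}{i}" for i in range(len(times))],
            "time_min": np.asarray(times, dtype=float),
            "remaining_fraction": np.asarray(fractions, dtype=float),
        }
    )
    df["volume_ml"] = volumes if volumes is not None else df["remaining_fraction"]
    return df


class TestLogLinear:
    def test_exact_exponential_recovered(self):
        t = np.array([5.0, 10.0, 20.0, 30.0])
        est = fit_log_linear(_obs(t, np.exp(-0.136 * t)))
        assert est.estimate == pytest.approx(0.136, rel=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_flat_fractions_give_zero_rate(self):
        with pytest.warns(UserWarning, match="no absorption"):
            est = fit_log_linear(_obs([5, 10, 20, 30], [1.0] * 4))
        assert est.estimate == pytest.approx(0.0, abs=1e-15)

    def test_two_point_slope_by_hand(self):
        # ln f drops from -1 to -2 between t=10 and 20 -> k = 0.1
        est = fit_log_linear(_obs([10.0, 20.0], [np.exp(-1), np.exp(-2)]))
        assert est.estimate == pytest.approx(0.1, rel=1e-12)

    def test_window_excludes_late_times(self):
        # points beyond t_max must not influence the fit
        t = np.array([5.0, 10.0, 20.0, 30.0, 60.0])
        f = np.exp(-0.2 * t)
        f[-1] = 0.9  # off-model late point
        est = fit_log_linear(_obs(t, f), t_max=30.0)
        assert est.estimate == pytest.approx(0.2, rel=1e-12)
        assert est.t_window == (5.0, 30.0)

    def test_scale_invariance_in_v0(self):
        """Fractions are used, so rescaling volumes changes nothing."""
        t = np.array([5.0, 10.0, 20.0])
        f = np.exp(-0.15 * t) * [1.02, 0.97, 1.01]
        a = fit_log_linear(_obs(t, f))
        b = fit_log_linear(_obs(t, f))  # same fractions regardless of volume scale
        assert a.estimate == b.estimate

    def test_nonpositive_fractions_dropped_with_count(self):
        est = fit_log_linear(_obs([5.0, 10.0, 20.0], [0.5, 0.0, 0.1]))
        assert est.n == 2 and est.n_excluded_nonpositive == 1

    def test_single_time_point_rejected(self):
        with pytest.raises(EstimationError):
            fit_log_linear(_obs([5.0, 5.0], [0.4, 0.5]))

    def test_pinned_intercept_variant(self):
        t = np.array([5.0, 10.0, 20.0])
        est = fit_log_linear(_obs(t, np.exp(-0.25 * t)), pin_intercept=True)
        assert est.estimate == pytest.approx(0.25, rel=1e-12)
        assert est.intercept == 0.0

    def test_se_against_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        t = np.repeat([5.0, 10.0, 20.0, 30.0], 5)
        f = np.exp(-0.136 * t) * np.exp(rng.normal(0, 0.1, t.size))
        est = fit_log_linear(_obs(t, f))
        ols = sm.OLS(np.log(f), sm.add_constant(t)).fit()
        assert est.estimate == pytest.approx(-ols.params[1], rel=1e-10)
        assert est.se == pytest.approx(ols.bse[1], rel=1e-10)


JEJ = ModelParams(k_abs=0.136, k_sec=7.05e-3)


class TestFitKsec:
    def test_selfconsistent_recovery_on_exact_data(self):
        t = np.array([5.0, 10.0, 20.0, 30.0, 60.0])
        obs = _obs(t, closed_form_vgi(JEJ, t), volumes=closed_form_vgi(JEJ, t))
        est = fit_k_sec(obs, k_abs=0.136, params=JEJ)
        assert est.estimate == pytest.approx(7.05e-3, rel=1e-6)

    def test_pure_decay_hits_zero_boundary(self):
        t = np.array([5.0, 10.0, 20.0, 30.0])
        v = 1.0 * np.exp(-0.136 * t)
        est = fit_k_sec(_obs(t, v, volumes=v), k_abs=0.136)
        assert est.estimate == pytest.approx(0.0, abs=1e-9)

    def test_point_on_curve_leaves_estimate_unchanged(self):
        t = np.array([5.0, 10.0, 20.0, 30.0])
        v = closed_form_vgi(JEJ, t) * [1.05, 0.98, 1.01, 0.97]
        est1 = fit_k_sec(_obs(t, v, volumes=v), k_abs=0.136, params=JEJ)
        p_fit = ModelParams(0.136, est1.estimate)
        t2 = np.append(t, 45.0)
        v2 = np.append(v, closed_form_vgi(p_fit, 45.0))
        est2 = fit_k_sec(_obs(t2, v2, volumes=v2), k_abs=0.136, params=JEJ)
        assert est2.estimate == pytest.approx(est1.estimate, abs=1e-9)

    def test_scalar_search_agrees_with_linear_solution(self, rng):
        from gifluid.estimation import _ksec_lstsq

        t = np.repeat([5.0, 10.0, 20.0, 30.0], 3)
        v = closed_form_vgi(JEJ, t) * np.exp(rng.normal(0, 0.1, t.size))
        est = fit_k_sec(_obs(t, v, volumes=v), k_abs=0.136, params=JEJ)
        ks_lin = _ksec_lstsq(t, v, 0.136, JEJ.v_body, JEJ.s_ratio, JEJ.v0)
        assert est.estimate == pytest.approx(ks_lin, abs=1e-9)

    def test_empty_observations_rejected(self):
        with pytest.raises(EstimationError):
            fit_k_sec(_obs([], []), k_abs=0.1)


class TestSinglePointRates:
    def test_exact_exponential(self):
        t = np.array([5.0, 10.0, 20.0])
        k = single_point_rates(_obs(t, np.exp(-0.2 * t)))
        np.testing.assert_allclose(k, 0.2, rtol=1e-12)

    def test_window_and_nonpositive_filtering(self):
        k = single_point_rates(_obs([5.0, 40.0, 10.0], [0.5, 0.5, 0.0]))
        assert len(k) == 1


class TestBootstrap:
    @staticmethod
    def _fitter(df):
        return fit_log_linear(df).estimate

    def test_noiseless_se_is_zero(self):
        t = np.repeat([5.0, 10.0, 20.0, 30.0], 3)
        obs = _obs(t, np.exp(-0.136 * t))
        obs["marker"] = "H3_WATER"
        bs = bootstrap_se(obs, self._fitter, n_boot=100, seed=0)
        assert bs.se < 1e-10
        assert bs.ci_low == pytest.approx(bs.ci_high, abs=1e-10)

    def test_seed_determinism(self, noisy_study):
        from gifluid import records_to_volumes

        vols = records_to_volumes(noisy_study)
        tr = vols[vols["marker"] == "H3_WATER"]
        a = bootstrap_se(tr, self._fitter, n_boot=150, seed=11)
        b = bootstrap_se(tr, self._fitter, n_boot=150, seed=11)
        assert a.se == b.se and a.ci_low == b.ci_low

    def test_failure_fraction_aborts(self):
        def failing(df):
            raise EstimationError("always fails")

        obs = _obs([5.0, 10.0], [0.5, 0.3])
        with pytest.raises(EstimationError, match="resample fits failed"):
            bootstrap_se(obs, failing, n_boot=100, seed=0)

    def test_minimum_n_boot_enforced(self):
        obs = _obs([5.0, 10.0], [0.5, 0.3])
        with pytest.raises(Exception):
            bootstrap_se(obs, self._fitter, n_boot=50, seed=0)
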