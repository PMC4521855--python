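"""Transfer functions, SARIMA fitting, joint intervention estimation,
pruning, diagnostics and effect sizes."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from bushmarket import intervention_ts as it
from bushmarket import synthetic_market as sm

MONTHS = pd.period_range("1997-10", periods=60, freq="M")


class TestTransferResponse:
    def test_pure_step(self):
        spec = it.InterventionSpec("2000-01", step_weight=1.0)
        resp = it.transfer_response(spec, MONTHS)
        k = MONTHS.get_loc(pd.Period("2000-01", "M"))
        assert np.all(resp[:k] == 0.0)
        assert np.all(resp[k:] == 1.0)

    def test_pulse_without_lag_is_single_spike(self):
        spec = it.InterventionSpec("1998-02", pulse_weight=-1.357)
        resp = it.transfer_response(spec, MONTHS)
        k = MONTHS.get_loc(pd.Period("1998-02", "M"))
        assert resp[k] == pytest.approx(-1.357)
        assert np.count_nonzero(resp) == 1

    def test_lagged_pulse_geometric_decay(self):
        spec = it.InterventionSpec("2000-01", pulse_weight=-5.202, lag_delta=0.945)
        resp = it.transfer_response(spec, MONTHS)
        k = MONTHS.get_loc(pd.Period("2000-01", "M"))
        assert resp[k + 1] == pytest.approx(-5.202 * 0.945)
        assert resp[k + 2] == pytest.approx(-5.202 * 0.945**2)

    @given(
        w_s=st.one_of(st.none(), st.floats(-5, 5)),
        w_p=st.floats(-6, 6),
        delta=st.floats(-0.95, 0.95),
        event=st.integers(0, 59),
    )
    @settings(max_examples=50, deadline=None)
    def test_recursion_identity(self, w_s, w_p, delta, event):
        """m_t - delta*m_{t-1} = w_P*P_t + w_S*(S_t - delta*S_{t-1}) holds
        exactly at every t."""
        spec = it.InterventionSpec(
            MONTHS[event], step_weight=w_s, pulse_weight=w_p, lag_delta=delta
        )
        m = it.transfer_response(spec, MONTHS)
        k = np.arange(len(MONTHS)) - event
        P = (k == 0).astype(float)
        S = (k >= 0).astype(float)
        ws = w_s if w_s is not None else 0.0
        lhs = m[1:] - delta * m[:-1]
        rhs = w_p * P[1:] + ws * (S[1:] - delta * S[:-1])
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_event_after_series_rejected(self):
        spec = it.InterventionSpec("2030-01", step_weight=1.0)
        with pytest.raises(ValueError, match="after the series"):
            it.transfer_response(spec, MONTHS)

    def test_invalid_lag_rejected(self):
        with pytest.raises(ValueError, match="lag_delta"):
            it.InterventionSpec("2000-01", pulse_weight=1.0, lag_delta=1.0)
        with pytest.raises(ValueError, match="component"):
            it.InterventionSpec("2000-01")


class TestSarimaFit:
    def test_white_noise_null_model(self, rng):
        z = pd.Series(rng.normal(0, 1, 200))
        fit = it.sarima_fit(z, it.SarimaSpec(p=1, P=0))
        assert abs(fit.spec.ar[0]) < 2 * fit.ses["ar.L1"]

    def test_css_matches_brute_force_grid(self):
        """AR(1) conditional-least-squares estimate equals direct numeric
        minimization of the conditional sum of squares."""
        rng = np.random.default_rng(8)
        y = np.empty(40)
        y[0] = 0.0
        for t in range(1, 40):
            y[t] = 1.0 + 0.6 * y[t - 1] + rng.normal()
        fit = it.sarima_fit(pd.Series(y), it.SarimaSpec(p=1, P=0), method="css")

        def css(theta):
            mu, phi = theta
            e = (y[1:] - mu) - phi * (y[:-1] - mu)
            return np.sum(e**2)

        best = optimize.brute(
            css, ranges=[(0.0, 5.0), (-0.99, 0.99)], Ns=60, finish=optimize.fmin
        )
        assert fit.spec.mean == pytest.approx(best[0], abs=1e-3)
        assert fit.spec.ar[0] == pytest.approx(best[1], abs=1e-3)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            it.sarima_fit(pd.Series(np.zeros(20)))

    def test_mean_recovered(self, study_noise):
        z = sm.generate_sqrt_series(replace(study_noise, mean=2.0, sigma=1.0), [], 400, seed=3)
        fit = it.sarima_fit(z)
        assert fit.spec.mean == pytest.approx(2.0, abs=3 * fit.ses["intercept"])


class TestArimaxFit:
    def test_empty_interventions_reproduces_sarima_fit(self, study_noise):
        z = sm.generate_sqrt_series(study_noise, [], 121, seed=4)
        base = it.sarima_fit(z)
        joint = it.arimax_fit(z, it.SarimaSpec(), [])
        assert joint.llf == pytest.approx(base.llf, abs=1e-8)
        assert joint.noise.spec.ar == base.spec.ar

    def test_noiseless_step_recovered_exactly(self):
        """A deterministic step series returns the step weight to
        optimizer tolerance."""
        months = pd.period_range("1997-10", periods=80, freq="M")
        truth = it.InterventionSpec("2001-01", step_weight=-2.5)
        z = pd.Series(4.0 + it.transfer_response(truth, months), index=months)
        # tiny jitter keeps the Gaussian likelihood finite
        z = z + 1e-7 * np.sin(np.arange(80))
        fit = it.arimax_fit(z, it.SarimaSpec(p=1, P=0),
                            [it.InterventionSpec("2001-01", step_weight=0.0)])
        assert fit.interventions[0].step_weight == pytest.approx(-2.5, abs=1e-4)
        assert fit.noise.spec.mean == pytest.approx(4.0, abs=1e-4)

    def test_zero_weight_interventions_near_zero(self, study_noise):
        z = sm.generate_sqrt_series(replace(study_noise, mean=2.0), [], 156, seed=9)
        shapes = [it.InterventionSpec("2003-11", step_weight=0.0, pulse_weight=0.0)]
        fit = it.arimax_fit(z, it.SarimaSpec(), shapes)
        got = fit.interventions[0]
        assert abs(got.step_weight) < 2.5 * got.step_se
        assert abs(got.pulse_weight) < 2.5 * got.pulse_se

    def test_collinear_components_rejected(self, study_noise):
        z = sm.generate_sqrt_series(study_noise, [], 121, seed=1)
        shapes = [
            it.InterventionSpec("2003-11", step_weight=0.0),
            it.InterventionSpec("2003-11", step_weight=0.0),
        ]
        with pytest.raises(ValueError, match="collinear"):
            it.arimax_fit(z, it.SarimaSpec(), shapes)

    def test_aic_favors_true_event_and_penalizes_null(self, study_noise):
        """Adding the true step event lowers AIC; adding a spurious event
        raises it on average across simulations."""
        noise = replace(study_noise, mean=2.0)
        truth = [it.InterventionSpec("2004-06", step_weight=1.5)]
        d_true, d_null = [], []
        for seed in range(12):
            z = sm.generate_sqrt_series(noise, truth, 121, seed=seed)
            bare = it.arimax_fit(z, it.SarimaSpec(), [])
            with_true = it.arimax_fit(
                z, it.SarimaSpec(), [it.InterventionSpec("2004-06", step_weight=0.0)]
            )
            with_null = it.arimax_fit(
                z, it.SarimaSpec(),
                [
                    it.InterventionSpec("2004-06", step_weight=0.0),
                    it.InterventionSpec("2001-01", pulse_weight=0.0),
                ],
            )
            d_true.append(with_true.aic - bare.aic)
            d_null.append(with_null.aic - with_true.aic)
        assert np.mean(d_true) < 0  # real effect earns its parameter
        assert np.mean(d_null) > 0  # spurious one does not


class TestPrune:
    def test_all_significant_unchanged(self, study_noise):
        noise = replace(study_noise, mean=2.0)
        truth = [it.InterventionSpec("2004-06", step_weight=3.0)]
        z = sm.generate_sqrt_series(noise, truth, 121, seed=2)
        fit = it.arimax_fit(z, it.SarimaSpec(), it.fit_shapes(truth))
        pruned = it.prune_nonsignificant(fit)
        assert pruned.interventions[0].step_weight == fit.interventions[0].step_weight

    def test_null_component_removed(self, study_noise):
        noise = replace(study_noise, mean=2.0)
        truth = [it.InterventionSpec("2004-06", step_weight=3.0)]
        z = sm.generate_sqrt_series(noise, truth, 121, seed=5)
        shapes = it.fit_shapes(truth) + [it.InterventionSpec("2001-01", pulse_weight=0.0)]
        pruned = it.prune_nonsignificant(it.arimax_fit(z, it.SarimaSpec(), shapes))
        kept = {s.event_month.strftime("%Y-%m") for s in pruned.interventions}
        assert kept == {"2004-06"}


class TestLjungBox:
    def test_matches_term_by_term_summation(self):
        """Fixed 20-point series: Q equals the hand-computed sum
        n(n+2) * sum rho_k^2/(n-k)."""
        rng = np.random.default_rng(12)
        e = rng.normal(0, 1, 20)
        res = it.ljung_box(e, lags=5)
        n = 20
        ec = e - e.mean()
        denom = np.sum(ec**2)
        q = 0.0
        for k in range(1, 6):
            rho = np.sum(ec[k:] * ec[:-k]) / denom
            q += rho**2 / (n - k)
        q *= n * (n + 2)
        assert res.statistic == pytest.approx(q, abs=1e-12)
        assert res.df == 5
        assert res.pvalue == pytest.approx(stats.chi2.sf(q, 5), abs=1e-12)

    def test_df_adjusted_for_fitted_parameters(self, rng):
        e = rng.normal(0, 1, 100)
        res = it.ljung_box(e, lags=12, n_fitted_params=3)
        assert res.df == 9

    def test_power_against_ar1_residuals(self):
        """Strongly autocorrelated residuals are rejected far more often
        than the 5% nominal level."""
        rejections = 0
        n_rep = 100
        for seed in range(n_rep):
            g = np.random.default_rng(seed)
            e = np.empty(100)
            e[0] = g.normal()
            for t in range(1, 100):
                e[t] = 0.6 * e[t - 1] + g.normal()
            if it.ljung_box(e, lags=10).pvalue < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.5

    def test_constant_residuals_error(self):
        with pytest.raises(ValueError, match="constant"):
            it.ljung_box(np.ones(50), lags=5)

    def test_too_many_lags_error(self):
        with pytest.raises(ValueError, match="lags"):
            it.ljung_box(np.arange(10.0), lags=5)


@pytest.fixture(scope="module")
def step_fit():
    months = pd.period_range("1997-10", periods=80, freq="M")
    truth = it.InterventionSpec("2001-01", step_weight=-3.0)
    rng = np.random.default_rng(3)
    z = pd.Series(
        4.0 + it.transfer_response(truth, months) + 0.05 * rng.normal(size=80),
        index=months,
    )
    return it.arimax_fit(z, it.SarimaSpec(p=1, P=0),
                         [it.InterventionSpec("2001-01", step_weight=0.0)])


class TestPercentChange:
    def test_squared_scale_change(self, step_fit):
        """sqrt-scale 4 -> 1 is a (16-1)/16 = 93.75% decline in rates."""
        pct, ci = it.percent_change(step_fit, "2000-12", "2001-01")
        assert pct == pytest.approx(93.75, abs=0.5)
        assert ci[0] < pct < ci[1]

    def test_no_event_no_change(self, step_fit):
        pct, _ = it.percent_change(step_fit, "1998-02", "1998-03")
        assert pct == pytest.approx(0.0, abs=1e-6)

    def test_delta_and_bootstrap_agree(self, step_fit):
        """Delta-method and parametric-bootstrap CI endpoints agree within
        10% of the interval width."""
        pct, ci_d = it.percent_change(step_fit, "2000-12", "2001-01", method="delta")
        _, ci_b = it.percent_change(
            step_fit, "2000-12", "2001-01", method="bootstrap", n_boot=1000, seed=0
        )
        width = ci_d[1] - ci_d[0]
        assert ci_b[0] == pytest.approx(ci_d[0], abs=0.1 * width + 1e-6)
        assert ci_b[1] == pytest.approx(ci_d[1], abs=0.1 * width + 1e-6)

    def test_month_outside_range_rejected(self, step_fit):
        with pytest.raises(ValueError, match="not in fitted range"):
            it.percent_change(step_fit, "1990-01", "2001-01")
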