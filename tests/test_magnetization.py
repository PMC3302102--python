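"""Two-site longitudinal exchange: simulation and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from gatekin.magnetization import (
    InversionTransferModel,
    MagnetizationCurve,
    TwoSiteExchangeModel,
    fit_inversion_recovery,
    fit_inversion_transfer,
    simulate_inversion_transfer,
)
from gatekin.synthetic import GeneratorConfig, make_inversion_transfer


def study_model(k_star_out=21.0, r1_bound=0.5):
    """Two-site model on the high-guest design (flux balance built in)."""
    return TwoSiteExchangeModel.from_balance(
        k_star_out, 1.0 / 3.30, r1_bound, m_eq_free=0.0485, m_eq_bound=0.0015)


rate_floats = st.floats(0.01, 50.0)


class TestSimulation:
    def test_decoupled_pools_relax_monoexponentially(self):
        m = TwoSiteExchangeModel(0.0, 0.0, 0.4, 0.9, 1.0, 0.3)
        tau = np.linspace(0.0, 5.0, 30)
        c = simulate_inversion_transfer(m, tau)
        expect_free = 1.0 - 2.0 * np.exp(-0.4 * tau)
        np.testing.assert_allclose(c.intensity_free, expect_free, atol=1e-12)
        np.testing.assert_allclose(c.intensity_bound, 0.3, atol=1e-12)

    def test_closed_form_matches_ode_integration(self):
        m = study_model()
        tau = np.linspace(0.0, 2.0, 40)
        c = simulate_inversion_transfer(m, tau)
        K = m.rate_matrix()
        m_eq = np.array([m.m_eq_free, m.m_eq_bound])
        sol = solve_ivp(lambda t, y: -K @ (y - m_eq), (0.0, 2.0),
                        np.array([-m.m_eq_free, m.m_eq_bound]),
                        t_eval=tau, rtol=1e-12, atol=1e-14)
        assert np.max(np.abs(sol.y[0] - np.array(c.intensity_free))) < 1e-8
        assert np.max(np.abs(sol.y[1] - np.array(c.intensity_bound))) < 1e-8

    def test_long_delay_asymptote_is_equilibrium(self):
        m = study_model()
        c = simulate_inversion_transfer(m, [1e3])
        assert c.intensity_free[0] == pytest.approx(m.m_eq_free, rel=1e-9)
        assert c.intensity_bound[0] == pytest.approx(m.m_eq_bound, rel=1e-9)

    def test_partial_inversion_efficiency(self):
        m = study_model()
        c = simulate_inversion_transfer(m, [0.0], inversion_efficiency=0.9)
        assert c.intensity_free[0] == pytest.approx((1 - 1.8) * m.m_eq_free, rel=1e-12)

    @given(rate_floats, rate_floats, rate_floats, st.floats(0.01, 10.0))
    @settings(max_examples=60, deadline=None)
    def test_eigenvalues_real_positive(self, k_out, r1f, r1b, m_b):
        m = TwoSiteExchangeModel.from_balance(k_out, r1f, r1b, 1.0, m_b)
        lam = m.eigenrates()
        assert np.all(np.abs(np.imag(lam)) == 0)
        assert np.all(lam > 0)

    def test_total_deviation_magnetization_decays(self):
        m = study_model()
        tau = np.linspace(0.0, 3.0, 200)
        c = simulate_inversion_transfer(m, tau)
        dev = np.abs(np.array(c.intensity_free) - m.m_eq_free) + \
            np.abs(np.array(c.intensity_bound) - m.m_eq_bound)
        assert np.all(np.diff(dev) <= 1e-12)

    def test_flux_balance_enforced_at_construction(self):
        with pytest.raises(ValueError):
            TwoSiteExchangeModel(1.0, 21.0, 0.3, 0.5, 1.0, 0.9)


class TestInversionTransferFit:
    def test_noise_free_roundtrip(self):
        cfg = GeneratorConfig(seed=5, intensity_noise=0.0)
        curve, truth = make_inversion_transfer(cfg)
        res = fit_inversion_transfer(curve, cfg.t1_free)
        assert res.k_star_out == pytest.approx(truth["k_star_out"], rel=1e-6)
        assert res.k_star_in == pytest.approx(truth["k_star_in"], rel=1e-6)
        assert res.r1_bound == pytest.approx(truth["r1_bound"], rel=1e-4)

    def test_monte_carlo_k_out_recovery(self):
        est = [fit_inversion_transfer(make_inversion_transfer(GeneratorConfig(seed=i))[0],
                                      3.30).k_star_out for i in range(30)]
        assert abs(np.median(est) - 21.0) / 21.0 < 0.15

    def test_missing_channel_rejected(self):
        with pytest.raises(ValueError):
            MagnetizationCurve((0.0, 0.1), None, (1.0, 1.0))

    def test_too_few_delays_rejected(self):
        c = MagnetizationCurve((0.0, 0.1, 0.2), (1.0, 1.1, 1.2), (0.1, 0.1, 0.1))
        with pytest.raises(ValueError):
            InversionTransferModel(c, t1_free=3.30)

    def test_fitted_model_respects_flux_balance(self):
        cfg = GeneratorConfig(seed=2, intensity_noise=0.005)
        curve, _ = make_inversion_transfer(cfg)
        res = fit_inversion_transfer(curve, cfg.t1_free)
        m = res.fitted_model
        assert m.k_star_in * m.m_eq_free == pytest.approx(
            m.k_star_out * m.m_eq_bound, rel=1e-9)


class TestInversionRecovery:
    def test_noise_free_t1_recovery(self):
        t1, m_eq, A = 3.30, 1.0, 1.95
        tau = np.geomspace(0.05, 20.0, 14)
        I = m_eq - A * np.exp(-tau / t1)
        res = fit_inversion_recovery(tau, I)
        assert res.t1 == pytest.approx(t1, rel=1e-8)
        assert res.m_eq == pytest.approx(m_eq, rel=1e-8)

    def test_zero_delay_intensity_identity(self):
        res = fit_inversion_recovery(np.geomspace(0.05, 20.0, 10),
                                     1.0 - 2.0 * np.exp(-np.geomspace(0.05, 20.0, 10) / 3.3))
        assert res.predict([0.0])[0] == pytest.approx(res.m_eq - res.amplitude, rel=1e-12)

    def test_monte_carlo_t1_bias_small(self, rng):
        tau = np.geomspace(0.05, 20.0, 12)
        clean = 1.0 - 2.0 * np.exp(-tau / 3.30)
        est = []
        for _ in range(50):
            I = clean + rng.normal(0.0, 0.01, tau.size)
            est.append(fit_inversion_recovery(tau, I).t1)
        assert abs(np.median(est) - 3.30) / 3.30 < 0.02

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_inversion_recovery([0.1, 1.0, 5.0], [-0.9, 0.2, 0.9])
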