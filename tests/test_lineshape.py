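"""Two-site exchange-broadened line shapes: limits, coalescence, fitting."""

import numpy as np
import pytest

from gatekin.lineshape import (
    ExchangeSpectrum,
    LineshapeModel,
    LineshapeParams,
    coalescence_rate,
    fit_k_from_lineshape,
    simulate_lineshape,
)
from gatekin.synthetic import GeneratorConfig, make_lineshapes
from gatekin.thermokinetics import EyringModel


def lorentzian(f, nu0, width):
    r2 = np.pi * width
    return r2 / (r2 ** 2 + (2 * np.pi * (f - nu0)) ** 2)


class TestSimulation:
    def test_slow_exchange_limit_two_lorentzians(self):
        p = LineshapeParams(nu_a=-50.0, nu_b=50.0, k=1e-9, width=2.0)
        spec = simulate_lineshape(p)
        f, y = spec.frequencies, spec.intensities
        expect = 0.5 * lorentzian(f, -50.0, 2.0) + 0.5 * lorentzian(f, 50.0, 2.0)
        assert np.max(np.abs(y / y.max() - expect / expect.max())) < 0.01

    def test_fast_exchange_limit_single_line_at_mean(self):
        p = LineshapeParams(nu_a=-60.0, nu_b=40.0, k=1e8, width=2.0, p_a=0.25)
        spec = simulate_lineshape(p)
        mean = 0.25 * -60.0 + 0.75 * 40.0
        peak = spec.frequencies[np.argmax(spec.intensities)]
        assert abs(peak - mean) < 0.5
        expect = lorentzian(spec.frequencies, mean, 2.0)
        assert np.max(np.abs(spec.intensities / spec.intensities.max()
                             - expect / expect.max())) < 0.01

    def test_coalescence_at_pi_dnu_over_sqrt2(self):
        dnu = 100.0
        kc = coalescence_rate(dnu)

        def center_curvature(k):
            p = LineshapeParams(nu_a=-50.0, nu_b=50.0, k=k, width=0.5)
            f = np.linspace(-2.0, 2.0, 7)
            return np.polyfit(f, simulate_lineshape(p, f).intensities, 2)[0]

        lo, hi = 0.5 * kc, 2.0 * kc
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if center_curvature(mid) > 0:   # central dip persists: still slow
                lo = mid
            else:
                hi = mid
        assert abs(0.5 * (lo + hi) - kc) / kc < 0.01

    @pytest.mark.parametrize("k_factor", [0.1, 1.0, 10.0])
    def test_integrated_area_independent_of_k(self, k_factor):
        kc = coalescence_rate(100.0)
        f = np.linspace(-6000.0, 6000.0, 60001)
        slow = simulate_lineshape(
            LineshapeParams(-50.0, 50.0, 1e-6, width=2.0), f).intensities
        spec = simulate_lineshape(
            LineshapeParams(-50.0, 50.0, k_factor * kc, width=2.0), f).intensities
        assert np.trapezoid(spec, f) == pytest.approx(np.trapezoid(slow, f), rel=1e-3)

    def test_symmetry_for_equal_populations(self):
        p = LineshapeParams(nu_a=-50.0, nu_b=50.0, k=150.0, width=2.0)
        f = np.linspace(-300.0, 300.0, 1201)
        y = simulate_lineshape(p, f).intensities
        np.testing.assert_allclose(y, y[::-1], rtol=1e-9)

    def test_peak_separation_shrinks_toward_coalescence(self):
        dnu = 100.0
        kc = coalescence_rate(dnu)
        seps = []
        f = np.linspace(-120.0, 120.0, 9601)
        for k in (0.05 * kc, 0.2 * kc, 0.5 * kc, 0.8 * kc):
            y = simulate_lineshape(LineshapeParams(-50.0, 50.0, k, width=1.0), f).intensities
            half = f > 0
            seps.append(2 * f[half][np.argmax(y[half])])
        assert all(s2 <= s1 + 1e-9 for s1, s2 in zip(seps, seps[1:]))

    def test_j_coupling_splits_slow_exchange_doublets(self):
        p = LineshapeParams(nu_a=-50.0, nu_b=50.0, k=1e-9, width=1.0, j=10.0)
        f = np.linspace(-70.0, -30.0, 4001)
        y = simulate_lineshape(p, f).intensities
        peaks = f[np.argsort(y)[-200:]]
        assert peaks.min() < -53.0 and peaks.max() > -47.0  # two components at ±J/2


class TestFitting:
    def test_noise_free_rate_recovery(self):
        truth = 300.0
        p = LineshapeParams(nu_a=-50.0, nu_b=50.0, k=truth, width=2.0, j=10.0)
        spec = simulate_lineshape(p)
        res = fit_k_from_lineshape(spec, LineshapeParams(-50.0, 50.0, 1.0, 2.0, j=10.0))
        assert res.k == pytest.approx(truth, rel=1e-4)
        assert res.ab_approximation

    @pytest.mark.parametrize("k_factor", [0.1, 1.0, 10.0])
    def test_monte_carlo_bias_under_noise(self, k_factor, rng):
        kc = coalescence_rate(100.0)
        truth = k_factor * kc
        p = LineshapeParams(nu_a=-50.0, nu_b=50.0, k=truth, width=2.0)
        clean = simulate_lineshape(p)
        peak = clean.intensities.max()
        est = []
        for _ in range(15):
            noisy = ExchangeSpectrum(
                clean.frequencies,
                clean.intensities + rng.normal(0.0, 0.01 * peak, clean.intensities.size))
            est.append(LineshapeModel(noisy, LineshapeParams(-50.0, 50.0, 1.0, 2.0)).fit().k)
        assert abs(np.median(est) - truth) / truth < 0.05

    def test_spectrum_must_cover_both_sites(self):
        spec = simulate_lineshape(LineshapeParams(-50.0, 50.0, 10.0, 2.0),
                                  np.linspace(-10.0, 10.0, 101))
        with pytest.raises(ValueError):
            LineshapeModel(spec, LineshapeParams(-50.0, 50.0, 1.0, 2.0))

    def test_temperature_series_feeds_eyring_within_3pct(self):
        cfg = GeneratorConfig(seed=13, ls_noise=0.002)
        spectra, truth = make_lineshapes(cfg)
        temps, rates = [], []
        for T, spec in spectra:
            fixed = LineshapeParams(cfg.nu_a, cfg.nu_b, 1.0, cfg.linewidth,
                                    j=cfg.j_coupling)
            temps.append(T)
            rates.append(LineshapeModel(spec, fixed).fit().k)
        res = EyringModel(temps, rates).fit()
        assert res.dH == pytest.approx(truth["dH_rac"], rel=0.03)
        dg_true = truth["dH_rac"] - 250.0 * truth["dS_rac"]
        assert res.barrier(250.0).value == pytest.approx(dg_true, rel=0.03)
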