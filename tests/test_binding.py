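"""Speciation, isotherm fitting and rate-law order diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatekin.binding import (
    ExchangeRatePair,
    TitrationModel,
    TitrationSeries,
    elementary_from_magnetization,
    fit_isotherm,
    order_diagnostics,
    speciation,
)
from gatekin.synthetic import GeneratorConfig, make_titration


def fixed_point_complex(B0, G0, K):
    """Independent speciation oracle: bisection on K(B0-x)(G0-x) = x."""
    f = lambda x: K * (B0 - x) * (G0 - x) - x
    lo, hi = 0.0, min(B0, G0)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestSpeciation:
    def test_no_binding_limit(self):
        s = speciation(1e-3, 5e-2, 0.0)
        assert s.complex == 0.0 and s.host_free == 1e-3 and s.guest_free == 5e-2

    def test_against_fixed_point_oracle(self):
        # high-guest design with the kinetic K_a = k_in/k_out
        s = speciation(1.65e-3, 50.0e-3, 210.0)
        x = fixed_point_complex(1.65e-3, 50.0e-3, 210.0)
        assert s.complex == pytest.approx(x, rel=1e-10)
        assert s.complex == pytest.approx(1.5024741484e-3, rel=1e-8)  # frozen oracle value
        assert s.host_free == pytest.approx(0.14752585e-3, rel=1e-6)

    def test_symmetric_point_matches_oracle(self):
        K = 54.0
        B0 = G0 = 1.0 / K
        s = speciation(B0, G0, K)
        assert s.complex == pytest.approx(fixed_point_complex(B0, G0, K), rel=1e-10)

    @given(st.floats(1e-6, 1e-1), st.floats(1e-6, 1.0), st.floats(0.0, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_mass_balance_and_equilibrium(self, B0, G0, K):
        s = speciation(B0, G0, K)
        assert s.host_free + s.complex == pytest.approx(B0, rel=1e-12)
        assert s.guest_free + s.complex == pytest.approx(G0, rel=1e-12)
        if K > 0 and s.complex > 1e-14:
            assert K * s.host_free * s.guest_free == pytest.approx(s.complex, rel=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            speciation(-1e-3, 1e-2, 54.0)


class TestIsothermFit:
    def test_noise_free_exact_recovery(self):
        cfg = GeneratorConfig(seed=0, shift_noise=0.0)
        series, truth = make_titration(cfg)
        res = fit_isotherm(series)
        assert res.K_a == pytest.approx(truth["K_a"], rel=1e-6)
        assert res.delta_free == pytest.approx(truth["delta_free"], abs=1e-8)
        assert res.delta_bound == pytest.approx(truth["delta_bound"], abs=1e-6)
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_point_order_invariance(self):
        series, _ = make_titration(GeneratorConfig(seed=3))
        res = fit_isotherm(series)
        perm = np.random.default_rng(0).permutation(len(series.guest_total))
        shuffled = TitrationSeries(
            tuple(np.array(series.host_total)[perm]),
            tuple(np.array(series.guest_total)[perm]),
            tuple(np.array(series.observed_shift)[perm]))
        res2 = fit_isotherm(shuffled)
        assert res2.K_a == pytest.approx(res.K_a, rel=1e-5)

    def test_constant_shift_rejected(self):
        with pytest.raises(ValueError):
            TitrationModel([1e-3] * 5, [0, 0.1, 0.2, 0.3, 0.4], [7.0] * 5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            TitrationModel([1e-3] * 3, [0, 0.1, 0.2], [7.0, 7.1, 7.2])

    def test_monte_carlo_recovery_within_5pct(self):
        est = [fit_isotherm(make_titration(GeneratorConfig(seed=i))[0]).K_a
               for i in range(40)]
        assert abs(np.median(est) - 54.0) / 54.0 < 0.05

    def test_fit_quality_on_study_design(self):
        series, _ = make_titration(GeneratorConfig(seed=11))
        assert fit_isotherm(series).rsquared >= 0.99


class TestElementaryRates:
    def test_kin_from_pseudo_first_order(self):
        from gatekin.binding import SpeciationState

        pair = ExchangeRatePair(0.21, 10.0)
        state = SpeciationState(host_free=1.0e-4, guest_free=4.8e-2,
                                complex=1.4e-3, K_a=210.0)
        out = elementary_from_magnetization(pair, state)
        assert out["k_in"] == pytest.approx(2.1e3, rel=1e-12)
        assert out["k_out"] == 10.0

    def test_detailed_balance_identity(self):
        k_in, k_out = 2.1e3, 10.0
        s = speciation(1.65e-3, 50e-3, k_in / k_out)
        assert k_in * s.host_free * s.guest_free == pytest.approx(
            k_out * s.complex, rel=1e-9)

    def test_zero_free_host_rejected(self):
        pair = ExchangeRatePair(0.21, 10.0)
        from gatekin.binding import SpeciationState

        state = SpeciationState(0.0, 1e-2, 1e-3, 100.0)
        with pytest.raises(ZeroDivisionError):
            elementary_from_magnetization(pair, state)


def _mechanism_data(k_in=2.1e3, k_out=10.0, interchange=0.0):
    """Rates over a concentration series under a chosen mechanism."""
    K = k_in / k_out
    pairs, states = [], []
    for G0 in (0.016, 0.05, 0.1, 0.15, 0.2):
        s = speciation(1.65e-3, G0, K)
        kso = k_out + interchange * s.guest_free  # interchange adds guest-order term
        pairs.append(ExchangeRatePair(k_in * s.host_free, kso))
        states.append(s)
    return pairs, states


class TestOrderDiagnostics:
    def test_first_order_mechanism_classified(self):
        pairs, states = _mechanism_data()
        diag = order_diagnostics(pairs, states)
        assert diag.kin_rsquared > 0.99
        assert diag.kout_flat
        assert diag.mechanism == "dissociative"
        assert diag.k_in == pytest.approx(2.1e3, rel=1e-6)

    def test_interchange_mechanism_detected(self):
        pairs, states = _mechanism_data(interchange=200.0)
        diag = order_diagnostics(pairs, states)
        assert not diag.kout_flat
        assert diag.mechanism == "interchange-like"

    def test_hyperbolic_guest_dependence(self):
        # k*_in = k_out.[complex]/(K_a.[G_free]) ~ a/[G_free] at high guest
        pairs, states = _mechanism_data()
        diag = order_diagnostics(pairs, states)
        assert diag.hyperbola_rsquared > 0.95

    def test_degenerate_design_rejected(self):
        s = speciation(1.65e-3, 0.05, 210.0)
        pair = ExchangeRatePair(0.2, 10.0)
        with pytest.raises(ValueError):
            order_diagnostics([pair, pair, pair], [s, s, s])

    def test_too_few_conditions_rejected(self):
        pairs, states = _mechanism_data()
        with pytest.raises(ValueError):
            order_diagnostics(pairs[:2], states[:2])
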