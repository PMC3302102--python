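"""1:1 host-guest speciation, titration-isotherm fitting, and the rate law
mapping pseudo-first-order magnetization exchange rates to elementary rate
constants.

The encapsulation rate law under test is

    rate_in  = k_in [host][guest]        (first order in each)
    rate_out = k_out [complex]           (zeroth order in free guest)

so the pseudo-first-order magnetization coefficients obey k*_in = k_in·[host]
(equivalently k*_in = k_out·[complex]/(K_a·[guest]) at equilibrium) while
k*_out = k_out is concentration independent.  ``order_diagnostics`` tests
exactly these signatures and flags the alternative interchange mechanism
(direct guest-by-guest displacement), which would make k*_out grow with the
free-guest concentration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

__all__ = [
    "SpeciationState",
    "TitrationSeries",
    "ExchangeRatePair",
    "speciation",
    "bound_fraction",
    "TitrationModel",
    "TitrationResults",
    "fit_isotherm",
    "elementary_from_magnetization",
    "OrderDiagnostics",
    "order_diagnostics",
]


@dataclass(frozen=True)
class SpeciationState:
    """Equilibrium concentrations (M) of free host, free guest and 1:1 complex."""

    host_free: float
    guest_free: float
    complex: float
    K_a: float

    def __post_init__(self) -> None:
        for name in ("host_free", "guest_free", "complex", "K_a"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def host_total(self) -> float:
        return self.host_free + self.complex

    @property
    def guest_total(self) -> float:
        return self.guest_free + self.complex


def speciation(host_total: float, guest_total: float, K_a: float) -> SpeciationState:
    """Solve the 1:1 binding equilibrium for given totals and K_a.

    The complex concentration is the physical (smaller) root of

        K_a·x² − (K_a·(B0+G0) + 1)·x + K_a·B0·G0 = 0,

    evaluated in the numerically stable form 2c/(−b + sqrt(b² − 4ac)) so mass
    balance holds to machine precision even for weak binding.
    """
    if host_total < 0 or guest_total < 0 or K_a < 0:
        raise ValueError("totals and K_a must be non-negative")
    if K_a == 0 or host_total == 0 or guest_total == 0:
        return SpeciationState(host_total, guest_total, 0.0, K_a)
    a = K_a
    b = -(K_a * (host_total + guest_total) + 1.0)
    c = K_a * host_total * guest_total
    disc = b * b - 4.0 * a * c
    x = 2.0 * c / (-b + math.sqrt(disc))
    x = min(x, host_total, guest_total)  # guard rounding at saturation
    return SpeciationState(host_total - x, guest_total - x, x, K_a)


def bound_fraction(host_total: float, guest_total: float, K_a: float) -> float:
    """Fraction of host bound, [complex]/[host]_total."""
    if host_total == 0:
        return 0.0
    return speciation(host_total, guest_total, K_a).complex / host_total


@dataclass(frozen=True)
class TitrationSeries:
    """An NMR titration: host/guest totals (M) and the observed shift (ppm)."""

    host_total: tuple
    guest_total: tuple
    observed_shift: tuple

    def __post_init__(self) -> None:
        n = len(self.host_total)
        if len(self.guest_total) != n or len(self.observed_shift) != n:
            raise ValueError("titration columns differ in length")
        if any(g < 0 for g in self.guest_total) or any(h < 0 for h in self.host_total):
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class ExchangeRatePair:
    """Pseudo-first-order magnetization exchange rates under one condition."""

    k_star_in: float
    k_star_out: float
    conditions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_star_in <= 0 or self.k_star_out <= 0:
            raise ValueError("exchange rates must be positive")


@dataclass
class TitrationResults:
    """1:1 isotherm fit: association constant and limiting shifts.

    The fitted model is δ_obs = δ_free + (δ_bound − δ_free)·f_bound with the
    bound fraction from the exact 1:1 speciation at each titration point.
    """

    K_a: float
    delta_free: float
    delta_bound: float
    K_a_se: float
    delta_free_se: float
    delta_bound_se: float
    rsquared: float
    nobs: int
    model: "TitrationModel" = None

    def predict(self, host_total=None, guest_total=None) -> np.ndarray:
        m = self.model
        B = np.asarray(m.host_total if host_total is None else host_total, dtype=float)
        G = np.asarray(m.guest_total if guest_total is None else guest_total, dtype=float)
        f = np.array([bound_fraction(b, g, self.K_a) for b, g in zip(np.broadcast_to(B, G.shape), G)])
        return self.delta_free + (self.delta_bound - self.delta_free) * f

    def summary(self) -> str:
        lines = [
            "1:1 binding isotherm fit",
            f"  n points : {self.nobs}",
            f"  K_a      : {self.K_a:.4g} ± {self.K_a_se:.2g} M⁻¹",
            f"  δ_free   : {self.delta_free:.4f} ± {self.delta_free_se:.2g} ppm",
            f"  δ_bound  : {self.delta_bound:.4f} ± {self.delta_bound_se:.2g} ppm",
            f"  R²       : {self.rsquared:.6f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed shifts and the fitted isotherm versus total guest."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.plot(m.guest_total, m.shift, "o", label="observed")
        grid = np.linspace(0, float(np.max(m.guest_total)), 200)
        B = np.full_like(grid, float(np.mean(m.host_total)))
        ax.plot(grid, self.predict(B, grid), "-", label=f"fit, K_a={self.K_a:.1f} M⁻¹")
        ax.set_xlabel("guest total (M)")
        ax.set_ylabel("shift (ppm)")
        ax.legend()
        return ax


class TitrationModel:
    """Nonlinear least-squares fit of an NMR titration to the 1:1 model."""

    def __init__(self, host_total, guest_total, shift):
        self.host_total = np.asarray(host_total, dtype=float)
        self.guest_total = np.asarray(guest_total, dtype=float)
        self.shift = np.asarray(shift, dtype=float)
        if not (self.host_total.size == self.guest_total.size == self.shift.size):
            raise ValueError("titration columns differ in length")
        if self.shift.size < 4:
            raise ValueError("need at least 4 titration points")
        if np.ptp(self.shift) == 0:
            raise ValueError("degenerate titration: observed shift is constant")

    @classmethod
    def from_series(cls, series: TitrationSeries) -> "TitrationModel":
        return cls(series.host_total, series.guest_total, series.observed_shift)

    @classmethod
    def from_dataframe(cls, df) -> "TitrationModel":
        return cls(df["host_total_M"].to_numpy(), df["guest_total_M"].to_numpy(),
                   df["shift_ppm"].to_numpy())

    def _predict(self, K_a, d_free, d_bound):
        f = np.array([bound_fraction(b, g, K_a)
                      for b, g in zip(self.host_total, self.guest_total)])
        return d_free + (d_bound - d_free) * f

    def fit(self, K_a0: float | None = None) -> TitrationResults:
        y = self.shift
        g = self.guest_total
        d_free0 = y[np.argmin(g)]
        d_bound0 = y[np.argmax(g)] + (y[np.argmax(g)] - d_free0) * 0.2
        if d_bound0 == d_free0:
            d_bound0 = d_free0 + np.ptp(y)
        if K_a0 is None:
            gpos = g[g > 0]
            K_a0 = 1.0 / float(np.median(gpos)) if gpos.size else 1.0

        def resid(theta):
            K, df_, db_ = theta
            return self._predict(K, df_, db_) - y

        sol = least_squares(resid, x0=[K_a0, d_free0, d_bound0],
                            bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol.success:
            raise RuntimeError(f"isotherm fit failed: {sol.message}")
        K, d_free, d_bound = sol.x
        n, p = y.size, 3
        dof = max(n - p, 1)
        s2 = 2.0 * sol.cost / dof
        JTJ = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(JTJ) * s2
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
        ss_res = float(np.sum(resid(sol.x) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        return TitrationResults(K_a=K, delta_free=d_free, delta_bound=d_bound,
                                K_a_se=se[0], delta_free_se=se[1], delta_bound_se=se[2],
                                rsquared=rsq, nobs=n, model=self)


def fit_isotherm(series: TitrationSeries) -> TitrationResults:
    """Convenience wrapper: ``TitrationModel.from_series(series).fit()``."""
    return TitrationModel.from_series(series).fit()


def elementary_from_magnetization(pair: ExchangeRatePair, state: SpeciationState) -> dict:
    """Map pseudo-first-order magnetization rates to elementary rate constants.

    Under the dissociative rate law, k_in = k*_in/[host_free] (M^-1 s^-1) and
    k_out = k*_out unchanged (the dissociation is zeroth order in free guest).
    """
    if state.host_free <= 0:
        raise ZeroDivisionError("free-host concentration must be positive to recover k_in")
    return {"k_in": pair.k_star_in / state.host_free, "k_out": pair.k_star_out}


@dataclass
class OrderDiagnostics:
    """Reaction-order diagnostics over a set of exchange-rate conditions.

    ``kin_*`` describe the straight-line fit of k*_in against the free-host
    concentration (slope = second-order k_in); ``hyperbola_*`` the one-parameter
    fit k*_in = a/[guest_free]; ``kout_*`` the slope test of k*_out against the
    free-guest concentration.  ``kout_flat`` is True when the 95% confidence
    interval on that slope contains zero — the signature of a dissociative
    (zeroth-order-in-guest) mechanism; a non-flat positive slope points to an
    interchange (direct displacement) mechanism.
    """

    k_in: float
    k_in_se: float
    kin_intercept: float
    kin_rsquared: float
    hyperbola_coeff: float
    hyperbola_rsquared: float
    kout_mean: float
    kout_sd: float
    kout_slope: float
    kout_slope_ci: tuple
    kout_flat: bool
    nobs: int

    @property
    def mechanism(self) -> str:
        return "dissociative" if self.kout_flat else "interchange-like"

    def summary(self) -> str:
        lo, hi = self.kout_slope_ci
        return "\n".join([
            "Rate-law order diagnostics",
            f"  n conditions        : {self.nobs}",
            f"  k_in (slope)        : {self.k_in:.4g} ± {self.k_in_se:.2g} M⁻¹s⁻¹ (R²={self.kin_rsquared:.4f})",
            f"  k*_in hyperbola a   : {self.hyperbola_coeff:.4g} s⁻¹·M (R²={self.hyperbola_rsquared:.4f})",
            f"  k*_out              : {self.kout_mean:.4g} ± {self.kout_sd:.2g} s⁻¹",
            f"  k*_out slope vs [G] : {self.kout_slope:.4g} (95% CI {lo:.4g}..{hi:.4g})",
            f"  verdict             : {self.mechanism}",
        ])


def order_diagnostics(pairs: Sequence[ExchangeRatePair],
                      states: Sequence[SpeciationState]) -> OrderDiagnostics:
    """Classify the exchange mechanism from rates measured across conditions."""
    if len(pairs) != len(states):
        raise ValueError("pairs and states differ in length")
    if len(pairs) < 3:
        raise ValueError("order diagnostics need at least 3 conditions")
    hf = np.array([s.host_free for s in states])
    gf = np.array([s.guest_free for s in states])
    conds = set(zip(np.round(hf, 12), np.round(gf, 12)))
    if len(conds) < 3:
        raise ValueError("degenerate design: fewer than 3 distinct conditions")
    kin = np.array([p.k_star_in for p in pairs])
    kout = np.array([p.k_star_out for p in pairs])

    if np.ptp(hf) == 0:
        raise ValueError("degenerate design: free-host concentration is not varied")
    res_in = sm.OLS(kin, sm.add_constant(hf)).fit()
    # one-parameter hyperbola k*_in = a/[G_free], closed-form LS
    w = 1.0 / gf
    a = float(np.sum(kin * w) / np.sum(w * w))
    ss_res = float(np.sum((kin - a * w) ** 2))
    ss_tot = float(np.sum((kin - kin.mean()) ** 2))
    hyp_rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    if np.ptp(gf) == 0:
        # guest concentration not varied: no guest-order information in k*_out
        slope, lo, hi = 0.0, 0.0, 0.0
    else:
        res_out = sm.OLS(kout, sm.add_constant(gf)).fit()
        slope = float(res_out.params[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-residual fits emit dof warnings
            ci = res_out.conf_int(alpha=0.05)
        lo, hi = float(ci[1][0]), float(ci[1][1])
        if not np.isfinite(lo) or not np.isfinite(hi):
            lo = hi = slope  # perfect fit: CI collapses to the point estimate
    flat = lo <= 0.0 <= hi
    kin_rsq = 1.0 if np.allclose(res_in.resid, 0) else float(res_in.rsquared)

    return OrderDiagnostics(
        k_in=float(res_in.params[1]),
        k_in_se=float(res_in.bse[1]),
        kin_intercept=float(res_in.params[0]),
        kin_rsquared=kin_rsq,
        hyperbola_coeff=a,
        hyperbola_rsquared=hyp_rsq,
        kout_mean=float(kout.mean()),
        kout_sd=float(kout.std(ddof=1)),
        kout_slope=slope,
        kout_slope_ci=(lo, hi),
        kout_flat=bool(flat),
        nobs=len(pairs),
    )
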