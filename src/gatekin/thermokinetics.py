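"""Closed-form thermodynamic and kinetic conversions.

Eyring interconversion between first-order rate constants and activation
free energies, transition-state (Eyring) and van't Hoff linear fits, and
the statistical factor-of-two correction applied to a degenerate two-route
racemization rate.

All free energies are in kcal/mol, temperatures in kelvin, first-order rate
constants in s^-1 and association constants in M^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .constants import KB_OVER_H, R_KCAL

__all__ = [
    "RateConstant",
    "FreeEnergy",
    "VanTHoffSeries",
    "eyring_barrier",
    "eyring_rate",
    "statistical_correction",
    "EyringModel",
    "EyringResults",
    "VantHoffModel",
    "VantHoffResults",
    "vant_hoff_from_anchor",
    "eyring_fit",
    "vant_hoff_fit",
]


@dataclass(frozen=True)
class RateConstant:
    """A rate constant with its reaction order and temperature.

    ``value`` is in s^-1 for order 1 and M^-1 s^-1 for order 2.
    """

    value: float
    temperature: float
    order: int = 1

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"rate constant must be positive, got {self.value}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.order not in (1, 2):
            raise ValueError(f"reaction order must be 1 or 2, got {self.order}")


@dataclass(frozen=True)
class FreeEnergy:
    """A free energy (kcal/mol) tagged with temperature and kind.

    ``kind`` is ``"activation"`` for barriers (ΔG‡) or ``"binding"`` for
    equilibrium free energies (ΔG°).
    """

    value: float
    temperature: float
    kind: str = "activation"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.kind not in ("activation", "binding"):
            raise ValueError(f"kind must be 'activation' or 'binding', got {self.kind!r}")


@dataclass(frozen=True)
class VanTHoffSeries:
    """Variable-temperature association constants for a van't Hoff analysis."""

    temperatures: tuple
    association_constants: tuple

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, dtype=float)
        K = np.asarray(self.association_constants, dtype=float)
        if T.size != K.size:
            raise ValueError("temperatures and association constants differ in length")
        if T.size < 2:
            raise ValueError("need at least 2 points for a van't Hoff analysis")
        if np.any(T <= 0) or np.any(K <= 0):
            raise ValueError("temperatures and association constants must be positive")


def _as_rate(k: "RateConstant | float", temperature: float | None) -> tuple[float, float]:
    if isinstance(k, RateConstant):
        T = temperature if temperature is not None else k.temperature
        return k.value, T
    if temperature is None:
        raise ValueError("temperature required when k is a bare number")
    return float(k), float(temperature)


def eyring_barrier(
    k: "RateConstant | float",
    temperature: float | None = None,
    *,
    R: float = R_KCAL,
    kb_over_h: float = KB_OVER_H,
) -> FreeEnergy:
    """Activation free energy ΔG‡ = R·T·ln(k_B·T / (h·k)) for a first-order rate.

    Transmission coefficient is unity.  Raises for non-positive rate or
    temperature.
    """
    kval, T = _as_rate(k, temperature)
    if kval <= 0:
        raise ValueError(f"rate constant must be positive, got {kval}")
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    dG = R * T * math.log(kb_over_h * T / kval)
    return FreeEnergy(value=dG, temperature=T, kind="activation")


def eyring_rate(
    dG: "FreeEnergy | float",
    temperature: float | None = None,
    *,
    R: float = R_KCAL,
    kb_over_h: float = KB_OVER_H,
) -> RateConstant:
    """First-order rate k = (k_B·T/h)·exp(−ΔG‡/(R·T)) from a barrier in kcal/mol."""
    if isinstance(dG, FreeEnergy):
        T = temperature if temperature is not None else dG.temperature
        g = dG.value
    else:
        if temperature is None:
            raise ValueError("temperature required when dG is a bare number")
        g, T = float(dG), float(temperature)
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    k = kb_over_h * T * math.exp(-g / (R * T))
    return RateConstant(value=k, temperature=T, order=1)


def statistical_correction(k_rac: "RateConstant | float") -> "RateConstant | float":
    """Statistical correction for racemization through a symmetric intermediate.

    The open (solvated) intermediate collapses with equal likelihood to either
    enantiomeric conformer, so only half of the barrier crossings register as
    racemization events: k_rac' = 2·k_rac.  The derived barrier drops by
    exactly R·T·ln 2.
    """
    if isinstance(k_rac, RateConstant):
        return RateConstant(value=2.0 * k_rac.value, temperature=k_rac.temperature, order=k_rac.order)
    if k_rac <= 0:
        raise ValueError(f"rate constant must be positive, got {k_rac}")
    return 2.0 * float(k_rac)


def _linefit(x: np.ndarray, y: np.ndarray):
    """OLS of y on x with intercept; returns the statsmodels results."""
    X = sm.add_constant(x)
    return sm.OLS(y, X).fit()


@dataclass
class EyringResults:
    """Activation parameters from a linear Eyring fit.

    ``dH`` (ΔH‡) in kcal/mol, ``dS`` (ΔS‡) in kcal mol^-1 K^-1 with standard
    errors from the residual covariance of the straight-line fit.
    """

    dH: float
    dS: float
    dH_se: float
    dS_se: float
    rsquared: float
    nobs: int
    R: float = R_KCAL
    kb_over_h: float = KB_OVER_H

    def barrier(self, temperature: float) -> FreeEnergy:
        """ΔG‡(T) = ΔH‡ − T·ΔS‡ under the fitted line."""
        return FreeEnergy(self.dH - temperature * self.dS, temperature, "activation")

    def rate(self, temperature: float) -> RateConstant:
        return eyring_rate(self.barrier(temperature), R=self.R, kb_over_h=self.kb_over_h)

    @property
    def dS_cal(self) -> float:
        """ΔS‡ in cal mol^-1 K^-1 (entropy units)."""
        return self.dS * 1e3

    def summary(self) -> str:
        lines = [
            "Eyring fit (ln(k/T) vs 1/T)",
            f"  n points : {self.nobs}",
            f"  dH‡      : {self.dH:.4g} ± {self.dH_se:.2g} kcal/mol",
            f"  dS‡      : {self.dS_cal:.4g} ± {self.dS_se * 1e3:.2g} cal/(mol K)",
            f"  R²       : {self.rsquared:.6f}",
        ]
        return "\n".join(lines)


class EyringModel:
    """Linear Eyring analysis of a (T, k) series of first-order rates.

    ln(k/T) = ln(k_B/h) + ΔS‡/R − ΔH‡/(R·T); ordinary least squares of
    ln(k/T) on 1/T gives slope −ΔH‡/R and intercept ln(k_B/h) + ΔS‡/R.
    """

    def __init__(
        self,
        temperatures: Sequence[float],
        rates: Sequence[float],
        *,
        R: float = R_KCAL,
        kb_over_h: float = KB_OVER_H,
    ):
        T = np.asarray(temperatures, dtype=float)
        k = np.asarray(rates, dtype=float)
        if T.size != k.size:
            raise ValueError("temperatures and rates differ in length")
        if T.size < 2 or np.unique(T).size < 2:
            raise ValueError("need at least 2 distinct temperatures for an Eyring fit")
        if np.any(T <= 0) or np.any(k <= 0):
            raise ValueError("temperatures and rates must be positive")
        self.temperatures = T
        self.rates = k
        self.R = R
        self.kb_over_h = kb_over_h

    @classmethod
    def from_dataframe(cls, df, *, temperature_col: str = "T_K", rate_col: str = "k_per_s"):
        return cls(df[temperature_col].to_numpy(), df[rate_col].to_numpy())

    def fit(self) -> EyringResults:
        x = 1.0 / self.temperatures
        y = np.log(self.rates / self.temperatures)
        res = _linefit(x, y)
        slope, intercept = res.params[1], res.params[0]
        slope_se, intercept_se = res.bse[1], res.bse[0]
        rsq = 1.0 if res.nobs == 2 else float(res.rsquared)
        return EyringResults(
            dH=-slope * self.R,
            dS=(intercept - math.log(self.kb_over_h)) * self.R,
            dH_se=slope_se * self.R,
            dS_se=intercept_se * self.R,
            rsquared=rsq,
            nobs=int(res.nobs),
            R=self.R,
            kb_over_h=self.kb_over_h,
        )


@dataclass
class VantHoffResults:
    """Binding thermodynamics from a linear van't Hoff fit.

    ``dH0`` (ΔH°) in kcal/mol and ``dS0`` (ΔS°) in kcal mol^-1 K^-1; the
    fitted line supports extrapolation of K_a and ΔG° to any temperature.
    """

    dH0: float
    dS0: float
    dH0_se: float
    dS0_se: float
    rsquared: float
    nobs: int
    R: float = R_KCAL

    def K(self, temperature: float) -> float:
        """K_a(T) = exp(−ΔH°/(R·T) + ΔS°/R) under the fitted line."""
        return math.exp(-self.dH0 / (self.R * temperature) + self.dS0 / self.R)

    def dG(self, temperature: float) -> FreeEnergy:
        """ΔG°(T) = ΔH° − T·ΔS° = −R·T·ln K_a(T); signed (negative = favorable)."""
        return FreeEnergy(self.dH0 - temperature * self.dS0, temperature, "binding")

    def summary(self) -> str:
        lines = [
            "van't Hoff fit (ln K vs 1/T)",
            f"  n points : {self.nobs}",
            f"  dH°      : {self.dH0:.4g} ± {self.dH0_se:.2g} kcal/mol",
            f"  dS°      : {self.dS0 * 1e3:.4g} ± {self.dS0_se * 1e3:.2g} cal/(mol K)",
            f"  R²       : {self.rsquared:.6f}",
        ]
        return "\n".join(lines)


class VantHoffModel:
    """van't Hoff analysis of variable-temperature association constants."""

    def __init__(self, series: VanTHoffSeries | None = None, *, temperatures=None,
                 association_constants=None, R: float = R_KCAL):
        if series is None:
            series = VanTHoffSeries(tuple(temperatures), tuple(association_constants))
        self.series = series
        self.R = R

    @classmethod
    def from_dataframe(cls, df, *, temperature_col: str = "T_K", K_col: str = "K_a_per_M"):
        return cls(temperatures=df[temperature_col].tolist(),
                   association_constants=df[K_col].tolist())

    def fit(self) -> VantHoffResults:
        T = np.asarray(self.series.temperatures, dtype=float)
        K = np.asarray(self.series.association_constants, dtype=float)
        if np.unique(T).size < 2:
            raise ValueError("need at least 2 distinct temperatures for a van't Hoff fit")
        res = _linefit(1.0 / T, np.log(K))
        slope, intercept = res.params[1], res.params[0]
        rsq = 1.0 if res.nobs == 2 else float(res.rsquared)
        return VantHoffResults(
            dH0=-slope * self.R,
            dS0=intercept * self.R,
            dH0_se=res.bse[1] * self.R,
            dS0_se=res.bse[0] * self.R,
            rsquared=rsq,
            nobs=int(res.nobs),
            R=self.R,
        )


def vant_hoff_from_anchor(dH0: float, T_ref: float, K_ref: float,
                          *, R: float = R_KCAL) -> VantHoffResults:
    """The van't Hoff line fixed by a known enthalpy and one anchor point.

    Given ΔH° and K_a(T_ref), ΔS° follows from ΔG°(T_ref) = −R·T_ref·ln K_ref =
    ΔH° − T_ref·ΔS°.  Useful for extrapolating a published line to a new
    temperature.
    """
    if T_ref <= 0 or K_ref <= 0:
        raise ValueError("anchor temperature and K must be positive")
    dG_ref = -R * T_ref * math.log(K_ref)
    dS0 = (dH0 - dG_ref) / T_ref
    return VantHoffResults(dH0=dH0, dS0=dS0, dH0_se=0.0, dS0_se=0.0,
                           rsquared=float("nan"), nobs=1, R=R)


def eyring_fit(temperatures: Sequence[float], rates: Sequence[float]) -> EyringResults:
    """Convenience wrapper: ``EyringModel(T, k).fit()``."""
    return EyringModel(temperatures, rates).fit()


def vant_hoff_fit(series: VanTHoffSeries) -> VantHoffResults:
    """Convenience wrapper: ``VantHoffModel(series).fit()``."""
    return VantHoffModel(series).fit()
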