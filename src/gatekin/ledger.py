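"""Free-energy additivity analysis for gated encapsulation.

If gate opening and guest departure were perfectly synchronized, the exit
barrier would decompose additively,

    ΔG‡_out ≈ ΔG‡_rac′ + |ΔG°| + ΔG‡_sterics,

with ΔG‡_rac′ the (statistically corrected) gate-revolving barrier, |ΔG°| the
intrinsic binding energy to be paid on decomplexation, and ΔG‡_sterics the
slippage cost through the open host.  The deviation

    ΔΔG = (ΔG‡_rac′ + |ΔG°|) − ΔG‡_out

diagnoses desynchronization: gates that revolve without ejecting the guest
inflate the measured racemization barrier relative to the exit barrier.  For
a series of isosteric guests the module regresses both the additivity sum and
ΔΔG against ΔG‡_out and reports the trend of ΔΔG with guest affinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "GuestThermoRecord",
    "additivity_sum",
    "ddG",
    "packing_coefficient",
    "GuestSeriesModel",
    "GuestSeriesResults",
    "series_regression",
]


@dataclass(frozen=True)
class GuestThermoRecord:
    """Per-guest row of the additivity ledger (all energies kcal/mol).

    ``dG_binding`` is the signed intrinsic binding free energy (negative =
    favorable); the ledger arithmetic uses its magnitude.  ``dG_sterics`` is
    unknown for real systems and optional; it is never imputed.
    """

    guest_id: str
    dG_binding: float
    dG_rac_corrected: float
    dG_out: float
    temperature: float
    dG_sterics: float | None = None

    def __post_init__(self) -> None:
        if self.dG_rac_corrected < 0 or self.dG_out < 0:
            raise ValueError("activation barriers must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def additivity_sum(record: GuestThermoRecord) -> float:
    """ΔG‡_rac′ + |ΔG°| (+ ΔG‡_sterics when known), kcal/mol."""
    total = record.dG_rac_corrected + abs(record.dG_binding)
    if record.dG_sterics is not None:
        total += record.dG_sterics
    return total


def ddG(record: GuestThermoRecord) -> float:
    """ΔΔG = (ΔG‡_rac′ + |ΔG°|) − ΔG‡_out, the synchronicity deviation."""
    return record.dG_rac_corrected + abs(record.dG_binding) - record.dG_out


def packing_coefficient(guest_volume: float, cavity_volume: float) -> int:
    """Guest volume as an integer percentage of the host cavity volume."""
    if guest_volume <= 0 or cavity_volume <= 0:
        raise ValueError("volumes must be positive")
    return int(round(100.0 * guest_volume / cavity_volume))


def _ols(x: np.ndarray, y: np.ndarray) -> dict:
    res = sm.OLS(y, sm.add_constant(x)).fit()
    rsq = 1.0 if np.allclose(res.resid, 0) else float(res.rsquared)
    return {"slope": float(res.params[1]), "intercept": float(res.params[0]),
            "slope_se": float(res.bse[1]), "intercept_se": float(res.bse[0]),
            "rsquared": rsq}


@dataclass
class GuestSeriesResults:
    """Linear free-energy regressions over a guest series.

    ``sum_vs_out`` regresses ΔG‡_rac′ + |ΔG°| on ΔG‡_out; ``ddg_vs_out``
    regresses ΔΔG on ΔG‡_out; ``ddg_vs_affinity`` regresses ΔΔG on |ΔG°|.
    ``affinity_trend_positive`` flags the synchronicity signature: stronger
    binders deviate more from additivity.
    """

    sum_vs_out: dict
    ddg_vs_out: dict
    ddg_vs_affinity: dict
    records: list
    ddG_values: list

    @property
    def affinity_trend_positive(self) -> bool:
        return self.ddg_vs_affinity["slope"] > 0

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for rec, d in zip(self.records, self.ddG_values):
            rows.append({"guest_id": rec.guest_id,
                         "dG_binding_kcal_mol": rec.dG_binding,
                         "dG_rac_corrected_kcal_mol": rec.dG_rac_corrected,
                         "dG_out_kcal_mol": rec.dG_out,
                         "additivity_sum_kcal_mol": additivity_sum(rec),
                         "ddG_kcal_mol": d})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        s, d, a = self.sum_vs_out, self.ddg_vs_out, self.ddg_vs_affinity
        trend = "positive" if self.affinity_trend_positive else "non-positive"
        return "\n".join([
            "Guest-series free-energy additivity analysis",
            f"  n guests                    : {len(self.records)}",
            f"  (ΔG‡_rac′+|ΔG°|) vs ΔG‡_out : slope {s['slope']:.3f} ± {s['slope_se']:.2g}, R² = {s['rsquared']:.4f}",
            f"  ΔΔG vs ΔG‡_out              : slope {d['slope']:.3f} ± {d['slope_se']:.2g}, R² = {d['rsquared']:.4f}",
            f"  ΔΔG vs |ΔG°|                : slope {a['slope']:.3f} ± {a['slope_se']:.2g} ({trend} affinity trend)",
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        out = [r.dG_out for r in self.records]
        sums = [additivity_sum(r) for r in self.records]
        ax.plot(out, sums, "ks", label="ΔG‡_rac′ + |ΔG°|")
        ax.plot(out, out, "r-", label="ΔG‡_out (identity)")
        ax.set_xlabel("ΔG‡_out (kcal/mol)")
        ax.set_ylabel("kcal/mol")
        ax.legend()
        return ax


class GuestSeriesModel:
    """Additivity regressions over ≥3 guest thermodynamic records."""

    def __init__(self, records: Sequence[GuestThermoRecord]):
        if len(records) < 3:
            raise ValueError("need at least 3 guest records for a series regression")
        self.records = list(records)

    @classmethod
    def from_dataframe(cls, df) -> "GuestSeriesModel":
        records = [GuestThermoRecord(
            guest_id=str(r["guest_id"]),
            dG_binding=float(r["dG_binding_kcal_mol"]),
            dG_rac_corrected=float(r["dG_rac_corrected_kcal_mol"]),
            dG_out=float(r["dG_out_kcal_mol"]),
            temperature=float(r["T_K"]),
        ) for _, r in df.iterrows()]
        return cls(records)

    def fit(self) -> GuestSeriesResults:
        out = np.array([r.dG_out for r in self.records])
        sums = np.array([additivity_sum(r) for r in self.records])
        devs = np.array([ddG(r) for r in self.records])
        aff = np.array([abs(r.dG_binding) for r in self.records])
        return GuestSeriesResults(sum_vs_out=_ols(out, sums),
                                  ddg_vs_out=_ols(out, devs),
                                  ddg_vs_affinity=_ols(aff, devs),
                                  records=self.records,
                                  ddG_values=devs.tolist())


def series_regression(records: Sequence[GuestThermoRecord]) -> GuestSeriesResults:
    """Convenience wrapper: ``GuestSeriesModel(records).fit()``."""
    return GuestSeriesModel(records).fit()
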