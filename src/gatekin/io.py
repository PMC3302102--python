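"""File formats, analysis configuration and the end-to-end pipeline.

All tabular input is headered CSV with unit-suffixed column names (``_M``,
``_s``, ``_ppm``, ``_K``, ``_kcal_mol``) because unit confusion is the main
failure mode in this domain.  Schema violations raise :class:`SchemaError`
naming the offending file, column and line.  The pipeline report is a pure
function of (inputs, config) and is fully deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding, exsy, ledger, lineshape, magnetization, thermokinetics
from .constants import KB_OVER_H, R_KCAL

__all__ = [
    "SchemaError",
    "AnalysisConfig",
    "read_table",
    "TITRATION_COLUMNS",
    "VANTHOFF_COLUMNS",
    "EYRING_COLUMNS",
    "INVTRANSFER_COLUMNS",
    "EXSY_COLUMNS",
    "LINESHAPE_COLUMNS",
    "GUESTS_COLUMNS",
    "run_pipeline",
]

log = logging.getLogger("gatekin")

TITRATION_COLUMNS = ("host_total_M", "guest_total_M", "shift_ppm")
VANTHOFF_COLUMNS = ("T_K", "K_a_per_M")
EYRING_COLUMNS = ("T_K", "k_per_s")
INVTRANSFER_COLUMNS = ("tau_s", "I_free", "I_bound")
EXSY_COLUMNS = ("mixing_time_s", "obs_site", "origin_site", "volume")
LINESHAPE_COLUMNS = ("T_K", "freq_hz", "intensity")
GUESTS_COLUMNS = ("guest_id", "dG_binding_kcal_mol", "dG_rac_corrected_kcal_mol",
                  "dG_out_kcal_mol", "T_K")

_NON_NUMERIC = {"obs_site", "origin_site", "guest_id"}


class SchemaError(ValueError):
    """A CSV input does not match its declared schema."""


def read_table(path, required_columns) -> pd.DataFrame:
    """Read a headered CSV and validate the required columns.

    Numeric columns with unparsable entries are reported with their file line
    number (header = line 1).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")
    for col in required_columns:
        if col in _NON_NUMERIC:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(f"{path}: column '{col}' has non-numeric value "
                              f"at line {int(bad[0]) + 2}")
        if coerced.isna().any():
            raise SchemaError(f"{path}: column '{col}' has missing value at line "
                              f"{int(df.index[coerced.isna()][0]) + 2}")
        df[col] = coerced
    return df


@dataclass
class AnalysisConfig:
    """Configuration for the end-to-end analysis.

    ``inputs`` maps stage names (titration, vanthoff, eyring, invtransfer,
    exsy, lineshape, ratelaw, guests) to CSV paths; only the stages present
    are run.  Physical constants default to the package values but can be
    overridden.  Round-trips losslessly through JSON.
    """

    inputs: dict = field(default_factory=dict)
    temperature: float = 250.0          # K, at which barriers are evaluated
    t1_free: float = 3.30               # s, free-pool T1 for inversion transfer
    K_a: float | None = None            # speciation K_a for the rate-law stage
    lineshape_params: dict = field(default_factory=dict)  # nu_a, nu_b, width, j
    R: float = R_KCAL
    kb_over_h: float = KB_OVER_H
    output_dir: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        return cls.from_json(Path(path).read_text())


def _stage_titration(cfg: AnalysisConfig) -> dict:
    df = read_table(cfg.inputs["titration"], TITRATION_COLUMNS)
    res = binding.TitrationModel.from_dataframe(df).fit()
    log.info("titration: K_a = %.4g ± %.2g M^-1 (R²=%.4f)", res.K_a, res.K_a_se, res.rsquared)
    return {"K_a_per_M": res.K_a, "K_a_se": res.K_a_se,
            "delta_free_ppm": res.delta_free, "delta_bound_ppm": res.delta_bound,
            "rsquared": res.rsquared, "n": res.nobs}


def _stage_vanthoff(cfg: AnalysisConfig) -> dict:
    df = read_table(cfg.inputs["vanthoff"], VANTHOFF_COLUMNS)
    res = thermokinetics.VantHoffModel.from_dataframe(df).fit()
    T = cfg.temperature
    log.info("vanthoff: dH0 = %.4g kcal/mol, |dG0(%.1f K)| = %.4g", res.dH0, T, abs(res.dG(T).value))
    return {"dH0_kcal_mol": res.dH0, "dH0_se": res.dH0_se,
            "dS0_kcal_mol_K": res.dS0, "dS0_se": res.dS0_se,
            "rsquared": res.rsquared,
            "K_a_298_per_M": res.K(298.0),
            "dG0_kcal_mol": res.dG(T).value,
            "abs_dG0_kcal_mol": abs(res.dG(T).value),
            "evaluated_at_K": T}


def _stage_eyring(cfg: AnalysisConfig) -> dict:
    df = read_table(cfg.inputs["eyring"], EYRING_COLUMNS)
    res = thermokinetics.EyringModel.from_dataframe(df).fit()
    T = cfg.temperature
    return {"dH_kcal_mol": res.dH, "dH_se": res.dH_se,
            "dS_kcal_mol_K": res.dS, "dS_se": res.dS_se,
            "rsquared": res.rsquared,
            "dG_kcal_mol": res.barrier(T).value, "evaluated_at_K": T}


def _stage_invtransfer(cfg: AnalysisConfig) -> dict:
    df = read_table(cfg.inputs["invtransfer"], INVTRANSFER_COLUMNS)
    res = magnetization.InversionTransferModel.from_dataframe(df, cfg.t1_free).fit()
    T = cfg.temperature
    barrier = thermokinetics.eyring_barrier(res.k_star_out, T,
                                            R=cfg.R, kb_over_h=cfg.kb_over_h)
    log.info("invtransfer: k*_out = %.4g ± %.2g s^-1", res.k_star_out, res.k_star_out_se)
    return {"k_star_in_per_s": res.k_star_in, "k_star_in_se": res.k_star_in_se,
            "k_star_out_per_s": res.k_star_out, "k_star_out_se": res.k_star_out_se,
            "r1_bound_per_s": res.r1_bound, "rsquared": res.rsquared,
            "dG_out_kcal_mol": barrier.value, "evaluated_at_K": T}


def _stage_exsy(cfg: AnalysisConfig) -> dict:
    df = read_table(cfg.inputs["exsy"], EXSY_COLUMNS)
    res = exsy.ExsyModel.from_dataframe(df).fit()
    T = cfg.temperature
    barrier = thermokinetics.eyring_barrier(res.k_star_out, T,
                                            R=cfg.R, kb_over_h=cfg.kb_over_h)
    log.info("exsy: k*_out = %.4g ± %.2g s^-1 (mean ± SD)", res.k_star_out, res.k_star_out_sd)
    return {"k_star_in_per_s": res.k_star_in, "k_star_in_sd": res.k_star_in_sd,
            "k_star_out_per_s": res.k_star_out, "k_star_out_sd": res.k_star_out_sd,
            "n_mixing_times": res.nobs,
            "dG_out_kcal_mol": barrier.value, "evaluated_at_K": T}


def _stage_ratelaw(cfg: AnalysisConfig, report: dict) -> dict:
    cols = ("host_total_M", "guest_total_M", "k_star_in_per_s", "k_star_out_per_s")
    df = read_table(cfg.inputs["ratelaw"], cols)
    K_a = cfg.K_a
    if K_a is None and "titration" in report:
        K_a = report["titration"]["K_a_per_M"]
    if K_a is None:
        raise SchemaError("rate-law stage needs K_a (config.K_a or a titration stage)")
    pairs, states = [], []
    for _, r in df.iterrows():
        states.append(binding.speciation(r["host_total_M"], r["guest_total_M"], K_a))
        pairs.append(binding.ExchangeRatePair(r["k_star_in_per_s"], r["k_star_out_per_s"]))
    diag = binding.order_diagnostics(pairs, states)
    log.info("ratelaw: k_in = %.4g ± %.2g M^-1 s^-1, mechanism %s",
             diag.k_in, diag.k_in_se, diag.mechanism)
    return {"k_in_per_M_s": diag.k_in, "k_in_se": diag.k_in_se,
            "kin_rsquared": diag.kin_rsquared,
            "k_out_per_s": diag.kout_mean, "k_out_sd": diag.kout_sd,
            "kout_slope": diag.kout_slope, "kout_slope_ci": list(diag.kout_slope_ci),
            "mechanism": diag.mechanism, "K_a_used_per_M": K_a}


def _stage_lineshape(cfg: AnalysisConfig) -> dict:
    df = read_table(cfg.inputs["lineshape"], LINESHAPE_COLUMNS)
    p = cfg.lineshape_params
    for key in ("nu_a", "nu_b", "width"):
        if key not in p:
            raise SchemaError(f"lineshape stage needs lineshape_params['{key}']")
    rates, temps = [], []
    for T, grp in df.groupby("T_K"):
        fixed = lineshape.LineshapeParams(nu_a=p["nu_a"], nu_b=p["nu_b"], k=1.0,
                                          width=p["width"], j=p.get("j", 0.0))
        spec = lineshape.ExchangeSpectrum(grp["freq_hz"].to_numpy(),
                                          grp["intensity"].to_numpy())
        res = lineshape.LineshapeModel(spec, fixed).fit()
        temps.append(float(T))
        rates.append(res.k)
        log.info("lineshape: T = %.1f K, k_rac = %.4g s^-1", T, res.k)
    out = {"temperatures_K": temps, "k_rac_per_s": rates}
    if len(temps) >= 2:
        ey = thermokinetics.EyringModel(temps, rates).fit()
        T = cfg.temperature
        dg_rac = ey.barrier(T).value
        k_rac = ey.rate(T).value
        k_rac_corr = thermokinetics.statistical_correction(k_rac)
        dg_corr = thermokinetics.eyring_barrier(k_rac_corr, T,
                                                R=cfg.R, kb_over_h=cfg.kb_over_h).value
        out.update({"dH_rac_kcal_mol": ey.dH, "dS_rac_kcal_mol_K": ey.dS,
                    "eyring_rsquared": ey.rsquared,
                    "dG_rac_kcal_mol": dg_rac,
                    "k_rac_per_s_at_T": k_rac,
                    "k_rac_corrected_per_s": k_rac_corr,
                    "dG_rac_corrected_kcal_mol": dg_corr,
                    "evaluated_at_K": T})
    return out


def _stage_guests(cfg: AnalysisConfig) -> dict:
    df = read_table(cfg.inputs["guests"], GUESTS_COLUMNS)
    res = ledger.GuestSeriesModel.from_dataframe(df).fit()
    return {"per_guest": res.to_dataframe().to_dict(orient="records"),
            "sum_vs_out": res.sum_vs_out, "ddg_vs_out": res.ddg_vs_out,
            "ddg_vs_affinity": res.ddg_vs_affinity,
            "affinity_trend_positive": res.affinity_trend_positive}


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every configured stage and assemble the machine-readable report.

    When the van't Hoff, line-shape and EXSY (or inversion-transfer) stages
    are all present, the additivity ledger for the primary guest is assembled
    from their outputs: ΔΔG = (ΔG‡_rac′ + |ΔG°|) − ΔG‡_out.
    """
    stage_fns = {"titration": _stage_titration, "vanthoff": _stage_vanthoff,
                 "eyring": _stage_eyring, "invtransfer": _stage_invtransfer,
                 "exsy": _stage_exsy, "lineshape": _stage_lineshape,
                 "guests": _stage_guests}
    report: dict = {"config": json.loads(config.to_json())}
    order = ["titration", "vanthoff", "eyring", "invtransfer", "exsy",
             "ratelaw", "lineshape", "guests"]
    for stage in order:
        if stage not in config.inputs:
            continue
        log.info("running stage: %s", stage)
        if stage == "ratelaw":
            report[stage] = _stage_ratelaw(config, report)
        else:
            report[stage] = stage_fns[stage](config)

    if "vanthoff" in report and "lineshape" in report and \
            "dG_rac_corrected_kcal_mol" in report.get("lineshape", {}):
        dg_out_src = None
        if "exsy" in report:
            dg_out_src = ("exsy", report["exsy"]["dG_out_kcal_mol"])
        elif "invtransfer" in report:
            dg_out_src = ("invtransfer", report["invtransfer"]["dG_out_kcal_mol"])
        if dg_out_src is not None:
            rec = ledger.GuestThermoRecord(
                guest_id="primary",
                dG_binding=report["vanthoff"]["dG0_kcal_mol"],
                dG_rac_corrected=report["lineshape"]["dG_rac_corrected_kcal_mol"],
                dG_out=dg_out_src[1],
                temperature=config.temperature)
            report["ledger"] = {
                "additivity_sum_kcal_mol": ledger.additivity_sum(rec),
                "ddG_kcal_mol": ledger.ddG(rec),
                "dG_out_source": dg_out_src[0],
            }

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
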