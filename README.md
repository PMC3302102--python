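# gatekin

Dynamic-NMR inference of gated molecular encapsulation kinetics.

Gated molecular baskets are synthetic hosts whose aromatic "gates" open and
close through hydrogen bonding, controlling how guests enter and leave the
cavity. `gatekin` implements the complete inference chain from raw dynamic
¹H NMR observables to the mechanistic conclusions a supramolecular kineticist
wants out of them:

- **1:1 binding** — speciation from the exact quadratic equilibrium,
  nonlinear titration-isotherm fitting for *K*ₐ, and van't Hoff analysis of
  variable-temperature *K*ₐ data for ΔH°, ΔS° and the extrapolated ΔG°(T).
- **Exchange kinetics** — two-site longitudinal Bloch–McConnell
  simulation/fitting of selective inversion-transfer decays, full-matrix 2-D
  EXSY rate extraction via the matrix logarithm of peak-volume matrices, and
  reaction-order diagnostics that map the pseudo-first-order magnetization
  coefficients *k*\*ᵢₙ, *k*\*ₒᵤₜ to the elementary rate law
  rateᵢₙ = *k*ᵢₙ[host][guest], rateₒᵤₜ = *k*ₒᵤₜ[complex] and flag an
  interchange (direct-displacement) mechanism if *k*\*ₒᵤₜ grows with guest
  concentration.
- **Gate dynamics** — two-site exchange-broadened line-shape simulation and
  fitting for the gate-revolving (racemization) rate *k*_rac, Eyring analysis
  of its temperature dependence, and the statistical correction
  *k*_rac′ = 2·*k*_rac for racemization through a symmetric open intermediate.
- **Free-energy additivity ledger** — per-guest
  ΔΔG = (ΔG‡_rac′ + |ΔG°|) − ΔG‡_out and the linear free-energy regressions
  over an isosteric guest series that diagnose how well gate motion is
  synchronized with guest trafficking.

Everything is organised as model classes whose `fit()` returns a results
object with estimates, standard errors and a `summary()` table
(`TitrationModel`, `InversionTransferModel`, `ExsyModel`, `LineshapeModel`,
`EyringModel`, `VantHoffModel`, `GuestSeriesModel`), plus closed-form helpers
(`eyring_barrier`, `speciation`, `additivity_sum`, …). A synthetic-data
module generates every input with the statistical structure the analysis
assumes, and a `gatekin` CLI wires the stages into an end-to-end pipeline.

## Worked example

```python
import gatekin as gk
from gatekin.synthetic import GeneratorConfig, make_titration, make_inversion_transfer

series, truth = make_titration(GeneratorConfig(seed=11))
print(gk.fit_isotherm(series).summary())

curve, t = make_inversion_transfer(GeneratorConfig(seed=11))
fit = gk.fit_inversion_transfer(curve, t1_free=3.30)
print(fit.summary())

dg = gk.eyring_barrier(fit.k_star_out, 250.0)
print(f"exit barrier from fitted k*_out: {dg.value:.2f} kcal/mol")

line = gk.vant_hoff_from_anchor(-3.56, 298.0, 86.0)
print(f"|dG0(250 K)|: {abs(line.dG(250.0).value):.2f} kcal/mol")

rec = gk.GuestThermoRecord("2", -2.79, 11.4, 13.4, 250.0)
print(f"additivity sum: {gk.additivity_sum(rec):.1f}, ddG: {gk.ddG(rec):.1f} kcal/mol")
```

prints

```
1:1 binding isotherm fit
  n points : 12
  K_a      : 53.64 ± 1.4 M⁻¹
  δ_free   : 11.2983 ± 0.0013 ppm
  δ_bound  : 11.6001 ± 0.00068 ppm
  R²       : 0.999802
Two-site inversion-transfer fit (Bloch-McConnell)
  n points  : 12 delays x 2 channels
  k*_in     : 0.6304 ± 0.21 s⁻¹
  k*_out    : 21.9 ± 7.2 s⁻¹
  R1_bound  : 0.5743 ± 0.17 s⁻¹
  R1_free   : 0.303 s⁻¹ (fixed)
  R²        : 0.999631
exit barrier from fitted k*_out: 13.01 kcal/mol
|dG0(250 K)|: 2.79 kcal/mol
additivity sum: 14.2, ddG: 0.8 kcal/mol
```

The titration recovers the generating *K*ₐ = 54 M⁻¹ within its standard
error; the inversion-transfer fit recovers the generating dissociation rate
*k*\*ₒᵤₜ = 21 s⁻¹; and the ledger arithmetic shows the ~0.8 kcal/mol excess
of the gate-opening-plus-decomplexation sum over the measured exit barrier —
the signature that the gates sometimes revolve without ejecting the guest.

## Command line

```bash
gatekin simulate all --seed 3 --out data/        # synthetic bundle + truth.json
gatekin titrate data/titration.csv               # K_a from the isotherm
gatekin invtransfer data/invtransfer.csv --t1-free 3.30
gatekin exsy data/exsy.csv
gatekin run --config config.json                 # full pipeline -> JSON report
```

All tabular I/O is headered CSV with unit-suffixed columns (`…_M`, `…_s`,
`…_ppm`, `…_K`, `…_kcal_mol`). Exit codes: 0 success, 2 validation error,
3 fit failure.

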