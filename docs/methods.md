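# Methods

This note documents the models behind `gatekin`, the choices made where the
design was genuinely open, and what the synthetic-data studies do and do not
demonstrate.

## Unit system and constants

Free energies are kcal/mol, temperatures kelvin, first-order rates s⁻¹,
second-order rates M⁻¹s⁻¹, association constants M⁻¹ on a 1 M standard
state. Fixed constants: R = 1.98720×10⁻³ kcal mol⁻¹ K⁻¹ and
k_B/h = 2.08366×10¹⁰ s⁻¹ K⁻¹. The Eyring transmission coefficient is unity —
the universal dynamic-NMR convention; every function that uses the constants
accepts overrides.

## Binding equilibrium and the titration isotherm

For host total B₀, guest total G₀ and association constant K, the complex
concentration is the physical (smaller) root of
K·x² − (K(B₀+G₀)+1)·x + K·B₀·G₀ = 0, evaluated in the numerically stable
form 2c/(−b + √(b²−4ac)); mass balance then holds to machine precision for
any K from 0 (no binding) to strong saturation. The fast-exchange observed
shift is the bound-fraction-weighted average
δ_obs = δ_free + (δ_bound − δ_free)·[complex]/B₀, fitted by
Levenberg–Marquardt-style least squares over (K_a, δ_free, δ_bound) with
standard errors from the Jacobian at the optimum. Degenerate series
(constant shift, <4 points) are rejected rather than fitted.

## Rate law and order diagnostics

The dissociative mechanism implies k\*_in = k_in·[host_free] (linear in free
host, hyperbolic ∝ 1/[guest_free] at high guest where the complex
concentration saturates) and k\*_out = k_out independent of concentrations.
`order_diagnostics` fits all three signatures: OLS of k\*_in on [host_free]
(slope = k_in), the one-parameter hyperbola k\*_in = a/[guest_free], and OLS
of k\*_out on [guest_free]. The flatness verdict uses a 95% confidence
interval on the k\*_out slope: the dissociative call requires the CI to
contain zero. This replaces an informal "the small slope is likely an
artifact" argument with a formal test; on noise-free data the CI collapses
to the point estimate, so exact generators are classified deterministically.
A design in which the guest concentration is never varied carries no
guest-order information; the slope is then reported as zero-width at zero
rather than failing.

## Two-site longitudinal exchange (inversion transfer)

Deviations of the pool magnetizations from equilibrium evolve as
dm/dt = −K m with K = [[R1f + k\*_in, −k\*_out], [−k\*_in, R1b + k\*_out]].
The solution is computed by eigendecomposition (the matrix is similar to a
symmetric one under detailed balance, so its spectrum is real and positive;
this is asserted property-style on random models, and the closed form is
checked against high-order ODE integration to <10⁻⁸). Selective inversion
is perfect by default (free pool at −M_eq at τ = 0); an inversion-efficiency
parameter is exposed for robustness studies.

The fitter holds R1_free fixed at 1/T1 from a separate inversion-recovery
measurement, normalizes both channels to the free-pool equilibrium
intensity, weights them equally, and fits (k\*_in, k\*_out, R1_bound,
M_eq_free) with the flux balance k\*_in·M_eq_free = k\*_out·M_eq_bound built
into the parameterization. R1_bound is a free parameter bounded to
[0.01, 100] s⁻¹ (the bound-pool relaxation is generally not measured
separately); three starting values bracketing the bound-channel dip time
guard against local minima. If all delays are long compared with the fast
eigenmode the fit warns that the exchange rates are poorly identified.

## EXSY full-matrix rate extraction

With site order (free, bound), the peak-volume matrix obeys
A(τ_m) = exp(−K·τ_m)·A(0) with diagonal A(0). Rates follow from
K = −ln(A·A(0)⁻¹)/τ_m via eigendecomposition: off-diagonals give −k\*_in and
−k\*_out, the diagonal absorbs relaxation and is discarded (it is still
reported as apparent R1s). Eigenvalues with imaginary parts above 10⁻⁹
relative, or non-positive real parts, raise an explicit aliasing error —
the matrix logarithm is no longer unique when the mixing time is too long
relative to the exchange. Estimates are invariant to global volume scaling.
Multiple mixing times are analysed independently and summarized as
mean ± SD, not jointly fitted. Cross peaks corrupted by T₁ noise (the
high-guest failure mode) are represented as masked entries; a masked set is
rejected with a message routing the user to the inversion-transfer analysis
instead of guessing.

## Exchange-broadened line shapes

The absorption profile solves the 2×2 steady-state transverse
Bloch–McConnell system per frequency. The rate parameter k is the
site-to-site hopping rate at equal populations; for unequal populations the
directional rates k_AB = 2p_B·k, k_BA = 2p_A·k satisfy detailed balance and
reduce correctly. The natural linewidth W (Hz, FWHM) maps to R2 = πW. The
classical equal-population coalescence condition k_c = πΔν/√2 is verified
numerically: the central curvature of the simulated profile changes sign
within 1% of k_c. A geminal coupling J is treated in the pairwise
line-exchange approximation — two independently exchanging pairs at
ν_A ± J/2 ↔ ν_B ∓ J/2 — valid when |ν_A − ν_B| dominates deviations from
first order; results carry an explicit approximation flag. A full
Liouville-space AB treatment is out of scope.

Fitting holds (ν_A, ν_B, W, J, populations) fixed from a slow-exchange
reference and fits k (internally log-scaled) plus amplitude and constant
baseline. A 31-point log-spaced grid over six decades around k_c seeds the
refinement, which removes the local-minimum trap near coalescence. Deep
fast-exchange spectra where Δν is unresolvable produce a wide-CI warning.

## Thermodynamic fits

Eyring: OLS of ln(k/T) on 1/T; slope = −ΔH‡/R, intercept = ln(k_B/h) + ΔS‡/R.
van't Hoff: OLS of ln K on 1/T; slope = −ΔH°/R, intercept = ΔS°/R, with
extrapolation K(T\*) and ΔG°(T\*) = ΔH° − T\*ΔS° along the fitted line.
Uncertainties are the standard errors of slope/intercept from the residual
covariance. `vant_hoff_from_anchor` constructs the line fixed by a known
ΔH° and one (T, K) anchor — the standard way to carry a published line to a
new temperature. The statistical racemization correction k′ = 2k (a
symmetric intermediate collapses to either enantiomer with equal
likelihood) lowers any derived barrier by exactly R·T·ln 2.

## Additivity ledger

ΔΔG = (ΔG‡_rac′ + |ΔG°|) − ΔG‡_out. The binding free energy enters as a
magnitude (the decomplexation cost), while the signed value is retained in
the record. ΔG‡_sterics is optional and never imputed. For a guest series
the package emits three regressions — additivity sum vs ΔG‡_out, ΔΔG vs
ΔG‡_out, and ΔΔG vs |ΔG°| — privileging none, plus a boolean flag for the
positive affinity trend (stronger binders deviating more from additivity).

## Synthetic data: what it emulates, and what it does not

Every generator is the exact forward model of its consuming fitter at zero
noise, so recovery studies measure estimator behaviour, not model mismatch.
Defaults reproduce the study conditions: titration of 0.67 mM host with
0–0.65 M guest in 12 points at K_a = 54 M⁻¹ and 0.3 ppm shift contrast with
σ = 0.001 ppm Gaussian shift noise; inversion transfer on 1.65 mM host /
50 mM guest with k\*_out = 21 s⁻¹, k_in = 2.1×10³ M⁻¹s⁻¹ (so the kinetic
K_a = 100 M⁻¹ fixes the speciation), T1_free = 3.30 s, 12 delays (0 plus
log-spaced 1 ms–15 s) and 1% relative intensity noise; EXSY at mixing times
40–250 ms with k\*_out = 10 s⁻¹ and 2% volume noise; a variable-temperature
line-shape series generated from an Eyring law chosen to give the
gate-revolving barrier ≈11.7 kcal/mol at 250 K (≈11.4 after statistical
correction); and a five-guest isosteric series with |ΔG°| spanning
1–6 kcal/mol under an exact linear ΔΔG law (slope 0.3 per kcal/mol of
affinity) with optional 0.1 kcal/mol barrier noise. The bound-pool R1
(never printed for the real system) defaults to 0.5 s⁻¹ — slightly faster
than the free pool's 0.30 s⁻¹, as expected in the constrained cavity.

Noise is Gaussian and independent per point in every channel. Real spectra
violate this in ways the generators deliberately do not emulate: correlated
baseline roll, phase errors, t₁ noise ridges, imperfect selective inversion,
temperature drift across a titration. Passing recovery studies therefore
demonstrate estimator correctness and precision at the stated designs, not
robustness to those instrumental artifacts (the inversion-efficiency
parameter and the masked-EXSY route are the designed-in escape hatches).

All randomness derives from a single integer seed; per-kind salts
decorrelate the streams, and identical configurations are bit-reproducible.

## Problem sizes

Recovery studies use 100 replicates (median reported) at the designs above;
the 12-point titration, 12-delay transfer curve, 4 mixing times and
4096-point spectra match the scale of the corresponding experiments. The
whole suite and the acceptance script each run in well under a minute on one
core.

## Known limitations

Two-site models only (no >2-site networks, no NOE/exchange disentanglement,
no transverse relaxation in the longitudinal module); no cooperative or 2:1
binding; no heat-capacity terms in the thermodynamic fits; the line-shape
module's J treatment is first-order. The kinetic and thermodynamic routes to
K_a, and the EXSY versus inversion-transfer routes to k\*_out, are reported
side by side and never reconciled or averaged — disagreement between them is
scientific signal, not something the software should hide.
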