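"""Physical constants in the unit system used throughout the package.

Free energies are kcal/mol, temperatures kelvin, rate constants s^-1 (or
M^-1 s^-1 for second order), association constants M^-1 (1 M standard state).
The transmission coefficient in the Eyring equation is taken as unity, the
universal dynamic-NMR convention.
"""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL: float = 1.98720e-3

#: Boltzmann constant over Planck constant, s^-1 K^-1.
KB_OVER_H: float = 2.08366e10
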