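"""Physical constants and unit-conversion factors.

Internal conventions: lengths in nm, number densities in nm^-3,
concentrations in mg/mL, pressures in kPa, temperatures in K,
energies in units of k_B*T.
"""

#: Boltzmann constant, J/K (CODATA 2018 exact).
K_BOLTZMANN = 1.380649e-23

#: Avogadro constant, 1/mol (CODATA 2018 exact).
N_AVOGADRO = 6.02214076e23

#: Molar gas constant, J/(mol K).
R_GAS = K_BOLTZMANN * N_AVOGADRO

#: Conversion: 1 nm^-3 = 1e27 m^-3.
PER_NM3_TO_PER_M3 = 1.0e27

#: Pa per kPa.
PA_PER_KPA = 1.0e3

#: Diameter of a monomeric gamma-crystallin, nm.
SIGMA_CRYSTALLIN = 3.6

#: Default molar mass used for concentration <-> density conversion, g/mol
#: (typical gamma-crystallin).
M_CRYSTALLIN = 21_000.0

#: Reference temperature for isotherm comparisons, K.
T_REFERENCE = 298.15

#: Packing fraction above which the two-body theory becomes unreliable
#: (many-body effects neglected); operations emit a warning beyond it.
PHI_VALIDITY_CEILING = 0.4
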