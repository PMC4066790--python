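"""Physical constants and package-wide defaults (units: Å, kcal/mol, K, e)."""

import math

#: Gas constant / Boltzmann constant per mole, kcal mol^-1 K^-1.
R_KCAL = 1.987204259e-3

#: Coulomb conversion constant e^2/(4 pi eps0 * 1 Å) in kcal mol^-1, i.e. the
#: electrostatic energy of two unit charges 1 Å apart.  Evaluated from CODATA
#: e = 1.602176634e-19 C, eps0 = 8.8541878128e-12 F/m, N_A = 6.02214076e23.
COULOMB_K = 332.06371

#: Molecular diameter of water used as the hard-sphere probe, Å.
DEFAULT_DS = 2.8

#: Number density of bulk water on the saturation curve at 298 K, Å^-3.
RHO_WATER = 0.0333

#: Reference temperature, K.
DEFAULT_T = 298.0

#: Packing fraction of the hard-sphere solvent matching water's density and
#: diameter: eta = pi * rho * dS^3 / 6.
DEFAULT_ETA = math.pi * RHO_WATER * DEFAULT_DS**3 / 6.0

#: Isobaric thermal expansion coefficient of water at 298 K, K^-1.
ALPHA_WATER = 2.57e-4

#: Isothermal compressibility of water at 298 K, Pa^-1.
KAPPA_T_WATER = 4.52e-10

#: Conversion Pa * Å^3 -> kcal/mol (1e-30 m^3 * N_A / 4184 J/kcal).
PA_A3_TO_KCAL_MOL = 1e-30 * 6.02214076e23 / 4184.0

#: Boltzmann constant, J/K (used in the isochoric -> isobaric conversion).
KB_J = 1.380649e-23
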