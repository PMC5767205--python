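"""Physical constants and the unit system used throughout the package.

All energies are kJ/mol on disk and at the API boundary; estimators work in
reduced (dimensionless) units, i.e. energies divided by k_B*T.  Lengths are
nm and charges are elementary charges (e).
"""

#: Boltzmann constant in kJ/mol/K (CODATA).
BOLTZMANN_KJ_PER_MOL_K = 0.008314462618

#: Coulomb constant 1/(4*pi*eps0) in kJ mol^-1 nm e^-2.
COULOMB_CONSTANT = 138.935458

#: Cubic lattice-sum (Wigner) integration constant for a cubic box.
XI_LS = -2.837

#: Default simulation temperature in kelvin.
DEFAULT_TEMPERATURE = 300.0

#: Static relative dielectric permittivity of TIP3P water.
TIP3P_EPSILON = 97.0

#: Quadrupole-moment trace of TIP3P relative to its vdW site, in e nm^2.
TIP3P_GAMMA = 0.00764


def kt_kj_per_mol(temperature: float) -> float:
    """k_B*T in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_KJ_PER_MOL_K * temperature
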