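"""Physical constants in GROMACS-style MD units (nm, ps, kJ/mol, e, K, u)."""

#: Coulomb constant e^2/(4 pi eps0), kJ mol^-1 nm e^-2.
K_COULOMB = 138.935458

#: Boltzmann constant, kJ mol^-1 K^-1 (equals the molar gas constant R).
KB = 8.314462618e-3

#: Molar gas constant, kJ mol^-1 K^-1.
R_GAS = KB

#: Avogadro's number, mol^-1.
N_AVOGADRO = 6.02214076e23

#: Vacuum permittivity in e^2 mol kJ^-1 nm^-1 (1 / (4 pi K_COULOMB)).
EPS0 = 1.0 / (4.0 * 3.141592653589793 * K_COULOMB)

#: Relative dielectric constant of water at 300 K (implicit-solvent screening).
EPS_WATER = 78.5

#: kJ mol^-1 nm^-1 expressed in piconewtons per molecule.
KJ_PER_MOL_NM_TO_PN = 1e12 * 1e9 * 1e3 / N_AVOGADRO  # ~1.6605 pN

#: Conversion pN -> kJ mol^-1 nm^-1.
PN_TO_KJ_PER_MOL_NM = 1.0 / KJ_PER_MOL_NM_TO_PN

#: 1 kJ mol^-1 e^-1 in volts.
KJ_PER_MOL_E_TO_VOLT = 1e3 / (N_AVOGADRO * 1.602176634e-19)

#: Ion molar masses, g/mol (standard atomic weights; reporting only).
MOLAR_MASS = {
    "Mg2+": 24.305,
    "Ca2+": 40.078,
    "Sr2+": 87.62,
    "Ba2+": 137.327,
    "Na+": 22.98976928,
    "Cl-": 35.453,
}
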