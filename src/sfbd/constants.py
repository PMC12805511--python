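"""Physical constants and unit conversions (CODATA 2018).

Internal unit policy: geometry is handled in angstroms and radians at the
user-facing level; hydrodynamic friction is formed in SI and the generalized
diffusion tensor is returned with internal-coordinate rows in (angstrom, rad)
units so that it can be combined directly with a curvature matrix expressed in
J/(angstrom, rad)^2 per molecule.
"""

KB = 1.380649e-23  # Boltzmann constant, J/K
HBAR = 1.054571817e-34  # reduced Planck constant, J s
MU0 = 1.25663706212e-6  # vacuum permeability, N/A^2
AVOGADRO = 6.02214076e23  # 1/mol

ANGSTROM = 1e-10  # m
KCAL_PER_MOL = 4184.0 / AVOGADRO  # J (per molecule)

# gyromagnetic ratios, rad s^-1 T^-1
GAMMA = {
    "1H": 26.7522187e7,
    "13C": 6.728284e7,
    "15N": -2.71261804e7,
}

# standard atomic masses for the elements used by the toy fixtures, u
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.06, "Cl": 35.45,
}
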