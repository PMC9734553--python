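"""Physical constants and per-residue property tables.

Units throughout the package: length nm, time ps, mass Da (g/mol),
energy kJ/mol, charge in elementary charges, temperature K.  In this
unit system 1 Da nm^2/ps^2 == 1 kJ/mol, so no conversion factors appear
in the integrator.
"""

from __future__ import annotations

import math

from scipy import constants as _sc

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = _sc.k * _sc.N_A / 1000.0

#: Coulomb prefactor e^2 N_A / (4 pi eps0), kJ mol^-1 nm (divide by eps_r).
COULOMB_PREFACTOR = (
    _sc.e**2 * _sc.N_A / (4.0 * math.pi * _sc.epsilon_0) / 1000.0 * 1e9
)

#: Standard one-letter amino-acid alphabet.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue (monomer) masses in Da, water subtracted.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Charged residues: D, E carry -1; R, K carry +1; everything else 0
#: (histidine treated as neutral).
RESIDUE_CHARGE = {"D": -1.0, "E": -1.0, "R": 1.0, "K": 1.0}

#: Aromatic-ring residues.
AROMATIC_RESIDUES = frozenset("FYW")

#: Cationic residues participating in cation-pi pairs.
CATIONIC_RESIDUES = frozenset("RK")

# Kyte-Doolittle hydropathy, rescaled to [0, 1].
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "E": -3.5,
    "Q": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Normalised hydrophobicity scale in [0, 1] used by the chain-chain
#: hydrophobic attraction.
HYDROPHOBICITY = {aa: (kd + 4.5) / 9.0 for aa, kd in _KD.items()}

#: Three-letter -> one-letter residue code map (PDB parsing).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common variants
    "MSE": "M", "HSD": "H", "HSE": "H", "HSP": "H", "SEC": "C",
}
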