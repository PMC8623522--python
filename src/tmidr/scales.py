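"""Bundled per-residue tables: masses, pKa values, and amino-acid scales.

All tables cover the 20 standard residues. Unknown symbols (``X`` and
padding) are handled by the callers, conventionally as zero.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Average isotopic residue masses (Da), i.e. the amino-acid mass minus one
#: water; a peptide's MW is the sum of residue masses plus one water.
RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155,
    "F": 147.1766, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "K": 128.1741, "L": 113.1594, "M": 131.1926, "N": 114.1038,
    "P": 97.1167, "Q": 128.1307, "R": 156.1875, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.01524

#: Side-chain pKa values (EMBOSS set) for the ionizable residues, plus the
#: free termini. Positive groups: H, K, R and the N-terminus; negative
#: groups: D, E, C, Y and the C-terminus.
PKA_POSITIVE = {"H": 6.5, "K": 10.8, "R": 12.5, "Nterm": 8.6}
PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "Cterm": 3.6}

# Nine non-redundant per-residue scales used as window features: a spread of
# hydrophobicity, bulk, flexibility, charge and secondary-structure
# propensity information.

#: Kyte-Doolittle hydropathy.
HYDROPHOBICITY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}

#: Grantham polarity.
POLARITY = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2, "G": 9.0,
    "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9, "M": 5.7, "N": 11.6,
    "P": 8.0, "Q": 10.5, "R": 10.5, "S": 9.2, "T": 8.6, "V": 5.9,
    "W": 5.4, "Y": 6.2,
}

#: Zamyatnin residue volume (A^3).
VOLUME = {
    "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9,
    "G": 60.1, "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7,
    "M": 162.9, "N": 114.1, "P": 112.7, "Q": 143.8, "R": 173.4,
    "S": 89.0, "T": 116.1, "V": 140.0, "W": 227.8, "Y": 193.6,
}

#: Vihinen average flexibility index.
FLEXIBILITY = {
    "A": 0.984, "C": 0.906, "D": 1.068, "E": 1.094, "F": 0.915,
    "G": 1.031, "H": 0.950, "I": 0.927, "K": 1.102, "L": 0.935,
    "M": 0.952, "N": 1.048, "P": 1.049, "Q": 1.037, "R": 1.008,
    "S": 1.046, "T": 0.997, "V": 0.931, "W": 0.904, "Y": 0.929,
}

#: Formal side-chain charge at pH 7.
CHARGE = {
    "A": 0.0, "C": 0.0, "D": -1.0, "E": -1.0, "F": 0.0, "G": 0.0,
    "H": 0.1, "I": 0.0, "K": 1.0, "L": 0.0, "M": 0.0, "N": 0.0,
    "P": 0.0, "Q": 0.0, "R": 1.0, "S": 0.0, "T": 0.0, "V": 0.0,
    "W": 0.0, "Y": 0.0,
}

#: Chou-Fasman alpha-helix propensity.
HELIX = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13, "G": 0.57,
    "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21, "M": 1.45, "N": 0.67,
    "P": 0.57, "Q": 1.11, "R": 0.98, "S": 0.77, "T": 0.83, "V": 1.06,
    "W": 1.08, "Y": 0.69,
}

#: Chou-Fasman beta-sheet propensity.
SHEET = {
    "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38, "G": 0.75,
    "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30, "M": 1.05, "N": 0.89,
    "P": 0.55, "Q": 1.10, "R": 0.93, "S": 0.75, "T": 1.19, "V": 1.70,
    "W": 1.37, "Y": 1.47,
}

#: Chou-Fasman turn/coil propensity.
COIL = {
    "A": 0.66, "C": 1.19, "D": 1.46, "E": 0.74, "F": 0.60, "G": 1.56,
    "H": 0.95, "I": 0.47, "K": 1.01, "L": 0.59, "M": 0.60, "N": 1.56,
    "P": 1.52, "Q": 0.98, "R": 0.95, "S": 1.43, "T": 0.96, "V": 0.50,
    "W": 0.96, "Y": 1.14,
}

#: Aromaticity indicator.
AROMATICITY = {aa: 1.0 if aa in "FWYH" else 0.0 for aa in AMINO_ACIDS}

#: Ordered mapping used by the feature schema; 9 scales.
SCALES = {
    "hydrophobicity": HYDROPHOBICITY,
    "polarity": POLARITY,
    "volume": VOLUME,
    "flexibility": FLEXIBILITY,
    "charge": CHARGE,
    "helix": HELIX,
    "sheet": SHEET,
    "coil": COIL,
    "aromaticity": AROMATICITY,
}

#: TOP-IDP-style disorder propensity (Campen et al.); positive values favour
#: disorder. Used only by the composition-only baseline, not by the models.
DISORDER_PROPENSITY = {
    "A": 0.06, "C": 0.02, "D": 0.192, "E": 0.736, "F": -0.697,
    "G": 0.166, "H": 0.303, "I": -0.486, "K": 0.586, "L": -0.326,
    "M": -0.397, "N": 0.007, "P": 0.987, "Q": 0.318, "R": 0.180,
    "S": 0.341, "T": 0.059, "V": -0.121, "W": -0.884, "Y": -0.510,
}


def scale_matrix() -> np.ndarray:
    """Return the (20, 9) matrix of scale values, rows in AMINO_ACIDS order."""
    return np.array(
        [[table[aa] for table in SCALES.values()] for aa in AMINO_ACIDS]
    )


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a sequence to integer codes; non-standard symbols become -1."""
    return np.array([AA_INDEX.get(aa, -1) for aa in sequence], dtype=np.int64)
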