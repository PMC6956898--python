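"""Per-residue amino-acid scales used by the target meta-features.

The hydrophobicity registry compiles 38 published per-residue scales
(experimental transfer free energies, chromatographic retention, buriedness
propensities, antigenicity, ...). Values for the widely used scales follow
the original publications; the registry is a versioned, configurable
compilation, not a normative reference — meta-features built on it only
require the scales to be fixed, per-residue and mutually diverse. A content
hash of the registry is exposed so a feature set can be tied to the exact
scale values that produced it.

Also embedded: the Boman residue solubility scale (protein-interaction
index; kcal/mol, higher = more protein-binding potential) and the EMBOSS
pKa set used for net charge and isoelectric point.
"""

from __future__ import annotations

import hashlib
import json

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

HYDROPHOBICITY_SCALES: dict[str, dict[str, float]] = {
    "KyteDoolittle": {"A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2},
    "HoppWoods": {"A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5},
    "Eisenberg": {"A": 0.62, "R": -2.53, "N": -0.78, "D": -0.9, "C": 0.29, "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.4, "I": 1.38, "L": 1.06, "K": -1.5, "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08},
    "EngelmanGES": {"A": 1.6, "R": -12.3, "N": -4.8, "D": -9.2, "C": 2.0, "Q": -4.1, "E": -8.2, "G": 1.0, "H": -3.0, "I": 3.1, "L": 2.8, "K": -8.8, "M": 3.4, "F": 3.7, "P": -0.2, "S": 0.6, "T": 1.2, "W": 1.9, "Y": -0.7, "V": 2.6},
    "Janin": {"A": 0.3, "R": -1.4, "N": -0.5, "D": -0.6, "C": 0.9, "Q": -0.7, "E": -0.7, "G": 0.3, "H": -0.1, "I": 0.7, "L": 0.5, "K": -1.8, "M": 0.4, "F": 0.5, "P": -0.3, "S": -0.1, "T": -0.2, "W": 0.3, "Y": -0.4, "V": 0.6},
    "Rose": {"A": 0.74, "R": 0.64, "N": 0.63, "D": 0.62, "C": 0.91, "Q": 0.62, "E": 0.62, "G": 0.72, "H": 0.78, "I": 0.88, "L": 0.85, "K": 0.52, "M": 0.85, "F": 0.88, "P": 0.64, "S": 0.66, "T": 0.7, "W": 0.85, "Y": 0.76, "V": 0.86},
    "FaucherePliska": {"A": 0.31, "R": -1.01, "N": -0.6, "D": -0.77, "C": 1.54, "Q": -0.22, "E": -0.64, "G": 0.0, "H": 0.13, "I": 1.8, "L": 1.7, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72, "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22},
    "WolfendenRadzicka": {"A": 1.94, "R": -19.92, "N": -9.68, "D": -10.95, "C": -1.24, "Q": -9.38, "E": -10.2, "G": 2.39, "H": -10.27, "I": 2.15, "L": 2.28, "K": -9.52, "M": -1.48, "F": -0.76, "P": 0.0, "S": -5.06, "T": -4.88, "W": -5.88, "Y": -6.11, "V": 1.99},
    "Chothia": {"A": 0.38, "R": 0.01, "N": 0.12, "D": 0.15, "C": 0.45, "Q": 0.07, "E": 0.18, "G": 0.36, "H": 0.17, "I": 0.6, "L": 0.45, "K": 0.03, "M": 0.4, "F": 0.5, "P": 0.18, "S": 0.22, "T": 0.23, "W": 0.27, "Y": 0.15, "V": 0.54},
    "BullBreese": {"A": 0.61, "R": 0.69, "N": 0.89, "D": 0.61, "C": 0.36, "Q": 0.97, "E": 0.51, "G": 0.81, "H": 0.69, "I": -1.45, "L": -1.65, "K": 0.46, "M": -0.66, "F": -1.52, "P": -0.17, "S": 0.42, "T": 0.29, "W": -1.2, "Y": -1.43, "V": -0.75},
    "Guy": {"A": 0.1, "R": 1.91, "N": 0.48, "D": 0.78, "C": -1.42, "Q": 0.95, "E": 0.83, "G": 0.33, "H": -0.5, "I": -1.13, "L": -1.18, "K": 1.4, "M": -1.59, "F": -2.12, "P": 0.73, "S": 0.52, "T": 0.07, "W": -0.51, "Y": -0.21, "V": -1.27},
    "MiyazawaJernigan": {"A": 5.33, "R": 4.18, "N": 3.71, "D": 3.59, "C": 7.93, "Q": 3.87, "E": 3.65, "G": 4.48, "H": 5.1, "I": 8.83, "L": 8.47, "K": 2.95, "M": 8.95, "F": 9.03, "P": 3.87, "S": 4.09, "T": 4.49, "W": 7.66, "Y": 5.89, "V": 7.63},
    "Roseman": {"A": 0.39, "R": -3.95, "N": -1.91, "D": -3.81, "C": 0.25, "Q": -1.3, "E": -2.91, "G": 0.0, "H": -0.64, "I": 1.82, "L": 1.82, "K": -2.77, "M": 0.96, "F": 2.27, "P": 0.99, "S": -1.24, "T": -1.0, "W": 2.13, "Y": 1.47, "V": 1.3},
    "SweetEisenberg": {"A": -0.4, "R": -0.59, "N": -0.92, "D": -1.31, "C": 0.17, "Q": -0.91, "E": -1.22, "G": -0.67, "H": -0.64, "I": 1.25, "L": 1.22, "K": -0.67, "M": 1.02, "F": 1.92, "P": -0.49, "S": -0.55, "T": -0.28, "W": 0.5, "Y": 1.67, "V": 0.91},
    "Tanford": {"A": 0.62, "R": -2.53, "N": -0.78, "D": -0.09, "C": 0.29, "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.4, "I": 1.38, "L": 1.53, "K": -1.5, "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.8},
    "Welling": {"A": 0.115, "R": 0.058, "N": -0.077, "D": 0.065, "C": -0.12, "Q": -0.011, "E": -0.071, "G": -0.184, "H": 0.312, "I": -0.292, "L": 0.075, "K": 0.206, "M": -0.385, "F": -0.141, "P": -0.016, "S": -0.026, "T": -0.045, "W": -0.114, "Y": 0.013, "V": -0.013},
    "Wilson": {"A": -0.3, "R": -1.1, "N": -0.2, "D": -1.4, "C": 6.3, "Q": -0.2, "E": 0.0, "G": 1.2, "H": -1.3, "I": 4.3, "L": 6.6, "K": -3.6, "M": 2.5, "F": 7.5, "P": 2.2, "S": -0.6, "T": -2.2, "W": 7.9, "Y": 7.1, "V": 5.9},
    "Parker": {"A": 2.1, "R": 4.2, "N": 7.0, "D": 10.0, "C": 1.4, "Q": 6.0, "E": 7.8, "G": 5.7, "H": 2.1, "I": -8.0, "L": -9.2, "K": 5.7, "M": -4.2, "F": -9.2, "P": 2.1, "S": 6.5, "T": 5.2, "W": -10.0, "Y": -1.9, "V": -3.7},
    "Ponnuswamy": {"A": 12.28, "R": 11.49, "N": 11.0, "D": 10.97, "C": 14.93, "Q": 11.28, "E": 11.19, "G": 12.01, "H": 12.84, "I": 14.77, "L": 14.1, "K": 10.8, "M": 14.33, "F": 13.43, "P": 11.19, "S": 11.26, "T": 11.65, "W": 13.41, "Y": 13.29, "V": 15.07},
    "AbrahamLeo": {"A": 0.44, "R": -2.42, "N": -1.32, "D": -0.31, "C": 0.58, "Q": -0.71, "E": -0.34, "G": 0.0, "H": -0.01, "I": 2.46, "L": 2.46, "K": -2.45, "M": 1.1, "F": 2.54, "P": 1.29, "S": -0.84, "T": -0.41, "W": 2.56, "Y": 1.63, "V": 1.73},
    "Argos": {"A": 0.61, "R": 0.6, "N": 0.06, "D": 0.46, "C": 1.07, "Q": 0.0, "E": 0.47, "G": 0.07, "H": 0.61, "I": 2.22, "L": 1.53, "K": 1.15, "M": 1.18, "F": 2.02, "P": 1.95, "S": 0.05, "T": 0.05, "W": 2.65, "Y": 1.88, "V": 1.32},
    "BlackMould": {"A": 0.616, "R": 0.0, "N": 0.236, "D": 0.028, "C": 0.68, "Q": 0.251, "E": 0.043, "G": 0.501, "H": 0.165, "I": 0.943, "L": 0.943, "K": 0.283, "M": 0.738, "F": 1.0, "P": 0.711, "S": 0.359, "T": 0.45, "W": 0.878, "Y": 0.88, "V": 0.825},
    "CasariSippl": {"A": 0.2, "R": -0.7, "N": -0.5, "D": -1.4, "C": 1.9, "Q": -1.1, "E": -1.3, "G": -0.1, "H": 0.4, "I": 1.4, "L": 0.6, "K": -1.6, "M": 0.5, "F": 1.0, "P": -1.0, "S": -0.7, "T": -0.4, "W": 1.6, "Y": 0.5, "V": 0.7},
    "Cid": {"A": 0.17, "R": -0.7, "N": -0.9, "D": -1.05, "C": 1.24, "Q": -1.2, "E": -1.19, "G": -0.57, "H": -0.25, "I": 2.06, "L": 0.96, "K": -0.62, "M": 0.6, "F": 1.29, "P": -0.21, "S": -0.83, "T": -0.62, "W": 1.51, "Y": 0.66, "V": 1.21},
    "CowanWhittaker34": {"A": 0.42, "R": -1.56, "N": -1.03, "D": -0.51, "C": 0.84, "Q": -0.96, "E": -0.37, "G": 0.0, "H": -2.28, "I": 1.81, "L": 1.8, "K": -2.03, "M": 1.18, "F": 1.74, "P": 0.86, "S": -0.64, "T": -0.26, "W": 1.46, "Y": 0.51, "V": 1.34},
    "CowanWhittaker75": {"A": 0.35, "R": -1.5, "N": -0.44, "D": -2.15, "C": 0.76, "Q": -0.93, "E": -1.95, "G": 0.0, "H": -0.65, "I": 1.83, "L": 1.8, "K": -1.54, "M": 1.1, "F": 1.69, "P": 0.84, "S": -0.63, "T": -0.27, "W": 1.35, "Y": 0.39, "V": 1.32},
    "Aboderin": {"A": 5.1, "R": 2.0, "N": 0.6, "D": 0.7, "C": 0.0, "Q": 1.4, "E": 1.8, "G": 4.1, "H": 1.6, "I": 9.3, "L": 10.0, "K": 1.3, "M": 8.7, "F": 9.6, "P": 4.9, "S": 3.1, "T": 3.5, "W": 9.2, "Y": 8.0, "V": 8.5},
    "Juretic": {"A": 1.1, "R": -5.1, "N": -3.5, "D": -3.6, "C": 2.5, "Q": -3.68, "E": -3.2, "G": -0.64, "H": -3.2, "I": 4.5, "L": 3.8, "K": -4.11, "M": 1.9, "F": 2.8, "P": -1.9, "S": -0.5, "T": -0.7, "W": -0.46, "Y": -1.3, "V": 4.2},
    "KideraFactor4": {"A": -0.27, "R": 1.87, "N": 0.81, "D": 0.81, "C": -1.05, "Q": 1.1, "E": 1.17, "G": -0.16, "H": 0.28, "I": -0.77, "L": -1.1, "K": 1.7, "M": -0.73, "F": -1.43, "P": 0.38, "S": 0.42, "T": 0.63, "W": -1.57, "Y": -0.56, "V": -0.4},
    "Levitt": {"A": 0.6, "R": -3.0, "N": -0.6, "D": -0.9, "C": 1.6, "Q": -0.9, "E": -0.7, "G": 0.3, "H": -0.1, "I": 1.4, "L": 1.0, "K": -1.8, "M": 1.3, "F": 1.2, "P": -0.2, "S": -0.2, "T": -0.1, "W": 0.7, "Y": -0.7, "V": 1.1},
    "Manavalan": {"A": 12.97, "R": 11.72, "N": 11.42, "D": 10.85, "C": 14.63, "Q": 11.76, "E": 11.89, "G": 12.43, "H": 12.16, "I": 15.67, "L": 14.9, "K": 11.36, "M": 14.39, "F": 14.0, "P": 11.37, "S": 11.23, "T": 11.69, "W": 13.93, "Y": 13.42, "V": 15.71},
    "Zimmerman": {"A": 0.83, "R": 0.83, "N": 0.09, "D": 0.64, "C": 1.48, "Q": 0.0, "E": 0.65, "G": 0.1, "H": 1.1, "I": 3.07, "L": 2.52, "K": 1.6, "M": 1.4, "F": 2.75, "P": 2.7, "S": 0.14, "T": 0.54, "W": 0.31, "Y": 2.97, "V": 1.79},
    "RaoArgade": {"A": 0.44, "R": -0.82, "N": -0.55, "D": -0.65, "C": 0.61, "Q": -0.57, "E": -0.64, "G": 0.25, "H": -0.46, "I": 1.36, "L": 1.21, "K": -0.86, "M": 0.84, "F": 1.26, "P": -0.06, "S": -0.26, "T": -0.18, "W": 1.07, "Y": 0.49, "V": 1.14},
    "Fasman": {"A": -0.21, "R": 2.11, "N": 0.96, "D": 1.36, "C": -6.04, "Q": 1.52, "E": 2.3, "G": 0.0, "H": -1.23, "I": -4.81, "L": -4.68, "K": 3.88, "M": -3.66, "F": -4.65, "P": 0.75, "S": 1.74, "T": 0.78, "W": -3.32, "Y": -1.01, "V": -3.5},
    "BhaskaranPonnuswamy": {"A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346, "Q": 0.493, "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462, "L": 0.365, "K": 0.466, "M": 0.295, "F": 0.314, "P": 0.509, "S": 0.507, "T": 0.444, "W": 0.305, "Y": 0.42, "V": 0.386},
    "GoldsackChalifoux": {"A": 0.75, "R": 0.75, "N": 0.69, "D": 0.0, "C": 1.0, "Q": 0.59, "E": 0.0, "G": 0.0, "H": 0.0, "I": 2.95, "L": 2.4, "K": 1.5, "M": 1.3, "F": 2.65, "P": 2.6, "S": 0.0, "T": 0.45, "W": 3.0, "Y": 2.85, "V": 1.7},
    "Kuhn": {"A": 0.78, "R": 0.31, "N": 0.48, "D": 0.44, "C": 0.84, "Q": 0.49, "E": 0.5, "G": 0.62, "H": 0.59, "I": 1.03, "L": 0.98, "K": 0.31, "M": 0.9, "F": 1.0, "P": 0.64, "S": 0.56, "T": 0.57, "W": 0.97, "Y": 0.87, "V": 0.95},
    "Prabhakaran": {"A": 9.36, "R": 0.27, "N": 2.31, "D": 0.94, "C": 2.56, "Q": 1.14, "E": 0.94, "G": 6.17, "H": 0.47, "I": 13.73, "L": 16.64, "K": 0.58, "M": 3.93, "F": 10.99, "P": 1.96, "S": 5.58, "T": 4.68, "W": 2.2, "Y": 3.13, "V": 12.43},
}

#: Residue solubility values behind the protein-interaction (Boman) index,
#: kcal/mol; proline was not determined in the source set and is neutral by
#: convention.
BOMAN_SCALE: dict[str, float] = {
    "L": -4.92, "I": -4.92, "V": -4.04, "F": -2.98, "M": -2.35, "W": -2.33,
    "A": -1.81, "C": -1.28, "G": -0.94, "Y": 0.14, "T": 2.57, "S": 3.4,
    "H": 4.66, "Q": 5.54, "K": 5.55, "N": 6.64, "E": 6.81, "D": 8.72,
    "R": 14.92, "P": 0.0,
}

#: EMBOSS side-chain and termini pKa values.
EMBOSS_PKA: dict[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}

#: Relative side-chain volume coefficients of the aliphatic index.
ALIPHATIC_COEFFICIENTS = {"V": 2.9, "I": 3.9, "L": 3.9}


def registry_checksum(scales: dict[str, dict[str, float]] | None = None) -> str:
    """SHA-256 of the (sorted, JSON-serialised) scale registry."""
    scales = HYDROPHOBICITY_SCALES if scales is None else scales
    payload = json.dumps(scales, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _validate_registry() -> None:
    for name, scale in HYDROPHOBICITY_SCALES.items():
        if set(scale) != set(AA_ORDER):
            raise AssertionError(f"scale {name} does not cover the 20 residues")


_validate_registry()
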