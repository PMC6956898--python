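"""Protein-target meta-features.

Per-target descriptors computed from the amino-acid sequence: aliphatic
index, Boman (protein-interaction) index, 38 hydrophobicity scale means,
theoretical net charge and isoelectric point, molecular weight, sequence
length, instability index, and the 400-dimensional dipeptide composition.
All are composition- or adjacency-based, hence cheap and deterministic.

Net charge follows the Henderson–Hasselbalch treatment of the ionisable
side chains (D, E, C, Y, H, K, R) plus the two termini: a positively
ionisable group contributes ``1 / (1 + 10^(pH - pKa))`` and a negatively
ionisable one ``-1 / (1 + 10^(pKa - pH))``. The charge is strictly
decreasing in pH, so the isoelectric point is found by bisection.

Instability index and molecular weight delegate to Biopython's embedded
Guruprasad dipeptide-weight (DIWV) table and average-mass table.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .scales import (
    ALIPHATIC_COEFFICIENTS,
    BOMAN_SCALE,
    EMBOSS_PKA,
    HYDROPHOBICITY_SCALES,
)

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

POSITIVE_GROUPS = ("H", "K", "R")
NEGATIVE_GROUPS = ("D", "E", "C", "Y")

DIPEPTIDES = ["".join(p) for p in itertools.product(sorted(CANONICAL_AA), repeat=2)]

STABILITY_THRESHOLD = 40.0  # instability index below this predicts a stable protein


def _clean(sequence: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = sorted(set(seq) - CANONICAL_AA)
    if bad:
        raise ValueError(f"non-canonical residue(s): {', '.join(bad)}")
    return seq


def aliphatic_index(sequence: str) -> float:
    """Relative volume occupied by aliphatic side chains (A, V, I, L).

    ``X(Ala) + 2.9 X(Val) + 3.9 (X(Ile) + X(Leu))`` with X in mole percent.
    """
    seq = _clean(sequence)
    n = len(seq)
    mole_pct = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return (
        mole_pct["A"]
        + ALIPHATIC_COEFFICIENTS["V"] * mole_pct["V"]
        + ALIPHATIC_COEFFICIENTS["I"] * mole_pct["I"]
        + ALIPHATIC_COEFFICIENTS["L"] * mole_pct["L"]
    )


def boman_index(sequence: str) -> float:
    """Potential protein-interaction index: mean residue solubility value
    (kcal/mol per residue); higher means more protein-binding potential."""
    seq = _clean(sequence)
    return float(np.mean([BOMAN_SCALE[aa] for aa in seq]))


def hydrophobicity_profile(
    sequence: str, registry: dict[str, dict[str, float]] | None = None
) -> pd.Series:
    """Mean value of the sequence on each scale of the registry.

    Composition-only: invariant to residue order. Defaults to the embedded
    38-scale registry.
    """
    seq = _clean(sequence)
    registry = HYDROPHOBICITY_SCALES if registry is None else registry
    values = {
        name: float(np.mean([scale[aa] for aa in seq]))
        for name, scale in registry.items()
    }
    return pd.Series(values, name="hydrophobicity")


def net_charge(
    sequence: str, pH: float = 7.0, pka: dict[str, float] | None = None
) -> float:
    """Theoretical net charge (elementary charges) at the given pH."""
    if not (0.0 < pH < 14.0):
        raise ValueError("pH must lie in (0, 14)")
    seq = _clean(sequence)
    pka = EMBOSS_PKA if pka is None else pka
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - pH))
    for aa in POSITIVE_GROUPS:
        charge += seq.count(aa) / (1.0 + 10.0 ** (pH - pka[aa]))
    for aa in NEGATIVE_GROUPS:
        charge -= seq.count(aa) / (1.0 + 10.0 ** (pka[aa] - pH))
    return charge


def isoelectric_point(
    sequence: str,
    pka: dict[str, float] | None = None,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge is zero, by bisection on [0.1, 13.9].

    The charge is strictly decreasing in pH and every peptide has charged
    termini, so a unique root exists in the search interval.
    """
    lo, hi = 0.1, 13.9
    f_lo = net_charge(sequence, lo, pka)
    f_hi = net_charge(sequence, hi, pka)
    if f_lo < 0:
        return lo
    if f_hi > 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def instability_index(sequence: str) -> float:
    """Guruprasad instability index: ``(10/L) * sum`` of dipeptide weights
    over consecutive residue pairs. Below 40 predicts a stable protein."""
    from Bio.SeqUtils.ProtParamData import DIWV

    seq = _clean(sequence)
    if len(seq) < 2:
        raise ValueError("instability index needs at least 2 residues")
    total = sum(DIWV[seq[i]][seq[i + 1]] for i in range(len(seq) - 1))
    return 10.0 / len(seq) * total


def is_stable(sequence: str) -> bool:
    return instability_index(sequence) < STABILITY_THRESHOLD


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Da (peptide-bond water-corrected)."""
    from Bio.SeqUtils import molecular_weight as bio_mw

    return float(bio_mw(_clean(sequence), seq_type="protein"))


def dipeptide_composition(sequence: str) -> pd.Series:
    """Fractions of the 400 ordered residue pairs at adjacent positions.

    Counts divided by ``L - 1``; entries sum to one for any sequence of
    length at least two.
    """
    seq = _clean(sequence)
    if len(seq) < 2:
        raise ValueError("dipeptide composition needs at least 2 residues")
    counts = dict.fromkeys(DIPEPTIDES, 0)
    for i in range(len(seq) - 1):
        counts[seq[i : i + 2]] += 1
    total = len(seq) - 1
    return pd.Series(
        {dp: counts[dp] / total for dp in DIPEPTIDES}, name="dipeptide_composition"
    )


def target_metafeatures(sequence: str, prefix: str = "tg_") -> pd.Series:
    """All numeric target meta-features for one sequence, prefixed."""
    seq = _clean(sequence)
    values: dict[str, float] = {
        f"{prefix}aliphatic_index": aliphatic_index(seq),
        f"{prefix}boman_index": boman_index(seq),
        f"{prefix}net_charge": net_charge(seq),
        f"{prefix}isoelectric_point": isoelectric_point(seq),
        f"{prefix}molecular_weight": molecular_weight(seq),
        f"{prefix}sequence_length": float(len(seq)),
        f"{prefix}instability_index": instability_index(seq),
    }
    hydro = hydrophobicity_profile(seq)
    for name, val in hydro.items():
        values[f"{prefix}hydro_{name}"] = val
    for dp, val in dipeptide_composition(seq).items():
        values[f"{prefix}dc_{dp}"] = val
    return pd.Series(values)
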