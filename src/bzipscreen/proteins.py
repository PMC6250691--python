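"""Physicochemical property calculators for bZIP protein sequences.

Computes the properties tabulated for protein family surveys: residue
length, average molecular weight (Da), theoretical isoelectric point (the
ExPASy ProtParam convention: Henderson-Hasselbalch net charge over the
termini and the D, E, C, Y, K, R, H side chains with the Bjellqvist pKa
set, solved by bisection) and GRAVY (grand average of hydropathicity, the
mean Kyte-Doolittle index).

Only the 20 standard amino-acid letters are accepted; ambiguity codes
(B, Z, X, U, O, J) are rejected rather than guessed, because a silently
substituted residue corrupts the charge balance underlying pI.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils import IsoelectricPoint as _IP
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

__all__ = [
    "ProteinRecord",
    "molecular_weight",
    "gravy",
    "net_charge",
    "isoelectric_point",
    "protein_properties",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
WATER_DA = 18.02

#: Bjellqvist pKa values (positively / negatively ionizable groups).
POSITIVE_PKA: dict[str, float] = dict(_IP.positive_pKs)  # Nterm, K, R, H
NEGATIVE_PKA: dict[str, float] = dict(_IP.negative_pKs)  # Cterm, D, E, C, Y


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    length: int
    mw: float
    pi: float
    gravy: float


def _validate(sequence: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    for i, aa in enumerate(seq):
        if aa not in STANDARD_AA:
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")
    return seq


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Daltons: residue masses plus one water."""
    seq = _validate(sequence)
    residue_sum = sum(protein_weights[aa] - WATER_DA for aa in seq)
    return residue_sum + WATER_DA


def gravy(sequence: str) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle index."""
    seq = _validate(sequence)
    return sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)


def net_charge(sequence: str, ph: float) -> float:
    """Modeled net charge at a given pH (Henderson-Hasselbalch).

    Strictly decreasing in pH, so the pI root is unique.
    """
    seq = _validate(sequence)
    counts = {aa: seq.count(aa) for aa in set(seq)}
    positive = 10 ** -ph / (10 ** -POSITIVE_PKA["Nterm"] + 10 ** -ph)
    for aa in ("K", "R", "H"):
        n = counts.get(aa, 0)
        if n:
            positive += n * 10 ** -ph / (10 ** -POSITIVE_PKA[aa] + 10 ** -ph)
    negative = 10 ** -NEGATIVE_PKA["Cterm"] / (10 ** -NEGATIVE_PKA["Cterm"] + 10 ** -ph)
    for aa in ("D", "E", "C", "Y"):
        n = counts.get(aa, 0)
        if n:
            negative += n * 10 ** -NEGATIVE_PKA[aa] / (10 ** -NEGATIVE_PKA[aa] + 10 ** -ph)
    return positive - negative


def isoelectric_point(sequence: str, tolerance: float = 1e-4) -> float:
    """pH at which the modeled net charge is zero, by bisection on [0, 14]."""
    seq = _validate(sequence)
    lo, hi = 0.0, 14.0
    while hi - lo > tolerance:
        mid = (lo + hi) / 2
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def protein_properties(records: dict[str, str]) -> pd.DataFrame:
    """Property table for a set of sequences (id -> sequence).

    Columns: id, length, mw_da, pi, gravy.
    """
    rows = []
    for seq_id, seq in records.items():
        seq = _validate(seq)
        rows.append(
            {
                "id": seq_id,
                "length": len(seq),
                "mw_da": molecular_weight(seq),
                "pi": isoelectric_point(seq),
                "gravy": gravy(seq),
            }
        )
    return pd.DataFrame(rows, columns=["id", "length", "mw_da", "pi", "gravy"])
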