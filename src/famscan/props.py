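"""Physicochemical protein characterization: length, ORF length,
molecular weight and isoelectric point.

Conventions follow the ProtParam tool: average (not monoisotopic) residue
masses, and the Bjellqvist pKa set for the isoelectric point.  The pI is
the root of the Henderson-Hasselbalch net-charge function, found by
bisection on pH in [0, 14].
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Data.IUPACData import protein_weights as _FREE_AA_WEIGHTS

from .models import AMINO_ACIDS, ProteinRecord

WATER_DA = 18.0153

#: Bjellqvist pKa values (ExPASy-compatible).  Positive groups carry
#: charge below their pKa, negative groups above it.  The terminal pKa is
#: refined by the identity of the terminal residue, as in ProtParam.
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_NTERMINAL = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
PKA_CTERMINAL = {"D": 4.55, "E": 4.75}


def orf_length(length_aa: int) -> int:
    """Open-reading-frame length in bp for a protein of ``length_aa``
    residues: one codon per residue plus the stop codon."""
    if length_aa < 0:
        raise ValueError("protein length must be non-negative")
    return 3 * (length_aa + 1)


def molecular_weight(sequence: str) -> float:
    """Average-isotopic molecular weight in kDa: sum of residue masses
    plus one water."""
    if not sequence:
        raise ValueError("empty sequence")
    total = WATER_DA
    for pos, aa in enumerate(sequence, start=1):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {aa!r} at position {pos}")
        # free amino-acid mass minus the water released by the peptide bond
        total += _FREE_AA_WEIGHTS[aa] - WATER_DA
    return total / 1000.0


def net_charge(sequence: str, ph: float, pka_positive=None, pka_negative=None) -> float:
    """Net charge of the protein at a given pH under the
    Henderson-Hasselbalch model (termini plus D, E, C, Y, H, K, R)."""
    pos = dict(PKA_POSITIVE if pka_positive is None else pka_positive)
    neg = dict(PKA_NEGATIVE if pka_negative is None else pka_negative)
    if pka_positive is None and sequence and sequence[0] in PKA_NTERMINAL:
        pos["Nterm"] = PKA_NTERMINAL[sequence[0]]
    if pka_negative is None and sequence and sequence[-1] in PKA_CTERMINAL:
        neg["Cterm"] = PKA_CTERMINAL[sequence[-1]]
    counts_pos = {"Nterm": 1}
    counts_neg = {"Cterm": 1}
    for aa in sequence:
        if aa in pos:
            counts_pos[aa] = counts_pos.get(aa, 0) + 1
        elif aa in neg:
            counts_neg[aa] = counts_neg.get(aa, 0) + 1
    charge = 0.0
    for group, n in counts_pos.items():
        charge += n / (1.0 + 10.0 ** (ph - pos[group]))
    for group, n in counts_neg.items():
        charge -= n / (1.0 + 10.0 ** (neg[group] - ph))
    return charge


def isoelectric_point(
    sequence: str,
    pka_positive=None,
    pka_negative=None,
    charge_tol: float = 1e-4,
    ph_tol: float = 1e-3,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The pKa tables are injectable so an EMBOSS-style set can be compared
    against the default Bjellqvist set.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        charge = net_charge(sequence, mid, pka_positive, pka_negative)
        if abs(charge) < charge_tol or (hi - lo) < ph_tol:
            return mid
        if charge > 0:  # still positively charged: pI is higher
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass(frozen=True)
class ProteinProperties:
    id: str
    length: int
    orf_length: int
    mw: float  # kDa
    pi: float


def protein_properties(protein: ProteinRecord) -> ProteinProperties:
    seq = protein.sequence
    return ProteinProperties(
        id=protein.id,
        length=len(seq),
        orf_length=orf_length(len(seq)),
        mw=molecular_weight(seq),
        pi=isoelectric_point(seq),
    )


def properties_table(proteins: list[ProteinRecord]) -> pd.DataFrame:
    """Characteristics table (one row per protein), MW and pI rounded to
    the conventional 2 decimals."""
    rows = [protein_properties(p) for p in proteins]
    return pd.DataFrame(
        {
            "id": [r.id for r in rows],
            "length_aa": [r.length for r in rows],
            "orf_bp": [r.orf_length for r in rows],
            "mw_kda": [round(r.mw, 2) for r in rows],
            "pi": [round(r.pi, 2) for r in rows],
        }
    )
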