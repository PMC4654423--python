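"""Sequence-derived physicochemical protein properties.

Molecular weight is the sum of average residue masses plus one water;
the isoelectric point is found by bisection on the Henderson–Hasselbalch
net charge with Bjellqvist pKa values; the instability index is the
Guruprasad dipeptide-weight statistic (unstable above 40 by convention).
Residue mass and dipeptide weight tables come from Biopython's data
modules; the pKa set is packaged here and swappable per call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.ProtParamData import DIWV

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinProperties",
    "BJELLQVIST_PKA",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "instability_index",
    "protein_properties",
    "properties_table",
]

WATER_MASS = 18.0153  # average mass of H2O, Da

_RESIDUE_MASS = {aa: w - WATER_MASS for aa, w in protein_weights.items()}
_RESIDUE_MASS["X"] = sum(_RESIDUE_MASS[aa] for aa in "ACDEFGHIKLMNPQRSTVWY") / 20.0

#: Bjellqvist pKa values (as used by the classical ProtParam-style pI).
BJELLQVIST_PKA: Mapping[str, float] = {
    "Nterm": 7.50,
    "Cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "H": 5.98,
    "C": 9.00,
    "Y": 10.00,
    "K": 10.00,
    "R": 12.00,
}
_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")

INSTABILITY_THRESHOLD = 40.0


@dataclass(frozen=True)
class ProteinProperties:
    protein_id: str
    length_aa: int
    mw_da: float
    pi: float
    instability_index: float
    stability: str  # "stable" | "unstable"


def molecular_weight(seq: str) -> float:
    """Average-mass molecular weight in daltons (residues + one water)."""
    if not seq:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for aa in seq:
        if aa == "X":
            logger.debug("molecular_weight: X residue uses the mean residue mass")
        try:
            total += _RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown amino acid {aa!r}") from None
    return total


def net_charge(
    seq: str, pH: float, pka: Mapping[str, float] = BJELLQVIST_PKA
) -> float:
    """Henderson–Hasselbalch net charge at a given pH.

    Sums the N-terminus, C-terminus and ionizable side chains
    (D, E, C, Y, K, R, H); strictly decreasing in pH.
    """
    if not seq:
        raise ValueError("empty sequence")
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")

    def positive(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pk))

    def negative(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - pH))

    charge = positive(pka["Nterm"]) + negative(pka["Cterm"])
    for aa in _BASIC:
        charge += seq.count(aa) * positive(pka[aa])
    for aa in _ACIDIC:
        charge += seq.count(aa) * negative(pka[aa])
    return charge


def isoelectric_point(
    seq: str, tol: float = 1e-4, pka: Mapping[str, float] = BJELLQVIST_PKA
) -> float:
    """pH at which the net charge vanishes, by bisection over [0, 14]."""
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def instability_index(seq: str) -> float:
    """Guruprasad dipeptide instability index: (10/L) * sum of DIWV weights."""
    if len(seq) < 2:
        raise ValueError("instability index needs length >= 2")
    total = 0.0
    for a, b in zip(seq, seq[1:]):
        try:
            total += DIWV[a][b]
        except KeyError:
            logger.debug("instability_index: no weight for %s%s, using 0", a, b)
    return 10.0 * total / len(seq)


def protein_properties(
    rec_id: str, seq: str, threshold: float = INSTABILITY_THRESHOLD
) -> ProteinProperties:
    ii = instability_index(seq)
    return ProteinProperties(
        protein_id=rec_id,
        length_aa=len(seq),
        mw_da=molecular_weight(seq),
        pi=isoelectric_point(seq),
        instability_index=ii,
        stability="unstable" if ii > threshold else "stable",
    )


def properties_table(records: Iterable) -> pd.DataFrame:
    """Per-protein property table (id, length, MW kDa, pI, II, stability)."""
    rows = []
    for rec in records:
        p = protein_properties(rec.id, rec.sequence)
        rows.append(
            {
                "protein_id": p.protein_id,
                "length_aa": p.length_aa,
                "mw_kda": round(p.mw_da / 1000.0, 4),
                "pi": round(p.pi, 2),
                "instability_index": round(p.instability_index, 2),
                "stability": p.stability,
            }
        )
    return pd.DataFrame(rows)
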