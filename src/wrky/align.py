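"""Shared pairwise-alignment helpers.

All global alignments in the package go through Biopython's
:class:`Bio.Align.PairwiseAligner`.  Proteins are scored with BLOSUM62
(gap open 10, extend 0.5, as in common BLASTP-like practice); nucleotides
with a simple match/mismatch scheme.  Identity is always reported as
matches over aligned columns (dual gaps cannot occur in a pairwise
alignment), or over the shorter sequence where an operation says so.
"""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "protein_aligner",
    "nucleotide_aligner",
    "identity_over_columns",
    "identity_over_shorter",
    "align_pair",
    "alignment_score",
]


def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def _get_aligner(kind: str) -> Align.PairwiseAligner:
    if kind == "protein":
        return protein_aligner()
    if kind == "nucleotide":
        return nucleotide_aligner()
    raise ValueError(f"unknown aligner kind: {kind!r}")


def align_pair(a: str, b: str, kind: str = "protein") -> tuple[str, str]:
    """Globally align two sequences; return the two gapped rows."""
    aln = _get_aligner(kind).align(a, b)[0]
    return str(aln[0]), str(aln[1])


def alignment_score(a: str, b: str, kind: str = "protein") -> float:
    return _get_aligner(kind).score(a, b)


def _counts(a: str, b: str, kind: str):
    aln = _get_aligner(kind).align(a, b)[0]
    c = aln.counts()
    return c.identities, c.identities + c.mismatches + c.gaps


def identity_over_columns(a: str, b: str, kind: str = "protein") -> tuple[float, int]:
    """Fraction identical over all aligned columns (gap columns included).

    Returns ``(identity, n_columns)``.
    """
    ident, ncols = _counts(a, b, kind)
    return ident / ncols, ncols


def identity_over_shorter(a: str, b: str, kind: str = "protein") -> float:
    """Matches divided by the length of the shorter sequence (CD-HIT style)."""
    ident, _ = _counts(a, b, kind)
    return ident / min(len(a), len(b))
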