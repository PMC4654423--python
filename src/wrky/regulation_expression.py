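"""Promoter cis-element scanning, expression normalisation and enrichment.

Cis-regulatory elements are matched as IUPAC consensus patterns on both
strands of a promoter (PLACE-style consensi, no position weight
matrices); ``N`` in the promoter never matches.  Expression support
covers RPKM normalisation of read-count tables, qRT-PCR relative
expression by the 2^-ddCt method (100% primer efficiency assumed), and
hypergeometric term enrichment with Benjamini–Hochberg correction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import reverse_complement

__all__ = [
    "CREPattern",
    "MotifHit",
    "EnrichmentResult",
    "load_catalog",
    "default_catalog",
    "scan_cre",
    "rpkm",
    "log2_matrix",
    "fold_change_ddct",
    "qpcr_fold_changes",
    "hypergeometric_enrichment",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class CREPattern:
    name: str
    iupac: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.iupac) < 4:
            raise ValueError(f"{self.name}: pattern must be >= 4 bases")
        for ch in self.iupac:
            if ch not in _IUPAC:
                raise ValueError(f"{self.name}: {ch!r} is not an IUPAC code")

    def regex(self) -> re.Pattern:
        # classes over ACGT only: a promoter N never satisfies any code
        body = "".join(
            c if len(_IUPAC[c]) == 1 else f"[{_IUPAC[c]}]" for c in self.iupac
        )
        return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class MotifHit:
    promoter_id: str
    pattern: str
    start: int  # 0-based, plus-strand coordinate of the leftmost base
    strand: str
    matched: str


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int
    K: int
    n: int
    M: int
    p: float
    q: float


def load_catalog(path) -> list[CREPattern]:
    """Load a TSV catalog with columns name, iupac, description."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        CREPattern(str(r["name"]), str(r["iupac"]).upper(),
                   str(r.get("description", "")))
        for _, r in df.iterrows()
    ]


def default_catalog() -> list[CREPattern]:
    """The packaged element catalog (W-box and other PLACE-style consensi)."""
    ref = resources.files("wrky").joinpath("data/cre_catalog.tsv")
    with resources.as_file(ref) as path:
        return load_catalog(path)


def scan_cre(
    promoter: str,
    catalog: Sequence[CREPattern],
    promoter_id: str = "promoter",
) -> list[MotifHit]:
    """Every occurrence of every catalog pattern on both strands.

    Minus-strand hits are reported in plus-strand coordinates of their
    leftmost base; overlapping hits are all reported.
    """
    promoter = promoter.upper()
    if not catalog:
        raise ValueError("empty catalog")
    rc = reverse_complement(promoter)
    L = len(promoter)
    hits: list[MotifHit] = []
    for pat in catalog:
        rx = pat.regex()
        for m in rx.finditer(promoter):
            hits.append(MotifHit(promoter_id, pat.name, m.start(), "+", m.group(1)))
        for m in rx.finditer(rc):
            start = L - m.start() - len(pat.iupac)
            hits.append(MotifHit(promoter_id, pat.name, start, "-", m.group(1)))
    return sorted(hits, key=lambda h: (h.start, h.pattern, h.strand))


def hit_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [h.__dict__ for h in hits],
        columns=["promoter_id", "pattern", "start", "strand", "matched"],
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def rpkm(
    counts: pd.DataFrame,
    lengths: Mapping[str, float] | pd.Series,
    library_sizes: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads: 1e9 * C / (N * L).

    ``counts`` is genes x samples; ``lengths`` gives transcript length in
    bp per gene.  ``library_sizes`` defaults to the per-sample column sums.
    """
    counts = counts.astype(float)
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    L = pd.Series(lengths).reindex(counts.index)
    if L.isna().any() or (L <= 0).any():
        raise ValueError("every gene needs a positive length")
    if library_sizes is None:
        N = counts.sum(axis=0)
    else:
        N = pd.Series(library_sizes).reindex(counts.columns)
    if N.isna().any() or (N <= 0).any():
        raise ValueError("library sizes must be positive")
    return 1e9 * counts.div(N, axis=1).div(L, axis=0)


def log2_matrix(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Heatmap-ready log2(RPKM + pseudocount) matrix."""
    return np.log2(expr + pseudocount)


def fold_change_ddct(
    ct_target_treated,
    ct_ref_treated,
    ct_target_control,
    ct_ref_control,
) -> float:
    """Relative expression by 2^-ddCt.

    Arguments may be scalars or replicate arrays (replicates are averaged
    before differencing).  ddCt = (Ct_tgt,T - Ct_ref,T) -
    (Ct_tgt,C - Ct_ref,C).
    """
    vals = [
        np.mean(np.asarray(v, dtype=float))
        for v in (ct_target_treated, ct_ref_treated,
                  ct_target_control, ct_ref_control)
    ]
    if not all(np.isfinite(vals)):
        raise ValueError("Ct values must be finite")
    ddct = (vals[0] - vals[1]) - (vals[2] - vals[3])
    return float(2.0 ** (-ddct))


def qpcr_fold_changes(
    ct: pd.DataFrame,
    reference_gene: str,
    control_timepoint: str = "0h",
) -> pd.DataFrame:
    """Per gene/condition/timepoint fold changes from a long-format Ct table.

    Expected columns: gene, condition, timepoint, replicate, ct.  The
    control timepoint within each condition is the calibrator, so its fold
    change is 1 by construction.
    """
    required = {"gene", "condition", "timepoint", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    means = ct.groupby(["gene", "condition", "timepoint"])["ct"].mean()
    rows = []
    genes = sorted(set(ct["gene"]) - {reference_gene})
    for gene in genes:
        for cond in sorted(set(ct["condition"])):
            try:
                tgt_c = means[(gene, cond, control_timepoint)]
                ref_c = means[(reference_gene, cond, control_timepoint)]
            except KeyError:
                continue
            for tp in sorted(set(ct.loc[ct["condition"] == cond, "timepoint"])):
                tgt_t = means.get((gene, cond, tp))
                ref_t = means.get((reference_gene, cond, tp))
                if tgt_t is None or ref_t is None:
                    continue
                fold = fold_change_ddct(tgt_t, ref_t, tgt_c, ref_c)
                rows.append(
                    {"gene": gene, "condition": cond, "timepoint": tp,
                     "fold_change": fold}
                )
    return pd.DataFrame(rows, columns=["gene", "condition", "timepoint",
                                       "fold_change"])


def hypergeometric_enrichment(
    study: set[str],
    population: set[str],
    annotation: Mapping[str, set[str]],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment with BH correction.

    For each term with K >= 1 annotated genes in the population,
    p = P(X >= k) for k study hits out of n = |study| draws from
    M = |population|; q-values by Benjamini–Hochberg over all tested terms.
    """
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    M, n = len(population), len(study)
    tested = []
    for term in sorted(annotation):
        members = annotation[term] & population
        K = len(members)
        if K == 0:
            continue
        k = len(members & study)
        p = float(hypergeom.sf(k - 1, M, K, n))
        tested.append((term, k, K, p))
    if not tested:
        return []
    _, qvals, _, _ = multipletests([t[3] for t in tested], method="fdr_bh")
    return [
        EnrichmentResult(term, k, K, n, M, p, float(q))
        for (term, k, K, p), q in zip(tested, qvals)
    ]
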