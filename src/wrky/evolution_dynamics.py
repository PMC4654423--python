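"""Gene-family evolutionary dynamics.

Covers paralog detection by global-alignment identity, tandem and
segmental (collinear-block) duplication classification over gene ranks,
codon-aware back-translation of protein alignments, the Nei–Gojobori
(1986) Ka/Ks estimator with Jukes–Cantor correction, molecular-clock
divergence dating T = Ks / (2 lambda), and reciprocal-best-hit orthology.

The NG86 estimator counts synonymous/nonsynonymous *sites* per codon as
the fraction of the three possible changes at each position that preserve
the encoded amino acid (changes to stop codons count as nonsynonymous,
so S + N is always exactly 3 x compared codons), and counts observed
differences by averaging over all minimal substitution pathways with
equal weight, excluding pathways through stop codons.  Proportions at or
beyond 3/4 are reported as saturated rather than corrected.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .align import align_pair, alignment_score, identity_over_columns
from .io_formats import GeneModel, SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "HomologPair",
    "DuplicationPair",
    "SyntenyBlock",
    "KaKsResult",
    "DEFAULT_LAMBDA",
    "find_homolog_pairs",
    "detect_tandem",
    "detect_segmental",
    "segmental_pairs",
    "codon_align",
    "ng86_kaks",
    "divergence_time",
    "reciprocal_best_hits",
]

#: Synonymous substitution rate per site per year (grass molecular clock).
DEFAULT_LAMBDA = 6.5e-9

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"


def _aa(codon: str) -> str:
    return "*" if codon in _STOPS else _TABLE.forward_table[codon]


@dataclass(frozen=True)
class HomologPair:
    id_a: str
    id_b: str
    identity: float
    aln_length: int

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise ValueError("HomologPair ids must be in sorted order")


@dataclass(frozen=True)
class DuplicationPair:
    pair: HomologPair
    dup_type: str  # "tandem" | "segmental"
    block_id: str | None = None


@dataclass(frozen=True)
class SyntenyBlock:
    block_id: str
    chrom_a: str
    chrom_b: str
    pairs: tuple[tuple[HomologPair, int, int], ...]  # (pair, rank_a, rank_b)
    orientation: str  # "same" | "inverted"

    @property
    def size(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class KaKsResult:
    ka: float | None
    ks: float | None
    ratio: float | None
    S: float
    N: float
    sd: float
    nd: float
    ka_saturated: bool
    ks_saturated: bool
    n_codons: int
    lam: float = DEFAULT_LAMBDA

    @property
    def time_years(self) -> float | None:
        if self.ks is None:
            return None
        return divergence_time(self.ks, self.lam)


# ---------------------------------------------------------------------------
# Homology and duplication
# ---------------------------------------------------------------------------

def find_homolog_pairs(
    proteins: Sequence[SeqRecord], min_identity: float = 0.90
) -> list[HomologPair]:
    """All unordered pairs at >= ``min_identity`` global-alignment identity."""
    pairs: list[HomologPair] = []
    ordered = sorted(proteins, key=lambda r: r.id)
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            ident, ncols = identity_over_columns(a.sequence, b.sequence)
            if ident >= min_identity:
                pairs.append(HomologPair(a.id, b.id, ident, ncols))
    return pairs


def detect_tandem(
    pairs: Iterable[HomologPair],
    gene_models: Mapping[str, GeneModel],
    max_intervening: int = 1,
) -> list[DuplicationPair]:
    """Homolog pairs adjacent on a chromosome (MCScanX tandem convention).

    A pair is tandem when both genes share a chromosome with at most
    ``max_intervening`` genes between them (|rank difference| <=
    max_intervening + 1).
    """
    out = []
    for p in pairs:
        ma, mb = gene_models[p.id_a], gene_models[p.id_b]
        if ma.chromosome != mb.chromosome:
            continue
        if abs(ma.rank - mb.rank) <= max_intervening + 1:
            out.append(DuplicationPair(p, "tandem"))
    return out


def _chain(points: list[tuple[int, int, HomologPair]], inverted: bool,
           max_gap: int) -> list[int]:
    """Longest strictly monotonic chain (indices into ``points``).

    ``points`` must be sorted by (rank_a, rank_b).  Consecutive chain steps
    must advance rank_a and rank_b (decreasing rank_b when ``inverted``)
    by at least 1 and at most ``max_gap``.
    """
    n = len(points)
    if n == 0:
        return []
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        ra_i, rb_i, _ = points[i]
        for j in range(i):
            ra_j, rb_j, _ = points[j]
            da = ra_i - ra_j
            db = (rb_j - rb_i) if inverted else (rb_i - rb_j)
            if 1 <= da <= max_gap and 1 <= db <= max_gap:
                if best_len[j] + 1 > best_len[i]:
                    best_len[i] = best_len[j] + 1
                    prev[i] = j
    end = max(range(n), key=lambda i: (best_len[i], -points[i][0], -points[i][1]))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def detect_segmental(
    pairs: Iterable[HomologPair],
    gene_models: Mapping[str, GeneModel],
    min_block: int = 3,
    max_rank_gap: int = 10,
) -> list[SyntenyBlock]:
    """Collinear blocks of homolog pairs in gene-rank space.

    Within each chromosome pair, homolog pairs are chained by the longest
    strictly monotonic subsequence in rank space (both orientations tried,
    per-step rank gap <= ``max_rank_gap`` on both sides).  Chains of at
    least ``min_block`` pairs become blocks; each pair belongs to at most
    one block (longest chain first, ties by earliest start rank).
    """
    grouped: dict[tuple[str, str], list[tuple[int, int, HomologPair]]] = {}
    for p in pairs:
        ma, mb = gene_models[p.id_a], gene_models[p.id_b]
        key = tuple(sorted((ma.chromosome, mb.chromosome)))
        if ma.chromosome == key[0] and (
            ma.chromosome != mb.chromosome or ma.rank <= mb.rank
        ):
            ra, rb = ma.rank, mb.rank
        else:
            ra, rb = mb.rank, ma.rank
        grouped.setdefault(key, []).append((ra, rb, p))

    blocks: list[SyntenyBlock] = []
    counter = 0
    for key in sorted(grouped):
        points = sorted(grouped[key], key=lambda t: (t[0], t[1]))
        while True:
            candidates = []
            for orientation in ("same", "inverted"):
                chain = _chain(points, orientation == "inverted", max_rank_gap)
                if len(chain) >= min_block:
                    start = points[chain[0]]
                    candidates.append(
                        (-len(chain), start[0], start[1],
                         0 if orientation == "same" else 1, chain, orientation)
                    )
            if not candidates:
                break
            candidates.sort()
            *_, chain, orientation = candidates[0]
            counter += 1
            members = tuple(
                (points[i][2], points[i][0], points[i][1]) for i in chain
            )
            blocks.append(
                SyntenyBlock(f"block{counter}", key[0], key[1], members,
                             orientation)
            )
            used = set(chain)
            points = [pt for i, pt in enumerate(points) if i not in used]
    return blocks


def segmental_pairs(blocks: Iterable[SyntenyBlock]) -> list[DuplicationPair]:
    return [
        DuplicationPair(pair, "segmental", block.block_id)
        for block in blocks
        for pair, _, _ in block.pairs
    ]


# ---------------------------------------------------------------------------
# Codon alignment and NG86
# ---------------------------------------------------------------------------

def codon_align(
    protein_alignment: Sequence[tuple[str, str]],
    cds_map: Mapping[str, str],
) -> list[tuple[str, str]]:
    """Back-translate a gapped protein alignment onto its CDS sequences.

    Each amino-acid column maps to its codon triplet; protein gaps become
    ``---``.  A terminal stop codon on a CDS is stripped; a length mismatch
    or internal stop raises ``ValueError``.
    """
    out = []
    for seq_id, aa_row in protein_alignment:
        cds = cds_map[seq_id].upper()
        plen = len(aa_row.replace("-", ""))
        if len(cds) == 3 * (plen + 1) and cds[-3:] in _STOPS:
            cds = cds[:-3]
        if len(cds) != 3 * plen:
            raise ValueError(
                f"{seq_id}: CDS length {len(cds)} does not match "
                f"3 x {plen} ungapped residues"
            )
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        for k, codon in enumerate(codons):
            if codon in _STOPS:
                raise ValueError(f"{seq_id}: internal stop codon at codon {k + 1}")
        row, k = [], 0
        for aa in aa_row:
            if aa == "-":
                row.append("---")
            else:
                row.append(codons[k])
                k += 1
        out.append((seq_id, "".join(row)))
    return out


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Synonymous site count of a codon (0..3, NG86 convention)."""
    aa = _aa(codon)
    syn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _aa(alt) == aa and alt not in _STOPS:
                syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, pathway-averaged.

    All orders of the differing positions are enumerated; pathways passing
    through a stop codon are excluded (unless every pathway does, in which
    case all are kept).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS and nxt != c2:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        sd = sum(1 for a, b in steps if _aa(a) == _aa(b))
        nd = len(steps) - sd
        pathways.append((blocked, sd, nd))
    valid = [(sd, nd) for blocked, sd, nd in pathways if not blocked]
    if not valid:
        valid = [(sd, nd) for _, sd, nd in pathways]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    """Jukes–Cantor correction; ``None`` when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def _comparable_codons(aln_a: str, aln_b: str) -> list[tuple[str, str]]:
    if len(aln_a) != len(aln_b) or len(aln_a) % 3:
        raise ValueError("codon alignment rows must share a length divisible by 3")
    out = []
    for i in range(0, len(aln_a), 3):
        ca, cb = aln_a[i : i + 3], aln_b[i : i + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        out.append((ca, cb))
    return out


def ng86_kaks(aln_a: str, aln_b: str, lam: float = DEFAULT_LAMBDA) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction.

    ``aln_a``/``aln_b`` are aligned codon rows (gaps ``-`` allowed in
    triplets); codon columns containing a gap or N are dropped.  Symmetric
    in its two arguments.
    """
    codons = _comparable_codons(aln_a, aln_b)
    if not codons:
        raise ValueError("no comparable codons")
    S = sum((_syn_sites(ca) + _syn_sites(cb)) / 2.0 for ca, cb in codons)
    N = 3.0 * len(codons) - S
    sd = nd = 0.0
    for ca, cb in codons:
        dsd, dnd = _pair_differences(ca, cb)
        sd += dsd
        nd += dnd
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(
        ka=ka,
        ks=ks,
        ratio=ratio,
        S=S,
        N=N,
        sd=sd,
        nd=nd,
        ka_saturated=ka is None,
        ks_saturated=ks is None,
        n_codons=len(codons),
        lam=lam,
    )


def kaks_for_pair(
    seq_a: SeqRecord, seq_b: SeqRecord, cds_map: Mapping[str, str],
    lam: float = DEFAULT_LAMBDA,
) -> KaKsResult:
    """Convenience: align two proteins, back-translate, run NG86."""
    row_a, row_b = align_pair(seq_a.sequence, seq_b.sequence)
    aligned = codon_align([(seq_a.id, row_a), (seq_b.id, row_b)], cds_map)
    return ng86_kaks(aligned[0][1], aligned[1][1], lam)


def divergence_time(ks: float, lam: float = DEFAULT_LAMBDA) -> float:
    """Molecular-clock divergence time in years: T = Ks / (2 lambda)."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return ks / (2.0 * lam)


# ---------------------------------------------------------------------------
# Orthology
# ---------------------------------------------------------------------------

def reciprocal_best_hits(
    set_a: Sequence[SeqRecord],
    set_b: Sequence[SeqRecord],
    min_identity: float = 0.90,
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit ortholog pairs between two protein sets.

    (a, b) is reported iff b is a's unique best-scoring match in ``set_b``,
    a is b's unique best-scoring match in ``set_a``, and their alignment
    identity is >= ``min_identity``.  Score ties yield no call (logged).
    """
    a_recs = sorted(set_a, key=lambda r: r.id)
    b_recs = sorted(set_b, key=lambda r: r.id)
    scores = np.array(
        [[alignment_score(a.sequence, b.sequence) for b in b_recs] for a in a_recs]
    )

    def unique_best(row: np.ndarray) -> int | None:
        best = row.max()
        idx = np.flatnonzero(row == best)
        return int(idx[0]) if len(idx) == 1 else None

    out = []
    for i, a in enumerate(a_recs):
        j = unique_best(scores[i, :])
        if j is None:
            logger.info("reciprocal_best_hits: tie for %s, no call", a.id)
            continue
        if unique_best(scores[:, j]) != i:
            continue
        b = b_recs[j]
        ident, _ = identity_over_columns(a.sequence, b.sequence)
        if ident >= min_identity:
            out.append((a.id, b.id))
    return out


def kaks_table(results: Mapping[tuple[str, str], KaKsResult]) -> pd.DataFrame:
    rows = []
    for (a, b), r in sorted(results.items()):
        rows.append(
            {
                "id_a": a,
                "id_b": b,
                "n_codons": r.n_codons,
                "S": round(r.S, 4),
                "N": round(r.N, 4),
                "Ka": round(r.ka, 6) if r.ka is not None else "saturated",
                "Ks": round(r.ks, 6) if r.ks is not None else "saturated",
                "Ka_Ks": round(r.ratio, 6) if r.ratio is not None else "NA",
                "time_mya": round(r.time_years / 1e6, 4)
                if r.time_years is not None
                else "NA",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id_a", "id_b", "n_codons", "S", "N", "Ka", "Ks",
                 "Ka_Ks", "time_mya"],
    )
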