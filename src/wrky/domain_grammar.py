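"""WRKY domain detection as an explicit motif grammar.

A WRKY domain is the WRKYGQK heptapeptide (or a degenerate variant that
lacks the GQK signature) followed, within a bounded window, by a
zinc-finger structure C-x(4,8)-C-x(22,28)-H-x(1,2)-[HC].  The unified
spacer envelope accepts both published zinc-finger consensi
(CX4-5CX22-23HXH and CX5-8CX25-28HX1-2C); the terminal residue
disambiguates C2H2 from C2HC fingers.

Scanning is purely positional and deterministic: no profile scoring, no
E-values.  Degenerate heptapeptides count as domain evidence only when a
zinc finger is found downstream (they occur as supporting second domains,
not as standalone evidence).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "HeptapeptideHit",
    "ZincFingerHit",
    "WRKYDomainHit",
    "CANONICAL_HEPTAPEPTIDE",
    "DEGENERATE_PATTERN",
    "scan_heptapeptide",
    "scan_zinc_finger",
    "assemble_domains",
    "domain_region",
    "hit_table",
]

CANONICAL_HEPTAPEPTIDE = "WRKYGQK"
#: Degenerate heptapeptide consensus covering GQK-less second domains.
DEGENERATE_PATTERN = r"W[RK]KY[GA].K"

_CANON_RE = re.compile(r"(?=WRKYGQK)")
_DEGEN_RE = re.compile(rf"(?=({DEGENERATE_PATTERN}))")


@dataclass(frozen=True)
class HeptapeptideHit:
    start: int  # 0-based
    motif: str
    variant: str  # "canonical" | "degenerate"

    @property
    def end(self) -> int:
        """0-based exclusive end of the 7-residue motif."""
        return self.start + 7


@dataclass(frozen=True)
class ZincFingerHit:
    c1: int
    c2: int
    h1: int
    t: int
    finger_type: str  # "C2H2" | "C2HC"

    @property
    def spacer1(self) -> int:
        return self.c2 - self.c1 - 1

    @property
    def spacer2(self) -> int:
        return self.h1 - self.c2 - 1

    @property
    def spacer3(self) -> int:
        return self.t - self.h1 - 1


@dataclass(frozen=True)
class WRKYDomainHit:
    heptapeptide: HeptapeptideHit
    zinc_finger: ZincFingerHit | None

    @property
    def complete(self) -> bool:
        return self.zinc_finger is not None


def scan_heptapeptide(seq: str) -> list[HeptapeptideHit]:
    """All non-overlapping heptapeptide matches, canonical preferred.

    Canonical WRKYGQK matches are collected first, left to right; degenerate
    matches (``W[RK]KY[GA].K``) are then added wherever they do not overlap
    an accepted hit.
    """
    hits: list[HeptapeptideHit] = []
    occupied: list[tuple[int, int]] = []

    def overlaps(s: int) -> bool:
        return any(s < e and s + 7 > b for b, e in occupied)

    for m in _CANON_RE.finditer(seq):
        s = m.start()
        if not overlaps(s):
            hits.append(HeptapeptideHit(s, seq[s : s + 7], "canonical"))
            occupied.append((s, s + 7))
    for m in _DEGEN_RE.finditer(seq):
        s = m.start()
        motif = m.group(1)
        if motif == CANONICAL_HEPTAPEPTIDE or overlaps(s):
            continue
        hits.append(HeptapeptideHit(s, motif, "degenerate"))
        occupied.append((s, s + 7))
    return sorted(hits, key=lambda h: h.start)


def scan_zinc_finger(
    seq: str, from_index: int, window: int = 60
) -> ZincFingerHit | None:
    """Earliest zinc-finger match starting at or after ``from_index``.

    The first cysteine must lie within ``window`` residues of
    ``from_index``.  Among candidates sharing the same first cysteine the
    lexicographically smallest (spacer1, spacer2, spacer3) wins, which the
    nested search order guarantees.
    """
    n = len(seq)
    last_c1 = min(n - 1, from_index + window)
    for c1 in range(from_index, last_c1 + 1):
        if seq[c1] != "C":
            continue
        for s1 in range(4, 9):
            c2 = c1 + s1 + 1
            if c2 >= n or seq[c2] != "C":
                continue
            for s2 in range(22, 29):
                h1 = c2 + s2 + 1
                if h1 >= n or seq[h1] != "H":
                    continue
                for s3 in (1, 2):
                    t = h1 + s3 + 1
                    if t >= n or seq[t] not in "HC":
                        continue
                    ftype = "C2H2" if seq[t] == "H" else "C2HC"
                    return ZincFingerHit(c1, c2, h1, t, ftype)
    return None


def assemble_domains(seq: str, window: int = 60) -> list[WRKYDomainHit]:
    """Pair each heptapeptide hit with its downstream zinc-finger search.

    Degenerate heptapeptides without a finger are dropped; canonical ones
    are retained as incomplete domains.  Hits are ordered by position.
    """
    domains: list[WRKYDomainHit] = []
    for hepta in scan_heptapeptide(seq):
        finger = scan_zinc_finger(seq, hepta.end, window)
        if finger is None and hepta.variant == "degenerate":
            continue
        domains.append(WRKYDomainHit(hepta, finger))
    return domains


def domain_region(seq: str, hit: WRKYDomainHit, flank: int = 25) -> str:
    """The domain-spanning subsequence with ``flank`` residues either side."""
    lo = max(0, hit.heptapeptide.start - flank)
    hi = hit.zinc_finger.t + 1 if hit.complete else hit.heptapeptide.end
    return seq[lo : min(len(seq), hi + flank)]


def hit_table(records: Iterable) -> "pd.DataFrame":
    """Per-protein domain hit table (TSV-ready)."""
    import pandas as pd

    rows = []
    for rec in records:
        for d in assemble_domains(rec.sequence):
            zf = d.zinc_finger
            rows.append(
                {
                    "protein_id": rec.id,
                    "start": d.heptapeptide.start,
                    "motif": d.heptapeptide.motif,
                    "variant": d.heptapeptide.variant,
                    "complete": d.complete,
                    "finger_type": zf.finger_type if zf else "",
                    "spacer1": zf.spacer1 if zf else -1,
                    "spacer2": zf.spacer2 if zf else -1,
                    "spacer3": zf.spacer3 if zf else -1,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "start", "motif", "variant", "complete",
            "finger_type", "spacer1", "spacer2", "spacer3",
        ],
    )
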