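"""Group and subgroup assignment for WRKY proteins.

Group rules (domain-count / finger-type based):

* **I** — at least two complete domains (heptapeptide + zinc finger);
* **II** — exactly one complete domain with a C2H2 finger, subdivided into
  IIa–IIe by nearest labelled reference over the domain region;
* **III** — exactly one complete domain with a C2HC finger;
* **IV** — heptapeptide evidence but no complete domain (candidate
  pseudogenes / truncations);
* **none** — no heptapeptide evidence at all (non-family decoys).

Subgroup assignment replaces phylogenetic clade reading with a nearest
labelled reference: the query's domain region (plus 25 flanking residues)
is globally aligned to every reference and takes the label of the closest
one; exact ties fall back to a 3-nearest-neighbour majority, then the
lexicographically smallest label.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .align import identity_over_columns
from .domain_grammar import WRKYDomainHit, assemble_domains, domain_region
from .io_formats import SeqRecord, read_fasta, write_fasta

__all__ = [
    "GROUPS",
    "SUBGROUPS",
    "FamilyAssignment",
    "Reference",
    "ReferenceSet",
    "assign_group",
    "assign_subgroup",
    "classify_proteome",
]

SUBGROUPS = ("IIa", "IIb", "IIc", "IId", "IIe")
GROUPS = ("I",) + SUBGROUPS + ("III", "IV", "none")

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class FamilyAssignment:
    protein_id: str
    group: str
    n_complete_domains: int
    finger_types: tuple[str, ...]
    evidence: str


@dataclass(frozen=True)
class Reference:
    label: str
    ref_id: str
    sequence: str


class ReferenceSet:
    """Labelled domain-region exemplars for subgroup assignment."""

    def __init__(self, references: Sequence[Reference]):
        refs = list(references)
        counts = Counter(r.label for r in refs)
        for label in SUBGROUPS:
            if counts.get(label, 0) < 2:
                raise ValueError(
                    f"reference set needs >=2 references per subgroup; "
                    f"{label} has {counts.get(label, 0)}"
                )
        self.references = tuple(sorted(refs, key=lambda r: (r.label, r.ref_id)))

    def __len__(self) -> int:
        return len(self.references)

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSet":
        """Load references from FASTA with a ``subgroup=`` description tag."""
        refs = []
        for rec in read_fasta(path, "protein"):
            tag = [t for t in rec.description.split() if t.startswith("subgroup=")]
            if not tag:
                raise ValueError(f"reference {rec.id!r} lacks a subgroup= tag")
            refs.append(Reference(tag[0].split("=", 1)[1], rec.id, rec.sequence))
        return cls(refs)

    def to_fasta(self, path) -> None:
        write_fasta(
            [SeqRecord(r.ref_id, r.sequence, f"subgroup={r.label}")
             for r in self.references],
            path,
        )


def assign_group(domains: Sequence[WRKYDomainHit]) -> str:
    """Group label (I/II/III/IV/none) from assembled domain hits.

    Group II is returned unsubtyped here (see :func:`assign_subgroup`).
    """
    if not domains:
        return "none"
    complete = [d for d in domains if d.complete]
    if len(complete) >= 2:
        return "I"
    if len(complete) == 1:
        return "II" if complete[0].zinc_finger.finger_type == "C2H2" else "III"
    return "IV"


def assign_subgroup(query_region: str, refs: ReferenceSet) -> str:
    """Subgroup (IIa–IIe) of a group-II query via nearest labelled reference."""
    if len(refs) == 0:
        raise ValueError("empty reference set")
    scored = []
    for ref in refs.references:
        ident, _ = identity_over_columns(query_region, ref.sequence)
        scored.append((1.0 - ident, ref.label, ref.ref_id))
    scored.sort()
    best = scored[0][0]
    contenders = [s for s in scored if s[0] - best <= _TIE_TOL]
    if len(contenders) == 1:
        return contenders[0][1]
    top3 = scored[:3]
    tally = Counter(label for _, label, _ in top3)
    peak = max(tally.values())
    return min(label for label, n in tally.items() if n == peak)


def _classify_one(
    rec: SeqRecord,
    refs: ReferenceSet | None,
    window: int,
    flank: int,
) -> FamilyAssignment:
    domains = assemble_domains(rec.sequence, window)
    group = assign_group(domains)
    complete = [d for d in domains if d.complete]
    fingers = tuple(d.zinc_finger.finger_type for d in complete)
    evidence = (
        f"{len(domains)} heptapeptide hit(s), {len(complete)} complete domain(s)"
        f"{', fingers ' + '/'.join(fingers) if fingers else ''}"
    )
    if group == "II" and refs is not None:
        region = domain_region(rec.sequence, complete[0], flank)
        group = assign_subgroup(region, refs)
        evidence += f"; nearest reference subgroup {group}"
    return FamilyAssignment(rec.id, group, len(complete), fingers, evidence)


def classify_proteome(
    proteins: Iterable[SeqRecord],
    refs: ReferenceSet | None = None,
    window: int = 60,
    flank: int = 25,
) -> tuple[pd.DataFrame, Counter]:
    """Classify every protein; return the assignment table and group counts.

    Every input protein appears exactly once and the per-group counts sum
    to the input size.  Without a reference set, group II is reported
    unsubtyped as ``"II"``.
    """
    assignments = [_classify_one(rec, refs, window, flank) for rec in proteins]
    table = pd.DataFrame(
        [
            {
                "protein_id": a.protein_id,
                "group": a.group,
                "n_complete_domains": a.n_complete_domains,
                "finger_types": "/".join(a.finger_types),
                "evidence": a.evidence,
            }
            for a in assignments
        ],
        columns=["protein_id", "group", "n_complete_domains",
                 "finger_types", "evidence"],
    )
    return table, Counter(a.group for a in assignments)
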