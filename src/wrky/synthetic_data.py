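"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators invert the detection rules: proteins are random background
with planted heptapeptide/zinc-finger templates satisfying exactly one
group's grammar; genomes carry ordered gene models with tandem-adjacent
and collinear-block duplicate pairs whose CDSs diverge at controlled
synonymous/nonsynonymous proportions; promoters carry planted IUPAC
elements; count and Ct tables encode known fold changes.  Every dataset
is accompanied by a truth record sufficient to score any stage's output.

All randomness flows through one seeded :class:`numpy.random.Generator`
passed explicitly; identical seeds give byte-identical outputs.
Background residue frequencies are uniform over the 20 amino acids;
domain-template filler avoids C and W so the planted grammar cannot be
shadowed by accidental cysteines or heptapeptide seeds.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .domain_grammar import assemble_domains, domain_region, scan_heptapeptide
from .family_classifier import (
    Reference,
    ReferenceSet,
    SUBGROUPS,
    assign_group,
    assign_subgroup,
)
from .evolution_dynamics import (
    HomologPair,
    _aa,
    _pair_differences,
    _syn_sites,
)
from .io_formats import (
    GeneModel,
    SeqRecord,
    assign_ranks,
    extract_upstream,
    reverse_complement,
    write_fasta,
    write_gff,
)
from .regulation_expression import CREPattern, MotifHit, scan_cre

__all__ = [
    "generate_wrky_protein",
    "generate_decoy",
    "generate_proteome",
    "generate_reference_set",
    "reverse_translate",
    "random_cds",
    "mutate_cds",
    "generate_genome",
    "SyntheticGenome",
    "generate_promoters",
    "generate_counts",
    "generate_ct_table",
    "paper_shaped",
    "PAPER_SHAPED_COMPOSITION",
    "SyntheticDataset",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_FILLER = "ADEFGHIKLMNPQRSTVY"  # no C (finger anchors), no W (heptapeptide)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_NONSTOP_CODONS = tuple(sorted(set(_TABLE.forward_table)))
_CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for codon, aa in _TABLE.forward_table.items():
    _CODONS_FOR_AA.setdefault(aa, tuple())
_CODONS_FOR_AA = {
    aa: tuple(sorted(c for c, a in _TABLE.forward_table.items() if a == aa))
    for aa in set(_TABLE.forward_table.values())
}


def _stable_seed(tag: str) -> int:
    return int.from_bytes(hashlib.md5(tag.encode()).digest()[:4], "little")


def _filler(tag: str, n: int) -> str:
    rng = np.random.default_rng(_stable_seed(tag))
    return "".join(rng.choice(list(_FILLER), size=n))


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA20), size=n))


# ---------------------------------------------------------------------------
# Domain templates
# ---------------------------------------------------------------------------

_SUBGROUP_FINGERS = {
    "IIa": (4, 22, 1, "H"),
    "IIb": (5, 23, 1, "H"),
    "IIc": (4, 23, 1, "H"),
    "IId": (5, 22, 1, "H"),
    "IIe": (4, 22, 2, "H"),
    "III": (5, 25, 1, "C"),
}


def _finger(tag: str, s1: int, s2: int, s3: int, terminal: str):
    body = (
        "C" + _filler(f"{tag}:f1", s1) + "C" + _filler(f"{tag}:f2", s2)
        + "H" + _filler(f"{tag}:f3", s3) + terminal
    )
    anchors = {0, 1 + s1, 2 + s1 + s2, 3 + s1 + s2 + s3}
    return body, anchors


def _domain(tag: str, hepta: str, s1: int, s2: int, s3: int, terminal: str):
    """heptapeptide + linker + finger; anchors relative to the domain start."""
    link = _filler(f"{tag}:link", 6)
    finger, fa = _finger(tag, s1, s2, s3, terminal)
    anchors = set(range(7)) | {7 + 6 + a for a in fa}
    return hepta + link + finger, anchors


def _group_template(group: str) -> tuple[str, set[int], tuple[int, ...]]:
    """(template, anchor offsets, heptapeptide offsets) for a group label."""
    if group in _SUBGROUP_FINGERS:
        sig = _filler(f"{group}:sig", 10)
        dom, anchors = _domain(group, "WRKYGQK", *_SUBGROUP_FINGERS[group])
        return sig + dom, {10 + a for a in anchors}, (10,)
    if group == "I":
        sig = _filler("I:sig", 10)
        d1, a1 = _domain("I:d1", "WRKYGQK", 4, 22, 1, "H")
        mid = _filler("I:mid", 10)
        d2, a2 = _domain("I:d2", "WKKYGKK", 4, 23, 1, "H")
        template = sig + d1 + mid + d2
        off2 = 10 + len(d1) + 10
        anchors = {10 + a for a in a1} | {off2 + a for a in a2}
        return template, anchors, (10, off2)
    if group == "IV":
        sig = _filler("IV:sig", 10)
        return sig + "WRKYGQK", set(range(10, 17)), (10,)
    raise ValueError(f"unknown group label {group!r}")


_EXPECTED_MAJOR = {**{sg: "II" for sg in SUBGROUPS}, "I": "I", "III": "III",
                   "IV": "IV"}


def generate_wrky_protein(
    group: str,
    length: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noise: float = 0.0,
) -> tuple[str, dict]:
    """Random-background protein with a planted group-specific domain template.

    ``noise`` substitutes non-anchor positions (background and template
    filler, never the heptapeptide or finger-coordinating residues) at the
    given per-site rate.  The result is rejection-sampled until the domain
    scanner recovers exactly the planted heptapeptides and the requested
    group, so planted truth is guaranteed by construction.

    Returns ``(sequence, truth)`` with the template span and anchors.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    template, anchors, hepta_offsets = _group_template(group)
    if length is None:
        length = len(template) + 100
    if length < len(template) + 20:
        raise ValueError(
            f"length {length} too short for group {group} "
            f"(template {len(template)} aa)"
        )
    expected = _EXPECTED_MAJOR[group]
    for _ in range(300):
        left = int(rng.integers(10, length - len(template) - 9))
        seq = list(
            _random_aa(rng, left) + template
            + _random_aa(rng, length - len(template) - left)
        )
        abs_anchors = {left + a for a in anchors}
        if noise > 0:
            for i in np.flatnonzero(rng.random(length) < noise):
                if int(i) in abs_anchors:
                    continue
                alternatives = _AA20.replace(seq[int(i)], "")
                seq[int(i)] = alternatives[int(rng.integers(len(alternatives)))]
        cand = "".join(seq)
        hits = scan_heptapeptide(cand)
        if [h.start for h in hits] != [left + o for o in hepta_offsets]:
            continue
        if assign_group(assemble_domains(cand)) != expected:
            continue
        return cand, {
            "group": group,
            "template_start": left,
            "template_end": left + len(template),
            "anchors": tuple(sorted(abs_anchors)),
        }
    raise RuntimeError(f"could not generate a clean group-{group} protein")


def generate_decoy(
    length: int, rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> str:
    """Background protein guaranteed free of heptapeptide matches."""
    rng = np.random.default_rng(seed) if rng is None else rng
    for _ in range(300):
        seq = _random_aa(rng, length)
        if not scan_heptapeptide(seq):
            return seq
    raise RuntimeError("could not generate a clean decoy")


def generate_proteome(
    composition: Mapping[str, int],
    n_decoys: int = 0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noise: float = 0.0,
    length_range: tuple[int, int] = (160, 260),
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """A proteome with a planted group composition plus decoys.

    Returns the records and a truth table (protein_id, group), decoys
    labelled ``none``.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    records, rows = [], []
    idx = 0
    for group in sorted(composition):
        template, _, _ = _group_template(group)
        for _ in range(composition[group]):
            idx += 1
            length = max(int(rng.integers(*length_range)), len(template) + 100)
            seq, _truth = generate_wrky_protein(group, length, rng=rng,
                                                noise=noise)
            records.append(SeqRecord(f"W{idx:04d}", seq, f"group={group}"))
            rows.append({"protein_id": f"W{idx:04d}", "group": group})
    for d in range(n_decoys):
        length = int(rng.integers(*length_range))
        records.append(SeqRecord(f"D{d + 1:04d}", generate_decoy(length, rng)))
        rows.append({"protein_id": f"D{d + 1:04d}", "group": "none"})
    return records, pd.DataFrame(rows, columns=["protein_id", "group"])


_REFSET_CACHE: dict[tuple[int, int], ReferenceSet] = {}


def generate_reference_set(per_subgroup: int = 3, seed: int = 0) -> ReferenceSet:
    """Labelled subgroup exemplars (domain regions) for classification."""
    key = (per_subgroup, seed)
    if key not in _REFSET_CACHE:
        rng = np.random.default_rng(seed)
        refs = []
        for label in SUBGROUPS:
            for k in range(per_subgroup):
                seq, _ = generate_wrky_protein(label, rng=rng)
                dom = [d for d in assemble_domains(seq) if d.complete][0]
                refs.append(
                    Reference(label, f"REF_{label}_{k + 1}",
                              domain_region(seq, dom))
                )
        _REFSET_CACHE[key] = ReferenceSet(refs)
    return _REFSET_CACHE[key]


# ---------------------------------------------------------------------------
# CDS generation and controlled divergence
# ---------------------------------------------------------------------------

def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous codon choice per residue (no stop appended)."""
    codons = []
    for aa in protein:
        options = _CODONS_FOR_AA[aa]
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random stop-free CDS of ``n_codons`` codons."""
    idx = rng.integers(len(_NONSTOP_CODONS), size=n_codons)
    return "".join(_NONSTOP_CODONS[int(i)] for i in idx)


def _inv_jc(d: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def mutate_cds(
    cds: str,
    target_ks: float,
    target_ka: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    protected_codons: frozenset[int] | set[int] = frozenset(),
) -> str:
    """Diverge a CDS to target Nei–Gojobori Ks and Ka values.

    Point substitutions are applied by rejection sampling — synonymous and
    nonsynonymous channels separately — until the measured NG86
    proportions reach the inverse-Jukes–Cantor-corrected targets.  A step
    that would overshoot is accepted with probability proportional to the
    remaining deficit (stochastic rounding), so recovered estimates are
    unbiased around the target.  Stops are never created; nonsynonymous
    changes are refused inside ``protected_codons``; ``target_ka = 0``
    leaves the translation untouched.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if target_ks < 0 or target_ka < 0:
        raise ValueError("targets must be non-negative")
    body = cds
    tail = ""
    if len(body) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    if body[-3:] in _STOPS:
        body, tail = body[:-3], body[-3:]
    orig = [body[i : i + 3] for i in range(0, len(body), 3)]
    if any(c in _STOPS for c in orig):
        raise ValueError("CDS has an internal stop codon")
    n = len(orig)
    cur = list(orig)
    s_cur = [_syn_sites(c) for c in cur]
    sd = [0.0] * n
    nd = [0.0] * n
    s_orig_half = sum(s_cur) / 2.0  # orig == cur at start

    def totals():
        S = s_orig_half + sum(s_cur) / 2.0
        return S, 3.0 * n - S, sum(sd), sum(nd)

    targets = (("nonsyn", _inv_jc(target_ka)), ("syn", _inv_jc(target_ks)))
    bases = "ACGT"
    for kind, target_p in targets:
        if target_p <= 0:
            continue
        for _ in range(100000):
            S, N, Sd, Nd = totals()
            cur_p = (Sd / S) if kind == "syn" else (Nd / N)
            if cur_p >= target_p:
                break
            # draw one candidate substitution of the requested kind
            cand = None
            for _ in range(500):
                i = int(rng.integers(n))
                if kind == "nonsyn" and i in protected_codons:
                    continue
                pos = int(rng.integers(3))
                base = bases[int(rng.integers(4))]
                if base == cur[i][pos]:
                    continue
                new = cur[i][:pos] + base + cur[i][pos + 1 :]
                if new in _STOPS:
                    continue
                same_aa = _aa(new) == _aa(cur[i])
                if (kind == "syn") != same_aa:
                    continue
                # keep the channels decoupled: a step must not disturb the
                # other channel's pathway-averaged difference count
                nsd, nnd = _pair_differences(orig[i], new)
                if kind == "syn" and abs(nnd - nd[i]) > 1e-12:
                    continue
                if kind == "nonsyn" and abs(nsd - sd[i]) > 1e-12:
                    continue
                cand = (i, new)
                break
            if cand is None:
                break
            i, new = cand
            old = (cur[i], s_cur[i], sd[i], nd[i])
            cur[i] = new
            s_cur[i] = _syn_sites(new)
            sd[i], nd[i] = _pair_differences(orig[i], new)
            S, N, Sd, Nd = totals()
            new_p = (Sd / S) if kind == "syn" else (Nd / N)
            if new_p > target_p:
                accept = (target_p - cur_p) / (new_p - cur_p)
                if rng.random() >= accept:
                    cur[i], s_cur[i], sd[i], nd[i] = old
                break
    return "".join(cur) + tail


# ---------------------------------------------------------------------------
# Genomes with planted duplications
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    models: list[GeneModel]
    cds: dict[str, str]
    truth: dict

    def truth_pairs(self) -> list[HomologPair]:
        out = []
        for p in self.truth["pairs"]:
            a, b = sorted((p["id_a"], p["id_b"]))
            out.append(HomologPair(a, b, 1.0, len(self.cds[a]) // 3))
        return out

    def models_by_id(self) -> dict[str, GeneModel]:
        return {m.gene_id: m for m in self.models}


def _gene_segment(
    cds: str, strand: str, rng: np.random.Generator,
    max_exons: int = 3, intron_range: tuple[int, int] = (60, 150),
) -> tuple[str, list[tuple[int, int]]]:
    """Genomic gene segment and 0-based half-open exon offsets within it."""
    n_ex = int(rng.integers(1, max_exons + 1))
    # split CDS into n_ex chunks of >= 30 nt (codon-boundary cuts not needed
    # for the exon/intron bookkeeping exercised here)
    if len(cds) < 30 * n_ex:
        n_ex = max(1, len(cds) // 30)
    cuts = sorted(rng.choice(
        np.arange(30, len(cds) - 29), size=n_ex - 1, replace=False
    )) if n_ex > 1 else []
    chunks = [cds[a:b] for a, b in zip([0, *cuts], [*cuts, len(cds)])]
    pieces, exons, pos = [], [], 0
    for k, chunk in enumerate(chunks):
        if k:
            intron_len = int(rng.integers(*intron_range))
            intron = "".join(rng.choice(list("ACGT"), size=intron_len))
            pieces.append(intron)
            pos += intron_len
        pieces.append(chunk)
        exons.append((pos, pos + len(chunk)))
        pos += len(chunk)
    construct = "".join(pieces)
    if strand == "-":
        construct = reverse_complement(construct)
        L = len(construct)
        exons = [(L - e, L - s) for s, e in exons][::-1]
    return construct, exons


def generate_genome(
    n_chromosomes: int = 2,
    genes_per_chr: int = 20,
    n_tandem_pairs: int = 1,
    segmental_blocks: Sequence[tuple[int, int, int, bool]] = ((0, 1, 5, False),),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    dup_ks: float = 0.2,
    dup_ka: float = 0.05,
    codon_range: tuple[int, int] = (100, 200),
    intergenic_range: tuple[int, int] = (300, 700),
) -> SyntheticGenome:
    """Random genome with planted tandem pairs and collinear blocks.

    ``segmental_blocks`` entries are ``(chrom_a_index, chrom_b_index,
    size, inverted)``.  Planted features are spaced so that distinct
    plants can never chain into one another (tandem pairs sit more than
    the default rank-gap window apart).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    slots: dict[str, list[dict]] = {
        c: [{"cds": None, "partner": None} for _ in range(genes_per_chr)]
        for c in chroms
    }
    used: dict[str, set[int]] = {c: set() for c in chroms}
    pairs_truth: list[dict] = []

    def claim_run(chrom: str, size: int, spacing: int) -> list[int]:
        free = [i for i in range(genes_per_chr) if i not in used[chrom]]
        for start in free:
            run = list(range(start, start + size))
            if run[-1] >= genes_per_chr or any(i in used[chrom] for i in run):
                continue
            near = any(abs(i - u) <= spacing for i in run for u in used[chrom])
            if near:
                continue
            used[chrom].update(run)
            return run
        raise ValueError(f"no room on {chrom} for a run of {size}")

    # tandem plants: adjacent slots, far from any other plant
    for t in range(n_tandem_pairs):
        chrom = chroms[t % n_chromosomes]
        i, j = claim_run(chrom, 2, spacing=12)
        slots[chrom][j]["partner"] = (chrom, i, "tandem", None, False)

    block_specs = []
    for b, (ia, ib, size, inverted) in enumerate(segmental_blocks):
        ca, cb = chroms[ia], chroms[ib]
        run_a = claim_run(ca, size, spacing=12)
        run_b = claim_run(cb, size, spacing=12)
        matched = list(zip(run_a, run_b[::-1] if inverted else run_b))
        for sa, sb in matched:
            slots[cb][sb]["partner"] = (ca, sa, "segmental", f"B{b + 1}",
                                        inverted)
        block_specs.append({"block": f"B{b + 1}", "chrom_a": ca, "chrom_b": cb,
                            "size": size, "inverted": inverted})

    # assign CDS: originals first, then mutated copies
    for chrom in chroms:
        for slot in slots[chrom]:
            if slot["partner"] is None:
                slot["cds"] = random_cds(int(rng.integers(*codon_range)), rng)
    for chrom in chroms:
        for idx, slot in enumerate(slots[chrom]):
            if slot["partner"] is not None:
                ca, sa, dup_type, block, inverted = slot["partner"]
                src = slots[ca][sa]["cds"]
                slot["cds"] = mutate_cds(src, dup_ks, dup_ka, rng=rng)
                pairs_truth.append(
                    {
                        "id_a": f"{ca}g{sa + 1:03d}",
                        "id_b": f"{chrom}g{idx + 1:03d}",
                        "dup_type": dup_type,
                        "block_id": block,
                        "inverted": inverted,
                        "target_ks": dup_ks,
                        "target_ka": dup_ka,
                    }
                )

    chromosomes: dict[str, str] = {}
    models: list[GeneModel] = []
    cds_map: dict[str, str] = {}
    for chrom in chroms:
        parts: list[str] = []
        pos = 0
        for idx, slot in enumerate(slots[chrom]):
            gap = int(rng.integers(*intergenic_range))
            parts.append("".join(rng.choice(list("ACGT"), size=gap)))
            pos += gap
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"{chrom}g{idx + 1:03d}"
            segment, exon_offsets = _gene_segment(slot["cds"], strand, rng)
            exons = tuple(
                (pos + s + 1, pos + e) for s, e in exon_offsets
            )
            models.append(GeneModel(gene_id, chrom, strand, exons))
            cds_map[gene_id] = slot["cds"]
            parts.append(segment)
            pos += len(segment)
        chromosomes[chrom] = "".join(parts)
    models = assign_ranks(models)
    truth = {
        "pairs": pairs_truth,
        "blocks": block_specs,
        "n_tandem_pairs": n_tandem_pairs,
        "n_segmental_pairs": sum(b["size"] for b in block_specs),
    }
    return SyntheticGenome(chromosomes, models, cds_map, truth)


# ---------------------------------------------------------------------------
# Promoters, counts, Ct tables
# ---------------------------------------------------------------------------

def _realize(pattern: CREPattern, rng: np.random.Generator) -> str:
    from .regulation_expression import _IUPAC

    return "".join(
        _IUPAC[c][int(rng.integers(len(_IUPAC[c])))] for c in pattern.iupac
    )


def generate_promoters(
    n: int,
    catalog: Sequence[CREPattern],
    plant_spec: Mapping[int, Sequence[tuple[str, int, str]]],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    length: int = 2000,
) -> tuple[list[SeqRecord], list[MotifHit]]:
    """Promoters with planted elements and scrubbed backgrounds.

    ``plant_spec`` maps promoter index (0-based) to ``(pattern_name,
    position, strand)`` plants.  Background occurrences of catalog
    patterns that do not overlap a planted interval are mutated away, so
    with a non-nested catalog the scanner reports exactly the plants.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    by_name = {p.name: p for p in catalog}
    records, truth = [], []
    for pi in range(n):
        pid = f"P{pi + 1:04d}"
        seq = list("".join(rng.choice(list("ACGT"), size=length)))
        keep: list[tuple[int, int]] = []
        for name, start, strand in plant_spec.get(pi, ()):  # plant
            pat = by_name[name]
            real = _realize(pat, rng)
            planted = real if strand == "+" else reverse_complement(real)
            seq[start : start + len(planted)] = list(planted)
            keep.append((start, start + len(planted)))
            truth.append(MotifHit(pid, name, start, strand, real))
        for _ in range(200):  # scrub accidental background hits
            hits = scan_cre("".join(seq), catalog, pid)
            offending = [
                h for h in hits
                if not any(s <= h.start and h.start + len(h.matched) <= e
                           for s, e in keep)
            ]
            if not offending:
                break
            for h in offending:
                span = [
                    i for i in range(h.start, h.start + len(h.matched))
                    if not any(s <= i < e for s, e in keep)
                ]
                if not span:
                    continue
                i = span[int(rng.integers(len(span)))]
                seq[i] = "ACGT".replace(seq[i], "")[int(rng.integers(3))]
        records.append(SeqRecord(pid, "".join(seq), "synthetic promoter"))
    return records, truth


def generate_counts(
    genes: Sequence[str],
    samples: Sequence[str],
    fold_spec: Mapping[tuple[str, str], float],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    lengths: Mapping[str, int] | None = None,
    base_depth: float = 2e6,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Read-count matrix with gene-specific rates scaled by planted folds.

    ``fold_spec`` maps (gene, sample) to a fold multiplier of the gene's
    baseline expression (default 1).  Returns (counts, lengths, truth).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if lengths is None:
        lengths = {g: int(rng.integers(600, 3000)) for g in genes}
    L = pd.Series(lengths).reindex(genes)
    base = pd.Series(
        np.exp(rng.normal(3.0, 1.0, size=len(genes))), index=genes
    )  # baseline expression level per gene (arbitrary units)
    counts = pd.DataFrame(index=list(genes), columns=list(samples), dtype=float)
    for s in samples:
        folds = np.array([fold_spec.get((g, s), 1.0) for g in genes])
        lam = base.values * folds * (L.values / 1000.0) * (base_depth / 1e6) / 50.0
        counts[s] = rng.poisson(lam)
    truth = {"fold_spec": {f"{g}|{s}": v for (g, s), v in fold_spec.items()}}
    return counts.astype(int), L, truth


def generate_ct_table(
    genes: Sequence[str],
    conditions: Sequence[str],
    fold_spec: Mapping[tuple[str, str, str], float],
    sd: float = 0.1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    reference_gene: str = "Act2",
    timepoints: Sequence[str] = ("0h", "1h", "24h"),
    n_replicates: int = 3,
    baseline_ct: float = 24.0,
    reference_ct: float = 18.0,
) -> tuple[pd.DataFrame, dict]:
    """Long-format qRT-PCR Ct table encoding known fold changes.

    Target Ct = baseline - log2(fold) + N(0, sd); the reference gene is
    flat.  ``fold_spec`` maps (gene, condition, timepoint) to the true
    fold change versus the control timepoint (default 1).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    rows = []
    for cond in conditions:
        for tp in timepoints:
            for gene in list(genes) + [reference_gene]:
                if gene == reference_gene:
                    mean_ct = reference_ct
                else:
                    fold = fold_spec.get((gene, cond, tp), 1.0)
                    mean_ct = baseline_ct - math.log2(fold)
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "gene": gene,
                            "condition": cond,
                            "timepoint": tp,
                            "replicate": rep,
                            "ct": round(float(mean_ct + rng.normal(0, sd)), 4),
                        }
                    )
    truth = {
        "fold_spec": {f"{g}|{c}|{t}": v for (g, c, t), v in fold_spec.items()},
        "sd": sd,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# The full survey-shaped dataset
# ---------------------------------------------------------------------------

#: Family composition of the survey-shaped preset (105 proteins).
PAPER_SHAPED_COMPOSITION = {
    "I": 10, "IIa": 5, "IIb": 8, "IIc": 20, "IId": 9, "IIe": 12,
    "III": 39, "IV": 2,
}

# tandem pairs: (chromosome, group); one group-I pair, two group-II pairs,
# seven group-III pairs
_TANDEM_PLAN = (
    ("chr3", "I"), ("chr4", "IIc"), ("chr9", "IIc"),
    ("chr1", "III"), ("chr1", "III"), ("chr5", "III"), ("chr5", "III"),
    ("chr7", "III"), ("chr7", "III"), ("chr8", "III"),
)
# collinear blocks between chr3 and chr5 (5 + 3 = 8 segmental pairs)
_SEGMENTAL_PLAN = (
    ("chr3", "chr5", ("IIc", "IIc", "IIc", "III", "III"), False),
    ("chr3", "chr5", ("IIe", "IIb", "III"), True),
)
_WRKY_PER_CHROM = {
    "chr1": 11, "chr2": 11, "chr3": 19, "chr4": 5, "chr5": 22,
    "chr6": 5, "chr7": 11, "chr8": 11, "chr9": 10,
}
# divergence targets: Ka/Ks ~0.13 at ~29 Mya (tandem), ~0.1 at ~23 Mya
# (segmental) under the default clock rate
TANDEM_KS, TANDEM_KA = 0.377, 0.049
SEGMENTAL_KS, SEGMENTAL_KA = 0.299, 0.030

_QPCR_CONDITIONS = ("dehydration", "salinity", "ABA", "SA", "MeJA")


@dataclass
class SyntheticDataset:
    """A complete survey input bundle plus its planted truth."""

    proteins: list[SeqRecord]
    genome: dict[str, str]
    models: list[GeneModel]
    cds: dict[str, str]
    counts: pd.DataFrame
    lengths: pd.Series
    ct: pd.DataFrame
    truth: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.fa")
        write_fasta(
            [SeqRecord(g, s) for g, s in sorted(self.genome.items())],
            outdir / "genome.fa",
        )
        write_fasta(
            [SeqRecord(g, self.cds[g]) for g in sorted(self.cds)],
            outdir / "cds.fa",
        )
        write_gff(self.models, outdir / "genes.gff3")
        self.counts.to_csv(outdir / "counts.tsv", sep="\t",
                           index_label="gene")
        self.ct.to_csv(outdir / "ct.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _mutated_partner(
    protein_a: str,
    truth_a: dict,
    cds_a: str,
    group: str,
    ks: float,
    ka: float,
    refs: ReferenceSet,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Diverged copy of a WRKY gene whose protein still classifies as planted."""
    protected = frozenset(truth_a["anchors"])
    expected = _EXPECTED_MAJOR[group]
    for _ in range(60):
        cds_b = mutate_cds(cds_a, ks, ka, rng=rng, protected_codons=protected)
        prot_b = str(Seq(cds_b[:-3]).translate())
        hits = scan_heptapeptide(prot_b)
        if [h.start for h in hits] != [h.start for h in
                                       scan_heptapeptide(protein_a)]:
            continue
        domains = assemble_domains(prot_b)
        if assign_group(domains) != expected:
            continue
        if expected == "II":
            dom = [d for d in domains if d.complete][0]
            if assign_subgroup(domain_region(prot_b, dom), refs) != group:
                continue
        return prot_b, cds_b
    raise RuntimeError(f"could not derive a clean {group} duplicate")


def paper_shaped(seed: int = 0) -> SyntheticDataset:
    """Survey-shaped dataset: 105 family proteins (I:10, II:54, III:39,
    IV:2) on 9 chromosomes with 10 tandem and 8 segmental duplicate pairs,
    promoters with planted elements, and count/Ct tables with known folds.
    """
    rng = np.random.default_rng(seed)
    refs = generate_reference_set()
    chroms = sorted(_WRKY_PER_CHROM)

    # ----- per-chromosome unit layout -------------------------------------
    # a unit is a list of entries; entry = {"kind": "wrky"/"filler", ...}
    singles_pool: list[str] = []
    used = {g: 0 for g in PAPER_SHAPED_COMPOSITION}
    for _, g in _TANDEM_PLAN:
        used[g] += 2
    for _, _, groups, _ in _SEGMENTAL_PLAN:
        for g in groups:
            used[g] += 2
    for g in sorted(PAPER_SHAPED_COMPOSITION):
        singles_pool += [g] * (PAPER_SHAPED_COMPOSITION[g] - used[g])

    n_singles_per_chrom = dict(_WRKY_PER_CHROM)
    for c, _ in _TANDEM_PLAN:
        n_singles_per_chrom[c] -= 2
    for ca, cb, groups, _ in _SEGMENTAL_PLAN:
        n_singles_per_chrom[ca] -= len(groups)
        n_singles_per_chrom[cb] -= len(groups)

    # group IV singles sit on chr5; group I singles avoid chr1 and chr4
    singles_by_chrom: dict[str, list[str]] = {c: [] for c in chroms}
    pool = [g for g in singles_pool if g != "IV"]
    singles_by_chrom["chr5"] += ["IV"] * singles_pool.count("IV")
    cap = {
        c: n_singles_per_chrom[c] - len(singles_by_chrom[c]) for c in chroms
    }
    i_allowed = [c for c in chroms if c not in ("chr1", "chr4")]
    k = 0
    for g in [g for g in pool if g == "I"]:
        while cap[i_allowed[k % len(i_allowed)]] <= 0:
            k += 1
        singles_by_chrom[i_allowed[k % len(i_allowed)]].append(g)
        cap[i_allowed[k % len(i_allowed)]] -= 1
        k += 1
    rest = [g for g in pool if g != "I"]
    rng.shuffle(rest)
    for c in chroms:
        while cap[c] > 0:
            singles_by_chrom[c].append(rest.pop())
            cap[c] -= 1
    assert not rest

    pair_specs: list[dict] = []  # {"group","type","block","ks","ka","slots"}

    def wrky_entry(group, pair=None, side=None):
        return {"kind": "wrky", "group": group, "pair": pair, "side": side}

    layout: dict[str, list[dict]] = {c: [] for c in chroms}

    def add_fillers(c, n):
        layout[c] += [{"kind": "filler"}] * n

    # segmental runs first/last on their chromosomes, singles + tandem in
    # between, so the two runs are always > 10 ranks apart on both sides
    seg_units: dict[str, list[list[dict]]] = {c: [] for c in chroms}
    for b, (ca, cb, groups, inverted) in enumerate(_SEGMENTAL_PLAN):
        pid = len(pair_specs)
        for g in groups:
            pair_specs.append(
                {"group": g, "type": "segmental", "block": f"B{b + 1}",
                 "ks": SEGMENTAL_KS, "ka": SEGMENTAL_KA, "inverted": inverted}
            )
        run_a = [wrky_entry(g, pid + i, "a") for i, g in enumerate(groups)]
        order_b = list(range(len(groups)))[::-1] if inverted else \
            list(range(len(groups)))
        run_b = [wrky_entry(groups[i], pid + i, "b") for i in order_b]
        seg_units[ca].append(run_a)
        seg_units[cb].append(run_b)

    tandem_by_chrom: dict[str, list[dict]] = {c: [] for c in chroms}
    for c, g in _TANDEM_PLAN:
        pid = len(pair_specs)
        pair_specs.append(
            {"group": g, "type": "tandem", "block": None,
             "ks": TANDEM_KS, "ka": TANDEM_KA, "inverted": False}
        )
        tandem_by_chrom[c].append({"pid": pid, "group": g})

    for c in chroms:
        runs = seg_units[c]
        if runs:  # leading run, with 0-1 fillers between members
            for i, e in enumerate(runs[0]):
                if i:
                    add_fillers(c, int(rng.integers(0, 2)))
                layout[c].append(e)
            add_fillers(c, 1)
        middle: list[list[dict]] = []
        for t in tandem_by_chrom[c]:
            middle.append([wrky_entry(t["group"], t["pid"], "a"),
                           wrky_entry(t["group"], t["pid"], "b")])
        for g in singles_by_chrom[c]:
            middle.append([wrky_entry(g)])
        order = rng.permutation(len(middle))
        for ui in order:
            layout[c] += middle[int(ui)]
            add_fillers(c, int(rng.integers(1, 3)))
        if len(runs) > 1:
            for i, e in enumerate(runs[1]):
                if i:
                    add_fillers(c, int(rng.integers(0, 2)))
                layout[c].append(e)
            add_fillers(c, 1)

    # ----- instantiate sequences -----------------------------------------
    pair_members: dict[int, dict[str, dict]] = {}
    wrky_counter = 0
    proteins: list[SeqRecord] = []
    models: list[GeneModel] = []
    cds_map: dict[str, str] = {}
    genome: dict[str, str] = {}
    groups_truth: dict[str, str] = {}
    cre_truth: list[dict] = []
    from .regulation_expression import default_catalog

    catalog = default_catalog()
    plantable = [p for p in catalog
                 if p.name in ("WBOXNT", "ABRELATERD1", "HSE", "GATABOX")]

    # pass 1: generate proteins/CDS for side-a members and singles
    entry_payload: dict[int, dict] = {}  # id(entry) -> payload
    for c in chroms:
        for e in layout[c]:
            if e["kind"] != "wrky":
                continue
            if e["pair"] is not None and e["side"] == "b":
                continue
            seq, tr = generate_wrky_protein(e["group"], rng=rng)
            cds = reverse_translate(seq, rng) + "TAA"
            entry_payload[id(e)] = {"protein": seq, "truth": tr, "cds": cds}
            if e["pair"] is not None:
                pair_members[e["pair"]] = {"a": entry_payload[id(e)]}
    # pass 2: derive side-b partners
    for c in chroms:
        for e in layout[c]:
            if e["kind"] != "wrky" or e["pair"] is None or e["side"] != "b":
                continue
            spec = pair_specs[e["pair"]]
            a = pair_members[e["pair"]]["a"]
            anchors_codons = {
                p for p in a["truth"]["anchors"]
            }
            prot_b, cds_b = _mutated_partner(
                a["protein"],
                {"anchors": anchors_codons},
                a["cds"],
                spec["group"],
                spec["ks"],
                spec["ka"],
                refs,
                rng,
            )
            entry_payload[id(e)] = {"protein": prot_b, "cds": cds_b}
            pair_members[e["pair"]]["b"] = entry_payload[id(e)]

    pair_ids: dict[int, dict[str, str]] = {i: {} for i in range(len(pair_specs))}
    filler_counter = 0
    for c in chroms:
        parts: list[str] = []
        pos = 0
        gene_sites = []  # (gene_id, strand, segment, exon_offsets, payload?)
        for e in layout[c]:
            gap = int(rng.integers(4300, 4700))
            parts.append("".join(rng.choice(list("ACGT"), size=gap)))
            pos += gap
            strand = "+" if rng.random() < 0.5 else "-"
            if e["kind"] == "wrky":
                wrky_counter += 1
                gene_id = f"W{wrky_counter:03d}"
                payload = entry_payload[id(e)]
                cds = payload["cds"]
                proteins.append(
                    SeqRecord(gene_id, payload["protein"],
                              f"group={e['group']}")
                )
                groups_truth[gene_id] = e["group"]
                cds_map[gene_id] = cds
                if e["pair"] is not None:
                    pair_ids[e["pair"]][e["side"]] = gene_id
            else:
                filler_counter += 1
                gene_id = f"F{filler_counter:03d}"
                cds = random_cds(int(rng.integers(100, 200)), rng) 
            segment, exon_offsets = _gene_segment(cds, strand, rng,
                                                  max_exons=4,
                                                  intron_range=(80, 200))
            exons = tuple((pos + s + 1, pos + e2) for s, e2 in exon_offsets)
            models.append(GeneModel(gene_id, c, strand, exons))
            parts.append(segment)
            pos += len(segment)
        parts.append("".join(rng.choice(list("ACGT"), size=2600)))
        genome[c] = "".join(parts)
    models = assign_ranks(models)

    # ----- plant promoter elements ---------------------------------------
    by_id = {m.gene_id: m for m in models}
    for gene_id in sorted(groups_truth):
        m = by_id[gene_id]
        chrom_seq = list(genome[m.chromosome])
        window = extract_upstream(genome, m, 2000)
        picks = rng.choice(len(plantable), size=int(rng.integers(2, 4)),
                           replace=False)
        taken: list[tuple[int, int]] = []
        wlist = list(window)
        for pi in picks:
            pat = plantable[int(pi)]
            for _ in range(50):
                start = int(rng.integers(0, 2000 - len(pat.iupac)))
                if all(start + len(pat.iupac) <= s or start >= e2
                       for s, e2 in taken):
                    break
            else:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            real = _realize(pat, rng)
            planted = real if strand == "+" else reverse_complement(real)
            wlist[start : start + len(planted)] = list(planted)
            taken.append((start, start + len(planted)))
            cre_truth.append(
                {"gene": gene_id, "pattern": pat.name, "start": start,
                 "strand": strand, "matched": real}
            )
        new_window = "".join(wlist)
        if m.strand == "+":
            lo = m.start - 1 - len(new_window)
            chrom_seq[lo : m.start - 1] = list(new_window)
        else:
            chrom_seq[m.end : m.end + len(new_window)] = list(
                reverse_complement(new_window)
            )
        genome[m.chromosome] = "".join(chrom_seq)

    # ----- expression tables ----------------------------------------------
    wrky_ids = sorted(groups_truth)
    samples = ("root", "leaf", "spica", "stem", "dehydration", "control")
    up_genes = list(rng.choice(wrky_ids, size=4, replace=False))
    count_folds = {(g, "dehydration"): 4.0 for g in up_genes}
    counts, lengths, counts_truth = generate_counts(
        wrky_ids, samples, count_folds, rng=rng,
        lengths={g: len(cds_map[g]) for g in wrky_ids},
    )
    candidates = sorted(rng.choice(wrky_ids, size=12, replace=False))
    qpcr_folds: dict[tuple[str, str, str], float] = {}
    for g in candidates[:2]:
        for cond in ("dehydration", "salinity"):
            qpcr_folds[(g, cond, "1h")] = 4.0
            qpcr_folds[(g, cond, "24h")] = 8.0
    ct, ct_truth = generate_ct_table(
        candidates, _QPCR_CONDITIONS, qpcr_folds, sd=0.1, rng=rng
    )

    wrky_per_chrom = {c: 0 for c in chroms}
    for gid, m in by_id.items():
        if gid in groups_truth:
            wrky_per_chrom[m.chromosome] += 1

    truth = {
        "seed": seed,
        "composition": PAPER_SHAPED_COMPOSITION,
        "groups": groups_truth,
        "wrky_per_chromosome": wrky_per_chrom,
        "pairs": [
            {
                "id_a": min(pair_ids[i].values()),
                "id_b": max(pair_ids[i].values()),
                "dup_type": pair_specs[i]["type"],
                "block_id": pair_specs[i]["block"],
                "inverted": pair_specs[i]["inverted"],
                "group": pair_specs[i]["group"],
                "target_ks": pair_specs[i]["ks"],
                "target_ka": pair_specs[i]["ka"],
            }
            for i in range(len(pair_specs))
        ],
        "n_tandem_pairs": sum(1 for p in pair_specs if p["type"] == "tandem"),
        "n_segmental_pairs": sum(
            1 for p in pair_specs if p["type"] == "segmental"
        ),
        "n_segmental_blocks": len(_SEGMENTAL_PLAN),
        "cres": cre_truth,
        "count_folds": counts_truth["fold_spec"],
        "qpcr_folds": ct_truth["fold_spec"],
        "qpcr_candidates": list(candidates),
    }
    return SyntheticDataset(
        proteins=proteins,
        genome=genome,
        models=models,
        cds=cds_map,
        counts=counts,
        lengths=lengths,
        ct=ct,
        truth=truth,
    )
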