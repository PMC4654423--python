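"""Sequence and annotation I/O plus sequence preparation.

FASTA reading/writing is delegated to Biopython; records are validated
against a declared alphabet and re-exposed through a lightweight
:class:`SeqRecord` container.  GFF3 gene models keep the native 1-based
inclusive coordinate convention end to end, so every operation below and
every file on disk speak the same coordinates.

The module also carries the transcriptome-preparation steps of the survey:
greedy length-sorted clustering of redundant transcripts and longest-ORF
prediction over all six frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq

from .align import identity_over_shorter

logger = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NT_ALPHABET = frozenset("ACGTN")

__all__ = [
    "SeqRecord",
    "GeneModel",
    "GeneStructure",
    "Cluster",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "gene_structure",
    "structure_table",
    "extract_upstream",
    "predict_orf",
    "cluster_transcripts",
    "reverse_complement",
]


@dataclass(frozen=True)
class SeqRecord:
    """One sequence with a unique id and a declared-alphabet residue string."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene: chromosome, strand and ordered 1-based inclusive exons.

    ``rank`` is the 1-based position of the gene along its chromosome after
    sorting genes by ascending start; it is what the duplication detectors
    reason about.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    rank: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        prev_end = 0
        for start, end in self.exons:
            if end < start:
                raise ValueError(
                    f"{self.gene_id}: exon ({start},{end}) has end < start"
                )
            if start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class GeneStructure:
    gene_id: str
    exon_count: int
    intron_count: int
    introns: tuple[tuple[int, int], ...]
    length_bp: int


class Cluster(NamedTuple):
    representative: SeqRecord
    members: tuple[str, ...]


def _validate_sequence(rec_id: str, seq: str, alphabet: str) -> None:
    allowed = AA_ALPHABET if alphabet == "protein" else NT_ALPHABET
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise ValueError(
                f"record {rec_id!r}: illegal {alphabet} character {ch!r} "
                f"at position {pos}"
            )


def read_fasta(path, alphabet: str = "protein") -> list[SeqRecord]:
    """Read a FASTA file, validating ids and the declared alphabet.

    ``alphabet`` is ``"protein"`` (20 canonical letters plus X) or
    ``"nucleotide"`` (ACGTN).  Wrapped lines are joined and sequences are
    uppercased.  Duplicate ids and illegal characters raise ``ValueError``.
    """
    if alphabet not in {"protein", "nucleotide"}:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        _validate_sequence(rec.id, seq, alphabet)
        desc = rec.description[len(rec.id):].strip()
        records.append(SeqRecord(rec.id, seq, desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns."""
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            handle.write(header + "\n")
            for i in range(0, len(rec.sequence), wrap):
                handle.write(rec.sequence[i : i + wrap] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff(path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GFF3 file.

    Exons are grouped under their parent gene, resolving one optional
    mRNA level in between.  Ranks are assigned per chromosome by ascending
    gene start.  An exon whose Parent chain does not reach a gene, or a
    feature with end < start, raises ``ValueError``.
    """
    genes: dict[str, dict] = {}
    parents: dict[str, str] = {}  # feature id -> Parent id (for mRNA level)
    exons: list[tuple[str, int, int]] = []  # (parent id, start, end)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = fields
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ValueError(
                    f"{path}:{lineno}: coordinate error, end {end} < start {start}"
                )
            attrs = _parse_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if not gid:
                    raise ValueError(f"{path}:{lineno}: gene feature without ID")
                genes[gid] = {"chromosome": chrom, "strand": strand, "exons": []}
            elif ftype == "mRNA":
                fid, parent = attrs.get("ID"), attrs.get("Parent")
                if fid and parent:
                    parents[fid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if not parent:
                    raise ValueError(f"{path}:{lineno}: exon without Parent")
                exons.append((parent, start, end))
    for parent, start, end in exons:
        gid = parents.get(parent, parent)
        gid = parents.get(gid, gid)
        if gid not in genes:
            raise ValueError(f"exon parent {parent!r} does not resolve to a gene")
        genes[gid]["exons"].append((start, end))
    models: list[GeneModel] = []
    for gid, info in genes.items():
        if not info["exons"]:
            raise ValueError(f"gene {gid!r} has no exons")
        models.append(
            GeneModel(
                gene_id=gid,
                chromosome=info["chromosome"],
                strand=info["strand"],
                exons=tuple(sorted(info["exons"])),
            )
        )
    return assign_ranks(models)


def assign_ranks(models: Iterable[GeneModel]) -> list[GeneModel]:
    """Return models with per-chromosome ranks by ascending gene start."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    out: list[GeneModel] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda m: (m.start, m.gene_id))
        for rank, m in enumerate(ordered, start=1):
            out.append(
                GeneModel(m.gene_id, m.chromosome, m.strand, m.exons, rank)
            )
    return out


def write_gff(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chromosome, m.start, m.gene_id)):
            handle.write(
                f"{m.chromosome}\twrky\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, start=1):
                handle.write(
                    f"{m.chromosome}\twrky\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                )


def gene_structure(model: GeneModel) -> GeneStructure:
    """Derive introns (the gaps between consecutive exons) from a gene model."""
    introns = tuple(
        (prev_end + 1, next_start - 1)
        for (_, prev_end), (next_start, _) in zip(model.exons, model.exons[1:])
    )
    return GeneStructure(
        gene_id=model.gene_id,
        exon_count=len(model.exons),
        intron_count=len(introns),
        introns=introns,
        length_bp=model.end - model.start + 1,
    )


def structure_table(models: Iterable[GeneModel]):
    """Exon/intron structure summary as a DataFrame (one row per gene)."""
    import pandas as pd

    rows = []
    for m in models:
        s = gene_structure(m)
        rows.append(
            {
                "gene_id": s.gene_id,
                "chromosome": m.chromosome,
                "strand": m.strand,
                "start": m.start,
                "end": m.end,
                "length_bp": s.length_bp,
                "exon_count": s.exon_count,
                "intron_count": s.intron_count,
            }
        )
    return pd.DataFrame(rows)


def extract_upstream(
    genome: dict[str, str], model: GeneModel, length: int = 2000
) -> str:
    """Upstream (promoter-side) sequence of a gene, default 2 kb.

    Plus strand: the ``length`` bases ending just before the gene start.
    Minus strand: the reverse complement of the ``length`` bases starting
    just after the gene end.  Truncated (never padded) at chromosome
    boundaries.
    """
    if model.chromosome not in genome:
        raise KeyError(f"chromosome {model.chromosome!r} not in genome")
    chrom = genome[model.chromosome]
    if model.strand == "+":
        lo = max(0, model.start - 1 - length)
        return chrom[lo : model.start - 1]
    hi = min(len(chrom), model.end + length)
    return reverse_complement(chrom[model.end : hi])


# ---------------------------------------------------------------------------
# Transcriptome preparation
# ---------------------------------------------------------------------------

def predict_orf(transcript: SeqRecord, min_codons: int = 30) -> SeqRecord | None:
    """Longest ATG-initiated ORF over all six frames, translated.

    The stop codon is excluded from the peptide; ORFs may run off the end
    of the transcript.  Ties are broken by smaller frame index (0..2), then
    forward strand, then 5'-most start.  Returns ``None`` (with a log entry)
    when no ORF reaches ``min_codons``.
    """
    seq = transcript.sequence.upper()
    best: tuple[int, int, int, int, str] | None = None  # (-len, frame, strandord, start, pep)
    for strand_ord, strand_seq in enumerate((seq, reverse_complement(seq))):
        for frame in range(3):
            codons = [
                strand_seq[i : i + 3]
                for i in range(frame, len(strand_seq) - 2, 3)
            ]
            i = 0
            while i < len(codons):
                if codons[i] == "ATG":
                    j = i
                    while j < len(codons) and str(Seq(codons[j]).translate()) != "*":
                        j += 1
                    orf = "".join(codons[i:j])
                    pep = str(Seq(orf).translate())
                    key = (-len(pep), frame, strand_ord, i, pep)
                    if best is None or key < best:
                        best = key
                    i = j + 1
                else:
                    i += 1
    if best is None or -best[0] < min_codons:
        logger.info("predict_orf: %s skipped (no ORF >= %d codons)",
                    transcript.id, min_codons)
        return None
    return SeqRecord(transcript.id, best[4], "predicted ORF")


def cluster_transcripts(
    records: Iterable[SeqRecord],
    identity: float = 0.90,
    kind: str = "nucleotide",
) -> list[Cluster]:
    """Greedy length-sorted clustering (CD-HIT-like).

    Records are sorted by descending length (ties by id); each record joins
    the first cluster whose representative it matches at >= ``identity``
    over the shorter sequence (global alignment), else founds a new cluster.
    Representatives are the founders.
    """
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    clusters: list[tuple[SeqRecord, list[str]]] = []
    for rec in ordered:
        for rep, members in clusters:
            if identity_over_shorter(rec.sequence, rep.sequence, kind) >= identity:
                members.append(rec.id)
                break
        else:
            clusters.append((rec, [rec.id]))
    return [Cluster(rep, tuple(members)) for rep, members in clusters]
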