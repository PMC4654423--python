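"""End-to-end survey orchestration.

``run_survey`` sequences the stages — domain scan, family classification,
protein properties, phylogeny, duplication detection, Ka/Ks dating,
optional orthology, promoter scanning, expression summaries — over plain
FASTA/GFF/TSV inputs, writing one TSV per stage, a Newick tree and a JSON
summary.  Stage outputs are flat files so each stage is independently
re-runnable; reruns under the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import align_pair
from .domain_grammar import hit_table
from .evolution_dynamics import (
    DEFAULT_LAMBDA,
    codon_align,
    detect_segmental,
    detect_tandem,
    divergence_time,
    find_homolog_pairs,
    kaks_table,
    ng86_kaks,
    reciprocal_best_hits,
    segmental_pairs,
)
from .family_classifier import ReferenceSet, classify_proteome
from .io_formats import read_fasta, read_gff, extract_upstream, structure_table
from .phylogeny import kmer_distance, nj_tree, pairwise_distance, bootstrap_support
from .protein_properties import properties_table
from .regulation_expression import (
    default_catalog,
    hit_frame,
    load_catalog,
    log2_matrix,
    qpcr_fold_changes,
    rpkm,
    scan_cre,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_survey"]


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one survey run."""

    proteins: str
    outdir: str
    gff: str | None = None
    genome: str | None = None
    cds: str | None = None
    counts: str | None = None
    ct: str | None = None
    ortholog_proteins: str | None = None
    alignment: str | None = None
    reference_fasta: str | None = None
    cre_catalog: str | None = None
    seed: int = 0
    # thresholds, with the survey's published settings as defaults
    ortholog_min_identity: float = 0.90
    paralog_min_identity: float = 0.70
    upstream_length: int = 2000
    bootstrap: int = 1000
    lam: float = DEFAULT_LAMBDA
    min_block: int = 3
    max_intervening: int = 1
    max_rank_gap: int = 10
    reference_gene: str = "Act2"
    run_kaks: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.ortholog_min_identity <= 1:
            raise ValueError("ortholog_min_identity must lie in (0, 1]")
        if not 0 < self.paralog_min_identity <= 1:
            raise ValueError("paralog_min_identity must lie in (0, 1]")
        if self.upstream_length <= 0 or self.lam <= 0:
            raise ValueError("upstream_length and lambda must be positive")
        if self.bootstrap < 0 or self.min_block < 1:
            raise ValueError("invalid bootstrap or min_block")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate_inputs(self) -> None:
        """Fail fast on missing files, before any compute."""
        required = {"proteins": self.proteins}
        for name in ("gff", "genome", "cds", "counts", "ct",
                     "ortholog_proteins", "alignment", "reference_fasta",
                     "cre_catalog"):
            value = getattr(self, name)
            if value is not None:
                required[name] = value
        if self.run_kaks and self.gff is not None and self.cds is None:
            raise ValueError(
                "Ka/Ks dating requested (run_kaks) but no CDS file configured"
            )
        for name, path in required.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"configured {name} file not found: {path}")


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, **kw)


def run_survey(config: PipelineConfig) -> dict:
    """Run every configured stage; return (and write) the summary dict."""
    config.validate_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "ortholog_min_identity": config.ortholog_min_identity,
            "paralog_min_identity": config.paralog_min_identity,
            "upstream_length": config.upstream_length,
            "bootstrap": config.bootstrap,
            "lambda": config.lam,
            "min_block": config.min_block,
            "max_intervening": config.max_intervening,
            "max_rank_gap": config.max_rank_gap,
        },
    }

    # --- scan + classification -------------------------------------------
    proteins = read_fasta(config.proteins, "protein")
    summary["n_proteins"] = len(proteins)
    hits = hit_table(proteins)
    _write(hits, outdir / "domain_hits.tsv")
    if config.reference_fasta:
        refs = ReferenceSet.from_fasta(config.reference_fasta)
    else:
        from .synthetic_data import generate_reference_set

        refs = generate_reference_set()
    assignments, counts = classify_proteome(proteins, refs)
    _write(assignments, outdir / "family_assignments.tsv")
    summary["group_counts"] = {g: int(counts.get(g, 0)) for g in sorted(counts)}

    # --- protein properties ------------------------------------------------
    props = properties_table(proteins)
    _write(props, outdir / "protein_properties.tsv")
    summary["n_unstable"] = int((props["stability"] == "unstable").sum())

    # --- phylogeny ----------------------------------------------------------
    family = [r for r, g in zip(proteins, assignments["group"]) if g != "none"]
    if len(family) >= 3:
        if config.alignment:
            aln = read_fasta(config.alignment, "protein")
            if config.bootstrap > 0:
                tree = bootstrap_support(aln, config.bootstrap, config.seed)
            else:
                tree = nj_tree(pairwise_distance(aln))
        else:
            tree = nj_tree(kmer_distance(family))
        (outdir / "tree.nwk").write_text(tree.newick(with_support=True) + "\n")

    # --- gene structure, duplication, Ka/Ks --------------------------------
    models = read_gff(config.gff) if config.gff else []
    models_by_id = {m.gene_id: m for m in models}
    if models:
        _write(structure_table(models), outdir / "gene_structure.tsv")
        wrky_models = {m.gene_id: m for m in models
                       if m.gene_id in {r.id for r in proteins}}
        chrom_counts: dict[str, int] = {}
        for m in wrky_models.values():
            chrom_counts[m.chromosome] = chrom_counts.get(m.chromosome, 0) + 1
        summary["wrky_per_chromosome"] = dict(sorted(chrom_counts.items()))

        paralogs = find_homolog_pairs(
            [r for r in proteins if r.id in wrky_models],
            config.paralog_min_identity,
        )
        tandem = detect_tandem(paralogs, models_by_id, config.max_intervening)
        tandem_ids = {(d.pair.id_a, d.pair.id_b) for d in tandem}
        blocks = detect_segmental(
            [p for p in paralogs if (p.id_a, p.id_b) not in tandem_ids],
            models_by_id,
            config.min_block,
            config.max_rank_gap,
        )
        seg = segmental_pairs(blocks)
        dup_rows = [
            {"id_a": d.pair.id_a, "id_b": d.pair.id_b, "dup_type": d.dup_type,
             "block_id": d.block_id or "", "identity": round(d.pair.identity, 4)}
            for d in tandem + seg
        ]
        _write(
            pd.DataFrame(dup_rows, columns=["id_a", "id_b", "dup_type",
                                            "block_id", "identity"]),
            outdir / "duplications.tsv",
        )
        dup_summary: dict = {
            "n_tandem_pairs": len(tandem),
            "n_segmental_pairs": len(seg),
            "n_segmental_blocks": len(blocks),
        }

        if config.run_kaks and config.cds:
            cds_map = {r.id: r.sequence
                       for r in read_fasta(config.cds, "nucleotide")}
            prot_by_id = {r.id: r for r in proteins}
            results = {}
            for d in tandem + seg:
                a, b = prot_by_id[d.pair.id_a], prot_by_id[d.pair.id_b]
                row_a, row_b = align_pair(a.sequence, b.sequence)
                rows = codon_align([(a.id, row_a), (b.id, row_b)], cds_map)
                results[(a.id, b.id)] = ng86_kaks(rows[0][1], rows[1][1],
                                                  config.lam)
            table = kaks_table(results)
            table.insert(2, "dup_type",
                         [d.dup_type for d in tandem + seg])
            _write(table, outdir / "kaks.tsv")
            for dup_type in ("tandem", "segmental"):
                vals = [
                    r for d, r in zip(tandem + seg, results.values())
                    if d.dup_type == dup_type and r.ratio is not None
                ]
                if vals:
                    dup_summary[dup_type] = {
                        "mean_ka": round(float(np.mean([r.ka for r in vals])), 4),
                        "mean_ks": round(float(np.mean([r.ks for r in vals])), 4),
                        "mean_ka_ks": round(
                            float(np.mean([r.ratio for r in vals])), 4),
                        "mean_time_mya": round(float(np.mean(
                            [r.time_years for r in vals])) / 1e6, 2),
                    }
        summary["duplication"] = dup_summary

    # --- orthologs ----------------------------------------------------------
    if config.ortholog_proteins:
        others = read_fasta(config.ortholog_proteins, "protein")
        rbh = reciprocal_best_hits(proteins, others,
                                   config.ortholog_min_identity)
        _write(pd.DataFrame(rbh, columns=["id_a", "id_b"]),
               outdir / "orthologs.tsv")
        summary["orthologs"] = {"n_pairs": len(rbh)}

    # --- promoters ----------------------------------------------------------
    if config.genome and models:
        genome = {r.id: r.sequence
                  for r in read_fasta(config.genome, "nucleotide")}
        catalog = (load_catalog(config.cre_catalog)
                   if config.cre_catalog else default_catalog())
        wrky_ids = {r.id for r in proteins}
        all_hits = []
        for m in models:
            if m.gene_id not in wrky_ids:
                continue
            window = extract_upstream(genome, m, config.upstream_length)
            all_hits += scan_cre(window, catalog, m.gene_id)
        _write(hit_frame(all_hits), outdir / "promoter_hits.tsv")
        summary["promoters"] = {
            "n_hits": len(all_hits),
            "n_patterns": len({h.pattern for h in all_hits}),
        }

    # --- expression ---------------------------------------------------------
    if config.counts:
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        if config.cds:
            lengths = {r.id: len(r.sequence)
                       for r in read_fasta(config.cds, "nucleotide")}
        else:
            lengths = {g: 1000 for g in counts.index}
        expr = rpkm(counts, pd.Series(lengths).reindex(counts.index))
        expr.round(4).to_csv(outdir / "rpkm.tsv", sep="\t",
                             index_label="gene")
        log2_matrix(expr).round(4).to_csv(outdir / "rpkm_log2.tsv", sep="\t",
                                          index_label="gene")
        summary["expression"] = {
            "n_genes": int(expr.shape[0]),
            "n_samples": int(expr.shape[1]),
        }
    if config.ct:
        ct = pd.read_csv(config.ct, sep="\t")
        folds = qpcr_fold_changes(ct, config.reference_gene)
        _write(folds.round(4), outdir / "qpcr_fold_changes.tsv")
        summary["qpcr"] = {"n_genes": int(folds["gene"].nunique())}

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("survey complete: %s", outdir / "summary.json")
    return summary
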