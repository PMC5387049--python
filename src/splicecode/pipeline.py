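"""End-to-end pipeline: genome + annotation -> splicing-code bundle.

Stages, in order: intron extraction, exon/intron classification, paired
consensus discovery, Fisher enrichment code table, U12 branch-point
scan, within-gene co-occurrence.  Each stage writes a TSV artifact; a
JSON summary collects per-class intron counts and fractions, motif
counts and the significant code-table cells.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import consensus, cooccurrence, enrichment, genome_model, u12
from .exon_classifier import IntronClass, classify_exons, classify_introns
from .genome_model import GenomeSequence, IntronRecord, TranscriptModel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome_path: Path | None = None
    annotation_path: Path | None = None
    output_dir: Path = Path("splicecode_out")
    donor_len: int = 10
    acceptor_len: int = 10
    min_count: int = 100
    prob_percentile: float = 0.95
    entropy_percentile: float = 0.05
    max_depth: int = 10
    alpha: float = 0.001
    u12_window: int = 60
    u12_top_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value, lo, hi in [
            ("prob_percentile", self.prob_percentile, 0.0, 1.0),
            ("entropy_percentile", self.entropy_percentile, 0.0, 1.0),
            ("alpha", self.alpha, 0.0, 1.0),
            ("u12_top_fraction", self.u12_top_fraction, 0.0, 1.0),
        ]:
            if not lo <= value <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}], got {value}")
        if self.min_count < 1 or self.max_depth < 2:
            raise ValueError("min_count >= 1 and max_depth >= 2 required")


@dataclass
class PipelineResult:
    introns: list[IntronRecord]
    exon_types: dict
    labels: dict[str, IntronClass]
    table: consensus.PairedConsensusTable
    assignments: dict[str, consensus.PairedConsensus | None]
    entries: list[enrichment.CodeTableEntry]
    code: enrichment.SplicingCodeTable
    branchpoint_hits: list[u12.BranchpointHit]
    branchpoint_summary: object
    cooccurrence_matrix: cooccurrence.CooccurrenceMatrix | None
    clusters: dict[int, int] | None
    summary: dict = field(default_factory=dict)


def run_stages(
    contigs: Mapping[str, GenomeSequence],
    transcripts: list[TranscriptModel],
    config: PipelineConfig,
) -> PipelineResult:
    """Run all analysis stages on in-memory transcript models."""
    t0 = time.time()
    genes = genome_model.group_by_gene(transcripts)

    introns: list[IntronRecord] = []
    exon_types_all: dict = {}
    labels: dict[str, IntronClass] = {}
    for gene_id in sorted(genes):
        txs = genes[gene_id]
        recs = genome_model.extract_introns(
            txs,
            contigs,
            donor_len=config.donor_len,
            acceptor_len=config.acceptor_len,
            store_full_sequence=True,
        )
        types = classify_exons(txs)
        exon_types_all[gene_id] = types
        labels.update(classify_introns(recs, types))
        introns.extend(recs)
    logger.info("classified %d introns in %.1fs", len(introns), time.time() - t0)

    table = consensus.build_paired_consensus_table(
        introns,
        min_count=config.min_count,
        prob_percentile=config.prob_percentile,
        entropy_percentile=config.entropy_percentile,
        max_depth=config.max_depth,
    )
    assignments = consensus.assign_all(introns, table)
    entries = enrichment.fisher_enrichment(assignments, labels, alpha=config.alpha)
    code = enrichment.build_code_table(entries, alpha=config.alpha)

    pwm = u12.default_u12_pwm()
    sequences = {
        r.intron_id: r.sequence for r in introns if len(r.sequence or "") >= len(pwm)
    }
    hits, bp_summary = u12.scan_branchpoints(
        sequences,
        pwm,
        window=config.u12_window,
        top_fraction=config.u12_top_fraction,
        labels={iid: labels[iid] for iid in sequences},
    )

    gene_rank_sets: dict[str, set[int]] = {}
    for rec in introns:
        pc = assignments[rec.intron_id]
        if pc is not None:
            gene_rank_sets.setdefault(rec.gene_id, set()).add(pc.rank)
    matrix = clusters = None
    if gene_rank_sets:
        matrix = cooccurrence.build_cooccurrence(gene_rank_sets)
        clusters, _ = cooccurrence.cluster_ranks(matrix)

    class_counts: dict[str, int] = {}
    for label in labels.values():
        class_counts[label.value] = class_counts.get(label.value, 0) + 1
    total = len(labels)
    n_sig = sum(e.significant_up or e.significant_down for e in entries)
    summary = {
        "n_genes": len(genes),
        "n_transcripts": len(transcripts),
        "n_introns": total,
        "class_counts": dict(sorted(class_counts.items())),
        "class_fractions": {
            k: round(100 * v / total, 2) for k, v in sorted(class_counts.items())
        },
        "n_motifs": len(table.motifs),
        "n_significant_cells": n_sig,
        "n_branchpoint_hits": sum(h.passes_threshold for h in hits),
        "runtime_s": round(time.time() - t0, 2),
    }
    return PipelineResult(
        introns=introns,
        exon_types=exon_types_all,
        labels=labels,
        table=table,
        assignments=assignments,
        entries=entries,
        code=code,
        branchpoint_hits=hits,
        branchpoint_summary=bp_summary,
        cooccurrence_matrix=matrix,
        clusters=clusters,
        summary=summary,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load genome + annotation from disk, run all stages, write outputs."""
    if config.genome_path is None or config.annotation_path is None:
        raise ValueError("genome_path and annotation_path are required")
    contigs, transcripts = genome_model.load_genome_annotation(
        config.genome_path, config.annotation_path
    )
    result = run_stages(contigs, transcripts, config)
    write_bundle(result, config.output_dir)
    return result


def write_bundle(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "introns": outdir / "introns.tsv",
        "consensus": outdir / "consensus_table.tsv",
        "code": outdir / "code_table.tsv",
        "code_grid": outdir / "code_grid.tsv",
        "enrichment": outdir / "enrichment.tsv",
        "u12": outdir / "u12_hits.tsv",
        "cooccurrence": outdir / "cooccurrence.tsv",
        "summary": outdir / "summary.json",
    }
    with open(paths["introns"], "w") as fh:
        fh.write(
            "gene_id\tcontig\tstrand\tstart\tend\tclass\tmotif\t"
            "donor_seq\tacceptor_seq\n"
        )
        for r in result.introns:
            pc = result.assignments[r.intron_id]
            fh.write(
                f"{r.gene_id}\t{r.contig_id}\t{r.strand}\t{r.interval[0]}\t"
                f"{r.interval[1]}\t{result.labels[r.intron_id].value}\t"
                f"{pc.motif if pc else 'none'}\t{r.donor_seq}\t{r.acceptor_seq}\n"
            )
    result.table.to_tsv(paths["consensus"])
    result.code.to_tsv(paths["code"])
    paths["code_grid"].write_text(result.code.render_grid() + "\n")
    enrichment.write_entries_tsv(result.entries, paths["enrichment"])
    u12.write_hits_tsv(result.branchpoint_hits, paths["u12"])
    if result.cooccurrence_matrix is not None:
        result.cooccurrence_matrix.to_tsv(paths["cooccurrence"])
    summary = dict(result.summary)
    summary["schema_version"] = 1
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2)
    return paths
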