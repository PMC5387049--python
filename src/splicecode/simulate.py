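"""Synthetic genomes with planted splicing structure.

The generator emits toy genomes (FASTA + GFF3 + ground truth) whose
multi-transcript gene models instantiate all seven exon splicing types,
and whose introns carry configurable motif-to-class associations:
selected intron classes receive a planted paired donor/acceptor
consensus with a given probability, everything else draws from a
background splice-site model (canonical ``gu...ag`` cores with
positionally biased interiors, or fully uniform interiors in stress
mode).  Every pipeline stage is therefore testable against known truth
with no external data.

Planting decisions are made per gene so that introns sharing a splice
site (alternative boundaries, skipped-exon spans) receive consistent
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .exon_classifier import ExonType, IntronClass
from .genome_model import GenomeSequence, TranscriptModel, reverse_complement
from .u12 import U12_BRANCH_CONSENSUS

RNA = "acgu"

#: Background splice-site model: per-position base probabilities (a,c,g,u)
#: for donor positions +3..+4 (after the invariant gu) and the acceptor
#: pyrimidine-leaning tract; all other interior positions are uniform.
DONOR_P3 = (0.45, 0.10, 0.35, 0.10)
DONOR_P4 = (0.40, 0.15, 0.30, 0.15)
ACCEPTOR_TRACT = (0.20, 0.30, 0.20, 0.30)
UNIFORM = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class MotifPlan:
    """Plant ``donor_acceptor`` on introns of ``target_class`` with the
    given per-gene probability; optionally also plant a U12 branch-point
    sequence upstream of the acceptor."""

    donor: str
    acceptor: str
    target_class: str  # IntronClass label, e.g. "S-S"
    probability: float = 0.85
    branchpoint: bool = False


#: Default study conditions: planted motifs in the two most populous
#: intron classes of the default event mix, planted at 0.85.  With a
#: min-count of 100 on a few thousand introns the quaternary tree has a
#: few dozen eligible branches, so the 95%/5% percentile filters can
#: certify only a handful of conserved branch ends; two planted motifs
#: (plus the canonical gu_ag background) sit comfortably inside that
#: budget.
DEFAULT_MOTIF_PLAN = (
    MotifPlan("guaugu", "ag", "R-R", 0.85),
    MotifPlan("guccug", "ag", "R-S", 0.85),
)

#: Per-gene event mix over the seven constructions (R-only genes plus one
#: gene template per alternative event type).
DEFAULT_EVENT_MIX = {
    "R": 0.35,
    "S": 0.25,
    "A5": 0.10,
    "A3": 0.10,
    "ME": 0.05,
    "APr": 0.075,
    "APA": 0.075,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 1500
    exon_length: tuple[int, int] = (80, 160)
    intron_length: tuple[int, int] = (60, 120)
    event_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_MIX)
    )
    motif_plan: Sequence[MotifPlan] = DEFAULT_MOTIF_PLAN
    donor_len: int = 10
    acceptor_len: int = 10
    uniform_background: bool = False
    intergenic: int = 60
    genes_per_contig: int = 100

    def __post_init__(self) -> None:
        total = sum(self.event_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"event_mix must sum to 1, got {total}")
        min_intron = self.intron_length[0]
        for plan in self.motif_plan:
            if len(plan.donor) + len(plan.acceptor) > min_intron:
                raise ValueError(
                    f"motif {plan.donor}_{plan.acceptor} does not fit in "
                    f"the minimum intron length {min_intron}"
                )
            if not 0.0 <= plan.probability <= 1.0:
                raise ValueError("planting probability must be in [0, 1]")
            IntronClass(plan.target_class)  # validates the label


@dataclass(frozen=True)
class TruthIntron:
    gene_id: str
    contig_id: str
    strand: str
    interval: tuple[int, int]
    intron_class: IntronClass
    motif: str | None  # "donor_acceptor" if planted, else None
    branchpoint: bool = False


@dataclass
class GroundTruth:
    """Planted exon types, intron classes and motifs of one simulation."""

    exon_types: dict[tuple[str, tuple[int, int]], ExonType]  # (gene, exon)
    introns: list[TruthIntron]

    def planted_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.introns:
            if t.motif is not None:
                counts[t.motif] = counts.get(t.motif, 0) + 1
        return counts

    def class_counts(self) -> dict[IntronClass, int]:
        counts: dict[IntronClass, int] = {}
        for t in self.introns:
            counts[t.intron_class] = counts.get(t.intron_class, 0) + 1
        return counts


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    contigs: dict[str, GenomeSequence]
    transcripts: list[TranscriptModel]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> tuple[Path, Path, Path]:
        """Write FASTA + GFF3 + ground-truth TSV; returns the three paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fa"
        gff = outdir / "annotation.gff3"
        truth = outdir / "truth.tsv"
        with open(fasta, "w") as fh:
            for name, contig in self.contigs.items():
                fh.write(f">{name}\n")
                seq = contig.sequence
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            by_gene: dict[str, list[TranscriptModel]] = {}
            for tx in self.transcripts:
                by_gene.setdefault(tx.gene_id, []).append(tx)
            for gene_id in sorted(by_gene):
                txs = by_gene[gene_id]
                start = min(t.exons[0][0] for t in txs)
                end = max(t.exons[-1][1] for t in txs)
                contig, strand = txs[0].contig_id, txs[0].strand
                fh.write(
                    f"{contig}\tsim\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                    f"ID={gene_id}\n"
                )
                for tx in sorted(txs, key=lambda t: t.transcript_id):
                    fh.write(
                        f"{contig}\tsim\tmRNA\t{tx.exons[0][0] + 1}\t"
                        f"{tx.exons[-1][1]}\t.\t{strand}\t.\t"
                        f"ID={tx.transcript_id};Parent={gene_id}\n"
                    )
                    for i, (s, e) in enumerate(tx.exons):
                        fh.write(
                            f"{contig}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                            f"ID={tx.transcript_id}.e{i + 1};"
                            f"Parent={tx.transcript_id}\n"
                        )
        with open(truth, "w") as fh:
            fh.write(
                "gene_id\tcontig\tstrand\tstart\tend\tclass\tmotif\tbranchpoint\n"
            )
            for t in self.truth.introns:
                fh.write(
                    f"{t.gene_id}\t{t.contig_id}\t{t.strand}\t{t.interval[0]}\t"
                    f"{t.interval[1]}\t{t.intron_class.value}\t"
                    f"{t.motif or 'background'}\t{int(t.branchpoint)}\n"
                )
        return fasta, gff, truth


# ---------------------------------------------------------------------------
# gene templates, in transcription-order local coordinates


def _draw_len(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def _build_template(
    event: str, rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[list[list[tuple[int, int]]], dict[tuple[int, int], ExonType], list[tuple[tuple[int, int], IntronClass]], int]:
    """One gene layout: (transcripts as local exon lists, exon types,
    unique introns with classes, total local length)."""
    E = lambda: _draw_len(rng, cfg.exon_length)
    I = lambda: _draw_len(rng, cfg.intron_length)
    R, S, A5, A3, ME, APr, APA = (
        ExonType.R,
        ExonType.S,
        ExonType.A5,
        ExonType.A3,
        ExonType.ME,
        ExonType.APR,
        ExonType.APA,
    )

    def lay(*lengths: int) -> list[int]:
        """Cumulative boundaries 0, l1, l1+l2, ..."""
        bounds = [0]
        for l in lengths:
            bounds.append(bounds[-1] + l)
        return bounds

    if event == "R":
        b = lay(E(), I(), E(), I(), E(), I(), E())
        e1, e2, e3, e4 = (
            (b[0], b[1]),
            (b[2], b[3]),
            (b[4], b[5]),
            (b[6], b[7]),
        )
        txs = [[e1, e2, e3, e4]]
        types = {e1: R, e2: R, e3: R, e4: R}
        introns = [
            ((e1[1], e2[0]), "R-R"),
            ((e2[1], e3[0]), "R-R"),
            ((e3[1], e4[0]), "R-R"),
        ]
    elif event == "S":
        b = lay(E(), I(), E(), I(), E(), I(), E())
        e1, e2, e3, e4 = (b[0], b[1]), (b[2], b[3]), (b[4], b[5]), (b[6], b[7])
        txs = [[e1, e2, e3, e4], [e1, e3, e4], [e1, e2, e4]]
        types = {e1: R, e2: S, e3: S, e4: R}
        introns = [
            ((e1[1], e2[0]), "R-S"),
            ((e2[1], e3[0]), "S-S"),
            ((e3[1], e4[0]), "S-R"),
            ((e1[1], e3[0]), "R-S"),
            ((e2[1], e4[0]), "S-R"),
        ]
    elif event == "A5":
        # E2' extends E2 on its donor side by delta, shortening intron 2
        i2 = I()
        delta = int(rng.integers(15, min(31, i2 - cfg.intron_length[0] // 2)))
        b = lay(E(), I(), E(), i2, E())
        e1, e2, e3 = (b[0], b[1]), (b[2], b[3]), (b[4], b[5])
        e2p = (e2[0], e2[1] + delta)
        txs = [[e1, e2, e3], [e1, e2p, e3]]
        types = {e1: R, e2: A5, e2p: A5, e3: R}
        introns = [
            ((e1[1], e2[0]), "R-A5"),
            ((e2[1], e3[0]), "A5-R"),
            ((e2p[1], e3[0]), "A5-R"),
        ]
    elif event == "A3":
        i1 = I()
        delta = int(rng.integers(15, min(31, i1 - cfg.intron_length[0] // 2)))
        b = lay(E(), i1, E(), I(), E())
        e1, e2, e3 = (b[0], b[1]), (b[2], b[3]), (b[4], b[5])
        e2p = (e2[0] + delta, e2[1])
        txs = [[e1, e2, e3], [e1, e2p, e3]]
        types = {e1: R, e2: A3, e2p: A3, e3: R}
        introns = [
            ((e1[1], e2[0]), "R-A3"),
            ((e1[1], e2p[0]), "R-A3"),
            ((e2[1], e3[0]), "A3-R"),
        ]
    elif event == "ME":
        b = lay(E(), I(), E(), I(), E(), I(), E())
        e1, e2, e3, e4 = (b[0], b[1]), (b[2], b[3]), (b[4], b[5]), (b[6], b[7])
        txs = [[e1, e2, e4], [e1, e3, e4]]
        types = {e1: R, e2: ME, e3: ME, e4: R}
        introns = [
            ((e1[1], e2[0]), "R-ME"),
            ((e2[1], e4[0]), "ME-R"),
            ((e1[1], e3[0]), "R-ME"),
            ((e3[1], e4[0]), "ME-R"),
        ]
    elif event == "APr":
        b = lay(E(), I(), E(), I(), E(), I(), E())
        e1a, e1b, e2, e3 = (b[0], b[1]), (b[2], b[3]), (b[4], b[5]), (b[6], b[7])
        txs = [[e1a, e2, e3], [e1b, e2, e3]]
        types = {e1a: APr, e1b: APr, e2: R, e3: R}
        introns = [
            ((e1a[1], e2[0]), "APr-R"),
            ((e1b[1], e2[0]), "APr-R"),
            ((e2[1], e3[0]), "R-R"),
        ]
    elif event == "APA":
        b = lay(E(), I(), E(), I(), E(), I(), E())
        e1, e2, e3a, e3b = (b[0], b[1]), (b[2], b[3]), (b[4], b[5]), (b[6], b[7])
        txs = [[e1, e2, e3a], [e1, e2, e3b]]
        types = {e1: R, e2: R, e3a: APA, e3b: APA}
        introns = [
            ((e1[1], e2[0]), "R-R"),
            ((e2[1], e3a[0]), "R-APA"),
            ((e2[1], e3b[0]), "R-APA"),
        ]
    else:
        raise ValueError(f"unknown event type {event!r}")

    length = max(e[1] for e in types)
    classes = [(iv, IntronClass(lbl)) for iv, lbl in introns]
    return txs, types, classes, length


def _draw_bases(rng: np.random.Generator, probs: Sequence[float], n: int) -> str:
    return "".join(RNA[i] for i in rng.choice(4, size=n, p=list(probs)))


def _background_donor(rng: np.random.Generator, n: int, uniform: bool) -> str:
    if uniform:
        return "gu" + _draw_bases(rng, UNIFORM, n - 2)
    parts = ["gu"]
    for pos in range(3, n + 1):
        p = DONOR_P3 if pos == 3 else DONOR_P4 if pos == 4 else UNIFORM
        parts.append(_draw_bases(rng, p, 1))
    return "".join(parts)


def _background_acceptor(rng: np.random.Generator, n: int, uniform: bool) -> str:
    tract = _draw_bases(rng, UNIFORM if uniform else ACCEPTOR_TRACT, n - 2)
    return tract + "ag"


def _pad_donor(rng: np.random.Generator, motif: str, n: int) -> str:
    return motif + _draw_bases(rng, UNIFORM, max(0, n - len(motif)))


def _pad_acceptor(rng: np.random.Generator, motif: str, n: int) -> str:
    return _draw_bases(rng, UNIFORM, max(0, n - len(motif))) + motif


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Deterministic toy genome from a configuration (seeded)."""
    rng = np.random.default_rng(config.seed)
    events = sorted(config.event_mix)
    probs = [config.event_mix[e] for e in events]
    plans_by_class: dict[str, MotifPlan] = {
        p.target_class: p for p in config.motif_plan
    }

    contigs: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    exon_types: dict[tuple[str, tuple[int, int]], ExonType] = {}
    truth_introns: list[TruthIntron] = []

    contig_parts: list[str] = []
    cursor = 0
    contig_idx = 0
    contig_name = "chr1"
    genes_on_contig = 0

    for g in range(config.n_genes):
        if genes_on_contig >= config.genes_per_contig:
            contigs[contig_name] = "".join(contig_parts)
            contig_idx += 1
            contig_name = f"chr{contig_idx + 1}"
            contig_parts, cursor, genes_on_contig = [], 0, 0
        gene_id = f"gene{g + 1:05d}"
        event = events[int(rng.choice(len(events), p=probs))]
        txs_local, types_local, introns_local, length = _build_template(
            event, rng, config
        )
        strand = "+" if rng.random() < 0.5 else "-"

        # local sense-strand sequence (transcription order)
        seq = list(_draw_bases(rng, UNIFORM, length))

        # per-gene planting decision per intron class
        gene_plants: dict[str, bool] = {
            lbl: rng.random() < plan.probability
            for lbl, plan in plans_by_class.items()
        }
        # writes keyed by splice-site position so introns sharing a donor
        # or acceptor (alternative boundaries, skipped-exon spans) stay
        # consistent; a planted write takes precedence over background
        donor_writes: dict[int, tuple[str, bool]] = {}  # start -> (seq, planted)
        acceptor_writes: dict[int, tuple[str, bool, bool]] = {}
        intron_meta: list[tuple[tuple[int, int], IntronClass, bool]] = []
        for (istart, iend), klass in introns_local:
            ilen = iend - istart
            d_len = min(config.donor_len, ilen)
            a_len = min(config.acceptor_len, ilen - d_len)
            plan = plans_by_class.get(klass.value)
            planted = plan is not None and gene_plants[klass.value]
            if planted:
                donor = _pad_donor(rng, plan.donor, d_len)
                acceptor = _pad_acceptor(rng, plan.acceptor, a_len)
                bp = plan.branchpoint
            else:
                donor = _background_donor(rng, d_len, config.uniform_background)
                acceptor = _background_acceptor(
                    rng, a_len, config.uniform_background
                )
                bp = False
            if planted or istart not in donor_writes:
                donor_writes[istart] = (donor, planted)
            if planted or iend not in acceptor_writes:
                acceptor_writes[iend] = (acceptor, bp, planted)
            intron_meta.append(((istart, iend), klass, bp))

        for istart, (donor, _) in donor_writes.items():
            seq[istart : istart + len(donor)] = donor
        for iend, (acceptor, bp, _) in acceptor_writes.items():
            seq[iend - len(acceptor) : iend] = acceptor
            if bp:
                # branch window upstream of the acceptor tract
                pos = iend - len(acceptor) - 15
                seq[pos : pos + len(U12_BRANCH_CONSENSUS)] = U12_BRANCH_CONSENSUS
        local = "".join(seq)

        def truth_motif(istart: int, iend: int) -> str | None:
            """Most specific plan motif matching the written sequence, so
            ground truth is consistent with the emitted FASTA even where
            shared splice sites made planting decisions interact."""
            ilen = iend - istart
            d_len = min(config.donor_len, ilen)
            a_len = min(config.acceptor_len, ilen - d_len)
            donor_actual = local[istart : istart + d_len]
            acceptor_actual = local[iend - a_len : iend]
            best: MotifPlan | None = None
            for plan in config.motif_plan:
                if donor_actual.startswith(plan.donor) and acceptor_actual.endswith(
                    plan.acceptor
                ):
                    if best is None or (len(plan.donor), len(plan.acceptor)) > (
                        len(best.donor),
                        len(best.acceptor),
                    ):
                        best = plan
            return f"{best.donor}_{best.acceptor}" if best else None

        # map to genomic coordinates
        offset = cursor
        dna = local.upper().replace("U", "T")
        genomic = dna if strand == "+" else reverse_complement(dna)

        def to_genomic(iv: tuple[int, int]) -> tuple[int, int]:
            s, e = iv
            if strand == "+":
                return (offset + s, offset + e)
            return (offset + length - e, offset + length - s)

        for t, exons in enumerate(txs_local):
            g_exons = tuple(sorted(to_genomic(e) for e in exons))
            transcripts.append(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=f"{gene_id}.t{t + 1}",
                    contig_id=contig_name,
                    strand=strand,
                    exons=g_exons,
                )
            )
        for exon, etype in types_local.items():
            exon_types[(gene_id, to_genomic(exon))] = etype
        for iv, klass, bp in intron_meta:
            truth_introns.append(
                TruthIntron(
                    gene_id=gene_id,
                    contig_id=contig_name,
                    strand=strand,
                    interval=to_genomic(iv),
                    intron_class=klass,
                    motif=truth_motif(*iv),
                    branchpoint=bp,
                )
            )

        contig_parts.append(genomic)
        contig_parts.append(
            "".join(
                "ACGT"[i]
                for i in rng.integers(0, 4, size=config.intergenic)
            )
        )
        cursor += length + config.intergenic
        genes_on_contig += 1

    contigs[contig_name] = "".join(contig_parts)
    genome = {
        name: GenomeSequence(name, seq) for name, seq in contigs.items() if seq
    }
    return SimulatedGenome(
        config=config,
        contigs=genome,
        transcripts=transcripts,
        truth=GroundTruth(exon_types=exon_types, introns=truth_introns),
    )
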