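"""Genome + annotation input layer: transcript models and intron extraction.

Coordinates are 0-based half-open internally; GFF3/GTF (1-based inclusive)
are converted on read.  Splice-site sequences are reported on the sense
(transcribed) strand as lowercase RNA, so every canonical intron reads
``gu ... ag``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """Lowercase RNA rendering of a DNA string (t -> u)."""
    return seq.lower().replace("t", "u")


@dataclass(frozen=True)
class GenomeSequence:
    """A single contig held in memory as an uppercase DNA string."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sense-strand DNA in [start, end); out-of-bounds lookups are errors."""
        if start < 0 or end > len(self.sequence) or start >= end:
            raise IndexError(
                f"[{start},{end}) outside contig {self.contig_id} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start:end]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered list of exon intervals on a strand.

    ``exons`` are 0-based half-open genomic intervals sorted by genomic
    start, non-overlapping, all on one contig and strand.
    """

    gene_id: str
    transcript_id: str
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def exons_transcription_order(self) -> tuple[tuple[int, int], ...]:
        """Exons 5' -> 3' on the transcribed strand."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def intron_intervals(self) -> list[tuple[int, int]]:
        """Genomic intervals between consecutive exons (n-1 for n exons)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass(frozen=True)
class IntronRecord:
    """A unique intron of one gene with its splice-site sequences.

    ``donor_seq`` is the first bases of the intron at the transcribed 5'
    end and ``acceptor_seq`` the last bases at the 3' end, both lowercase
    RNA on the sense strand.  Flanking exon ids are in transcription order.
    """

    gene_id: str
    contig_id: str
    strand: str
    interval: tuple[int, int]
    donor_seq: str
    acceptor_seq: str
    upstream_exon: tuple[int, int]
    downstream_exon: tuple[int, int]
    sequence: str | None = field(default=None, compare=False)

    @property
    def intron_id(self) -> str:
        return (
            f"{self.gene_id}:{self.contig_id}:{self.strand}:"
            f"{self.interval[0]}-{self.interval[1]}"
        )

    def __len__(self) -> int:
        return self.interval[1] - self.interval[0]


def _structurally_valid(exons: list[tuple[int, int]], contig_len: int) -> bool:
    if not exons:
        return False
    exons = sorted(exons)
    for (s, e) in exons:
        if e - s < 1 or s < 0 or e > contig_len:
            return False
    for (_, e_prev), (s_next, _) in zip(exons, exons[1:]):
        if s_next <= e_prev:  # overlap or abutting (zero-length intron)
            return False
    return True


def load_genome_annotation(
    fasta_path: str | Path, annotation_path: str | Path
) -> tuple[dict[str, GenomeSequence], list[TranscriptModel]]:
    """Read a FASTA genome and a GFF3/GTF annotation into transcript models.

    Transcripts failing the structural pre-filter (exons out of contig
    bounds, zero length, or overlapping within one transcript) are dropped
    with a warning.  Both GFF3 and GTF dialects are accepted; the dialect
    is sniffed by gffutils.

    Returns (contigs keyed by id, list of TranscriptModel).
    """
    fasta_path = Path(fasta_path)
    annotation_path = Path(annotation_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    if not annotation_path.exists():
        raise FileNotFoundError(annotation_path)

    fa = Fasta(str(fasta_path), rebuild=True, build_index=True)
    genome = {
        name: GenomeSequence(name, str(fa[name][:]).upper()) for name in fa.keys()
    }

    db = gffutils.create_db(
        str(annotation_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # Group exons by transcript, resolve transcript -> gene.
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, contig, strand)
    for exon in db.features_of_type("exon"):
        attrs = exon.attributes
        if "transcript_id" in attrs:  # GTF dialect
            tx_id = attrs["transcript_id"][0]
            gene_id = attrs.get("gene_id", [tx_id])[0]
        elif "Parent" in attrs:  # GFF3 dialect
            tx_id = attrs["Parent"][0]
            gene_id = tx_id
            try:
                parent = db[tx_id]
                gene_id = parent.attributes.get("Parent", [tx_id])[0]
            except gffutils.FeatureNotFoundError:
                pass
        else:
            logger.warning("exon without transcript linkage skipped: %s", exon)
            continue
        # GFF/GTF are 1-based inclusive -> 0-based half-open
        tx_exons.setdefault(tx_id, []).append((exon.start - 1, exon.end))
        tx_meta.setdefault(tx_id, (gene_id, exon.seqid, exon.strand))

    transcripts: list[TranscriptModel] = []
    for tx_id, exons in tx_exons.items():
        gene_id, contig_id, strand = tx_meta[tx_id]
        if contig_id not in genome:
            logger.warning(
                "transcript %s dropped: contig %s not in FASTA", tx_id, contig_id
            )
            continue
        if strand not in "+-":
            logger.warning("transcript %s dropped: strand %r", tx_id, strand)
            continue
        if not _structurally_valid(exons, len(genome[contig_id])):
            logger.warning(
                "transcript %s dropped by pre-filter (bounds/overlap)", tx_id
            )
            continue
        transcripts.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=tx_id,
                contig_id=contig_id,
                strand=strand,
                exons=tuple(sorted(exons)),
            )
        )

    if not transcripts:
        raise ValueError("no transcripts survive pre-filtering")
    return genome, transcripts


def extract_introns(
    transcripts_of_gene: Iterable[TranscriptModel],
    genome: GenomeSequence | Mapping[str, GenomeSequence],
    donor_len: int = 10,
    acceptor_len: int = 10,
    store_full_sequence: bool = False,
) -> list[IntronRecord]:
    """Unique introns of one gene with donor/acceptor splice sequences.

    Uniqueness key is (contig, strand, start, end) pooled across the
    gene's transcripts.  Minus-strand introns are reverse-complemented so
    ``donor_seq`` starts at the transcribed 5' end.  Introns shorter than
    donor_len + acceptor_len get truncated, non-overlapping windows.
    Introns whose splice windows contain N are excluded (a quaternary
    tree has no N branch) with a warning.
    """
    if donor_len < 2 or acceptor_len < 2:
        raise ValueError("donor_len and acceptor_len must be >= 2")
    transcripts = list(transcripts_of_gene)
    if not transcripts:
        return []

    records: dict[tuple[str, str, int, int], IntronRecord] = {}
    for tx in transcripts:
        contig = genome if isinstance(genome, GenomeSequence) else genome[tx.contig_id]
        exons_tr = tx.exons_transcription_order
        for i in range(len(exons_tr) - 1):
            up_exon, down_exon = exons_tr[i], exons_tr[i + 1]
            if tx.strand == "+":
                start, end = up_exon[1], down_exon[0]
            else:
                start, end = down_exon[1], up_exon[0]
            key = (tx.contig_id, tx.strand, start, end)
            if key in records:
                continue
            dna = contig.fetch(start, end)
            sense = dna if tx.strand == "+" else reverse_complement(dna)
            n = len(sense)
            d_len = min(donor_len, n)
            a_len = min(acceptor_len, n - d_len)
            donor = to_rna(sense[:d_len])
            acceptor = to_rna(sense[n - a_len :]) if a_len else ""
            if "n" in donor or "n" in acceptor:
                logger.warning(
                    "intron %s:%d-%d excluded: N in splice window",
                    tx.contig_id,
                    start,
                    end,
                )
                continue
            records[key] = IntronRecord(
                gene_id=tx.gene_id,
                contig_id=tx.contig_id,
                strand=tx.strand,
                interval=(start, end),
                donor_seq=donor,
                acceptor_seq=acceptor,
                upstream_exon=up_exon,
                downstream_exon=down_exon,
                sequence=to_rna(sense) if store_full_sequence else None,
            )
    return sorted(records.values(), key=lambda r: (r.contig_id, r.interval, r.strand))


def group_by_gene(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, list[TranscriptModel]]:
    genes: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        genes.setdefault(tx.gene_id, []).append(tx)
    return genes


def write_introns_tsv(records: Iterable[IntronRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcontig\tstrand\tstart\tend\tdonor_seq\tacceptor_seq\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.contig_id}\t{r.strand}\t{r.interval[0]}\t"
                f"{r.interval[1]}\t{r.donor_seq}\t{r.acceptor_seq}\n"
            )
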