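"""Genome and annotation I/O: FASTA, GFF3, spliced transcripts, BED/TSV output.

Coordinate convention: everything in memory is 0-based half-open on the
forward strand. GFF3 (1-based closed) is converted at the parsing boundary;
BED output is emitted 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO

from . import _intervals
from .errors import (
    AlphabetError,
    AnnotationError,
    CoordinateError,
    FastaFormatError,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str, *, name: str = "sequence") -> str:
    """Uppercase, convert U->T and validate against the ACGTN alphabet."""
    seq = raw.upper().replace("U", "T")
    for pos, ch in enumerate(seq):
        if ch not in VALID_BASES:
            raise AlphabetError(
                f"{name}: illegal character {ch!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class GenomeIndex:
    """In-memory genome: contig name -> uppercase ACGTN sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name in self.contigs:
            if not name:
                raise FastaFormatError("empty contig name")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Forward-strand slice [start, end) with bounds checking."""
        seq = self.contigs.get(contig)
        if seq is None:
            raise CoordinateError(f"unknown contig {contig!r}")
        if not (0 <= start <= end <= len(seq)):
            raise CoordinateError(
                f"[{start},{end}) outside contig {contig} (length {len(seq)})"
            )
        return seq[start:end]


def read_fasta(path: str | Path) -> GenomeIndex:
    """Read a multi-record FASTA into a :class:`GenomeIndex`.

    Sequences are uppercased and U is converted to T; characters outside
    ACGTUN are rejected. Duplicate headers and empty files are format errors.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FastaFormatError(f"duplicate FASTA header {rec.id!r}")
        contigs[rec.id] = normalize_sequence(str(rec.seq), name=rec.id)
    if not contigs:
        raise FastaFormatError(f"no FASTA records in {path}")
    return GenomeIndex(contigs)


@dataclass(frozen=True)
class Transcript:
    """One isoform: ordered exons (and optional CDS) in forward coordinates."""

    id: str
    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.id}: transcript without exons")
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise AnnotationError(f"{self.id}: overlapping exons")
        for s, e in exons:
            if s >= e:
                raise AnnotationError(f"{self.id}: empty exon [{s},{e})")
        if self.cds is not None:
            cds = tuple(sorted(self.cds))
            object.__setattr__(self, "cds", cds)
            for s, e in cds:
                if not _intervals.contains(exons, s, e):
                    raise AnnotationError(
                        f"{self.id}: CDS [{s},{e}) not within exons"
                    )

    @property
    def tss(self) -> int:
        """Genomic position (0-based) of the first transcribed base."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_positions(self) -> list[int]:
        """Genomic position of each transcript base, in 5'->3' order."""
        pos = [p for s, e in self.exons for p in range(s, e)]
        return pos if self.strand == "+" else pos[::-1]

    def cds_genomic_positions(self) -> list[int]:
        """Genomic position of each CDS base, 5'->3' (start codon first)."""
        if self.cds is None:
            return []
        pos = [p for s, e in self.cds for p in range(s, e)]
        return pos if self.strand == "+" else pos[::-1]


@dataclass(frozen=True)
class GeneModel:
    """All isoforms of one gene, on one contig and strand."""

    gene_id: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"{self.gene_id}: gene without transcripts")
        contigs = {t.contig for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(contigs) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"{self.gene_id}: transcripts span contigs/strands"
            )
        ids = [t.id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise AnnotationError(f"{self.gene_id}: duplicate transcript ids")

    @property
    def contig(self) -> str:
        return self.transcripts[0].contig

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand


_TX_TYPES = ("mRNA", "transcript")


def read_gff3(path: str | Path, genome: GenomeIndex) -> list[GeneModel]:
    """Parse GFF3 into gene models, validated against *genome*.

    Recognized feature types are gene, mRNA/transcript, exon and CDS; other
    types are ignored (a count is logged). GFF coordinates (1-based closed)
    are converted to 0-based half-open. Genes on contigs absent from the
    genome are skipped with a warning; an exon beyond its contig end raises
    :class:`CoordinateError`; a transcript whose Parent gene is missing
    raises :class:`AnnotationError`.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    known = {"gene", "exon", "CDS", *_TX_TYPES}
    ignored = sum(
        db.count_features_of_type(t)
        for t in db.featuretypes()
        if t not in known
    )
    if ignored:
        logger.info("ignored %d features of unrecognized types", ignored)

    gene_ids = {f.id for f in db.features_of_type("gene")}
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in genome.contigs:
            logger.warning(
                "gene %s on unknown contig %s: skipped", gene.id, gene.seqid
            )
            continue
        transcripts = []
        for tx in db.children(gene, featuretype=_TX_TYPES, level=1):
            exons = []
            cds = []
            for child in db.children(tx, level=1):
                iv = (child.start - 1, child.end)  # GFF -> half-open
                if iv[1] > len(genome.contigs[gene.seqid]) or iv[0] < 0:
                    raise CoordinateError(
                        f"{child.featuretype} {iv} of {tx.id} outside "
                        f"contig {gene.seqid}"
                    )
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "CDS":
                    cds.append(iv)
            transcripts.append(
                Transcript(
                    id=tx.id,
                    gene_id=gene.id,
                    contig=gene.seqid,
                    strand=tx.strand,
                    exons=tuple(sorted(exons)),
                    cds=tuple(sorted(cds)) or None,
                )
            )
        if transcripts:
            genes.append(GeneModel(gene.id, tuple(transcripts)))

    # orphan transcripts: a Parent that is not a known gene id
    for tx in db.features_of_type(_TX_TYPES):
        for parent in tx.attributes.get("Parent", []):
            if parent not in gene_ids:
                raise AnnotationError(
                    f"transcript {tx.id}: Parent {parent!r} is not a gene"
                )
    return genes


def transcript_sequence(t: Transcript, genome: GenomeIndex) -> str:
    """Spliced transcript sequence, 5'->3' on the transcript strand."""
    parts = [genome.fetch(t.contig, s, e) for s, e in t.exons]
    seq = "".join(parts)
    return revcomp(seq) if t.strand == "-" else seq


def write_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


BedRecord = tuple[str, int, int, str, float, str]


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    """BED6: name = guide id, score = rank score x1000 truncated to int."""
    with open(path, "w") as fh:
        for contig, start, end, name, score, strand in records:
            if not 0 <= start < end:
                raise CoordinateError(f"bad BED interval [{start},{end})")
            fh.write(
                f"{contig}\t{start}\t{end}\t{name}\t{int(score * 1000)}\t{strand}\n"
            )


def write_tsv(
    rows: Sequence[Mapping[str, object]],
    columns: Sequence[str],
    path: str | Path,
    *,
    header_comment: str | None = None,
) -> None:
    """Plain TSV with a frozen column order and an optional '#' header line."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"#{header_comment}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c)) for c in columns) + "\n")


def _fmt(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)
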