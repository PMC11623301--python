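"""Readers and writers for the plain-text formats the pipeline touches.

Conventions fixed here and used everywhere else in the package:

* Sequences are uppercase strings over the alphabet ``{A, C, G, T, N}``.
  Soft-masked (lowercase) input is uppercased on ingest; any other
  character is rejected.
* Internal coordinates are 0-based half-open on the forward strand.
  GFF3 (1-based inclusive) and BED (0-based half-open) are converted at
  the boundary, so no other module ever sees a 1-based coordinate.
* FASTA is written wrapped at 60 columns; FASTQ is Sanger Phred+33.
* Tabular results are TSV with a single ``#``-prefixed header line and
  floats printed with 4 decimals.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = frozenset("ACGTN")
FASTA_WRAP = 60

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when a file violates the dialect conventions fixed above."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence (assembly contig or synthetic chromosome)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-ACGTN character(s): "
                + ", ".join(sorted(bad))
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval in internal (0-based half-open) coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


def gene_sequence(gene: GeneAnnotation, genome: GenomeSequence) -> str:
    """Extract a gene's nucleotide sequence, reverse-complemented for '-' strand."""
    if gene.contig_id != genome.id:
        raise ValueError(f"gene {gene.gene_id} is on contig {gene.contig_id}, not {genome.id}")
    if gene.end > genome.length:
        raise ValueError(f"gene {gene.gene_id} extends past the end of {genome.id}")
    seq = genome.residues[gene.start : gene.end]
    return reverse_complement(seq) if gene.strand == "-" else seq


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike | io.TextIOBase) -> list[GenomeSequence]:
    """Read a multi-record FASTA file into validated GenomeSequence records.

    Lowercase residues are uppercased; duplicate ids, an empty file, or
    characters outside A/C/G/T/N raise :class:`FormatError`.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(id=rec.id, residues=str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records found in {path!r}")
    return records


def write_fasta(records: Sequence[GenomeSequence], path: str | os.PathLike) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id on write: {rec.id!r}")
        seen.add(rec.id)
    bio = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3 (gene features only; 1-based inclusive on disk)
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike) -> list[GeneAnnotation]:
    """Read ``gene`` features from a GFF3 file into internal coordinates.

    On-disk 1-based inclusive [start, end] becomes internal 0-based
    half-open [start-1, end). Features other than ``gene`` are ignored.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise FormatError(f"{path}:{lineno}: start {start_i} > end {end_i}")
            gene_id = None
            for item in attrs.split(";"):
                key, _, value = item.strip().partition("=")
                if key == "ID":
                    gene_id = value
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: gene feature without ID attribute")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    contig_id=contig,
                    start=start_i - 1,
                    end=end_i,
                    strand=strand if strand in "+-" else "+",
                )
            )
    return genes


def write_gff3(genes: Iterable[GeneAnnotation], path: str | os.PathLike) -> None:
    """Write gene features as GFF3 (internal half-open -> 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "starscreen",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTQ (Sanger Phred+33)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    qualities: str  # Phred+33 string, same length as sequence


def read_fastq(path: str | os.PathLike) -> list[ReadRecord]:
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(ReadRecord(id=rec.id, sequence=str(rec.seq).upper(), qualities=quals))
    if not reads:
        raise FormatError(f"no FASTQ records found in {path!r}")
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities}\n")


# ---------------------------------------------------------------------------
# BED6 (neighborhood spans)
# ---------------------------------------------------------------------------

def write_bed6(
    intervals: Iterable[tuple[str, int, int, str]], path: str | os.PathLike
) -> None:
    """Write (contig, start, end, name) intervals as BED6 (score '.', strand '+')."""
    with open(path, "w") as fh:
        for contig, start, end, name in intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t.\t+\n")


# ---------------------------------------------------------------------------
# TSV with a single '#'-prefixed header line
# ---------------------------------------------------------------------------

def write_tsv(rows: Iterable[dict], columns: Sequence[str], path: str | os.PathLike) -> None:
    """Write dict rows as TSV; floats with 4 decimals; None as empty field."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        for row in rows:
            out = []
            for col in columns:
                v = row.get(col)
                if v is None:
                    out.append("")
                elif isinstance(v, float):
                    out.append(f"{v:.4f}")
                else:
                    out.append(str(v))
            fh.write("\t".join(out) + "\n")


def read_tsv(path: str | os.PathLike) -> tuple[list[str], list[dict]]:
    """Read a '#'-headed TSV back into (columns, rows of strings; '' -> None)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing '#' header line")
        columns = header[1:].split("\t")
        rows = []
        for line in fh:
            values = line.rstrip("\n").split("\t")
            rows.append({c: (v if v != "" else None) for c, v in zip(columns, values)})
    return columns, rows
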