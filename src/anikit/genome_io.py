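"""Genome and CDS sequence types plus FASTA reading/writing.

A :class:`Genome` is an ordered set of nucleotide contigs; draft assemblies
are handled by treating all contigs jointly as one genome. Sequences are
normalized on input: lowercase is uppercased and IUPAC ambiguity codes other
than A/C/G/T are mapped to N (N never counts as an identical site in
alignments downstream).

Coordinates are 0-based half-open everywhere in memory; human-readable
output converts to 1-based inclusive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")
# IUPAC nucleotide codes; everything ambiguous collapses to N.
_NORMALIZE = str.maketrans(
    {c: "N" for c in "RYSWKMBDHVUryswkmbdhvu"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised when an input file violates FASTA expectations."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse ambiguity codes to N.

    Idempotent: ``normalize_sequence(normalize_sequence(s)) == normalize_sequence(s)``.
    Characters outside the IUPAC alphabet raise ``FastaFormatError``.
    """
    s = seq.upper().translate(_NORMALIZE)
    bad = set(s) - _VALID
    if bad:
        raise FastaFormatError(
            f"sequence contains non-nucleotide characters: {sorted(bad)!r}"
        )
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    """An identified set of nucleotide contigs.

    Parameters
    ----------
    genome_id
        Non-empty label, unique among genomes in a run.
    contigs
        Ordered ``(contig_id, sequence)`` pairs; sequences are normalized
        uppercase strings over {A,C,G,T,N}.
    """

    genome_id: str
    contigs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate contig ids in genome {self.genome_id!r}")
        object.__setattr__(
            self,
            "contigs",
            tuple((cid, normalize_sequence(seq)) for cid, seq in self.contigs),
        )

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    def contig_dict(self) -> dict[str, str]:
        return dict(self.contigs)

    def reverse_complemented(self) -> "Genome":
        """Genome with every contig reverse-complemented (testing aid)."""
        return Genome(
            self.genome_id,
            tuple((cid, reverse_complement(seq)) for cid, seq in self.contigs),
        )


@dataclass(frozen=True)
class CDSRecord:
    """A predicted coding sequence.

    ``start``/``end`` are 0-based half-open on the contig's forward strand;
    ``sequence`` is read 5'->3' on the coding strand, so for ``strand == '-'``
    it is the reverse complement of the contig slice.
    """

    cds_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"{self.cds_id}: span {self.end - self.start} != sequence length "
                f"{len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fasta(path: str | os.PathLike, genome_id: str | None = None) -> Genome:
    """Read a (multi-record, multi-line) FASTA file as one Genome.

    The first non-blank line must start with ``>``; records with empty
    sequences are rejected. ``genome_id`` defaults to the file stem.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first:
            raise FastaFormatError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FastaFormatError(
                f"{path}: first line must start with '>' (strict FASTA); "
                f"got {first.strip()[:40]!r}"
            )
    contigs: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has empty sequence")
        try:
            contigs.append((rec.id, normalize_sequence(seq)))
        except FastaFormatError as exc:
            raise FastaFormatError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not contigs:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return Genome(genome_id or path.stem.removesuffix(".fa").removesuffix(".fasta"),
                  tuple(contigs))


def write_fasta(
    records: Iterable[tuple[str, str]],
    path: str | os.PathLike,
    line_width: int = 70,
) -> None:
    """Write ``(id, sequence)`` pairs as FASTA; round-trips with read_fasta."""
    records = list(records)
    ids = [rid for rid, _ in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate record ids in FASTA output")
    if any(not rid for rid in ids):
        raise ValueError("empty record id in FASTA output")
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def write_genome_fasta(genome: Genome, path: str | os.PathLike,
                       line_width: int = 70) -> None:
    write_fasta(genome.contigs, path, line_width=line_width)


def write_cds_bed(cds_list: Sequence[CDSRecord], path: str | os.PathLike) -> None:
    """BED6 of CDS coordinates (0-based half-open, strand in column 6)."""
    with open(path, "w") as fh:
        for cds in cds_list:
            fh.write(
                f"{cds.contig_id}\t{cds.start}\t{cds.end}\t{cds.cds_id}\t0\t"
                f"{cds.strand}\n"
            )
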