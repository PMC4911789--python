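"""Synthetic bacterial genomes with planted genes and controlled divergence.

`random_genome` builds a uniform-random background with non-overlapping
planted protein-coding ORFs (valid start, no internal in-frame stop, valid
stop, random strand). Each planted cassette carries an in-frame stop codon
immediately upstream of the start codon, so that under the
first-start-after-stop ORF convention the planted coordinates are the
unique ground truth the ORF scanner should recover.

`evolve` derives a diverged copy: whole-gene loss, then short indels, then
point substitutions (uniform over the three alternative bases), all
reproducible from the seed. At substitution rate d the expected nucleotide
identity of homologous regions is 100*(1-d), which is what the ANI
pipeline should recover.

The generator emulates base composition and gene density only; it has no
codon-usage bias, GC skew, rearrangements or horizontal transfer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from anikit.genome_io import CDSRecord, Genome, reverse_complement
from anikit.orf_finder import START_CODONS, STOP_CODONS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = tuple(sorted(STOP_CODONS))


@dataclass(frozen=True)
class EvolveParams:
    """Divergence parameters for `evolve`.

    substitution_rate : per-site substitution probability d in [0, 0.3];
        substituted sites always receive one of the 3 alternative bases.
    indel_rate : per-site probability of starting an indel event.
    indel_max_len : indel lengths are uniform on [1, indel_max_len].
    gene_loss_fraction : fraction of planted genes whose spans are deleted.
    seed : RNG seed; the whole trajectory is reproducible from it.
    """

    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    indel_max_len: int = 5
    gene_loss_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate <= 0.3:
            raise ValueError("substitution_rate must be in [0, 0.3]")
        for name in ("indel_rate", "gene_loss_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.indel_max_len < 1:
            raise ValueError("indel_max_len must be >= 1")


@dataclass(frozen=True)
class EvolutionOutcome:
    """An evolved genome plus the realized event counts."""

    genome: Genome
    n_substitutions: int
    n_insertion_events: int
    n_deletion_events: int
    lost_gene_ids: tuple[str, ...]


def _random_codon(rng: np.random.Generator, avoid_stops: bool) -> str:
    while True:
        codon = "".join("ACGT"[b] for b in rng.integers(0, 4, 3))
        if not avoid_stops or codon not in STOP_CODONS:
            return codon


def _planted_gene_seq(rng: np.random.Generator, length: int) -> str:
    """A valid CDS: start codon, stop-free body, stop codon."""
    assert length % 3 == 0 and length >= 9
    start = sorted(START_CODONS)[int(rng.integers(0, len(START_CODONS)))]
    n_body = length // 3 - 2
    body = "".join(_random_codon(rng, avoid_stops=True) for _ in range(n_body))
    stop = _STOPS[int(rng.integers(0, len(_STOPS)))]
    return start + body + stop


def random_genome(
    length: int,
    n_genes: int,
    gene_len_range: tuple[int, int] = (300, 900),
    seed: int = 0,
    genome_id: str = "synthetic",
) -> tuple[Genome, list[CDSRecord]]:
    """Single-contig random genome with planted non-overlapping genes.

    Gene lengths are multiples of 3 drawn uniformly from ``gene_len_range``;
    each gene goes on a random strand and is preceded (in its reading
    direction) by an in-frame stop codon so the planted coordinates are
    exactly recoverable. Returns the genome and the ground-truth CDS
    records sorted by start. Fully reproducible from ``seed``.
    """
    lo, hi = gene_len_range
    if lo < 9 or hi < lo:
        raise ValueError("gene_len_range must satisfy 9 <= min <= max")
    if n_genes * hi > 0.8 * length:
        raise ValueError(
            f"infeasible packing: {n_genes} genes of up to {hi} bp do not fit "
            f"in 0.8 * {length} bp"
        )
    rng = np.random.default_rng(seed)
    seq = np.array(rng.choice(_BASES, size=length), dtype=np.uint8)

    # choose gene lengths (multiples of 3) and non-overlapping placements
    placements: list[tuple[int, int, str]] = []  # (start, end, strand) of cassette
    margin = 3  # upstream in-frame stop codon
    for _ in range(n_genes):
        glen = 3 * int(rng.integers(lo // 3 + (lo % 3 > 0), hi // 3 + 1))
        placed = False
        for _attempt in range(200):
            pos = int(rng.integers(0, length - glen - margin))
            cass = (pos, pos + glen + margin)
            if all(
                cass[1] + 3 <= s or cass[0] >= e + 3 for s, e, _ in placements
            ):
                strand = "+" if rng.random() < 0.5 else "-"
                placements.append((cass[0], cass[1], strand))
                placed = True
                break
        if not placed:
            raise ValueError(
                "infeasible packing: could not place all genes after 200 "
                "retries each; reduce n_genes or gene lengths"
            )
    placements.sort()

    genes: list[CDSRecord] = []
    text = seq.tobytes().decode()
    chars = list(text)
    for k, (cstart, cend, strand) in enumerate(placements, start=1):
        glen = cend - cstart - margin
        stop = _STOPS[int(rng.integers(0, len(_STOPS)))]
        gene = _planted_gene_seq(rng, glen)
        cassette = stop + gene  # stop codon immediately upstream, in frame
        if strand == "-":
            cassette = reverse_complement(cassette)
            gstart, gend = cstart, cstart + glen
            gene_seq = gene
        else:
            gstart, gend = cstart + margin, cend
            gene_seq = gene
        chars[cstart:cend] = cassette
        genes.append(
            CDSRecord(
                cds_id=f"{genome_id}_gene{k}",
                genome_id=genome_id,
                contig_id=f"{genome_id}_contig1",
                start=gstart,
                end=gend,
                strand=strand,
                sequence=gene_seq,
            )
        )
    genome = Genome(genome_id, ((f"{genome_id}_contig1", "".join(chars)),))
    return genome, genes


def evolve(
    genome: Genome,
    params: EvolveParams,
    planted_genes: Sequence[CDSRecord] = (),
) -> EvolutionOutcome:
    """Derive a diverged copy of a genome.

    Events are applied in a fixed order — whole-gene loss, short indels,
    point substitutions — so realized counts are reproducible from the
    seed. Gene loss requires ``planted_genes`` (ground truth from
    `random_genome`); only single-contig genomes support loss/indels of
    planted spans.
    """
    rng = np.random.default_rng(params.seed)
    contigs = []
    lost_ids: tuple[str, ...] = ()
    n_sub_total = 0
    n_ins_total = 0
    n_del_total = 0
    for contig_id, seq in genome.contigs:
        # 1) whole-gene loss
        if params.gene_loss_fraction > 0 and planted_genes:
            here = [g for g in planted_genes if g.contig_id == contig_id]
            n_lose = int(round(params.gene_loss_fraction * len(here)))
            idx = rng.choice(len(here), size=n_lose, replace=False) if n_lose else []
            lose = sorted((here[int(i)] for i in idx), key=lambda g: -g.start)
            lost_ids = tuple(sorted(g.cds_id for g in lose))
            for g in lose:
                seq = seq[: g.start] + seq[g.end :]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        # 2) short indels
        if params.indel_rate > 0:
            n_sites = len(arr)
            hits = np.nonzero(rng.random(n_sites) < params.indel_rate)[0]
            pieces: list[np.ndarray] = []
            prev = 0
            for pos in hits:
                if pos < prev:  # swallowed by a previous deletion
                    continue
                ln = int(rng.integers(1, params.indel_max_len + 1))
                if rng.random() < 0.5:  # insertion after pos
                    ins = rng.choice(_BASES, size=ln).astype(np.uint8)
                    pieces.append(arr[prev : pos + 1])
                    pieces.append(ins)
                    prev = pos + 1
                    n_ins_total += 1
                else:  # deletion starting at pos
                    pieces.append(arr[prev:pos])
                    prev = min(pos + ln, n_sites)
                    n_del_total += 1
            pieces.append(arr[prev:])
            arr = np.concatenate(pieces)
        # 3) point substitutions (uniform over the 3 alternatives)
        if params.substitution_rate > 0:
            enc = np.full(len(arr), 4, dtype=np.uint8)
            for i, c in enumerate(b"ACGT"):
                enc[arr == c] = i
            sites = np.nonzero(
                (rng.random(len(arr)) < params.substitution_rate) & (enc < 4)
            )[0]
            shift = rng.integers(1, 4, size=len(sites)).astype(np.uint8)
            enc[sites] = (enc[sites] + shift) % 4
            n_sub_total += len(sites)
            arr = np.where(enc < 4, _BASES[np.minimum(enc, 3)], ord("N")).astype(
                np.uint8
            )
        contigs.append((contig_id, arr.tobytes().decode()))
    return EvolutionOutcome(
        genome=Genome(genome_id=genome.genome_id + "_evolved", contigs=tuple(contigs)),
        n_substitutions=n_sub_total,
        n_insertion_events=n_ins_total,
        n_deletion_events=n_del_total,
        lost_gene_ids=lost_ids,
    )


def write_fixture(
    genome: Genome,
    genes: Sequence[CDSRecord],
    fasta_path,
    truth_json_path,
    outcome: EvolutionOutcome | None = None,
) -> None:
    """Write a fixture FASTA plus ground-truth JSON for the test suite."""
    from anikit.genome_io import write_genome_fasta

    write_genome_fasta(genome, fasta_path)
    truth = {
        "genome_id": genome.genome_id,
        "total_length": genome.total_length,
        "genes": [
            {
                "cds_id": g.cds_id,
                "contig_id": g.contig_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
            }
            for g in genes
        ],
    }
    if outcome is not None:
        truth["realized_events"] = {
            "substitutions": outcome.n_substitutions,
            "insertion_events": outcome.n_insertion_events,
            "deletion_events": outcome.n_deletion_events,
            "lost_gene_ids": list(outcome.lost_gene_ids),
        }
    with open(truth_json_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
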