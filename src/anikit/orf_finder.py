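"""Deterministic ORF-scan gene prediction.

This is the desk-scale stand-in for a trained gene caller: on each contig,
both strands and all three frames are scanned for maximal open reading
frames — from the first in-frame start codon after the previous in-frame
stop (the contig edge counts as a stop boundary) through the next in-frame
stop codon, stop included. ORFs shorter than ``min_length`` are discarded,
and overlaps beyond ``max_overlap`` are resolved greedily in favor of the
longer ORF. The defaults (min length 110 bp, max overlap 50 bp) mirror the
classic Glimmer settings ``-g110 -o50``. No coding-potential model is
applied: spurious short ORFs are expected and are removed downstream by the
identity/coverage filters, which modest over-prediction does not disturb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from anikit.genome_io import CDSRecord, Genome, reverse_complement

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfParams:
    """Gene-prediction parameters.

    min_length : minimum ORF span in bp (start through stop codon), default 110.
    max_overlap : maximum tolerated genomic overlap between retained ORFs, bp.
    """

    min_length: int = 110
    max_overlap: int = 50
    start_codons: frozenset[str] = START_CODONS
    stop_codons: frozenset[str] = STOP_CODONS

    def __post_init__(self) -> None:
        if self.min_length < 6:
            raise ValueError("min_length must be >= 6 (one start + one stop codon)")
        if self.max_overlap < 0:
            raise ValueError("max_overlap must be >= 0")


def _scan_strand(seq: str, params: OrfParams) -> list[tuple[int, int]]:
    """Maximal ORF spans (0-based half-open) on the forward reading of seq."""
    n = len(seq)
    spans: list[tuple[int, int]] = []
    for frame in range(3):
        start_pos: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in params.stop_codons:
                if start_pos is not None and pos + 3 - start_pos >= params.min_length:
                    spans.append((start_pos, pos + 3))
                start_pos = None
            elif start_pos is None and codon in params.start_codons:
                start_pos = pos
        # a frame that never hits a stop after the last start yields no ORF
    return spans


def find_orfs(genome: Genome, params: OrfParams | None = None) -> list[CDSRecord]:
    """Predict maximal ORFs on both strands of every contig.

    Returns CDS records sorted by (contig order, start); ids are
    ``<genome_id>_cds<k>`` with k assigned in that order, starting at 1.
    """
    params = params or OrfParams()
    raw: list[tuple[int, int, int, str, str]] = []  # (contig_idx, start, end, strand, seq)
    for ci, (contig_id, seq) in enumerate(genome.contigs):
        for s, e in _scan_strand(seq, params):
            raw.append((ci, s, e, "+", seq[s:e]))
        rc = reverse_complement(seq)
        L = len(seq)
        for s, e in _scan_strand(rc, params):
            raw.append((ci, L - e, L - s, "-", rc[s:e]))
    raw.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    records = []
    for k, (ci, s, e, strand, cds_seq) in enumerate(raw, start=1):
        records.append(
            CDSRecord(
                cds_id=f"{genome.genome_id}_cds{k}",
                genome_id=genome.genome_id,
                contig_id=genome.contigs[ci][0],
                start=s,
                end=e,
                strand=strand,
                sequence=cds_seq,
            )
        )
    return records


def _overlap(a: CDSRecord, b: CDSRecord) -> int:
    if a.contig_id != b.contig_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def resolve_overlaps(
    orfs: list[CDSRecord], max_overlap: int = 50
) -> list[CDSRecord]:
    """Greedy longest-first overlap resolution.

    ORFs are processed in decreasing length order (ties: smaller start
    first, then '+' strand first); an ORF is retained only if it overlaps
    every already-retained ORF by at most ``max_overlap`` bp. Output keeps
    the (contig, start) sort order of the input.
    """
    order = sorted(
        orfs, key=lambda c: (-c.length, c.start, 0 if c.strand == "+" else 1)
    )
    kept: list[CDSRecord] = []
    for cand in order:
        if all(_overlap(cand, k) <= max_overlap for k in kept):
            kept.append(cand)
    kept_ids = {c.cds_id for c in kept}
    return [c for c in orfs if c.cds_id in kept_ids]


def predict_cds(genome: Genome, params: OrfParams | None = None) -> list[CDSRecord]:
    """find_orfs followed by resolve_overlaps — the pipeline's step 1."""
    params = params or OrfParams()
    return resolve_overlaps(find_orfs(genome, params), params.max_overlap)
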