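"""ANI filtering rules, directed ANI values, and the all-pairs matrix.

A directed comparison aligns the query genome's predicted CDSs against a
target genome and applies three filters:

1. per-hit: at least 60% overall sequence identity (60.0 passes) AND an
   alignable region covering strictly more than 70% of the CDS length;
2. per-CDS: among surviving hits only the one with the highest count of
   identical sites is kept (CDSs with no survivor are treated as
   genome-specific and dropped);
3. per-comparison: if the kept hits cover less than 50% of the query
   genome length in total, the whole comparison is filtered out (exactly
   50% passes).

The directed ANI is the unweighted arithmetic mean of the kept best-hit
identities (a length-weighted mean is available via ``weighted=True``).
The all-pairs matrix is symmetrized by averaging the two directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from anikit.aligner import (
    AlignmentHit,
    ScoringScheme,
    align_cds,
    build_seed_index,
)
from anikit.genome_io import CDSRecord, Genome
from anikit.orf_finder import OrfParams, predict_cds


@dataclass(frozen=True)
class FilterParams:
    """Hit- and comparison-level filter thresholds.

    min_identity_pct : inclusive lower bound on hit identity (percent).
    min_alignable_fraction_of_cds : hits must cover strictly more than
        this fraction of the CDS length.
    min_total_alignable_fraction_of_genome : comparisons whose kept hits
        cover less than this fraction of the query genome are invalid
        (equality passes).
    """

    min_identity_pct: float = 60.0
    min_alignable_fraction_of_cds: float = 0.70
    min_total_alignable_fraction_of_genome: float = 0.50

    def __post_init__(self) -> None:
        ident = self.min_identity_pct
        if ident <= 0 or ident > 100:
            raise ValueError("min_identity_pct must be in (0, 100]")
        for name in (
            "min_alignable_fraction_of_cds",
            "min_total_alignable_fraction_of_genome",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class ANIResult:
    """One directed genome comparison."""

    query_genome_id: str
    target_genome_id: str
    ani_pct: float | None
    n_cds_total: int
    n_cds_kept: int
    total_alignable_bp: int
    alignable_fraction: float
    valid: bool

    def to_dict(self) -> dict:
        return {
            "query": self.query_genome_id,
            "target": self.target_genome_id,
            "ani_pct": self.ani_pct,
            "n_cds_total": self.n_cds_total,
            "n_cds_kept": self.n_cds_kept,
            "total_alignable_bp": self.total_alignable_bp,
            "alignable_fraction": self.alignable_fraction,
            "valid": self.valid,
        }


def filter_and_pick_best(
    hits: Sequence[AlignmentHit],
    cds: CDSRecord,
    params: FilterParams | None = None,
) -> AlignmentHit | None:
    """Apply per-hit filters and keep the single best hit for one CDS.

    Survivors need identity >= min_identity_pct and a query span covering
    strictly more than min_alignable_fraction_of_cds of the CDS. Among
    survivors the hit with the most identical sites wins; ties go to
    higher identity, then to the smaller target start coordinate.
    """
    params = params or FilterParams()
    best: AlignmentHit | None = None
    for h in hits:
        span = h.query_span[1] - h.query_span[0]
        if h.identity_pct < params.min_identity_pct:
            continue
        if span <= params.min_alignable_fraction_of_cds * cds.length:
            continue
        if best is None or (
            h.identical_sites,
            h.identity_pct,
            -h.target_span[0],
        ) > (best.identical_sites, best.identity_pct, -best.target_span[0]):
            best = h
    return best


def compute_ani(
    cds_list: Sequence[CDSRecord],
    hits_by_cds: Mapping[str, Sequence[AlignmentHit]],
    query_genome: Genome,
    target_genome_id: str,
    params: FilterParams | None = None,
    weighted: bool = False,
) -> ANIResult:
    """Directed ANI of a query genome against one target.

    ani_pct is the unweighted mean identity of per-CDS best kept hits
    (length-weighted when ``weighted``); it is undefined when fewer than
    half of the query genome bases are covered by kept hits, or when no
    hit survives.
    """
    params = params or FilterParams()
    kept: list[AlignmentHit] = []
    for cds in cds_list:
        best = filter_and_pick_best(hits_by_cds.get(cds.cds_id, ()), cds, params)
        if best is not None:
            kept.append(best)
    total_bp = sum(h.query_span[1] - h.query_span[0] for h in kept)
    glen = query_genome.total_length
    frac = total_bp / glen if glen else 0.0
    valid = bool(
        cds_list
        and kept
        and frac >= params.min_total_alignable_fraction_of_genome
    )
    ani: float | None = None
    if valid:
        if weighted:
            wsum = sum(h.query_span[1] - h.query_span[0] for h in kept)
            ani = sum(
                h.identity_pct * (h.query_span[1] - h.query_span[0]) for h in kept
            ) / wsum
        else:
            ani = sum(h.identity_pct for h in kept) / len(kept)
    return ANIResult(
        query_genome_id=query_genome.genome_id,
        target_genome_id=target_genome_id,
        ani_pct=ani,
        n_cds_total=len(cds_list),
        n_cds_kept=len(kept),
        total_alignable_bp=total_bp,
        alignable_fraction=frac,
        valid=valid,
    )


def compare_genomes(
    query: Genome,
    target: Genome,
    params: FilterParams | None = None,
    scoring: ScoringScheme | None = None,
    orf_params: OrfParams | None = None,
    cds_list: Sequence[CDSRecord] | None = None,
    index=None,
    weighted: bool = False,
) -> ANIResult:
    """Run the full directed comparison query -> target.

    ``cds_list`` / ``index`` allow reuse of predicted CDSs and seed
    indexes across the all-pairs matrix.
    """
    scoring = scoring or ScoringScheme()
    if cds_list is None:
        cds_list = predict_cds(query, orf_params)
    if index is None:
        index = build_seed_index(target, scoring.word_size)
    hits_by_cds = {
        cds.cds_id: align_cds(cds, index, scoring) for cds in cds_list
    }
    return compute_ani(
        cds_list, hits_by_cds, query, target.genome_id, params, weighted=weighted
    )


@dataclass
class ANIMatrix:
    """All-pairs directed ANI results plus the symmetrized grid."""

    genome_ids: list[str]
    results: dict[tuple[str, str], ANIResult]

    @property
    def symmetrized_pct(self) -> np.ndarray:
        """Symmetric grid: mean of the two directed values where both are
        valid, the single valid one otherwise, NaN when neither is;
        diagonal fixed at exactly 100."""
        ids = self.genome_ids
        n = len(ids)
        grid = np.full((n, n), np.nan)
        for i, gi in enumerate(ids):
            grid[i, i] = 100.0
            for j, gj in enumerate(ids):
                if i >= j:
                    continue
                fwd = self.results.get((gi, gj))
                rev = self.results.get((gj, gi))
                vals = [
                    r.ani_pct
                    for r in (fwd, rev)
                    if r is not None and r.valid and r.ani_pct is not None
                ]
                if vals:
                    grid[i, j] = grid[j, i] = float(np.mean(vals))
        return grid

    def symmetrized_value(self, a: str, b: str) -> float:
        grid = self.symmetrized_pct
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        return float(grid[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.symmetrized_pct, index=self.genome_ids, columns=self.genome_ids
        )

    def to_tsv(self, path) -> None:
        """Symmetrized matrix as TSV; undefined entries exported as NA."""
        self.to_dataframe().round(4).to_csv(path, sep="\t", na_rep="NA")

    def to_phylip(self, path) -> None:
        """PHYLIP square distance-style matrix of symmetrized ANI values
        (NA-as-blank is not legal PHYLIP, so undefined entries print 0.0)."""
        grid = self.symmetrized_pct
        with open(path, "w") as fh:
            fh.write(f"{len(self.genome_ids)}\n")
            for gid, row in zip(self.genome_ids, grid):
                vals = " ".join(
                    f"{0.0 if math.isnan(v) else v:.4f}" for v in row
                )
                fh.write(f"{gid[:10]:<10} {vals}\n")


def build_matrix(
    genomes: Sequence[Genome],
    params: FilterParams | None = None,
    scoring: ScoringScheme | None = None,
    orf_params: OrfParams | None = None,
    weighted: bool = False,
) -> ANIMatrix:
    """Directed ANI for every ordered pair of genomes.

    CDS prediction and seed indexing are done once per genome and reused
    across pairs.
    """
    scoring = scoring or ScoringScheme()
    ids = [g.genome_id for g in genomes]
    if len(genomes) < 2:
        raise ValueError("build_matrix needs at least 2 genomes")
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate genome ids: {sorted(ids)}")
    cds_cache = {g.genome_id: predict_cds(g, orf_params) for g in genomes}
    index_cache = {
        g.genome_id: build_seed_index(g, scoring.word_size) for g in genomes
    }
    results: dict[tuple[str, str], ANIResult] = {}
    for q in genomes:
        for t in genomes:
            if q.genome_id == t.genome_id:
                continue
            results[(q.genome_id, t.genome_id)] = compare_genomes(
                q,
                t,
                params,
                scoring,
                orf_params,
                cds_list=cds_cache[q.genome_id],
                index=index_cache[t.genome_id],
                weighted=weighted,
            )
    return ANIMatrix(genome_ids=list(ids), results=results)
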