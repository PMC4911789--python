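"""Local nucleotide alignment: seed-and-extend heuristic plus exact oracle.

The heuristic (`align_cds`) mirrors the BLASTN recipe: exact ``word_size``
k-mer seeds against an indexed target, seeds clustered by diagonal, an
ungapped X-drop extension from the best seed of each cluster, then banded
affine-gap (Gotoh) extension over a window around the cluster. The exact
oracle (`smith_waterman`) runs the same affine-gap local DP with an
unrestricted band and is intended for sequences up to a few kb; it is the
reference the heuristic is tested against.

Scoring: +match for an identical column, mismatch (negative) otherwise —
columns involving N are never identical — and a gap of length L costs
``gap_open + gap_extend * L``. Identity is computed over all alignment
columns including gap columns, matching the BLAST identity denominator.

Dynamic-programming tie-breaks are fixed: the optimum cell with the
smallest (query end, target end) wins, and traceback prefers diagonal over
up (gap in target) over left (gap in query).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from anikit.genome_io import CDSRecord, Genome, reverse_complement

# nucleotide encoding: A=0 C=1 G=2 T=3 N=4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _revcomp_enc(arr: np.ndarray) -> np.ndarray:
    out = np.where(arr < 4, 3 - arr, 4).astype(np.uint8)
    return out[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters (classic BLASTN-style defaults)."""

    match_reward: int = 2
    mismatch_penalty: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 11
    xdrop: int = 20
    band_radius: int = 20

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be > 0")
        if self.mismatch_penalty >= 0:
            raise ValueError("mismatch_penalty must be < 0")
        if self.gap_open < 0 or self.gap_extend < 1:
            raise ValueError("gap_open must be >= 0 and gap_extend >= 1")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.band_radius < 1:
            raise ValueError("band_radius must be >= 1")


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a CDS (or query string) against a target.

    Spans are 0-based half-open; ``query_span`` is on the CDS coding strand
    regardless of ``target_strand``. ``alignment_length`` counts all
    columns including gaps. ``aligned_query``/``aligned_target`` are the
    gapped alignment rows, kept so the score can be recomputed column by
    column.
    """

    cds_id: str
    target_contig: str
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    target_strand: str
    alignment_length: int
    identical_sites: int
    score: int
    aligned_query: str
    aligned_target: str

    @property
    def identity_pct(self) -> float:
        if self.alignment_length == 0:
            return 0.0
        return 100.0 * self.identical_sites / self.alignment_length

    def recompute_score(self, scoring: ScoringScheme) -> int:
        """Re-derive the alignment score from the stored columns."""
        score = 0
        in_gap = False
        for qa, ta in zip(self.aligned_query, self.aligned_target):
            if qa == "-" or ta == "-":
                score -= scoring.gap_extend + (0 if in_gap else scoring.gap_open)
                in_gap = True
            else:
                in_gap = False
                if qa == ta and qa in "ACGT":
                    score += scoring.match_reward
                else:
                    score += scoring.mismatch_penalty
        return score


_NEG = np.int32(-(10**9))


@njit(cache=True)
def _gotoh_local_banded(a, b, dlo, dhi, match, mismatch, go, ge):  # pragma: no cover
    """Affine-gap local DP restricted to diagonals j-i in [dlo, dhi].

    Returns (score, a_start, a_end, b_start, b_end, ops) where ops encodes
    the traceback: 0 = diagonal, 1 = up (consume a), 2 = left (consume b).
    With dlo = -len(a), dhi = len(b) this is the full Smith-Waterman.
    """
    n = a.shape[0]
    m = b.shape[0]
    W = dhi - dlo + 1
    H = np.zeros((n + 1, W), np.int32)
    E = np.full((n + 1, W), _NEG, np.int32)
    F = np.full((n + 1, W), _NEG, np.int32)
    PH = np.zeros((n + 1, W), np.uint8)
    PE = np.zeros((n + 1, W), np.uint8)
    PF = np.zeros((n + 1, W), np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        jlo = i + dlo
        if jlo < 1:
            jlo = 1
        jhi = i + dhi
        if jhi > m:
            jhi = m
        for j in range(jlo, jhi + 1):
            c = j - i - dlo
            # E: gap in a (left move, consume b); neighbor (i, j-1) -> col c-1
            e = _NEG
            pe = np.uint8(0)
            if c - 1 >= 0:
                opn = H[i, c - 1] - go - ge
                ext = E[i, c - 1] - ge
                if opn >= ext:
                    e = opn
                    pe = np.uint8(1)
                else:
                    e = ext
            E[i, c] = e
            PE[i, c] = pe
            # F: gap in b (up move, consume a); neighbor (i-1, j) -> col c+1
            f = _NEG
            pf = np.uint8(0)
            if c + 1 < W:
                opn = H[i - 1, c + 1] - go - ge
                ext = F[i - 1, c + 1] - ge
                if opn >= ext:
                    f = opn
                    pf = np.uint8(1)
                else:
                    f = ext
            F[i, c] = f
            PF[i, c] = pf
            ai = a[i - 1]
            bjc = b[j - 1]
            if ai < 4 and bjc < 4 and ai == bjc:
                s = match
            else:
                s = mismatch
            h = H[i - 1, c] + s  # diagonal neighbor (i-1, j-1) -> same col
            ph = np.uint8(1)
            if f > h:
                h = f
                ph = np.uint8(2)
            if e > h:
                h = e
                ph = np.uint8(3)
            if h <= 0:
                h = np.int32(0)
                ph = np.uint8(0)
            H[i, c] = h
            PH[i, c] = ph
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    ops = np.empty(n + m, np.uint8)
    nops = 0
    i = bi
    j = bj
    state = 0  # 0=H, 2=F, 3=E
    while i > 0 or j > 0:
        c = j - i - dlo
        if state == 0:
            p = PH[i, c]
            if p == 0:
                break
            if p == 1:
                ops[nops] = 0
                nops += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            p = PF[i, c]
            ops[nops] = 1
            nops += 1
            i -= 1
            if p == 1:
                state = 0
        else:
            p = PE[i, c]
            ops[nops] = 2
            nops += 1
            j -= 1
            if p == 1:
                state = 0
    return best, i, bi, j, bj, ops[:nops][::-1].copy()


@njit(cache=True)
def _xdrop_ungapped(q, t, qs, ts, klen, match, mismatch, xdrop):  # pragma: no cover
    """Ungapped X-drop extension of an exact seed q[qs:qs+klen]==t[ts:ts+klen].

    Returns (q_lo, q_hi, t_lo, t_hi, score) of the best ungapped segment.
    """
    n = q.shape[0]
    m = t.shape[0]
    score = klen * match
    # right
    best = score
    cur = score
    qi = qs + klen
    ti = ts + klen
    q_hi = qi
    t_hi = ti
    while qi < n and ti < m:
        if q[qi] < 4 and q[qi] == t[ti]:
            cur += match
        else:
            cur += mismatch
        qi += 1
        ti += 1
        if cur > best:
            best = cur
            q_hi = qi
            t_hi = ti
        elif best - cur > xdrop:
            break
    # left
    score = best
    cur = best
    qi = qs
    ti = ts
    q_lo = qs
    t_lo = ts
    while qi > 0 and ti > 0:
        qi -= 1
        ti -= 1
        if q[qi] < 4 and q[qi] == t[ti]:
            cur += match
        else:
            cur += mismatch
        if cur > score:
            score = cur
            q_lo = qi
            t_lo = ti
        elif score - cur > xdrop:
            break
    return q_lo, q_hi, t_lo, t_hi, score


def _ops_to_rows(
    a: str, b: str, a_start: int, b_start: int, ops: np.ndarray
) -> tuple[str, str, int]:
    """Materialize gapped rows from traceback ops; returns (row_a, row_b, n_ident)."""
    ra: list[str] = []
    rb: list[str] = []
    i, j = a_start, b_start
    ident = 0
    for op in ops:
        if op == 0:
            ca, cb = a[i], b[j]
            ra.append(ca)
            rb.append(cb)
            if ca == cb and ca in "ACGT":
                ident += 1
            i += 1
            j += 1
        elif op == 1:
            ra.append(a[i])
            rb.append("-")
            i += 1
        else:
            ra.append("-")
            rb.append(b[j])
            j += 1
    return "".join(ra), "".join(rb), ident


def smith_waterman(
    a: str, b: str, scoring: ScoringScheme | None = None
) -> AlignmentHit:
    """Optimal affine-gap local alignment of two nucleotide strings.

    Full dynamic programming with no heuristics; intended for sequences up
    to a few kb. Returns a zero-score hit with empty spans when no
    positive-scoring local alignment exists.
    """
    scoring = scoring or ScoringScheme()
    if not a or not b:
        raise ValueError("smith_waterman requires non-empty sequences")
    ea, eb = encode(a), encode(b)
    score, ai, aj, bi, bj, ops = _gotoh_local_banded(
        ea,
        eb,
        -len(a),
        len(b),
        scoring.match_reward,
        scoring.mismatch_penalty,
        scoring.gap_open,
        scoring.gap_extend,
    )
    if score <= 0:
        return AlignmentHit(
            "query", "subject", (0, 0), (0, 0), "+", 0, 0, 0, "", ""
        )
    row_a, row_b, ident = _ops_to_rows(a, b, ai, bi, ops)
    return AlignmentHit(
        cds_id="query",
        target_contig="subject",
        query_span=(ai, aj),
        target_span=(bi, bj),
        target_strand="+",
        alignment_length=len(ops),
        identical_sites=ident,
        score=int(score),
        aligned_query=row_a,
        aligned_target=row_b,
    )


class SeedIndex:
    """Exact k-mer lookup table over a target genome.

    Contigs are concatenated with runs of N (never indexed) between them;
    k-mers containing N are excluded. Both strands are handled at query
    time by also scanning the reverse complement of each query.
    """

    def __init__(self, target: Genome, word_size: int = 11) -> None:
        if word_size < 4:
            raise ValueError("word_size must be >= 4")
        self.target = target
        self.word_size = word_size
        sep = 100  # wide enough that no banded extension bridges contigs
        parts: list[np.ndarray] = []
        starts: list[int] = []
        pos = 0
        for cid, seq in target.contigs:
            starts.append(pos)
            parts.append(encode(seq))
            pos += len(seq)
            parts.append(np.full(sep, 4, dtype=np.uint8))
            pos += sep
        self.encoded = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        self.contig_starts = np.asarray(starts, dtype=np.int64)
        self.contig_lengths = np.asarray(
            [len(seq) for _, seq in target.contigs], dtype=np.int64
        )
        self.contig_ids = [cid for cid, _ in target.contigs]
        self._index = _build_kmer_dict(self.encoded, word_size)

    def lookup(self, code: int) -> np.ndarray:
        """Positions (in concatenated coordinates) of an encoded k-mer."""
        return self._index.get(code, _EMPTY_POSITIONS)

    def locate(self, pos: int) -> tuple[int, int]:
        """Map a concatenated coordinate to (contig index, offset)."""
        ci = int(np.searchsorted(self.contig_starts, pos, side="right")) - 1
        return ci, pos - int(self.contig_starts[ci])


_EMPTY_POSITIONS = np.empty(0, dtype=np.int64)


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, codes) of all N-free k-mers in an encoded sequence."""
    n = len(enc)
    if n < k:
        return _EMPTY_POSITIONS, _EMPTY_POSITIONS
    valid = enc < 4
    ok = np.ones(n - k + 1, dtype=bool)
    # window contains an N iff any of the k offsets is invalid
    for off in range(k):
        ok &= valid[off : off + n - k + 1]
    codes = np.zeros(n - k + 1, dtype=np.int64)
    e = enc.astype(np.int64)
    for off in range(k):
        codes = codes * 4 + np.where(valid[off : off + n - k + 1],
                                     e[off : off + n - k + 1], 0)
    pos = np.nonzero(ok)[0].astype(np.int64)
    return pos, codes[pos]


def _build_kmer_dict(enc: np.ndarray, k: int) -> dict[int, np.ndarray]:
    pos, codes = _kmer_codes(enc, k)
    if len(pos) == 0:
        return {}
    order = np.argsort(codes, kind="stable")
    codes_s = codes[order]
    pos_s = pos[order]
    boundaries = np.nonzero(np.diff(codes_s))[0] + 1
    chunks = np.split(pos_s, boundaries)
    uniq = codes_s[np.concatenate(([0], boundaries))] if len(codes_s) else codes_s
    return {int(c): np.sort(chunk) for c, chunk in zip(uniq, chunks)}


def build_seed_index(target: Genome, word_size: int = 11) -> SeedIndex:
    """Build the exact-match k-mer index used by `align_cds`."""
    return SeedIndex(target, word_size)


def _cluster_seeds(
    seeds: list[tuple[int, int, int]], band_radius: int, join_gap: int
) -> list[list[tuple[int, int, int]]]:
    """Group (diag, tpos, qpos) seeds into diagonal-band clusters."""
    seeds.sort()
    clusters: list[list[tuple[int, int, int]]] = []
    for seed in seeds:
        if (
            clusters
            and seed[0] - clusters[-1][-1][0] <= band_radius
            and abs(seed[1] - clusters[-1][-1][1]) <= join_gap
        ):
            clusters[-1].append(seed)
        else:
            clusters.append([seed])
    return clusters


def align_cds(
    cds: CDSRecord,
    index: SeedIndex,
    scoring: ScoringScheme | None = None,
) -> list[AlignmentHit]:
    """Seed-and-extend local alignment of one CDS against an indexed genome.

    Both orientations of the CDS are scanned for exact word matches; each
    diagonal cluster of seeds is extended (ungapped X-drop, then banded
    affine-gap DP over a window around the cluster). Hits with positive
    score are deduplicated so that no two reported hits overlap on the
    query by more than ``word_size`` bases, and returned sorted by
    descending score.
    """
    scoring = scoring or ScoringScheme()
    k = scoring.word_size
    if len(cds.sequence) < k:
        return []
    hits: list[AlignmentHit] = []
    q_fwd = encode(cds.sequence)
    n = len(q_fwd)
    for strand, q_enc in (("+", q_fwd), ("-", _revcomp_enc(q_fwd))):
        qpos, qcodes = _kmer_codes(q_enc, k)
        seeds: list[tuple[int, int, int]] = []
        for qp, code in zip(qpos, qcodes):
            for tp in index.lookup(int(code)):
                seeds.append((int(tp) - int(qp), int(tp), int(qp)))
        if not seeds:
            continue
        for cluster in _cluster_seeds(seeds, scoring.band_radius, max(1000, n)):
            hit = _extend_cluster(cds, q_enc, strand, cluster, index, scoring)
            if hit is not None:
                hits.append(hit)
    hits.sort(
        key=lambda h: (-h.score, h.target_contig, h.target_span, h.target_strand)
    )
    kept: list[AlignmentHit] = []
    for h in hits:
        qs, qe = h.query_span
        if all(
            min(qe, kh.query_span[1]) - max(qs, kh.query_span[0]) <= k
            for kh in kept
        ):
            kept.append(h)
    return kept


def _extend_cluster(
    cds: CDSRecord,
    q_enc: np.ndarray,
    strand: str,
    cluster: list[tuple[int, int, int]],
    index: SeedIndex,
    scoring: ScoringScheme,
) -> AlignmentHit | None:
    k = scoring.word_size
    n = len(q_enc)
    # ungapped X-drop from the seed with the most central query position
    diag0, tp0, qp0 = max(
        cluster, key=lambda s: -abs(s[2] - (n - k) // 2)
    )
    q_lo, q_hi, t_lo, t_hi, _score0 = _xdrop_ungapped(
        q_enc,
        index.encoded,
        qp0,
        tp0,
        k,
        scoring.match_reward,
        scoring.mismatch_penalty,
        scoring.xdrop,
    )
    diags = [s[0] for s in cluster]
    dmin, dmax = min(diags), max(diags)
    # window on the target large enough for the whole query plus band slack
    pad = scoring.band_radius + 10
    ci, _ = index.locate(cluster[0][1])
    c_start = int(index.contig_starts[ci])
    c_end = c_start + int(index.contig_lengths[ci])
    t_min = min(min(s[1] for s in cluster), t_lo)
    t_max = max(max(s[1] + k for s in cluster), t_hi)
    q_min = min(min(s[2] for s in cluster), q_lo)
    q_max = max(max(s[2] + k for s in cluster), q_hi)
    w_start = max(c_start, t_min - q_min - pad)
    w_end = min(c_end, t_max + (n - q_max) + pad)
    if w_end - w_start < k:
        return None
    window = index.encoded[w_start:w_end]
    dlo = dmin - w_start - scoring.band_radius
    dhi = dmax - w_start + scoring.band_radius
    score, a_s, a_e, b_s, b_e, ops = _gotoh_local_banded(
        q_enc,
        window,
        dlo,
        dhi,
        scoring.match_reward,
        scoring.mismatch_penalty,
        scoring.gap_open,
        scoring.gap_extend,
    )
    if score <= 0 or len(ops) == 0:
        return None
    q_str = cds.sequence if strand == "+" else reverse_complement(cds.sequence)
    w_str = "".join("ACGTN"[v] for v in window)
    row_q, row_t, ident = _ops_to_rows(q_str, w_str, a_s, b_s, ops)
    t_span = (w_start - c_start + b_s, w_start - c_start + b_e)
    if strand == "+":
        q_span = (a_s, a_e)
    else:
        q_span = (n - a_e, n - a_s)
    return AlignmentHit(
        cds_id=cds.cds_id,
        target_contig=index.contig_ids[ci],
        query_span=q_span,
        target_span=t_span,
        target_strand=strand,
        alignment_length=len(ops),
        identical_sites=ident,
        score=int(score),
        aligned_query=row_q,
        aligned_target=row_t,
    )


def hits_to_tabular(hits: Sequence[AlignmentHit]) -> str:
    """BLAST outfmt-6-style rows (1-based inclusive coordinates).

    Columns: query id, subject id, % identity, alignment length, mismatches,
    gap opens, q.start, q.end, s.start, s.end, score, "NA" (no E-value).
    """
    lines = []
    for h in hits:
        gaps = mism = 0
        in_gap = False
        for qa, ta in zip(h.aligned_query, h.aligned_target):
            if qa == "-" or ta == "-":
                if not in_gap:
                    gaps += 1
                in_gap = True
            else:
                in_gap = False
                if qa != ta or qa not in "ACGT":
                    mism += 1
        qs, qe = h.query_span
        ts, te = h.target_span
        if h.target_strand == "-":
            s_start, s_end = te, ts + 1
        else:
            s_start, s_end = ts + 1, te
        lines.append(
            f"{h.cds_id}\t{h.target_contig}\t{h.identity_pct:.2f}\t"
            f"{h.alignment_length}\t{mism}\t{gaps}\t{qs + 1}\t{qe}\t"
            f"{s_start}\t{s_end}\t{h.score}\tNA"
        )
    return "\n".join(lines) + ("\n" if lines else "")
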