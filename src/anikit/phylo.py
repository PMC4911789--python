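"""ANI matrix -> distance matrix -> neighbor-joining tree.

Distance is ``100 - symmetrized ANI`` — the simplest strictly decreasing
map, which preserves NJ topology on well-separated data. Undefined ANI
entries (both directions filtered out) are capped at distance 100 with a
logged warning. The tree step is standard Saitou-Nei neighbor joining
with deterministic tie-breaking (the smallest index pair wins) and the
usual post-processing of negative branch lengths: clamped to zero with
the deficit transferred to the sibling branch so leaf-path distances are
preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from anikit.ani import ANIMatrix

logger = logging.getLogger(__name__)

DISTANCE_CAP = 100.0


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal, non-negative

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n},{n})")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(d < 0):
            raise ValueError("distance matrix has negative entries")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")


@dataclass(frozen=True)
class PhyloTree:
    newick: str
    leaf_labels: tuple[str, ...]


def ani_to_distance(matrix: ANIMatrix) -> DistanceMatrix:
    """Convert a symmetrized ANI grid to distances d = 100 - ANI.

    Undefined entries (NaN: comparison filtered in both directions) are
    set to the cap value 100, with a warning listing the affected pairs.
    Requires >= 3 genomes; with fewer, no tree is produced and callers
    should fall back to the pairwise report.
    """
    ids = tuple(matrix.genome_ids)
    if len(ids) < 3:
        raise ValueError(
            "ani_to_distance needs >= 3 genomes; for 2 genomes use the "
            "pairwise ANI report (no tree is produced)"
        )
    grid = matrix.symmetrized_pct
    d = 100.0 - grid
    undefined = [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if np.isnan(grid[i, j])
    ]
    if undefined:
        logger.warning(
            "ANI undefined for %d pair(s) %s; capping distance at %.0f",
            len(undefined),
            undefined,
            DISTANCE_CAP,
        )
        d = np.where(np.isnan(d), DISTANCE_CAP, d)
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(ids=ids, d=d)


class _Node:
    __slots__ = ("label", "children")  # children: list of (child, branch_length)

    def __init__(self, label: str | None = None) -> None:
        self.label = label
        self.children: list[tuple["_Node", float]] = []

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(
            f"{child.newick()}:{bl:.6f}" for child, bl in self.children
        )
        return f"({inner})"


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sibling."""
    if la < 0:
        lb = max(lb + la, 0.0)
        la = 0.0
    elif lb < 0:
        la = max(la + lb, 0.0)
        lb = 0.0
    return la, lb


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Deterministic: among ties in the Q criterion the smallest (i, j)
    index pair is joined. The result is an unrooted tree serialized as
    Newick with a trifurcating root and 6-decimal branch lengths.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dm.d.astype(float).copy()
    nodes: list[_Node] = [_Node(label=str(t)) for t in dm.ids]
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest index pair among minima (row-major scan order)
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = _Node()
        parent.children = [(nodes[i], li), (nodes[j], lj)]
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        d = d2
    # join the last three nodes at an unrooted trifurcation
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    lens = [max(v, 0.0) for v in (l0, l1, l2)]
    deficit = sum((l0, l1, l2)) - sum(lens)
    if deficit:  # spread any clamped deficit over the positive branches
        pos = [k for k, v in enumerate(lens) if v > 0]
        for k in pos:
            lens[k] = max(lens[k] + deficit / len(pos), 0.0)
    root = _Node()
    root.children = [(nodes[k], lens[k]) for k in range(3)]
    newick = root.newick() + ";"
    return PhyloTree(newick=newick, leaf_labels=tuple(dm.ids))


def ascii_tree(tree: PhyloTree) -> str:
    """Very small ASCII rendering of the Newick tree for text reports."""
    import io
    import re

    # indent-based rendering by parenthesis depth
    out = io.StringIO()
    depth = 0
    token = ""

    def flush() -> None:
        nonlocal token
        if token.strip():
            label = token.split(":")[0].strip()
            if label:
                out.write("  " * depth + "+- " + label + "\n")
        token = ""

    for ch in tree.newick:
        if ch == "(":
            flush()
            out.write("  " * depth + "+\n")
            depth += 1
        elif ch == ")":
            flush()
            depth -= 1
        elif ch in ",;":
            flush()
        else:
            token += ch
    return out.getvalue()
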