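"""Distance-based phylogeny: pairwise-deletion distances, neighbor joining,
column-bootstrap support, and outgroup rooting.

The shipped distances are the proportion of differing sites (pairwise
deletion) and its Poisson correction d = -ln(1 - p); the distance function is
pluggable, and the 20-state correction d = -(19/20) ln(1 - (20/19) p) for the
uniform-exchange model is provided for calibration work.  Tree building is
the Saitou--Nei neighbor-joining algorithm with lexicographic tie-breaking
and clamp-and-transfer handling of negative branch-length estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .align import AlignedSet, GAP
from .sim import stream_rng
from .trees import Node, Tree

__all__ = [
    "DistanceMatrix",
    "PhyloError",
    "p_distance",
    "poisson_distance",
    "twenty_state_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "root_by_outgroup",
    "midpoint_root",
    "write_phylip",
]

#: minimum shared non-gap columns before a pairwise distance is defined
DEFAULT_MIN_SITES = 20


class PhyloError(ValueError):
    pass


def p_distance(aln: AlignedSet, pair: tuple[str, str], min_sites: int = DEFAULT_MIN_SITES):
    """Proportion of differing sites under pairwise deletion.

    Only columns where both rows are non-gap count.  Returns ``(p, n_sites)``;
    ``p`` is ``nan`` (undefined) when fewer than ``min_sites`` columns are
    shared.
    """
    a, b = (aln.row(s) for s in pair)
    n = diff = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            n += 1
            if x != y:
                diff += 1
    if n < min_sites:
        return float("nan"), n
    return diff / n, n


def poisson_distance(p: float) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p); nan at saturation."""
    if math.isnan(p) or p >= 1.0:
        return float("nan")
    if p < 0:
        raise ValueError("p must be >= 0")
    return -math.log(1.0 - p)


def twenty_state_distance(p: float) -> float:
    """Exact correction for the uniform 20-state exchange model:
    d = -(19/20) ln(1 - (20/19) p); nan at saturation (p >= 19/20)."""
    if math.isnan(p) or p >= 19.0 / 20.0:
        return float("nan")
    if p < 0:
        raise ValueError("p must be >= 0")
    return -(19.0 / 20.0) * math.log(1.0 - (20.0 / 19.0) * p)


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # square, symmetric, zero diagonal; nan = undefined
    n_sites: np.ndarray  # usable columns per pair

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if math.isnan(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out


def distance_matrix(
    aln: AlignedSet,
    correction: Callable[[float], float] = poisson_distance,
    min_sites: int = DEFAULT_MIN_SITES,
) -> DistanceMatrix:
    """All pairwise corrected distances from an alignment."""
    n = len(aln.ids)
    vals = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            p, ns = p_distance(aln, (aln.ids[i], aln.ids[j]), min_sites=min_sites)
            d = correction(p)
            vals[i, j] = vals[j, i] = d
            sites[i, j] = sites[j, i] = ns
    return DistanceMatrix(list(aln.ids), vals, sites)


def write_phylip(dm: DistanceMatrix, path) -> None:
    """PHYLIP-style square distance matrix (relaxed names, tab-separated)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, name in enumerate(dm.ids):
            row = "\t".join(format(x, ".6f") for x in dm.values[i])
            fh.write(f"{name}\t{row}\n")


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou--Nei neighbor joining; returns an unrooted tree represented
    with a trifurcating root.

    At each step the pair minimising Q(i,j) = (r-2) d(i,j) - R_i - R_j is
    joined (ties broken by the lexicographically smallest sorted id pair);
    branch lengths follow the standard split formula, with negative
    estimates clamped to 0 and the deficit transferred to the sibling branch
    so the pair's path length is preserved.
    """
    if len(dm.ids) < 3:
        raise PhyloError("neighbor joining needs >= 3 taxa")
    bad = dm.undefined_pairs()
    if bad:
        raise PhyloError(f"undefined distances for pairs: {bad}")

    nodes: dict[int, Node] = {i: Node(name) for i, name in enumerate(dm.ids)}
    reps: dict[int, str] = {i: name for i, name in enumerate(dm.ids)}
    d: dict[frozenset, float] = {
        frozenset((i, j)): float(dm.values[i, j])
        for i in range(len(dm.ids))
        for j in range(i + 1, len(dm.ids))
    }
    active = set(nodes)
    nxt = len(dm.ids)

    def dist(i, j):
        return d[frozenset((i, j))]

    while len(active) > 3:
        r = len(active)
        R = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for i in active:
            for j in active:
                if i >= j:
                    continue
                q = (r - 2) * dist(i, j) - R[i] - R[j]
                key = (q, *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (R[i] - R[j]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        a, b = nodes[i], nodes[j]
        a.length, b.length = li, lj
        parent.add_child(a)
        parent.add_child(b)
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            d[frozenset((nxt, k))] = dk
        active -= {i, j}
        nodes[nxt] = parent
        reps[nxt] = min(reps[i], reps[j])
        active.add(nxt)
        nxt += 1

    x, y, z = sorted(active, key=lambda c: reps[c])
    root = Node()
    lx = 0.5 * (dist(x, y) + dist(x, z) - dist(y, z))
    ly = 0.5 * (dist(x, y) + dist(y, z) - dist(x, z))
    lz = 0.5 * (dist(x, z) + dist(y, z) - dist(x, y))
    for c, ln in ((x, lx), (y, ly), (z, lz)):
        nodes[c].length = max(ln, 0.0)
        root.add_child(nodes[c])
    return Tree(root)


# ---------------------------------------------------------------------------
# Bootstrap support
# ---------------------------------------------------------------------------


def bootstrap_support(
    aln: AlignedSet,
    n_reps: int = 1000,
    seed: int = 0,
    correction: Callable[[float], float] = poisson_distance,
    min_sites: int = DEFAULT_MIN_SITES,
    reference: Optional[Tree] = None,
) -> tuple[Tree, int]:
    """Column bootstrap of the NJ tree.

    Columns are resampled with replacement ``n_reps`` times; each replicate is
    rebuilt with NJ; the support of each internal edge of the reference tree
    is the percentage of successful replicates containing its bipartition.
    Replicates with undefined distances are skipped and counted (a warning is
    raised if more than 10% are skipped).  Returns the reference tree with
    supports attached and the number of skipped replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = stream_rng(seed, "bootstrap")
    if reference is None:
        reference = neighbor_joining(distance_matrix(aln, correction, min_sites))
    ref_splits = reference.bipartitions()
    counts = {key: 0 for key in ref_splits}
    skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.width, size=aln.width)
        rows = ["".join(r[j] for j in cols) for r in aln.rows]
        rep_aln = AlignedSet(list(aln.ids), rows)
        dm = distance_matrix(rep_aln, correction, min_sites)
        if dm.undefined_pairs():
            skipped += 1
            continue
        rep_splits = set(neighbor_joining(dm).bipartitions())
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
    used = n_reps - skipped
    if skipped > 0.1 * n_reps:
        warnings.warn(
            f"{skipped}/{n_reps} bootstrap replicates skipped "
            "(undefined distances)"
        )
    for key, node in ref_splits.items():
        node.support = 100.0 * counts[key] / used if used else float("nan")
    return reference, skipped


# ---------------------------------------------------------------------------
# Outgroup rooting
# ---------------------------------------------------------------------------


def _reroot_above(tree: Tree, node: Node, fraction: float = 0.5) -> Tree:
    """Root the (unrooted) tree on the edge above ``node``, placing the new
    root at ``fraction`` of the edge length up from ``node``."""
    edge_len = node.length
    below = edge_len * fraction
    old_parent = node.parent
    node.detach()
    new_root = Node()
    new_root.add_child(node)
    node.length = below

    prev, prev_edge = new_root, edge_len - below
    cur = old_parent
    while cur is not None:
        nxt = cur.parent
        cur_len = cur.length
        cur.detach()
        prev.add_child(cur)
        cur.length = prev_edge
        prev, prev_edge = cur, cur_len
        cur = nxt
    # suppress the old root if it became a unary node
    old_root = prev
    if len(old_root.children) == 1:
        child = old_root.children[0]
        child.detach()
        child.length += old_root.length
        gp = old_root.parent
        old_root.detach()
        gp.add_child(child)
    return Tree(new_root)


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest leaf-to-leaf path (the standard
    fallback when no outgroup is available)."""
    work = tree.copy()
    leaves = sorted(work.leaves(), key=lambda n: n.name)

    def up_chain(n: Node) -> list[tuple[Node, float]]:
        chain, d = [], 0.0
        while n is not None:
            chain.append((n, d))
            d += n.length
            n = n.parent
        return chain

    best = None
    for i, a in enumerate(leaves):
        ua = dict((id(n), d) for n, d in up_chain(a))
        for b in leaves[i + 1 :]:
            x, dx = b, 0.0
            while id(x) not in ua:
                dx += x.length
                x = x.parent
            dist = dx + ua[id(x)]
            if best is None or dist > best[0]:
                best = (dist, a, b)
    total, a, b = best
    half = total / 2.0

    # the a->b path: a up to the meeting node, then down to b
    ua = up_chain(a)
    ua_ids = {id(n) for n, _ in ua}
    bb, dxb = b, 0.0
    b_side: list[tuple[Node, float]] = []  # node and distance from b to its lower end
    while id(bb) not in ua_ids:
        b_side.append((bb, dxb))
        dxb += bb.length
        bb = bb.parent
    meet = bb
    # walk up from a
    cum = 0.0
    for n, d in ua:
        if n is meet:
            break
        if cum + n.length >= half:
            frac = (half - cum) / n.length if n.length else 0.5
            return _reroot_above(work, n, fraction=frac)
        cum += n.length
    # otherwise the midpoint is on b's side: distance from b is total - half
    target = total - half
    cum = 0.0
    for n, d in b_side:
        if cum + n.length >= target:
            frac = (target - cum) / n.length if n.length else 0.5
            return _reroot_above(work, n, fraction=frac)
        cum += n.length
    # degenerate (zero-length path): root above a
    return _reroot_above(work, a, fraction=0.5)


def root_by_outgroup(tree: Tree, outgroup_ids) -> Tree:
    """Root on the edge separating the outgroup from the ingroup.

    If the outgroup is not monophyletic in the unrooted tree, the edge
    maximising outgroup purity on the outgroup side (then outgroup coverage)
    is used and a warning is emitted.  The input tree is not modified.
    """
    out = set(outgroup_ids)
    leaves = set(tree.leaf_names())
    missing = out - leaves
    if missing:
        raise PhyloError(f"outgroup ids not in tree: {sorted(missing)}")
    if out == leaves:
        raise PhyloError("outgroup cannot be all taxa")

    work = tree.copy()
    best = None
    exact = None
    for node in work.postorder():
        if node.parent is None:
            continue
        below = set(node.leaf_names())
        for side in (below, leaves - below):
            inter = len(out & side)
            if inter == 0:
                continue
            purity = inter / len(side)
            coverage = inter / len(out)
            # deterministic tie-break on the sorted side leaf list
            key = (purity, coverage, -len(side), tuple(sorted(side)))
            if best is None or key > best[0]:
                best = (key, node, side)
        if below == out or leaves - below == out:
            exact = node
    if exact is not None:
        return _reroot_above(work, exact)
    warnings.warn("outgroup is not monophyletic; rooting at maximum-purity edge")
    return _reroot_above(work, best[1])
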