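"""Independent reference implementations used only to check the package.

Everything here is deliberately brute force: exhaustive enumeration of
alignments, path-length matrices read off trees, and exhaustive enumeration
of gene-to-species reconciliation maps.  None of it shares code with the
implementation under test.
"""

from __future__ import annotations

import math

import numpy as np

from lygevol.trees import Node, Tree


# ---------------------------------------------------------------------------
# Alignment: exhaustive optimum over all global alignments (affine scoring)
# ---------------------------------------------------------------------------


def brute_force_alignment_score(a: str, b: str, scheme) -> float:
    """Max affine-gap global alignment score by enumerating all alignments."""
    best = -math.inf

    def score_alignment(ga, gb) -> float:
        sc = 0.0
        state = None  # None / "x" (gap in b) / "y" (gap in a)
        for x, y in zip(ga, gb):
            if x != "-" and y != "-":
                sc += scheme.score(x, y)
                state = None
            elif y == "-":
                sc += scheme.gap_extend + (scheme.gap_open if state != "x" else 0.0)
                state = "x"
            else:
                sc += scheme.gap_extend + (scheme.gap_open if state != "y" else 0.0)
                state = "y"
        return sc

    def rec(i, j, ga, gb):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score_alignment(ga, gb))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ga + [a[i]], gb + [b[j]])
        if i < len(a):
            rec(i + 1, j, ga + [a[i]], gb + ["-"])
        if j < len(b):
            rec(i, j + 1, ga + ["-"], gb + [b[j]])

    rec(0, 0, [], [])
    return best


# ---------------------------------------------------------------------------
# Trees: random rooted binary trees and exact path-length matrices
# ---------------------------------------------------------------------------


def random_binary_tree(labels, rng, min_len=0.1, max_len=1.0) -> Tree:
    nodes = [Node(name) for name in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        for c in (a, b):
            c.length = float(rng.uniform(min_len, max_len))
        p = Node()
        p.add_child(a)
        p.add_child(b)
        nodes.append(p)
    nodes[0].length = 0.0
    return Tree(nodes[0])


def path_length_matrix(tree: Tree):
    """Leaf ids and the exact additive leaf-to-leaf distance matrix."""
    leaves = tree.leaves()
    ids = [n.name for n in leaves]
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        up = {}
        x, d = leaves[i], 0.0
        while x is not None:
            up[id(x)] = d
            d += x.length
            x = x.parent
        for j in range(i + 1, n):
            x, d = leaves[j], 0.0
            while id(x) not in up:
                d += x.length
                x = x.parent
            D[i, j] = D[j, i] = d + up[id(x)]
    return ids, D


def random_ultrametric_tree(labels, rng) -> Tree:
    """Random topology with node heights making the tree ultrametric."""
    tree = random_binary_tree(labels, rng)
    # make ultrametric: set each leaf depth to the max by stretching pendants
    h = max(lf.depth() for lf in tree.leaves())
    for lf in tree.leaves():
        lf.length += h - lf.depth()
    return tree


# ---------------------------------------------------------------------------
# Reconciliation: exhaustive enumeration over valid gene->species maps
# ---------------------------------------------------------------------------


def _ancestors_or_self(snode):
    out = []
    while snode is not None:
        out.append(snode)
        snode = snode.parent
    return out


def _edge_distance(low, high) -> int:
    d = 0
    x = low
    while x is not high:
        x = x.parent
        d += 1
    return d


def brute_force_reconcile(gene_tree: Tree, species_tree: Tree, leaf_map) -> tuple[int, int]:
    """Minimum (duplications, losses) over every valid embedding.

    A map is valid when every internal node maps to an ancestor-or-self of
    the LCA of its children's images.  A node is a duplication iff its
    children's images do not lie in distinct child subtrees of its own image;
    losses on an edge are the species edges skipped, minus one below a
    speciation.  The minimum of both quantities is attained simultaneously,
    which is what the LCA implementation must reproduce.
    """
    sleaves = {n.name: n for n in species_tree.leaves()}
    gnodes = list(gene_tree.postorder())
    internal = [g for g in gnodes if not g.is_leaf]
    fixed = {id(g): sleaves[leaf_map[g.name]] for g in gnodes if g.is_leaf}

    def subtree_contains(root, node) -> bool:
        x = node
        while x is not None:
            if x is root:
                return True
            x = x.parent
        return False

    def lca(a, b):
        anc = set(id(x) for x in _ancestors_or_self(a))
        x = b
        while id(x) not in anc:
            x = x.parent
        return x

    candidates = {}
    # bottom-up: candidate images are ancestors-or-self of the children's LCA
    best = None
    order = [g for g in gene_tree.postorder() if not g.is_leaf]

    def assign(idx, current):
        nonlocal best
        if idx == len(order):
            # cost of this complete map
            full = dict(fixed)
            full.update(current)
            dups = 0
            losses = 0
            dup_flag = {}
            for g in internal:
                mg = full[id(g)]
                kids = [full[id(c)] for c in g.children]
                is_spec = (
                    not mg.is_leaf
                    and all(k is not mg for k in kids)
                    and not subtree_contains_same_child(mg, kids)
                )
                dup_flag[id(g)] = not is_spec
                dups += not is_spec
            for g in gnodes:
                if g.parent is None:
                    continue
                d = _edge_distance(full[id(g)], full[id(g.parent)])
                losses += d if dup_flag[id(g.parent)] else d - 1
            if best is None or (dups, losses) < best:
                best = (dups, losses)
            return
        g = order[idx]
        kids = [
            current[id(c)] if not c.is_leaf else fixed[id(c)] for c in g.children
        ]
        low = lca(kids[0], kids[1])
        for cand in _ancestors_or_self(low):
            current[id(g)] = cand
            assign(idx + 1, current)
        del current[id(g)]

    def subtree_contains_same_child(mg, kids):
        # True if both children's images fall under one child subtree of mg
        for child in mg.children:
            if all(subtree_contains(child, k) for k in kids):
                return True
        return False

    # enumerate in an order where children precede parents (postorder)
    assign(0, {})
    return best


def brute_force_min_losses(gene_tree, species_tree, leaf_map) -> int:
    return brute_force_reconcile(gene_tree, species_tree, leaf_map)[1]
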