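"""Gene-tree/species-tree reconciliation: LCA mapping, duplication calling
with ancestral-branch age labels, embedding-based loss counting, and
paralog-group naming.

The mapping M sends every gene-tree node to the lowest species-tree node
containing all of its descendant species; a node is a duplication iff one of
its children maps to the same species node.  Losses on a gene-tree edge
(u, v) follow the standard embedding count: the number of species-tree edges
between M(u) and M(v), minus one when u is a speciation.  Each loss is
attributed to the species-tree branch that the gene lineage failed to enter,
so per-branch counts sum exactly to the total.

Naming follows gene-family nomenclature practice: clades born from
duplications older than a configurable age tier get capital letters (A, B, C
by decreasing clade size), younger duplications get numeric suffixes, and
within-species duplicates get lowercase letters, composing to names like
``LygA``, ``LygA1`` and ``LygA1a``.  The letters and numbers distinguish
paralog groups; they do not by themselves assert orthology.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Optional

from .trees import Node, Tree

__all__ = [
    "ReconciliationError",
    "ReconciliationResult",
    "ParalogNaming",
    "NamingRules",
    "lca_reconcile",
    "label_duplication_ages",
    "count_losses_per_lineage",
    "assign_names",
]


class ReconciliationError(ValueError):
    pass


def _branch_key(snode: Node) -> str:
    """Stable name for the species branch above ``snode`` (falls back to a
    leaf-set signature when the node is unnamed)."""
    if snode.name:
        return snode.name
    return "anc(" + ",".join(sorted(snode.leaf_names())) + ")"


@dataclass
class ReconciliationResult:
    gene_tree: Tree
    species_tree: Tree
    mapping: dict  # gene Node -> species Node
    duplications: list  # gene Nodes, postorder
    losses_total: int
    losses_per_branch: dict  # species node name -> count (branch above it)
    copy_number: dict  # species name -> extant copies
    age_labels: dict = field(default_factory=dict)  # dup Node -> label
    dup_series: dict = field(default_factory=dict)  # species node name -> [dup Node,...]

    def duplication_names(self) -> list[str]:
        return [n.name for n in self.duplications if n.name]


def _species_ancestry(species_tree: Tree) -> dict:
    """Node -> list of ancestors from the node up to the root (inclusive)."""
    anc = {}
    for n in species_tree.preorder():
        chain = [n]
        p = n.parent
        while p is not None:
            chain.append(p)
            p = p.parent
        anc[n] = chain
    return anc


def lca_reconcile(
    gene_tree: Tree, species_tree: Tree, leaf_map: dict[str, str]
) -> ReconciliationResult:
    """Standard LCA reconciliation in one post-order pass.

    ``leaf_map`` sends every gene leaf label to a species-tree leaf label.
    Both trees must be rooted and binary.
    """
    if not gene_tree.is_binary():
        raise ReconciliationError("gene tree must be binary")
    if not species_tree.is_binary():
        raise ReconciliationError("species tree must be binary")
    sleaves = {n.name: n for n in species_tree.leaves()}
    ancestry = _species_ancestry(species_tree)

    def species_lca(a: Node, b: Node) -> Node:
        seen = set(id(x) for x in ancestry[a])
        for x in ancestry[b]:
            if id(x) in seen:
                return x
        raise ReconciliationError("disconnected species nodes")

    mapping: dict = {}
    duplications: list = []
    for g in gene_tree.postorder():
        if g.is_leaf:
            sp = leaf_map.get(g.name)
            if sp is None:
                raise ReconciliationError(f"gene leaf {g.name!r} has no species mapping")
            if sp not in sleaves:
                raise ReconciliationError(
                    f"species {sp!r} (gene leaf {g.name!r}) not in species tree"
                )
            mapping[g] = sleaves[sp]
        else:
            a, b = g.children
            mapping[g] = species_lca(mapping[a], mapping[b])
            if mapping[g] is mapping[a] or mapping[g] is mapping[b]:
                duplications.append(g)

    # --- losses ------------------------------------------------------------
    losses_total = 0
    losses_per_branch: dict[str, int] = {}

    def path_up(low: Node, high: Node) -> list[Node]:
        """Species nodes from ``low`` up to ``high`` inclusive."""
        chain = []
        x = low
        while x is not high:
            chain.append(x)
            x = x.parent
            if x is None:
                raise ReconciliationError("mapping not ancestral")
        chain.append(high)
        return chain

    dup_set = set(id(n) for n in duplications)
    for g in gene_tree.postorder():
        if g.parent is None:
            continue
        u, v = g.parent, g
        path = path_up(mapping[v], mapping[u])  # [M(v), ..., M(u)]
        # loss at species node x on the path: the lineage entered one child of
        # x and was lost in the other.  For a speciation parent the path's top
        # node is where the gene split, so losses occur strictly between; for
        # a duplication parent the copy also had to descend from M(u) itself.
        upper = len(path) - 1 if id(u) not in dup_set else len(path)
        for k in range(1, upper):
            x = path[k] if k < len(path) else None
            if x is None:
                continue
            below = path[k - 1]
            for child in x.children:
                if child is not below:
                    losses_total += 1
                    key = _branch_key(child)
                    losses_per_branch[key] = losses_per_branch.get(key, 0) + 1
    copy_number: dict[str, int] = {n.name: 0 for n in species_tree.leaves()}
    for g in gene_tree.leaves():
        copy_number[leaf_map[g.name]] += 1
    return ReconciliationResult(
        gene_tree=gene_tree,
        species_tree=species_tree,
        mapping=mapping,
        duplications=duplications,
        losses_total=losses_total,
        losses_per_branch=losses_per_branch,
        copy_number=copy_number,
    )


def label_duplication_ages(
    rec: ReconciliationResult, named_ancestors: Optional[dict[str, str]] = None
) -> ReconciliationResult:
    """Attach an ancestral-branch label to every duplication.

    A duplication inherits the supplied display name of its mapped species
    node (``named_ancestors`` maps species-node names to labels); unnamed
    nodes get a generated ``anc(<leaf-set signature>)`` label.  Duplications
    mapping to the same species node that are ancestor and descendant in the
    gene tree are reported as an ordered series in ``dup_series`` (gene-tree
    ancestors first), mirroring unresolved consecutive events such as the
    two amniote-ancestor duplications.
    """
    named_ancestors = named_ancestors or {}
    series: dict[str, list] = {}
    # preorder pass over duplications keeps ancestor-before-descendant order
    dup_ids = set(id(n) for n in rec.duplications)
    for g in rec.gene_tree.preorder():
        if id(g) not in dup_ids:
            continue
        snode = rec.mapping[g]
        if snode.name and snode.name in named_ancestors:
            label = named_ancestors[snode.name]
        elif snode.name:
            label = snode.name
        else:
            label = "anc(" + ",".join(sorted(snode.leaf_names())) + ")"
        rec.age_labels[g] = label
        series.setdefault(snode.name or label, []).append(g)
    rec.dup_series = series
    return rec


def count_losses_per_lineage(rec: ReconciliationResult) -> dict[str, int]:
    """Loss counts decomposed by species-tree branch (keyed by the name of
    the node below each branch); sums to ``rec.losses_total``."""
    return dict(rec.losses_per_branch)


# ---------------------------------------------------------------------------
# Paralog naming
# ---------------------------------------------------------------------------


@dataclass
class NamingRules:
    """Age tiers for name components.

    ``letter_min_age``: minimum age (species-node height, time units) of the
    duplication's mapped species node for its clades to receive capital
    letters; defaults to half the species-tree height.  Internal nodes
    younger than the tier give numeric suffixes; duplications mapping to a
    species leaf give lowercase letters (within-species duplicates).
    """

    letter_min_age: Optional[float] = None


@dataclass
class ParalogNaming:
    names: dict[str, str]  # gene leaf -> assigned name
    components: dict[str, str]  # gene leaf -> suffix after the family prefix
    tiers: dict[str, str]  # duplication node name/label -> tier used


def _letters(i: int) -> str:
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = string.ascii_uppercase[rem] + out
    return out


def assign_names(
    rec: ReconciliationResult,
    family_prefix: str = "Lyg",
    rules: Optional[NamingRules] = None,
) -> ParalogNaming:
    """Deterministic paralog-group names from the reconciled gene tree.

    Consecutive duplications of the same tier mapping to the same species
    node are flattened into one multi-way split, so an unresolved ancestral
    triplication yields three sibling letters (A, B, C) rather than nested
    pairs.  Sibling clades are ordered by decreasing size, ties broken by the
    lexicographically earliest leaf id.
    """
    rules = rules or NamingRules()
    s_height = rec.species_tree.root.max_leaf_distance()
    letter_min_age = (
        rules.letter_min_age if rules.letter_min_age is not None else 0.5 * s_height
    )
    dup_ids = set(id(n) for n in rec.duplications)

    def tier(g: Node) -> str:
        snode = rec.mapping[g]
        if snode.is_leaf:
            return "within_species"
        if snode.max_leaf_distance() >= letter_min_age:
            return "letter"
        return "number"

    names: dict[str, str] = {}
    components: dict[str, str] = {}
    tiers: dict[str, str] = {}

    def clade_key(n: Node):
        leaves = sorted(n.leaf_names())
        return (-len(leaves), leaves[0])

    def descend(node: Node, comp: str) -> None:
        if node.is_leaf:
            components[node.name] = comp
            names[node.name] = family_prefix + comp
            return
        if id(node) not in dup_ids:
            for c in node.children:
                descend(c, comp)
            return
        block_tier = tier(node)
        tiers[node.name or rec.age_labels.get(node, "dup")] = block_tier
        parts: list[Node] = []

        # chained duplications of one tier flatten into a single multi-way
        # series, so an ancestral triplication reads A/B/C, not A/BA/BB
        def collect(n: Node) -> None:
            if not n.is_leaf and id(n) in dup_ids and tier(n) == block_tier:
                tiers[n.name or rec.age_labels.get(n, "dup")] = block_tier
                for c in n.children:
                    collect(c)
            else:
                parts.append(n)

        collect(node)
        parts.sort(key=clade_key)
        for idx, part in enumerate(parts):
            if block_tier == "letter":
                sym = _letters(idx)
            elif block_tier == "number":
                sym = str(idx + 1)
            else:
                sym = string.ascii_lowercase[idx % 26] * (idx // 26 + 1)
            descend(part, comp + sym)

    descend(rec.gene_tree.root, "")
    return ParalogNaming(names=names, components=components, tiers=tiers)
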