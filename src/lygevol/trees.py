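"""Rooted trees with branch lengths, shared by the simulator, phylogeny and
reconciliation stages.

A :class:`Tree` is a thin wrapper around a root :class:`Node`.  Newick text is
parsed with dendropy and converted into this structure; serialisation back to
Newick is a direct recursive write so that support values and internal-node
names round-trip exactly the way the pipeline emits them.

Conventions: species trees are rooted, binary, ultrametric in time units, with
optionally named internal nodes (e.g. ``amniote_ancestor``).  Gene trees carry
leaf labels of the form ``<species>_<gene id>`` and, after bootstrapping,
integer support values in [0, 100] on internal edges.
"""

from __future__ import annotations

import io
from typing import Iterator, Optional

import dendropy

__all__ = ["Node", "Tree", "TreeError"]


class TreeError(ValueError):
    """Structural problem with a tree (non-binary, bad labels, ...)."""


class Node:
    """A tree node with parent/children links, a branch length and labels."""

    __slots__ = ("name", "length", "parent", "children", "support")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.support: Optional[float] = None

    # -- structure -------------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    # -- traversal -------------------------------------------------------
    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    # -- metrics ---------------------------------------------------------
    def depth(self) -> float:
        """Sum of branch lengths from the root down to (and including) self."""
        d, n = 0.0, self
        while n.parent is not None:
            d += n.length
            n = n.parent
        return d

    def max_leaf_distance(self) -> float:
        """Height of the subtree: max path length from self to a descendant leaf."""
        if self.is_leaf:
            return 0.0
        return max(c.length + c.max_leaf_distance() for c in self.children)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length:g}, deg={len(self.children)})"


class Tree:
    """A rooted tree; ``root`` is a :class:`Node` with no parent."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction ----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise TreeError(f"cannot parse Newick: {exc}") from exc
        return cls(cls._convert(dt.seed_node))

    @classmethod
    def read(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @staticmethod
    def _convert(dnode: "dendropy.Node") -> Node:
        name = None
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label is not None:
            name = dnode.label
        node = Node(name=name, length=dnode.edge.length or 0.0)
        for child in dnode.child_nodes():
            node.add_child(Tree._convert(child))
        return node

    def copy(self) -> "Tree":
        def rec(n: Node) -> Node:
            m = Node(n.name, n.length)
            m.support = n.support
            for c in n.children:
                m.add_child(rec(c))
            return m

        return Tree(rec(self.root))

    # -- queries ---------------------------------------------------------
    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def find(self, name: str) -> Node:
        for n in self.root.preorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def is_binary(self) -> bool:
        return all(n.is_leaf or len(n.children) == 2 for n in self.postorder())

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = [lf.depth() for lf in self.leaves()]
        return max(depths) - min(depths) <= tol

    def validate_species_tree(self) -> None:
        """Enforce the species-tree contract: rooted binary, unique leaf
        labels, non-negative branch lengths."""
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise TreeError("duplicate leaf labels in species tree")
        if not self.is_binary():
            raise TreeError("species tree must be binary")
        if any(n.length < 0 for n in self.postorder()):
            raise TreeError("negative branch length in species tree")

    def lca(self, nodes: list[Node]) -> Node:
        """Lowest common ancestor of a non-empty set of nodes."""
        if not nodes:
            raise ValueError("lca of empty node set")
        paths = []
        for n in nodes:
            path = []
            while n is not None:
                path.append(n)
                n = n.parent
            paths.append(list(reversed(path)))
        anc = paths[0][0]
        for i in range(min(len(p) for p in paths)):
            first = paths[0][i]
            if all(p[i] is first for p in paths):
                anc = first
            else:
                break
        return anc

    def bipartitions(self) -> dict[frozenset, Node]:
        """Non-trivial splits of the *unrooted* version of this tree.

        Each split is keyed by the smaller-or-lexicographically-first side as a
        frozenset of leaf names; the value is the child node whose subtree is
        that side (useful for attaching support values).
        """
        all_leaves = frozenset(self.leaf_names())
        out: dict[frozenset, Node] = {}
        for n in self.postorder():
            if n is self.root or n.is_leaf:
                continue
            below = frozenset(n.leaf_names())
            other = all_leaves - below
            if len(below) < 2 or len(other) < 2:
                continue
            key = min(below, other, key=lambda s: (len(s), sorted(s)))
            # the same split can appear twice around a root of degree 2; keep
            # the first (deepest) representative
            out.setdefault(key, n)
        return out

    # -- serialisation ---------------------------------------------------
    def to_newick(self, support_as_label: bool = True) -> str:
        buf = io.StringIO()

        def fmt_len(x: float) -> str:
            return format(x, ".10g")

        def rec(n: Node) -> None:
            if n.children:
                buf.write("(")
                for i, c in enumerate(n.children):
                    if i:
                        buf.write(",")
                    rec(c)
                buf.write(")")
                if n.support is not None and support_as_label:
                    buf.write(format(n.support, "g"))
                elif n.name:
                    buf.write(n.name)
            else:
                buf.write(n.name or "")
            if n.parent is not None:
                buf.write(f":{fmt_len(n.length)}")

        rec(self.root)
        buf.write(";")
        return buf.getvalue()

    def write(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree(<{len(self.leaves())} leaves>)"


def topologies_equal(a: Tree, b: Tree) -> bool:
    """Rooted topology equality on leaf-name clades (ignores branch lengths)."""

    def clades(t: Tree) -> set[frozenset]:
        return {frozenset(n.leaf_names()) for n in t.postorder()}

    return clades(a) == clades(b)


def unrooted_topologies_equal(a: Tree, b: Tree) -> bool:
    """Split-set equality of the unrooted topologies."""
    if set(a.leaf_names()) != set(b.leaf_names()):
        return False
    return set(a.bipartitions()) == set(b.bipartitions())
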