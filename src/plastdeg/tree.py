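"""Rooted phylogeny with parent links, built on dendropy for newick I/O.

The ancestral-reconstruction code needs little more than post-order
traversal, branch lengths and MRCA queries, so the tree is a plain node
structure; newick parsing and serialization are delegated to dendropy.
"""

from __future__ import annotations

import warnings
from typing import Iterator

import dendropy


class Node:
    __slots__ = ("name", "length", "parent", "children")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length  # None = absent in the input
        self.parent: "Node | None" = None
        self.children: list["Node"] = []

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Node {self.name or '(internal)'}>"


class Tree:
    """Rooted tree with unique tip labels and optional branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        labels = [n.name for n in self.leaves()]
        if len(labels) != len(set(labels)):
            dups = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dups}")
        if any(lb is None for lb in labels):
            raise ValueError("unlabeled tip")

    # -- traversal ------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def tip_labels(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def nodes(self) -> list[Node]:
        return list(self.postorder())

    def mrca(self, labels) -> Node:
        """Most recent common ancestor of the named tips."""
        want = set(labels)
        have = {n.name for n in self.leaves()}
        missing = want - have
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        below: dict[Node, set] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[n] = {n.name} & want
            else:
                below[n] = set().union(*(below[c] for c in n.children))
        node = self.root
        while True:
            nxt = [c for c in node.children if below[c] == want]
            if not nxt:
                return node
            node = nxt[0]

    def branch_length(self, node: Node, default: float = 1.0) -> float:
        """Branch length above ``node``; absent lengths fall back to ``default``."""
        if node.length is None:
            return default
        return node.length

    def has_missing_lengths(self) -> bool:
        return any(n.length is None for n in self.postorder() if n.parent is not None)

    # -- newick ---------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=False,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise ValueError(f"newick parse error: {exc}") from exc

        def convert(dn) -> Node:
            name = None
            if dn.taxon is not None:
                name = dn.taxon.label
            elif dn.label:
                name = dn.label
            node = Node(name=name, length=dn.edge.length)
            for ch in dn.child_nodes():
                node.add(convert(ch))
            return node

        return cls(convert(dt.seed_node))

    def to_newick(self) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                s = _quote(n.name)
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if n.name:
                    s += _quote(n.name)
            if n.length is not None and n.parent is not None:
                s += f":{n.length:g}"
            return s

        return fmt(self.root) + ";"

    def with_unit_lengths_where_missing(self, warn: bool = True) -> "Tree":
        """Copy of the tree with absent branch lengths replaced by 1.0."""
        if warn and self.has_missing_lengths():
            warnings.warn(
                "tree has branches without lengths; treating them as 1.0",
                stacklevel=2,
            )

        def copy(n: Node) -> Node:
            ln = n.length
            if ln is None and n.parent is not None:
                ln = 1.0
            m = Node(n.name, ln)
            for c in n.children:
                m.add(copy(c))
            return m

        return Tree(copy(self.root))


def _quote(name: str) -> str:
    if any(ch in name for ch in " ()[]{}:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name
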