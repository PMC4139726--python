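"""Phylogenetic tree container used across the package.

A :class:`ReferenceTree` stores an (operationally rooted) tree with
branch lengths in expected substitutions per site.  Likelihood code in
:mod:`pbstyper.phylo` is invariant to the rooting for reversible models,
so the arbitrary root carries no meaning.  Newick parsing and writing go
through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .seqio import FormatError


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class ReferenceTree:
    """Tree with unique leaf labels, non-negative finite branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "ReferenceTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=False,
                preserve_underscores=True)
        except Exception as exc:
            raise FormatError(f"cannot parse newick: {exc}") from exc
        return cls(_from_dendropy(dtree))

    @classmethod
    def read(cls, path) -> "ReferenceTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def copy(self) -> "ReferenceTree":
        return ReferenceTree.from_newick(self.to_newick())

    # -- validation ----------------------------------------------------

    def _validate(self):
        labels = [n.name for n in self.leaves()]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise FormatError(f"duplicate leaf labels: {sorted(dupes)}")
        for node in self.postorder():
            if node is not self.root:
                if node.length < 0 or node.length != node.length:
                    raise FormatError(
                        f"branch above {node.name or 'internal node'} has "
                        f"invalid length {node.length}")

    # -- traversal -----------------------------------------------------

    def postorder(self):
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out[::-1]

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[Node]:
        """Every edge, represented by the node below it, in postorder."""
        return [n for n in self.postorder() if n is not self.root]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions as canonical frozensets of leaf labels.

        Each internal edge splits the leaves in two; the canonical form is
        the lexicographically smaller side, making supports comparable
        across rerooted copies of the same unrooted topology.
        """
        all_leaves = frozenset(self.leaf_names())
        out = set()
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children))
        for node in self.edges():
            side = below[id(node)]
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out

    # -- editing -------------------------------------------------------

    def prune_leaf(self, name: str) -> "ReferenceTree":
        """Return a copy with one leaf removed and its edge path merged."""
        tree = self.copy()
        leaf = next((n for n in tree.leaves() if n.name == name), None)
        if leaf is None:
            raise KeyError(name)
        parent = leaf.parent
        if parent is None:
            raise ValueError("cannot prune the only node")
        parent.children.remove(leaf)
        # collapse now-unary nodes, summing lengths
        node = parent
        while node is not None and len(node.children) == 1 and node.parent is not None:
            (child,) = node.children
            child.length += node.length
            gp = node.parent
            gp.children[gp.children.index(node)] = child
            child.parent = gp
            node = gp
        if tree.root.children and len(tree.root.children) == 1:
            tree.root = tree.root.children[0]
            tree.root.parent = None
            tree.root.length = 0.0
        return ReferenceTree(tree.root)

    def reroot_at(self, leaf_name: str) -> "ReferenceTree":
        """Return a copy rerooted at the parent of the named leaf."""
        dtree = dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                  preserve_underscores=True)
        taxon = dtree.taxon_namespace.get_taxon(leaf_name)
        if taxon is None:
            raise KeyError(leaf_name)
        node = dtree.find_node_with_taxon_label(leaf_name)
        dtree.reroot_at_node(node.parent_node,
                             update_bipartitions=False,
                             suppress_unifurcations=True)
        return ReferenceTree(_from_dendropy(dtree))

    # -- serialization -------------------------------------------------

    def to_newick(self, support: dict | None = None) -> str:
        """Newick string; ``support`` optionally labels internal edges by
        their canonical bipartition."""
        all_leaves = frozenset(self.leaf_names())

        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if support is not None and node is not self.root:
                    side = frozenset(_leafset(node))
                    key = min(side, all_leaves - side,
                              key=lambda s: (len(s), sorted(s)))
                    if key in support:
                        body += format(support[key], "g")
                elif node.name:
                    body += node.name
            if node is self.root:
                return body
            return f"{body}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def write(self, path, support: dict | None = None):
        with open(path, "w") as fh:
            fh.write(self.to_newick(support=support) + "\n")
        return path

    def __repr__(self):
        return f"ReferenceTree({len(self.leaves())} leaves)"


def _leafset(node: Node):
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.name)
        stack.extend(n.children)
    return out


def _from_dendropy(dtree: dendropy.Tree) -> Node:
    def convert(dnode) -> Node:
        name = None
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label:
            name = dnode.label
        node = Node(name=name, length=dnode.edge.length or 0.0)
        for c in dnode.child_nodes():
            node.add(convert(c))
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0
    return root
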