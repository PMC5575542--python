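"""Phylogenetic tree handling: Newick I/O, naming, rooting, indexing.

Trees are held as :class:`dendropy.Tree` objects throughout the package.
Branch lengths are expected substitutions per site.  A deterministic Newick
serializer is provided so that identical trees always produce identical
output bytes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np

__all__ = [
    "load_tree",
    "parse_newick",
    "to_newick",
    "name_internal_nodes",
    "root_with_outgroup",
    "mrca_node",
    "TreeIndex",
    "RootingError",
]


class RootingError(ValueError):
    """Requested outgroup cannot root the tree (not monophyletic)."""


def parse_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def load_tree(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def _fmt_len(x: float | None) -> str:
    if x is None:
        return ""
    return f":{x:.10g}"


def to_newick(tree: dendropy.Tree) -> str:
    """Deterministic Newick string with branch lengths and node labels."""

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            label = node.taxon.label if node.taxon else (node.label or "")
            return f"{label}{_fmt_len(node.edge.length)}"
        inner = ",".join(render(c) for c in node.child_nodes())
        label = node.label or ""
        length = _fmt_len(node.edge.length) if node.parent_node else ""
        return f"({inner}){label}{length}"

    return render(tree.seed_node) + ";"


def save_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def name_internal_nodes(tree: dendropy.Tree, prefix: str = "N") -> dendropy.Tree:
    """Assign deterministic labels (postorder) to unlabeled internal nodes."""
    counter = 1
    existing = {n.label for n in tree.preorder_node_iter() if n.label}
    for node in tree.postorder_internal_node_iter():
        if not node.label:
            while f"{prefix}{counter}" in existing:
                counter += 1
            node.label = f"{prefix}{counter}"
            counter += 1
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def mrca_node(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of the given leaf taxa."""
    taxa = list(taxa)
    missing = set(taxa) - set(leaf_labels(tree))
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    node = tree.mrca(taxon_labels=taxa)
    if node is None:
        raise ValueError("MRCA could not be resolved")
    return node


def root_with_outgroup(
    tree: dendropy.Tree, outgroup_taxa: Iterable[str]
) -> dendropy.Tree:
    """Root on the branch separating the outgroup from the ingroup.

    The outgroup must be a single leaf or form a clade in the unrooted sense;
    the separating branch's length is split equally between the two new root
    children.  Returns a new tree; the input is not modified.
    """
    out = set(outgroup_taxa)
    tree = tree.clone(depth=1)
    leaves = set(leaf_labels(tree))
    if not out:
        raise RootingError("outgroup is empty")
    if not out <= leaves:
        raise RootingError(f"outgroup taxa not in tree: {sorted(out - leaves)}")
    ingroup = leaves - out
    if not ingroup:
        raise RootingError("outgroup cannot contain every leaf")

    root_children = tree.seed_node.child_nodes()
    if len(root_children) == 2:
        for child in root_children:
            below = {l.taxon.label for l in child.leaf_iter()}
            if below == out:
                return tree  # already rooted at the requested split

    target = None
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        if below == out or below == ingroup:
            target = node
            break
    if target is None:
        raise RootingError("outgroup is not monophyletic in the unrooted tree")

    length = target.edge.length or 0.0
    tree.reroot_at_edge(target.edge, length1=length / 2.0, length2=length / 2.0)
    tree.suppress_unifurcations()
    tree.is_rooted = True
    return tree


class TreeIndex:
    """Array view of a rooted tree for vectorized likelihood computations.

    Nodes are enumerated in postorder; ``parent[i]`` is the postorder index
    of node ``i``'s parent (-1 at the root) and ``lengths[i]`` the length of
    the branch above node ``i``.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.nodes: list[dendropy.Node] = list(tree.postorder_node_iter())
        self.n_nodes = len(self.nodes)
        index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.lengths = np.zeros(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.is_leaf = np.zeros(self.n_nodes, dtype=bool)
        self.labels: list[str] = []
        for i, node in enumerate(self.nodes):
            if node.parent_node is not None:
                p = index[id(node.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.lengths[i] = max(node.edge.length or 0.0, 0.0)
            if node.is_leaf():
                self.is_leaf[i] = True
                self.labels.append(node.taxon.label if node.taxon else node.label)
            else:
                self.labels.append(node.label or "")
        self.root = self.n_nodes - 1
        self.label_to_index = {lab: i for i, lab in enumerate(self.labels) if lab}

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def internal_labels(self) -> list[str]:
        return [self.labels[i] for i in range(self.n_nodes) if not self.is_leaf[i]]
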