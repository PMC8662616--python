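"""Rooted phylogenies with branch lengths, backed by dendropy.

Branch lengths are in expected substitutions per site; they are the clock
against which indel waiting times run (indel rates are ratios to the
substitution rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np


@dataclass(frozen=True)
class FlatTree:
    """Pre-order array view of a tree, used by the simulator.

    Node 0 is the root. ``parent[i]`` and ``blen[i]`` give the parent
    index and branch length of node i (parent[0] == -1, blen[0] == 0).
    ``leaf_nodes`` are the node indices of the leaves in ``leaf_labels``
    order.
    """

    parent: np.ndarray
    blen: np.ndarray
    leaf_nodes: np.ndarray
    leaf_labels: tuple[str, ...]


class PhyloTree:
    """A rooted phylogenetic tree with non-negative branch lengths.

    Invariants enforced on construction: a single bifurcating root, at
    least two leaves, unique leaf labels, and a branch length on every
    non-root edge.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        root = tree.seed_node
        children = root.child_nodes()
        if len(children) > 2:
            raise ValueError(
                f"tree root has {len(children)} children; the tree appears "
                "unrooted — root it (e.g. by outgroup or midpoint) first"
            )
        leaves = tree.leaf_nodes()
        if len(leaves) < 2:
            raise ValueError("tree must have at least 2 leaves")
        labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
        if any(lab is None for lab in labels):
            raise ValueError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels are not unique")
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise ValueError(
                    "missing branch length on an edge; all non-root edges "
                    "must carry a length in substitutions per site"
                )
            if node.edge.length < 0:
                raise ValueError(f"negative branch length {node.edge.length}")
        self._flat = self._flatten()

    def _flatten(self) -> FlatTree:
        nodes = list(self._tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent = np.empty(len(nodes), dtype=np.int64)
        blen = np.empty(len(nodes), dtype=np.float64)
        leaf_nodes, leaf_labels = [], []
        for i, n in enumerate(nodes):
            parent[i] = index[id(n.parent_node)] if n.parent_node else -1
            blen[i] = float(n.edge.length) if i else 0.0
            if n.is_leaf():
                leaf_nodes.append(i)
                leaf_labels.append(n.taxon.label)
        return FlatTree(
            parent=parent,
            blen=blen,
            leaf_nodes=np.asarray(leaf_nodes, dtype=np.int64),
            leaf_labels=tuple(leaf_labels),
        )

    @property
    def flat(self) -> FlatTree:
        return self._flat

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_leaves(self) -> int:
        return len(self._flat.leaf_labels)

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return self._flat.leaf_labels

    def total_branch_length(self) -> float:
        """Sum of all branch lengths (substitutions per site).

        Trees with total length below ~1.0 carry few indel events and give
        unreliable estimates; callers warn at that floor.
        """
        return float(self._flat.blen.sum())

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PhyloTree(n_leaves={self.n_leaves}, "
            f"total_branch_length={self.total_branch_length():.4g})"
        )


def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted newick tree with branch lengths."""
    with open(path) as fh:
        newick = fh.read()
    if not newick.strip():
        raise ValueError(f"{path}: empty tree file")
    return PhyloTree.from_newick(newick)


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
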