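"""Similarity → distance conversion, UPGMA clustering, canonical Newick trees.

Similarities are mapped to distances as d = 1 − s (negative similarities are
allowed and give distances above 1).  UPGMA repeatedly merges the closest
pair of clusters, with the inter-cluster distance of a merged cluster being
the size-weighted mean of its members' distances; node height is half the
merge distance, so the tree is ultrametric.  Ties are broken by the
lexicographically smallest pair of cluster minimum labels so the same input
always yields the same tree.

Trees are kept in canonical form: the children of every node are ordered by
the smallest leaf label beneath them, which gives each topology a unique
representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import dendropy
import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "TreeNode",
    "PhyloTree",
    "NewickParseError",
    "similarity_to_distance",
    "upgma",
    "to_newick",
    "from_newick",
    "write_newick",
    "canonicalize",
]


class NewickParseError(ValueError):
    """Malformed Newick input."""


@dataclass
class TreeNode:
    """A rooted-tree node: leaf (label set) or internal (children non-empty)."""

    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(l.label for l in self.leaves())

    def min_leaf_label(self) -> str:
        return min(l.label for l in self.leaves())


@dataclass
class PhyloTree:
    """Rooted tree with uniquely labeled leaves, stored in canonical child order."""

    root: TreeNode

    def __post_init__(self) -> None:
        labels = [l.label for l in self.root.leaves()]
        if any(l is None for l in labels):
            raise ValueError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")
        _canonical_order(self.root)

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def clade_sets(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes (the root clade included)."""
        return {n.leaf_labels() for n in self.internal_nodes()}

    def parent_clade(self, leaf_label: str) -> frozenset[str]:
        """Leaf set of the smallest clade properly containing the named leaf."""
        parent = self._parent_of(leaf_label)
        return parent.leaf_labels()

    def _parent_of(self, leaf_label: str) -> TreeNode:
        def walk(node: TreeNode) -> TreeNode | None:
            for c in node.children:
                if c.is_leaf and c.label == leaf_label:
                    return node
                found = walk(c)
                if found is not None:
                    return found
            return None

        parent = walk(self.root)
        if parent is None:
            raise KeyError(f"no leaf labeled {leaf_label!r}")
        return parent

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (branch-length sum) per leaf label."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            acc += node.branch_length or 0.0
            if node.is_leaf:
                depths[node.label] = acc
            for c in node.children:
                walk(c, acc)

        walk(self.root, 0.0)
        return depths

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.leaf_depths().values())
        return max(depths) - min(depths) <= tol


def _canonical_order(node: TreeNode) -> str:
    """Recursively sort children by their smallest contained leaf label."""
    if node.is_leaf:
        return node.label
    keyed = sorted((_canonical_order(c), c) for c in node.children)
    node.children = [c for _, c in keyed]
    return keyed[0][0]


def canonicalize(t: PhyloTree) -> PhyloTree:
    """Return the tree with canonical child ordering (idempotent)."""
    _canonical_order(t.root)
    return t


def similarity_to_distance(s: SimilarityMatrix) -> np.ndarray:
    """Distance matrix d = 1 − s with a zero diagonal.

    Similarities below zero (possible with negative penalty scores) yield
    distances above 1, which UPGMA handles without special treatment.
    """
    d = 1.0 - s.values
    np.fill_diagonal(d, 0.0)
    return d


def upgma(d: np.ndarray, labels: list[str] | None = None) -> PhyloTree:
    """UPGMA agglomeration of a symmetric distance matrix.

    Produces a binary rooted ultrametric tree; equal-distance merges are
    resolved sequentially with deterministic lexicographic tie-breaking.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    if labels is None:
        labels = [f"L{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("label count does not match matrix size")

    # active clusters: key → (node, size, min_label); distances in a dict of dicts
    nodes: dict[int, TreeNode] = {i: TreeNode(label=labels[i]) for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    min_label: dict[int, str] = {i: labels[i] for i in range(n)}
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_key = n
    active = set(range(n))
    while len(active) > 1:
        # closest pair; ties → lexicographically smallest (sorted) min-label pair
        best = min(
            (
                (dist[frozenset((i, j))], tuple(sorted((min_label[i], min_label[j]))), i, j)
                for i in active
                for j in active
                if i < j
            ),
        )
        merge_d, _, i, j = best
        height = merge_d / 2.0
        node = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].branch_length = height - heights[i]
        nodes[j].branch_length = height - heights[j]
        k = next_key
        next_key += 1
        for other in active - {i, j}:
            dij = (
                sizes[i] * dist[frozenset((i, other))] + sizes[j] * dist[frozenset((j, other))]
            ) / (sizes[i] + sizes[j])
            dist[frozenset((k, other))] = dij
        nodes[k] = node
        heights[k] = height
        sizes[k] = sizes[i] + sizes[j]
        min_label[k] = min(min_label[i], min_label[j])
        active -= {i, j}
        active.add(k)
    root = nodes[active.pop()]
    return PhyloTree(root)


def to_newick(t: PhyloTree) -> str:
    """Serialize (canonical child order, branch lengths where present)."""

    def emit(node: TreeNode) -> str:
        if node.is_leaf:
            body = node.label
        else:
            body = "(" + ",".join(emit(c) for c in node.children) + ")"
        if node.branch_length is not None:
            body += f":{node.branch_length:.10g}"
        return body

    return emit(t.root) + ";"


def from_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a canonical PhyloTree."""
    try:
        dtree = dendropy.Tree.get(
            file=StringIO(text), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        children = [convert(c) for c in dnode.child_nodes()]
        label = None
        if not children:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if label is None:
                raise NewickParseError("leaf without a label")
        bl = dnode.edge.length
        return TreeNode(label=label, children=children, branch_length=bl)

    tree = PhyloTree(convert(dtree.seed_node))
    # dendropy attaches a 0-length edge to the seed node; normalize absent root length
    if tree.root.branch_length in (0.0, None):
        tree.root.branch_length = None
    return tree


def write_newick(t: PhyloTree, path, metadata: dict | None = None) -> None:
    """Write a Newick file; optional JSON sidecar with method metadata."""
    from json import dump
    from pathlib import Path

    path = Path(path)
    path.write_text(to_newick(t) + "\n")
    if metadata is not None:
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            dump(metadata, fh, indent=2)
            fh.write("\n")
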