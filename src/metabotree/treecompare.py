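"""Leaf-neighborhood tree-similarity statistics.

Two rooted trees over the same organisms are compared leaf by leaf.  In the
binary statistic, a leaf scores 1 when the leaf set of its parent clade (the
smallest clade properly containing it) is identical in both trees, else 0;
K is the mean over leaves.

The weighted statistic grades each leaf over all N − 1 internal nodes of the
first tree, enumerated outward from the leaf (increasing topological
distance, ties resolved by canonical clade order).  The η-th node scores 1
when its leaf set occurs as a clade anywhere in the other tree, and the
contribution is down-weighted with distance:

    F(ξ) = (2/N) Σ_η (N − η)/(N − 1) · F̃(η, ξ),    K = mean_ξ F(ξ).

The weights sum to 1, so identical trees score K = 1 and local disagreement
near a leaf costs more than disagreement near the root.
"""

from __future__ import annotations

from dataclasses import dataclass

from .treebuild import PhyloTree, TreeNode

__all__ = ["TreeSimilarityResult", "binary_tree_similarity", "weighted_tree_similarity"]


@dataclass
class TreeSimilarityResult:
    """K plus the per-leaf scores it averages; mode is 'binary' or 'weighted'."""

    K: float
    per_leaf: dict[str, float]
    mode: str


def _check_leaf_sets(t_a: PhyloTree, t_b: PhyloTree) -> None:
    la, lb = t_a.leaf_labels, t_b.leaf_labels
    if la != lb:
        diff = sorted(la ^ lb)
        raise ValueError(f"trees have different leaf sets; symmetric difference: {diff}")


def binary_tree_similarity(t_a: PhyloTree, t_b: PhyloTree) -> TreeSimilarityResult:
    """Binary K: fraction of leaves whose parent clade is identical in both trees."""
    _check_leaf_sets(t_a, t_b)
    per_leaf = {
        leaf: 1.0 if t_a.parent_clade(leaf) == t_b.parent_clade(leaf) else 0.0
        for leaf in sorted(t_a.leaf_labels)
    }
    return TreeSimilarityResult(sum(per_leaf.values()) / len(per_leaf), per_leaf, "binary")


def _node_distances(t: PhyloTree, leaf_label: str) -> dict[int, tuple[int, frozenset[str]]]:
    """Topological edge-count distance from the named leaf to every node."""
    # build adjacency over node identities
    parent: dict[int, TreeNode] = {}
    nodes: dict[int, TreeNode] = {}
    leaf_node: TreeNode | None = None

    def walk(node: TreeNode) -> None:
        nonlocal leaf_node
        nodes[id(node)] = node
        if node.is_leaf and node.label == leaf_label:
            leaf_node = node
        for c in node.children:
            parent[id(c)] = node
            walk(c)

    walk(t.root)
    assert leaf_node is not None
    dist: dict[int, int] = {id(leaf_node): 0}
    frontier = [leaf_node]
    while frontier:
        nxt = []
        for node in frontier:
            d = dist[id(node)]
            neighbours = list(node.children)
            if id(node) in parent:
                neighbours.append(parent[id(node)])
            for nb in neighbours:
                if id(nb) not in dist:
                    dist[id(nb)] = d + 1
                    nxt.append(nb)
        frontier = nxt
    return {k: (d, nodes[k].leaf_labels()) for k, d in dist.items() if not nodes[k].is_leaf}


def ranked_clades(t: PhyloTree, leaf_label: str) -> list[frozenset[str]]:
    """Internal-node leaf sets ordered by increasing distance from the leaf.

    Ties (equal topological distance) are broken by canonical clade order:
    smaller clades first, then by sorted leaf labels.
    """
    entries = _node_distances(t, leaf_label).values()
    return [
        clade
        for _, clade in sorted(
            ((d, clade) for d, clade in entries),
            key=lambda e: (e[0], len(e[1]), tuple(sorted(e[1]))),
        )
    ]


def weighted_tree_similarity(t_a: PhyloTree, t_b: PhyloTree) -> TreeSimilarityResult:
    """Distance-weighted K over all internal-node clades of the first tree."""
    _check_leaf_sets(t_a, t_b)
    n = t_a.n_leaves
    if n < 2:
        raise ValueError("need at least 2 leaves")
    clades_b = t_b.clade_sets()
    per_leaf: dict[str, float] = {}
    for leaf in sorted(t_a.leaf_labels):
        ranked = ranked_clades(t_a, leaf)
        # integer accumulation of Σ (N − η)·F̃ keeps K(T, T) exactly 1
        numerator = sum(n - eta for eta, clade in enumerate(ranked, start=1) if clade in clades_b)
        per_leaf[leaf] = 2.0 * numerator / (n * (n - 1))
    return TreeSimilarityResult(sum(per_leaf.values()) / n, per_leaf, "weighted")
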