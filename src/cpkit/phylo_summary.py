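"""Phylogeny reporting utilities for chloroplast genome trees.

Chloroplast phylogenies of closely related cultivars have many branches
whose length (substitutions per bp) is below the resolution supported by
the data; collapsing branches shorter than a threshold turns those
near-zero splits into polytomies and exposes the well-supported clades.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

__all__ = ["p_distance", "collapse_short_branches", "clade_report", "CladeCluster"]

_VALID = frozenset("ACGT")


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Proportion of differing comparable columns (substitutions per bp).

    Columns where either symbol is a gap, N, or any non-ACGT character are
    excluded from both numerator and denominator.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError(
            f"aligned lengths differ: {len(aligned_a)} vs {len(aligned_b)}"
        )
    comparable = 0
    diffs = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in _VALID and y in _VALID:
            comparable += 1
            if x != y:
                diffs += 1
    if comparable == 0:
        raise ValueError("no comparable columns between the aligned sequences")
    return diffs / comparable


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def collapse_short_branches(
    tree: dendropy.Tree,
    threshold: float = 2e-4,
) -> dendropy.Tree:
    """Contract internal branches strictly shorter than ``threshold``.

    Contracting an internal branch re-attaches its child's children to the
    parent, producing a polytomy. Terminal branches are never contracted,
    so the leaf set is preserved; a threshold of 0 is the identity
    (strictly-shorter-than comparison).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = _clone(tree)
    to_collapse = [
        edge
        for edge in out.preorder_edge_iter()
        if edge.head_node is not None
        and edge.tail_node is not None
        and not edge.head_node.is_leaf()
        and edge.length is not None
        and edge.length < threshold
    ]
    for edge in to_collapse:
        edge.collapse()
    return out


@dataclass(frozen=True)
class CladeCluster:
    size: int
    leaves: tuple[str, ...]


def clade_report(
    tree: dendropy.Tree,
    threshold: float = 2e-4,
    include_terminal: bool = False,
) -> list[CladeCluster]:
    """Leaf clusters produced by short-branch contraction.

    Short internal branches are contracted first. In the collapsed tree,
    the leaf children of a polytomy (a node with three or more children)
    form one cluster — these are the leaves whose separating structure was
    below the resolution threshold; leaves attached to fully resolved
    (binary) nodes stay singletons. With ``include_terminal`` a leaf whose
    own branch reaches the threshold is kept out of its polytomy's cluster
    (the stricter reading where every branch inside a clade must be
    short). Clusters are sorted by descending size, ties lexicographic.
    """
    collapsed = collapse_short_branches(tree, threshold)

    clusters: list[tuple[str, ...]] = []

    def short_leaf(node) -> bool:
        if not include_terminal:
            return True
        return node.edge.length is not None and node.edge.length < threshold

    def walk(node) -> None:
        if node.is_leaf():
            clusters.append((node.taxon.label,))
            return
        children = node.child_nodes()
        leaf_children = [c for c in children if c.is_leaf()]
        grouped: list[str] = []
        singles: list[str] = []
        for c in leaf_children:
            if len(children) >= 3 and short_leaf(c):
                grouped.append(c.taxon.label)
            else:
                singles.append(c.taxon.label)
        if len(grouped) >= 2:
            clusters.append(tuple(sorted(grouped)))
        else:
            singles.extend(grouped)
        clusters.extend((label,) for label in singles)
        for child in children:
            if not child.is_leaf():
                walk(child)

    walk(collapsed.seed_node)
    return sorted(
        (CladeCluster(size=len(c), leaves=c) for c in clusters),
        key=lambda cl: (-cl.size, cl.leaves),
    )
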