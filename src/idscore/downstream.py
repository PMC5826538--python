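"""Hotspot selection, least-gapped controls, tree post-processing, purity.

Positions that score highly in many families at once ("specific functional
hotspots": conserved within families, but differently across them) carry most
of the information that separates families.  This module selects those
positions, selects equally many least-gapped control positions, post-processes
an externally inferred phylogenetic tree (midpoint rooting, ultrametrization,
binarization) and evaluates how purely tree cuts recover the family labels.
Tree *inference* is deliberately out of scope; trees arrive as Newick.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .alignment_io import FamilyAssignment, MasterAlignment
from .alphabet import GAP_INDEX
from .scoring import ScoreTable

log = logging.getLogger(__name__)


@dataclass
class Clustering:
    """A partition of the tree's leaves (labelled by sequence id)."""

    clusters: tuple[frozenset[str], ...]

    @property
    def k(self) -> int:
        return len(self.clusters)

    @property
    def n(self) -> int:
        return sum(len(c) for c in self.clusters)


# ---------------------------------------------------------------------------
# position selection


def hotspot_positions(
    score_table: ScoreTable | np.ndarray,
    score_cut: float = 0.1,
    family_fraction: float = 0.10,
    rounding: str = "ceil",
) -> list[int]:
    """1-based columns whose ID_score is ≥ ``score_cut`` in at least
    ``family_fraction`` of families.

    "At least 10% of families" is read as a count of ``ceil(fraction · F)``
    (``rounding="floor"`` available for sensitivity analysis).
    """
    ids = score_table.id_score if isinstance(score_table, ScoreTable) else np.asarray(score_table)
    F = ids.shape[0]
    qualifying = (ids >= score_cut).sum(axis=0)
    need = math.ceil(family_fraction * F) if rounding == "ceil" else math.floor(family_fraction * F)
    return [int(p) + 1 for p in np.nonzero(qualifying >= need)[0]]


def least_gapped_positions(alignment: MasterAlignment, k: int) -> list[int]:
    """The ``k`` columns with the fewest gaps; ties broken by lower index."""
    if not 1 <= k <= alignment.n_cols:
        raise ValueError(f"k must lie in 1..{alignment.n_cols}")
    gap_counts = (alignment.matrix() == GAP_INDEX).sum(axis=0)
    order = np.argsort(gap_counts, kind="stable")  # stable sort = index tie-break
    return sorted(int(p) + 1 for p in order[:k])


# ---------------------------------------------------------------------------
# tree post-processing


def read_tree(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    _zero_missing_lengths(tree)
    return tree


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    _zero_missing_lengths(tree)
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick")


def _zero_missing_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0


def _farthest_leaf(tree: dendropy.Tree, start) -> tuple:
    """(leaf, distance, parent-pointer map) for the leaf farthest from
    ``start``, treating the tree as an undirected weighted graph."""
    dist = {start: 0.0}
    prev = {start: None}
    stack = [start]
    while stack:
        node = stack.pop()
        neighbours = list(node.child_nodes())
        if node.parent_node is not None:
            neighbours.append(node.parent_node)
        for nb in neighbours:
            if nb in dist:
                continue
            edge_len = (nb.edge.length if nb.parent_node is node else node.edge.length) or 0.0
            dist[nb] = dist[node] + edge_len
            prev[nb] = node
            stack.append(nb)
    leaves = [n for n in dist if n.is_leaf()]
    far = max(leaves, key=lambda n: dist[n])
    return far, dist, prev


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path (returns a clone).

    The diameter path is found with the standard double traversal (farthest
    leaf from an arbitrary leaf, then farthest leaf from that one), and the
    root is placed on the edge containing the half-diameter point.
    """
    tree = tree.clone(depth=1)
    _zero_missing_lengths(tree)
    if tree.length() == 0:
        log.warning("zero-length tree: midpoint undefined, rooting left unchanged")
        return tree
    any_leaf = next(tree.leaf_node_iter())
    u, _, _ = _farthest_leaf(tree, any_leaf)
    v, dist, prev = _farthest_leaf(tree, u)
    if dist[v] == 0:
        log.warning("all leaf-to-leaf paths have zero length; rooting unchanged")
        return tree
    half = dist[v] / 2.0
    # walk back from v toward u to the deepest path node past the midpoint
    node = v
    while prev[node] is not None and dist[prev[node]] > half:
        node = prev[node]
    before = prev[node]  # on the u side of the midpoint: dist[before] <= half
    # the midpoint lies on the tree edge joining `node` and `before`;
    # reroot_at_edge takes the tail-side portion first
    if dist[before] == half:  # midpoint falls exactly on an existing node
        tree.reroot_at_node(before)
    elif before is node.parent_node:
        # edge tail = before, head = node
        tree.reroot_at_edge(
            node.edge, length1=half - dist[before], length2=dist[node] - half
        )
    else:  # `before` is a child of `node` in the tree orientation
        # edge tail = node, head = before
        tree.reroot_at_edge(
            before.edge, length1=dist[node] - half, length2=half - dist[before]
        )
    _zero_missing_lengths(tree)
    return tree


def make_ultrametric_binary(tree: dendropy.Tree) -> dendropy.Tree:
    """Extend terminal branches to a constant root distance and resolve
    polytomies into ladders of zero-length branches (returns a clone).

    Internal path structure is untouched: only terminal branch lengths grow,
    so leaf depths after the operation all equal the pre-existing maximum
    root-to-leaf distance.  Polytomy children are processed in input order
    (purity results do not depend on the resolution order).
    """
    tree = tree.clone(depth=1)
    _zero_missing_lengths(tree)
    tree.resolve_polytomies(limit=2, update_bipartitions=False)
    _zero_missing_lengths(tree)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    height = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += height - leaf.root_distance
    return tree


def tree_height(tree: dendropy.Tree) -> float:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return max(leaf.root_distance for leaf in tree.leaf_node_iter())


def cut_tree(tree: dendropy.Tree, depth: float) -> Clustering:
    """One cluster per edge crossing ``depth`` (distance from the root).

    ``depth = 0`` yields a single cluster; ``depth = height`` (on an
    ultrametric tree with positive terminal branches) yields singletons.
    """
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    height = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    if depth < 0 or depth > height + 1e-9:
        raise ValueError(f"cut depth {depth} outside [0, {height}]")
    if depth <= 0:
        leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        return Clustering(clusters=(leaves,))
    clusters = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.root_distance >= depth and node.parent_node.root_distance < depth:
            clusters.append(
                frozenset(l.taxon.label for l in node.leaf_iter())
            )
    return Clustering(clusters=tuple(clusters))


# ---------------------------------------------------------------------------
# purity


def cluster_purity(
    clustering: Clustering, families: FamilyAssignment | dict[str, str]
) -> float:
    """(1/n) Σ_i max_j |c_i ∩ f_j|: average dominant-family fraction."""
    labels = (
        families.seq_to_family if isinstance(families, FamilyAssignment) else families
    )
    n = 0
    total = 0
    for cluster in clustering.clusters:
        counts: dict[str, int] = {}
        for leaf in cluster:
            if leaf not in labels:
                raise ValueError(f"leaf {leaf!r} has no family label")
            fid = labels[leaf]
            counts[fid] = counts.get(fid, 0) + 1
        n += len(cluster)
        total += max(counts.values())
    return total / n


def purity_curve(
    tree: dendropy.Tree,
    families: FamilyAssignment | dict[str, str],
    n_cuts: int = 100,
) -> list[tuple[int, float]]:
    """(number of clusters, purity) pairs over a dense grid of cut depths."""
    height = tree_height(tree)
    out = []
    for depth in np.linspace(0.0, height, n_cuts):
        clustering = cut_tree(tree, float(depth))
        out.append((clustering.k, cluster_purity(clustering, families)))
    return out
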