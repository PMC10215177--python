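"""Neighbor-joining trees, Newick IO, bipartitions, and bootstrap support.

The NJ implementation is the classic Saitou–Nei agglomeration with the
Q-criterion, made fully deterministic: ties on Q are broken toward the
lowest (row, column) index pair, and negative branch lengths are clamped to
zero.  NJ is exact on additive matrices — it reproduces the generating
tree's topology and all pairwise path lengths.

:class:`PhyloTree` wraps a dendropy tree for Newick round-tripping and
path-length queries; bipartition (split) sets are computed here so that
bootstrap proportions can be attached to internal edges.
"""

from __future__ import annotations

import re
from typing import Callable, Optional

import dendropy
import numpy as np

from .alignment import Alignment
from .distances import DistanceMatrix, mcl_distances, p_distances, tn93_distances

__all__ = ["PhyloTree", "neighbor_joining", "bootstrap_support", "ESTIMATORS"]

ESTIMATORS: dict[str, Callable[[Alignment], DistanceMatrix]] = {
    "p": p_distances,
    "tn93": tn93_distances,
    "mcl": mcl_distances,
}


def _quote(label: str) -> str:
    if re.search(r"[\s()\[\]{}:;,'\"]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


class PhyloTree:
    """A phylogenetic tree with branch lengths and optional edge supports.

    Thin wrapper over :class:`dendropy.Tree`; supports (percent, 0–100) are
    stored per internal bipartition and rendered as internal node labels in
    Newick output.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    # -- construction / IO --------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls(tree)

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return s

    # -- basic queries ------------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def _leafset_below(self, node) -> frozenset:
        return frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions as normalized frozensets of leaf labels.

        Each internal edge induces a split; the side *not* containing the
        lexicographically smallest leaf is stored, so split sets compare
        across rootings.
        """
        all_leaves = frozenset(self.leaf_labels)
        ref = min(all_leaves)
        out: set[frozenset] = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            below = self._leafset_below(node)
            side = all_leaves - below if ref in below else below
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def rf_distance(self, other: "PhyloTree") -> int:
        """Unweighted Robinson–Foulds distance (symmetric split difference)."""
        if frozenset(self.leaf_labels) != frozenset(other.leaf_labels):
            raise ValueError("leaf sets differ")
        return len(self.splits() ^ other.splits())

    def path_distance_matrix(self, labels: Optional[list[str]] = None) -> np.ndarray:
        """Leaf-to-leaf path lengths (sum of branch lengths), in label order."""
        labels = labels or sorted(self.leaf_labels)
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(labels)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                out[i, j] = out[j, i] = d
        return out

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.tree.preorder_edge_iter()
        )

    # -- supports -----------------------------------------------------------

    def set_supports(self, supports: dict[frozenset, float]) -> None:
        """Attach bootstrap percentages to internal nodes by bipartition."""
        all_leaves = frozenset(self.leaf_labels)
        ref = min(all_leaves)
        normalized = {
            (all_leaves - side if ref in side else frozenset(side)): value
            for side, value in supports.items()
        }
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            below = self._leafset_below(node)
            side = all_leaves - below if ref in below else below
            if side in normalized:
                node.label = f"{normalized[side]:g}"

    def supports(self) -> dict[frozenset, float]:
        all_leaves = frozenset(self.leaf_labels)
        ref = min(all_leaves)
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf() or node.label is None:
                continue
            below = self._leafset_below(node)
            side = all_leaves - below if ref in below else below
            try:
                out[side] = float(node.label)
            except ValueError:
                pass
        return out


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining on a labelled distance matrix.

    Requires >= 3 taxa and no missing (NaN) distances.  Ties on the
    Q-criterion break toward the lowest index pair; negative branch lengths
    are clamped to 0.  The result is an unrooted tree written with a basal
    trifurcation.
    """
    if dm.has_missing():
        raise ValueError(
            "distance matrix contains missing values; review pairwise-deletion "
            "site counts (n_sites_used) before building a tree"
        )
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.values.copy()
    nodes = [_quote(label) for label in dm.labels]

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin == lowest (i, j) among ties
        i, j = divmod(int(np.argmin(Q)), r)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        merged = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D_next = np.empty((r - 1, r - 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = D_next[:-1, -1] = d_new[keep]
        D_next[-1, -1] = 0.0
        D = D_next
        nodes = [nodes[k] for k in keep] + [merged]

    # final 3-way join at a central node
    a, b, c = nodes
    la = max(0.5 * (D[0, 1] + D[0, 2] - D[1, 2]), 0.0)
    lb = max(0.5 * (D[0, 1] + D[1, 2] - D[0, 2]), 0.0)
    lc = max(0.5 * (D[0, 2] + D[1, 2] - D[0, 1]), 0.0)
    newick = f"({a}:{la:.10g},{b}:{lb:.10g},{c}:{lc:.10g});"
    return PhyloTree.from_newick(newick)


def bootstrap_support(
    aln: Alignment,
    estimator: str = "p",
    n_reps: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Alignment columns are resampled with replacement ``n_reps`` times
    (ignoring any gene partitions); each replicate gets its own distance
    matrix and NJ tree, and each internal bipartition of the full-data tree
    is labelled with the percentage of replicates containing it.  Fully
    reproducible for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    try:
        dist_fn = ESTIMATORS[estimator]
    except KeyError:
        raise ValueError(f"unknown estimator {estimator!r}") from None
    rng = np.random.default_rng(seed)
    base_tree = neighbor_joining(dist_fn(aln))
    base_splits = base_tree.splits()
    counts = {s: 0 for s in base_splits}
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_sites, size=aln.n_sites)
        rep_aln = aln.subsample_columns(cols)
        rep_tree = neighbor_joining(dist_fn(rep_aln))
        for s in rep_tree.splits():
            if s in counts:
                counts[s] += 1
    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    base_tree.set_supports(supports)
    return base_tree
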