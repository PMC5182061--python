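"""Average-linkage (UPGMA) clustering of similarity matrices.

Similarities are turned into distances as ``d = 1 - s``; undefined entries
become distance 1, so pairs without evidence never co-cluster. Flat
partitions come from cutting the dendrogram at a *similarity* threshold t,
i.e. at distance 1 - t: the clusters are the maximal subtrees all of whose
internal merge heights are <= 1 - t.

The merge order is fully deterministic: at each step the pair of active
clusters with the smallest distance merges, ties broken by the smallest
(index_a, index_b) pair in cluster-creation order (leaves first, in input
order, then merged clusters). UPGMA heights are monotone, so the cut is a
well-defined horizontal line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .similarity import SimilarityMatrix

__all__ = [
    "LinkageTree",
    "ClusterResult",
    "similarity_to_distance",
    "average_linkage",
    "cut_at_score",
    "adjusted_rand",
]


@dataclass
class LinkageTree:
    """UPGMA merge sequence over ``leaf_ids``.

    ``merges[m] = (a, b, height, size)`` merges clusters ``a`` and ``b``
    into a new cluster with index ``n_leaves + m`` (scipy convention:
    leaves are clusters ``0..n-1`` in ``leaf_ids`` order).
    """

    merges: list[tuple[int, int, float, int]]
    leaf_ids: list[int]

    def __post_init__(self) -> None:
        heights = [h for _, _, h, _ in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")
        if self.merges and self.merges[-1][3] != len(self.leaf_ids):
            raise ValueError("final merge must contain all leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_scipy(self) -> np.ndarray:
        """(n-1, 4) linkage array compatible with scipy.cluster.hierarchy."""
        return np.array(
            [[a, b, h, s] for a, b, h, s in self.merges], dtype=float
        ).reshape(-1, 4)

    def members(self, cluster_index: int) -> list[int]:
        """Leaf positions contained in a cluster index (creation order)."""
        n = self.n_leaves
        if cluster_index < n:
            return [cluster_index]
        a, b, _, _ = self.merges[cluster_index - n]
        return self.members(a) + self.members(b)

    def to_newick(self) -> str:
        """Newick string with merge-height differences as branch lengths."""
        n = self.n_leaves

        def height(idx: int) -> float:
            return 0.0 if idx < n else self.merges[idx - n][2]

        def render(idx: int, parent_height: float) -> str:
            bl = parent_height - height(idx)
            if idx < n:
                return f"{self.leaf_ids[idx]}:{bl:.10g}"
            a, b, h, _ = self.merges[idx - n]
            return f"({render(a, h)},{render(b, h)}):{bl:.10g}"

        if not self.merges:
            return f"({self.leaf_ids[0]}:0);" if self.leaf_ids else "();"
        root = n + len(self.merges) - 1
        a, b, h, _ = self.merges[-1]
        return f"({render(a, h)},{render(b, h)});"

    def save(self, path_prefix: Union[str, Path]) -> None:
        prefix = Path(path_prefix)
        with open(prefix.with_suffix(".nwk"), "w") as fh:
            fh.write(self.to_newick() + "\n")
        pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "size"]
        ).to_csv(prefix.with_suffix(".csv"), index=False)


@dataclass
class ClusterResult:
    """Flat partition from a dendrogram cut at a similarity threshold."""

    assignment: dict[int, int]  # neuron id -> cluster index (1-based)
    cut_score: float
    n_clusters: int

    def sizes(self) -> list[int]:
        counts: dict[int, int] = {}
        for v in self.assignment.values():
            counts[v] = counts.get(v, 0) + 1
        return [counts[k] for k in sorted(counts)]

    def save(self, path: Union[str, Path]) -> None:
        rows = [{"id": k, "cluster": v} for k, v in sorted(self.assignment.items())]
        pd.DataFrame(rows, columns=["id", "cluster"]).to_csv(path, index=False)


def similarity_to_distance(sim: SimilarityMatrix) -> np.ndarray:
    """Distance matrix 1 - s with undefined entries mapped to distance 1."""
    d = np.where(sim.defined, 1.0 - sim.values, 1.0)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def average_linkage(sim: Union[SimilarityMatrix, np.ndarray]) -> LinkageTree:
    """UPGMA tree of a similarity matrix (Lance-Williams average update).

    Accepts a :class:`SimilarityMatrix` (leaf ids taken from it) or a raw
    square similarity array (leaf ids are positions). Needs >= 2 leaves.
    """
    if isinstance(sim, SimilarityMatrix):
        leaf_ids = list(sim.ids)
        dist = similarity_to_distance(sim)
    else:
        values = np.asarray(sim, dtype=float)
        leaf_ids = list(range(values.shape[0]))
        dist = 1.0 - values
        np.fill_diagonal(dist, 0.0)
    n = len(leaf_ids)
    if n < 2:
        raise ValueError("clustering needs at least 2 leaves")
    if not np.allclose(dist, dist.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")

    # active cluster index -> (row in working matrix, size)
    work = dist.astype(float).copy()
    active: list[int] = list(range(n))  # cluster indices, creation order
    sizes = {i: 1 for i in range(n)}
    row_of = {i: i for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []

    for m in range(n - 1):
        best = None
        # lexicographic scan over creation-ordered active clusters picks the
        # smallest (a, b) pair among exact ties
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d = work[row_of[a], row_of[b]]
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        new = n + m
        size = sizes[a] + sizes[b]
        merges.append((a, b, float(d), size))
        # Lance-Williams average-linkage update, reusing cluster a's row
        ra, rb = row_of[a], row_of[b]
        for other in active:
            if other in (a, b):
                continue
            ro = row_of[other]
            nd = (sizes[a] * work[ra, ro] + sizes[b] * work[rb, ro]) / size
            work[ra, ro] = work[ro, ra] = nd
        active = [x for x in active if x not in (a, b)] + [new]
        sizes[new] = size
        row_of[new] = ra
    return LinkageTree(merges=merges, leaf_ids=leaf_ids)


def cut_at_score(tree: LinkageTree, score: float) -> ClusterResult:
    """Flat clusters whose members' merge heights are all <= 1 - score.

    Cutting at score 1 isolates every leaf (absent zero-height merges);
    cutting at score 0 yields a single cluster.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"cut score must be in [0, 1], got {score}")
    threshold = 1.0 - score
    n = tree.n_leaves
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (a, b, h, _) in enumerate(tree.merges):
        if h <= threshold + 1e-12:
            new = n + m
            parent[find(a)] = new
            parent[find(b)] = new

    # number clusters 1.. in leaf order for determinism
    label_of_root: dict[int, int] = {}
    assignment: dict[int, int] = {}
    for pos, leaf in enumerate(tree.leaf_ids):
        root = find(pos)
        if root not in label_of_root:
            label_of_root[root] = len(label_of_root) + 1
        assignment[leaf] = label_of_root[root]
    return ClusterResult(
        assignment=assignment, cut_score=score, n_clusters=len(label_of_root)
    )


def adjusted_rand(a: Mapping[int, int], b: Mapping[int, int]) -> float:
    """Chance-corrected Rand agreement between two partitions of one set."""
    if set(a) != set(b):
        raise ValueError("partitions must cover the same ids")
    keys = sorted(a)
    return float(adjusted_rand_score([a[k] for k in keys], [b[k] for k in keys]))
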