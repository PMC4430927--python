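"""Single-linkage (nearest point) hierarchical clustering of samples.

Samples are clustered over a chosen probe subset with Euclidean
distances; the inter-cluster distance is the nearest-point rule
d(u, v) = min_{i in u, j in v} d(i, j).  The agglomeration is written out
explicitly (it is the contracted primitive here) with a deterministic
tie rule; heights are non-decreasing by the single-linkage monotonicity
property.  Dendrograms export as a merge list and as Newick with branch
lengths equal to height differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import MethylationMatrix, SampleMeta


class ClusteringError(ValueError):
    pass


@dataclass
class Dendrogram:
    """Merge list [(cluster_u, cluster_v, height, size)] in merge order.

    Leaves are numbered 0..M-1 in sample order; internal clusters are
    numbered M, M+1, ... in merge order (scipy linkage convention).
    """

    merges: list
    leaf_labels: list

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_linkage(self) -> np.ndarray:
        """Merge list as a scipy-style (M-1) x 4 linkage matrix."""
        return np.array([[u, v, h, s] for u, v, h, s in self.merges], dtype=float)

    def members(self) -> dict:
        """Cluster id -> set of leaf indices, for leaves and internal nodes."""
        out = {i: {i} for i in range(self.n_leaves)}
        for t, (u, v, _, _) in enumerate(self.merges):
            out[self.n_leaves + t] = out[u] | out[v]
        return out

    def cophenetic(self) -> np.ndarray:
        """Matrix of cophenetic distances (merge height joining each pair)."""
        m = self.n_leaves
        coph = np.zeros((m, m))
        members = {i: {i} for i in range(m)}
        for t, (u, v, h, _) in enumerate(self.merges):
            for a in members[u]:
                for b in members[v]:
                    coph[a, b] = coph[b, a] = h
            members[m + t] = members[u] | members[v]
        return coph

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences."""
        m = self.n_leaves
        height = {i: 0.0 for i in range(m)}
        text = {i: str(self.leaf_labels[i]) for i in range(m)}
        for t, (u, v, h, _) in enumerate(self.merges):
            bu, bv = h - height[u], h - height[v]
            node = m + t
            text[node] = f"({text[u]}:{bu:.6g},{text[v]}:{bv:.6g})"
            height[node] = h
        return text[m + len(self.merges) - 1] + ";"


def single_linkage(matrix: MethylationMatrix, probe_subset=None) -> Dendrogram:
    """Agglomerative nearest-point clustering of the samples.

    ``probe_subset`` optionally restricts the Euclidean distance to a set
    of probe IDs.  Ties in the minimum inter-cluster distance are broken
    by the lexicographically smallest (cluster id, cluster id) pair.
    """
    if probe_subset is not None:
        probe_subset = [p for p in matrix.probe_ids if p in set(probe_subset)]
        if not probe_subset:
            raise ClusteringError("probe subset is empty")
        matrix = matrix.subset_probes(probe_subset)
    m = matrix.n_samples
    if m < 2:
        raise ClusteringError("need at least 2 samples")
    D = squareform(pdist(matrix.values.T, metric="euclidean"))

    # active cluster id -> (member leaf set)
    active = {i: {i} for i in range(m)}
    dist = {}  # frozenset({a,b}) of active ids -> nearest-point distance
    ids = list(active)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            dist[(a, b)] = D[a, b]
    merges = []
    next_id = m
    while len(active) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (u, v), h = best
        members = active.pop(u) | active.pop(v)
        del dist[(u, v)]
        new_dists = {}
        for key in list(dist):
            a, b = key
            if u in key or v in key:
                other = b if a in (u, v) else a
                d_old = dist.pop(key)
                prev = new_dists.get(other)
                new_dists[other] = d_old if prev is None else min(prev, d_old)
        for other, d in new_dists.items():
            dist[(min(other, next_id), max(other, next_id))] = d
        active[next_id] = members
        merges.append((u, v, float(h), len(members)))
        next_id += 1
    return Dendrogram(merges, list(matrix.sample_ids))


def cluster_report(dendrogram: Dendrogram, meta: SampleMeta, grouping: str) -> dict:
    """Does a sample grouping form clean subtrees of the dendrogram?

    For the requested metadata field, each group's purity flag records
    whether its leaves form a connected subtree (some cluster in the merge
    history equals the group's leaf set exactly); the report also gives
    the mean within- vs between-group cophenetic distance.
    """
    if grouping not in meta.table.columns:
        raise ClusteringError(f"unknown grouping field {grouping!r}")
    meta = meta.aligned_to(dendrogram.leaf_labels)
    labels = meta.table[grouping].to_numpy()
    m = dendrogram.n_leaves
    clusters = set(map(frozenset, dendrogram.members().values()))
    purity = {}
    for g in np.unique(labels):
        leaf_set = frozenset(np.flatnonzero(labels == g))
        purity[str(g)] = leaf_set in clusters or len(leaf_set) == 1
    coph = dendrogram.cophenetic()
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(m, dtype=bool)
    within = coph[same & off_diag]
    between = coph[~same]
    return {
        "grouping": grouping,
        "purity": purity,
        "all_pure": all(purity.values()),
        "mean_within": float(within.mean()) if within.size else float("nan"),
        "mean_between": float(between.mean()) if between.size else float("nan"),
    }
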