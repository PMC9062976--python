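"""Agglomerative hierarchical clustering with mean-of-joining-series linkage.

At each iteration the two most DTW-similar active nodes are merged; the new
node's representative series is the pointwise mean of the two merged
representatives (NOT the mean of all member series — a deliberate, literal
reading of "mean of the two joining time series"; the member-mean alternative
is available behind ``linkage="member_mean"`` for sensitivity analysis).
Distances from the new representative to every remaining node are recomputed
by DTW, so merge heights need not be monotone and no ultrametric structure is
assumed.

Cutting the tree at k undoes the last k-1 merges; clusters are numbered
1..k by decreasing size, ties broken by the smallest contained case index.
Shorter series are classified afterwards by nearest (path-length-normalized)
DTW distance to the cluster mean representatives.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dtw import DtwConfig, dtw_distance, dtw_matrix

__all__ = ["ClusterModel", "agglomerate", "cut", "classify_short", "label_archetypes"]


@dataclass
class ClusterModel:
    """Merge tree over n leaf series.

    Leaves are node ids 0..n-1; the node created by merge i is id n+i.
    ``merge_history`` rows are (node_a, node_b, distance, new_node_id) with
    the distance computed between the two representatives at merge time.
    """

    n_leaves: int
    merge_history: list[tuple[int, int, float, int]]
    representatives: dict[int, np.ndarray]
    members: dict[int, list[int]]
    dtw_config: DtwConfig = field(default_factory=DtwConfig)

    def cut(self, k: int) -> np.ndarray:
        return cut(self, k)

    def cluster_means(self, k: int) -> list[np.ndarray]:
        """Representative series of each cluster at the k-cut, in label order."""
        labels = self.cut(k)
        nodes = self._active_nodes(k)
        means = [None] * k
        for node in nodes:
            lab = labels[self.members[node][0]]
            means[lab - 1] = self.representatives[node]
        return means

    def _active_nodes(self, k: int) -> list[int]:
        active = set(range(self.n_leaves))
        for a, b, _, new in self.merge_history[: self.n_leaves - k]:
            active.discard(a)
            active.discard(b)
            active.add(new)
        return sorted(active)


def agglomerate(series, dtw_config: DtwConfig | None = None, linkage: str = "pair_mean") -> ClusterModel:
    """Build the full merge tree over equal-length scaled series.

    Ties in merge distance go to the lexicographically smallest
    (node_id_a, node_id_b) pair, making builds deterministic.
    """
    if linkage not in ("pair_mean", "member_mean"):
        raise ValueError("linkage must be 'pair_mean' or 'member_mean'")
    dtw_config = dtw_config or DtwConfig()
    series = [np.asarray(s, dtype=np.float64) for s in series]
    n = len(series)
    if n < 2:
        raise ValueError("need at least two series to cluster")
    if len({s.size for s in series}) != 1:
        raise ValueError("agglomerate requires equal-length series")

    reps: dict[int, np.ndarray] = {i: series[i] for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = list(range(n))
    # active distance matrix, kept in sync as nodes merge
    dist: dict[tuple[int, int], float] = {}
    D0 = dtw_matrix(series, dtw_config)
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D0[i, j]

    history: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for i_idx in range(len(active)):
            for j_idx in range(i_idx + 1, len(active)):
                a, b = active[i_idx], active[j_idx]
                key = (a, b) if a < b else (b, a)
                d = dist[key]
                if best is None or d < best[0] or (d == best[0] and key < best[1:]):
                    best = (d, *key)
        d, a, b = best
        if linkage == "pair_mean":
            new_rep = 0.5 * (reps[a] + reps[b])
        else:
            member_series = [series[i] for i in members[a] + members[b]]
            new_rep = np.mean(member_series, axis=0)
        reps[next_id] = new_rep
        members[next_id] = sorted(members[a] + members[b])
        active = [x for x in active if x not in (a, b)]
        for other in active:
            key = (other, next_id)
            dist[key] = dtw_distance(new_rep, reps[other], dtw_config)
        active.append(next_id)
        history.append((a, b, float(d), next_id))
        next_id += 1
    return ClusterModel(
        n_leaves=n,
        merge_history=history,
        representatives=reps,
        members=members,
        dtw_config=dtw_config,
    )


def cut(model: ClusterModel, k: int) -> np.ndarray:
    """Case -> cluster labels (1..k) after undoing the last k-1 merges.

    Clusters are numbered by decreasing size; ties by smallest case index.
    """
    n = model.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    nodes = model._active_nodes(k)
    order = sorted(nodes, key=lambda node: (-len(model.members[node]), model.members[node][0]))
    labels = np.empty(n, dtype=np.int64)
    for rank, node in enumerate(order, start=1):
        labels[model.members[node]] = rank
    return labels


def classify_short(short_series, cluster_means, dtw_config: DtwConfig | None = None) -> np.ndarray:
    """Assign each (shorter) series to the nearest cluster-mean representative.

    A 20-50-day series is a *truncation* of a full trajectory (follow-up
    simply stopped), so each one is compared against the prefix of every
    cluster mean covering the same days — never stretched across the full
    50-day mean, which would distort peak timing.  Distances are
    path-length-normalized DTW so scores are comparable across series of
    different lengths; ties go to the lower cluster number.
    """
    cluster_means = [np.asarray(m, dtype=np.float64) for m in cluster_means]
    if not cluster_means:
        raise ValueError("no cluster means to classify against")
    dtw_config = dtw_config or DtwConfig(normalize=True)
    labels = []
    for s in short_series:
        s = np.asarray(s, dtype=np.float64)
        d = np.array(
            [dtw_distance(s, m[: s.size], dtw_config) for m in cluster_means]
        )
        labels.append(int(np.argmin(d)) + 1)  # argmin takes the first minimum
    return np.asarray(labels, dtype=np.int64)


def label_archetypes(cluster_means, skeletons: dict[int, np.ndarray], dtw_config: DtwConfig | None = None) -> dict[int, int]:
    """Map cluster number -> archetype group id by nearest-DTW skeleton.

    ``skeletons`` maps group ids to scaled reference shapes (see
    :func:`dsadyn.synth.archetype_skeletons`).  The mapping is greedy on the
    globally smallest distances so that no two clusters take the same
    archetype while both remain assignable.
    """
    dtw_config = dtw_config or DtwConfig(normalize=True)
    cluster_means = list(cluster_means)
    pairs = []
    for c, mean in enumerate(cluster_means, start=1):
        for g, skel in skeletons.items():
            pairs.append((dtw_distance(mean, skel, dtw_config), c, g))
    pairs.sort()
    mapping: dict[int, int] = {}
    used_groups: set[int] = set()
    for _, c, g in pairs:
        if c in mapping or g in used_groups:
            continue
        mapping[c] = g
        used_groups.add(g)
    # more clusters than archetypes: fall back to unconstrained nearest
    for c, mean in enumerate(cluster_means, start=1):
        if c not in mapping:
            d = {g: dtw_distance(mean, skel, dtw_config) for g, skel in skeletons.items()}
            mapping[c] = min(d, key=d.get)
    return mapping
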