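"""Continuity-constrained metaclustering of SOM units with AIC model selection.

Units with similar weight vectors are grouped into metaclusters that must
each form a connected patch on the toroidal lattice (4-neighbor adjacency),
preserving the topology learned in training.  Centroids come from ordinary
k-means on the unit weight vectors; contiguity is then enforced by growing
each metacluster outward from the unit nearest its centroid, always
assigning next the unassigned unit with the smallest weight-space distance
to a centroid whose region it already touches.

The number of metaclusters k is chosen by scanning a range and scoring each
partition with AIC under a spherical-Gaussian likelihood,

    AIC(k) = n * D * ln(RSS / n) + 2 * k * D,

where n is the number of units, RSS the within-metacluster sum of squared
distances, and D the "dimensionality": the number of clusters obtained by
cutting an average-linkage hierarchical clustering of the unit vectors at
30% of its maximum merge height.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .som_core import SOMGrid

__all__ = [
    "Metaclustering",
    "estimate_dimensionality",
    "constrained_kmeans",
    "aic_score",
    "select_metaclustering",
    "is_contiguous",
    "lattice_neighbors",
]

RSS_FLOOR_PER_UNIT = 1e-12


@dataclass
class Metaclustering:
    k: int
    centroids: np.ndarray          # (k, n_cells) weight-space centroids
    labels: np.ndarray             # (n_units,) metacluster id, row-major unit order
    rows: int
    cols: int
    aic: float = np.nan
    dimensionality: int = 0
    aic_trace: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if len(self.labels) != self.rows * self.cols:
            raise ValueError("one label per unit required")
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValueError("labels must cover 0..k-1 with no empty metacluster")

    def members(self, mc: int) -> np.ndarray:
        return np.where(self.labels == mc)[0]

    def to_json(self, path: str) -> None:
        obj = {
            "k": self.k, "rows": self.rows, "cols": self.cols,
            "aic": self.aic, "dimensionality": self.dimensionality,
            "labels": self.labels.tolist(),
            "centroids": self.centroids.tolist(),
            "aic_trace": {str(k): v for k, v in self.aic_trace.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path: str) -> "Metaclustering":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            k=obj["k"], centroids=np.array(obj["centroids"]),
            labels=np.array(obj["labels"]), rows=obj["rows"], cols=obj["cols"],
            aic=obj["aic"], dimensionality=obj["dimensionality"],
            aic_trace={int(k): v for k, v in obj.get("aic_trace", {}).items()},
        )


# ---------------------------------------------------------------------------
# lattice adjacency helpers
# ---------------------------------------------------------------------------

def lattice_neighbors(idx: int, rows: int, cols: int,
                      eight: bool = False) -> list[int]:
    """Toroidal lattice neighbors of a flat row-major unit index."""
    r, c = divmod(idx, cols)
    deltas = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if eight:
        deltas += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    return [((r + dr) % rows) * cols + (c + dc) % cols for dr, dc in deltas]


def is_contiguous(labels: np.ndarray, rows: int, cols: int,
                  eight: bool = False) -> bool:
    """Check every metacluster is connected under toroidal adjacency (BFS)."""
    labels = np.asarray(labels)
    for mc in np.unique(labels):
        members = set(np.where(labels == mc)[0].tolist())
        start = next(iter(members))
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in lattice_neighbors(u, rows, cols, eight):
                if v in members and v not in seen:
                    seen.add(v)
                    stack.append(v)
        if seen != members:
            return False
    return True


# ---------------------------------------------------------------------------
# dimensionality estimate
# ---------------------------------------------------------------------------

def estimate_dimensionality(grid: SOMGrid, cut_fraction: float = 0.30,
                            method: str = "average") -> int:
    """Number of clusters in a hierarchical clustering of the unit weight
    vectors cut at ``cut_fraction`` of the maximum merge height."""
    Z = linkage(grid.weights, method=method, metric="euclidean")
    max_height = Z[-1, 2]
    if max_height <= 0:
        return 1
    labels = fcluster(Z, t=cut_fraction * max_height, criterion="distance")
    return int(labels.max())


# ---------------------------------------------------------------------------
# continuity-constrained k-means
# ---------------------------------------------------------------------------

def constrained_kmeans(grid: SOMGrid, k: int, seed: int = 0,
                       eight_neighbor: bool = False) -> Metaclustering:
    """Lattice-contiguous partition of the units around k-means centroids.

    Stage 1: standard k-means (k-means++ init, 10 restarts) on unit weights.
    Stage 2: contiguity repair — seed each metacluster at the unclaimed unit
    nearest its centroid, then grow regions with a global priority queue,
    always assigning the unassigned unit with the smallest weight-space
    distance to a centroid whose region is lattice-adjacent to it.
    """
    n_units = grid.n_units
    if not 1 <= k <= n_units:
        raise ValueError(f"k={k} out of range [1, {n_units}]")
    W = grid.weights
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    km.fit(W)
    centroids = km.cluster_centers_

    # distance of every unit to every centroid
    dist = np.linalg.norm(W[:, None, :] - centroids[None, :, :], axis=2)

    labels = np.full(n_units, -1, dtype=np.int64)
    # seed each metacluster at the unclaimed unit nearest its centroid
    for c in range(k):
        order = np.argsort(dist[:, c], kind="stable")  # row-major tie-break
        for u in order:
            if labels[u] == -1:
                labels[u] = c
                break

    # global priority growth
    heap: list[tuple[float, int, int]] = []
    pushed = set()

    def push_frontier(u: int) -> None:
        for v in lattice_neighbors(u, grid.rows, grid.cols, eight_neighbor):
            if labels[v] == -1 and (v, labels[u]) not in pushed:
                pushed.add((v, int(labels[u])))
                heapq.heappush(heap, (dist[v, labels[u]], v, int(labels[u])))

    for u in np.where(labels >= 0)[0]:
        push_frontier(int(u))
    while heap:
        _, u, c = heapq.heappop(heap)
        if labels[u] != -1:
            continue
        labels[u] = c
        push_frontier(u)

    assert np.all(labels >= 0)
    return Metaclustering(k=k, centroids=centroids, labels=labels,
                          rows=grid.rows, cols=grid.cols)


# ---------------------------------------------------------------------------
# AIC scoring and model selection
# ---------------------------------------------------------------------------

def aic_score(grid: SOMGrid, labels: np.ndarray, k: int,
              dimensionality: int) -> float:
    """AIC = n*D*ln(RSS/n) + 2*k*D with RSS floored at 1e-12*n."""
    labels = np.asarray(labels)
    n = grid.n_units
    rss = 0.0
    for mc in range(k):
        members = grid.weights[labels == mc]
        if len(members) == 0:
            continue
        mean = members.mean(axis=0)
        rss += float(((members - mean) ** 2).sum())
    rss = max(rss, RSS_FLOOR_PER_UNIT * n)
    D = dimensionality
    return n * D * np.log(rss / n) + 2.0 * k * D


def select_metaclustering(grid: SOMGrid, k_min: int, k_max: int,
                          seed: int = 0,
                          eight_neighbor: bool = False) -> Metaclustering:
    """Scan k in [k_min, k_max], score each contiguous partition with AIC and
    return the argmin (ties to the smallest k)."""
    if k_min > k_max:
        raise ValueError("k_min must be <= k_max")
    D = estimate_dimensionality(grid)
    best: Metaclustering | None = None
    trace: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        mc = constrained_kmeans(grid, k, seed=seed, eight_neighbor=eight_neighbor)
        mc.dimensionality = D
        mc.aic = aic_score(grid, mc.labels, k, D)
        trace[k] = mc.aic
        if best is None or mc.aic < best.aic:
            best = mc
    best.aic_trace = trace
    return best
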