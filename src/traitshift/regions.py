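"""Regionalization of community change by from-scratch K-means.

Each unmasked grid cell carries a vector of per-species change in relative
biomass (scenario minus current share).  Cells are partitioned into K
regions of similar community change with Lloyd's algorithm under k-means++
seeding and multiple restarts (the analysis uses K = 5 regions).  Rows are
raw share differences — every column is in the same units (proportions) —
so no standardization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChangeMatrix",
    "RegionPartition",
    "build_change_matrix",
    "kmeans",
    "relabel_by_size",
]


@dataclass
class ChangeMatrix:
    """Cells x species matrix of change in relative biomass share."""

    X: np.ndarray                # (n_cells, n_species)
    cells: np.ndarray            # flat cell index per row
    species: list[str]
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X)):
            raise ValueError("change matrix has non-finite entries")
        if self.X.shape != (len(self.cells), len(self.species)):
            raise ValueError("change matrix shape does not match cells/species")


def build_change_matrix(shares_current: dict[str, np.ndarray],
                        shares_future: dict[str, np.ndarray],
                        pool: list[str] | None = None) -> ChangeMatrix:
    """Stack per-species share changes over the cells valid in both scenarios."""
    if pool is None:
        pool = sorted(set(shares_current) & set(shares_future))
    if not pool:
        raise ValueError("empty species pool")
    shape = None
    valid = None
    for s in pool:
        a, b = np.asarray(shares_current[s]), np.asarray(shares_future[s])
        if a.shape != b.shape:
            raise ValueError(f"grid mismatch for species {s!r}")
        if shape is None:
            shape = a.shape
        elif a.shape != shape:
            raise ValueError("species grids differ in shape")
        v = ~np.isnan(a) & ~np.isnan(b)
        valid = v if valid is None else (valid & v)
    cells = np.flatnonzero(valid.ravel())
    cols = [np.asarray(shares_future[s]).ravel()[cells]
            - np.asarray(shares_current[s]).ravel()[cells] for s in pool]
    return ChangeMatrix(X=np.column_stack(cols), cells=cells,
                        species=list(pool), grid_shape=shape)


@dataclass
class RegionPartition:
    """K-means result: labels 1..K per row, centroids and total SSE."""

    labels: np.ndarray
    centroids: np.ndarray
    sse: float
    n_iter: int
    seed: int
    cells: np.ndarray | None = None
    grid_shape: tuple[int, int] | None = None

    @property
    def k(self) -> int:
        return len(self.centroids)

    def recomputed_sse(self, X: np.ndarray) -> float:
        return float(np.sum((X - self.centroids[self.labels - 1]) ** 2))

    def label_grid(self) -> np.ndarray:
        """Labels on the grid (0 = masked cell)."""
        if self.cells is None or self.grid_shape is None:
            raise ValueError("partition has no grid geometry attached")
        grid = np.zeros(self.grid_shape, dtype=int)
        grid.ravel()[self.cells] = self.labels
        return grid


def _sse_of(X: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    return float(np.sum((X - centroids[labels]) ** 2))


def _plusplus_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(X)
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = np.sum((X - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[j] = X[rng.integers(n)]
            continue
        probs = d2 / total
        centroids[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((X - centroids[j]) ** 2, axis=1))
    return centroids


def _lloyd(X: np.ndarray, centroids: np.ndarray, tol: float,
           max_iter: int) -> tuple[np.ndarray, np.ndarray, float, int]:
    k = len(centroids)
    prev_sse = np.inf
    labels = np.zeros(len(X), dtype=int)
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        sse = _sse_of(X, centroids, labels)
        assert sse <= prev_sse + 1e-9 * max(prev_sse, 1.0), \
            "SSE increased within a Lloyd run"
        # Empty clusters: give them the point farthest from its centroid
        # within the largest cluster.
        for j in range(k):
            if np.any(labels == j):
                continue
            counts = np.bincount(labels, minlength=k)
            big = int(np.argmax(counts))
            members = np.flatnonzero(labels == big)
            far = members[np.argmax(((X[members] - centroids[big]) ** 2).sum(axis=1))]
            labels[far] = j
        new_centroids = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
        sse = _sse_of(X, new_centroids, labels)
        if prev_sse - sse <= tol * max(prev_sse, 1.0):
            return labels, new_centroids, sse, it
        centroids = new_centroids
        prev_sse = sse
    return labels, centroids, prev_sse, max_iter


def kmeans(X: ChangeMatrix | np.ndarray, k: int = 5, n_init: int = 10,
           seed: int = 0, tol: float = 1e-6, max_iter: int = 300) -> RegionPartition:
    """Best-of-``n_init`` Lloyd's K-means with k-means++ seeding.

    Deterministic given the seed.  ``k`` may not exceed the number of
    distinct rows.  Labels are returned in 1..K (use
    :func:`relabel_by_size` for a stable size-ordered numbering).
    """
    cells = grid_shape = None
    if isinstance(X, ChangeMatrix):
        cells, grid_shape = X.cells, X.grid_shape
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if k < 1:
        raise ValueError("k must be at least 1")
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct rows")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        init = _plusplus_init(X, k, rng)
        labels, centroids, sse, n_iter = _lloyd(X, init, tol, max_iter)
        if best is None or sse < best[2]:
            best = (labels, centroids, sse, n_iter)
    labels, centroids, sse, n_iter = best
    return RegionPartition(labels=labels + 1, centroids=centroids, sse=sse,
                           n_iter=n_iter, seed=seed, cells=cells,
                           grid_shape=grid_shape)


def relabel_by_size(partition: RegionPartition) -> RegionPartition:
    """Renumber regions 1..K by descending cell count.

    Ties are broken by lexicographic order of the centroid coordinates, so
    the numbering is deterministic for any input labeling.
    """
    k = partition.k
    counts = np.bincount(partition.labels, minlength=k + 1)[1:]
    order = sorted(range(k),
                   key=lambda j: (-counts[j], tuple(partition.centroids[j])))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    new_labels = remap[partition.labels - 1]
    new_centroids = partition.centroids[order]
    return RegionPartition(labels=new_labels, centroids=new_centroids,
                           sse=partition.sse, n_iter=partition.n_iter,
                           seed=partition.seed, cells=partition.cells,
                           grid_shape=partition.grid_shape)
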