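"""TADPole clustering: density peaks over DTW with admissible pruning.

Density-peak clustering assigns each series a local density rho (number of
neighbours closer than a cutoff d_c) and a separation delta (distance to the
nearest series of higher density); cluster centers are the series with the
largest rho * delta products, and every other series inherits the cluster of
its nearest higher-density neighbour.  TADPole accelerates the construction
by deciding neighbour status from cheap admissible bounds wherever possible:
a pair whose diagonal upper bound is already below the cutoff is a neighbour,
a pair whose envelope lower bound is already above it is not, and the exact
banded DTW distance is computed only for the undecided remainder.  Pruning
never changes the result — rho and delta are identical to the full-matrix
computation.

Prototypes are PAM medoids (the member minimising summed within-cluster
distance), cluster validity is the mean silhouette index, and the clustering
model (number of clusters k and cutoff d_c) is selected by maximising the
silhouette over a grid.  All tie-breaks are deterministic index rules, so
the whole stage is reproducible without a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dtw import _dtw_band, pairwise_bounds, pairwise_dtw

STATUS_EXACT = 0
STATUS_UPPER_BOUNDED = 1
STATUS_LOWER_BOUNDED = 2
STATUS_NAMES = {
    STATUS_EXACT: "exact",
    STATUS_UPPER_BOUNDED: "upper_bounded",
    STATUS_LOWER_BOUNDED: "lower_bounded",
}


@dataclass
class DistanceMatrix:
    """Pairwise distances plus a per-entry pruning audit.

    ``values[i, j]`` is the exact DTW distance where ``status`` is exact,
    otherwise the bound that decided the pair's neighbour status.
    """

    values: np.ndarray
    status: np.ndarray  # STATUS_* codes

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_pruned(self) -> int:
        s = self.status[np.triu_indices(self.n, k=1)]
        return int((s != STATUS_EXACT).sum())


class DtwOracle:
    """Memoised exact-DTW access with precomputed admissible bounds."""

    def __init__(self, X: np.ndarray, window: int, D: np.ndarray | None = None):
        self.X = np.ascontiguousarray(X, dtype=float)
        self.window = int(window)
        self.n = self.X.shape[0]
        if D is not None:
            self._D = np.asarray(D, dtype=float)
            self._known = np.ones((self.n, self.n), dtype=bool)
            self.lb = self._D.copy()
            self.ub = self._D.copy()
        else:
            self._D = np.zeros((self.n, self.n))
            self._known = np.eye(self.n, dtype=bool)
            self.lb, self.ub = pairwise_bounds(self.X, self.window)

    def exact(self, i: int, j: int) -> float:
        if not self._known[i, j]:
            d = _dtw_band(self.X[i], self.X[j], self.window)
            self._D[i, j] = self._D[j, i] = d
            self._known[i, j] = self._known[j, i] = True
        return float(self._D[i, j])

    def n_exact_pairs(self) -> int:
        return int(self._known[np.triu_indices(self.n, k=1)].sum())


@dataclass
class ClusterModel:
    """Output of one TADPole run."""

    k: int
    cutoff: float
    window: int
    assignment: np.ndarray  # series index -> cluster id in 0..k-1
    centers: list[int]
    medoids: list[int]
    rho: np.ndarray
    delta: np.ndarray
    silhouette: float | None
    distances: DistanceMatrix
    grid: pd.DataFrame | None = field(default=None, repr=False)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster)


def _denser_than(rho: np.ndarray, i: int) -> np.ndarray:
    """Indices of strictly higher density than i, ties broken by smaller index."""
    idx = np.arange(rho.size)
    return idx[(rho > rho[i]) | ((rho == rho[i]) & (idx < i))]


def density_and_separation(
    dist: DtwOracle | np.ndarray, cutoff: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, DistanceMatrix]:
    """Per-series density rho, separation delta and nearest denser neighbour.

    ``rho_i`` counts neighbours with ``d(i, j) < cutoff``.  With an oracle,
    a pair is counted as neighbour without exact DTW when its upper bound is
    below the cutoff, as non-neighbour when its lower bound is at or above
    it (both decisions consistent with the strict inequality), and DTW is
    computed only otherwise; delta is found exactly by scanning denser
    candidates in lower-bound order and stopping once no candidate can beat
    the incumbent.  The top-density series gets ``delta = max_j d(i, j)`` and
    neighbour index -1.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if isinstance(dist, np.ndarray):
        oracle = None
        D = np.asarray(dist, dtype=float)
        n = D.shape[0]
    else:
        oracle = dist
        n = oracle.n

    status = np.full((n, n), STATUS_EXACT, dtype=np.int8)
    values = np.zeros((n, n))

    # --- density ---
    rho = np.zeros(n, dtype=int)
    if oracle is None:
        rho = (D < cutoff).sum(axis=1) - (np.diag(D) < cutoff).astype(int)
        values = D.copy()
    else:
        for i in range(n):
            for j in range(i + 1, n):
                if oracle._known[i, j]:
                    d = oracle.exact(i, j)
                    neighbor = d < cutoff
                    values[i, j] = values[j, i] = d
                elif oracle.ub[i, j] < cutoff:
                    neighbor = True
                    status[i, j] = status[j, i] = STATUS_UPPER_BOUNDED
                    values[i, j] = values[j, i] = oracle.ub[i, j]
                elif oracle.lb[i, j] >= cutoff:
                    neighbor = False
                    status[i, j] = status[j, i] = STATUS_LOWER_BOUNDED
                    values[i, j] = values[j, i] = oracle.lb[i, j]
                else:
                    d = oracle.exact(i, j)
                    neighbor = d < cutoff
                    values[i, j] = values[j, i] = d
                if neighbor:
                    rho[i] += 1
                    rho[j] += 1

    # --- separation ---
    delta = np.zeros(n)
    nhd = np.full(n, -1, dtype=int)
    order = np.lexsort((np.arange(n), -rho))  # decreasing rho, ties by index
    top = order[0]
    for i in range(n):
        denser = _denser_than(rho, i)
        if denser.size == 0:
            continue
        if oracle is None:
            dists = D[i, denser]
            best_pos = int(np.argmin(dists))
            # ties by smaller candidate index: argmin returns the first,
            # and `denser` is in increasing index order
            delta[i] = float(dists[best_pos])
            nhd[i] = int(denser[best_pos])
        else:
            lb_order = denser[np.argsort(oracle.lb[i, denser], kind="stable")]
            best = np.inf
            best_j = -1
            for j in lb_order:
                if oracle.lb[i, j] >= best:
                    break
                d = oracle.exact(i, j)
                if d < best or (d == best and j < best_j):
                    best, best_j = d, int(j)
            # re-impose the smallest-index tie rule over all candidates
            for j in denser:
                if j == best_j:
                    continue
                if oracle.lb[i, j] <= best and oracle.exact(i, j) == best and j < best_j:
                    best_j = int(j)
            delta[i] = best
            nhd[i] = best_j
    if oracle is None:
        delta[top] = float(np.max(D[top])) if n > 1 else 0.0
    else:
        delta[top] = max((oracle.exact(top, j) for j in range(n) if j != top), default=0.0)

    if oracle is not None:
        for i in range(n):
            for j in range(i + 1, n):
                if oracle._known[i, j]:
                    status[i, j] = status[j, i] = STATUS_EXACT
                    values[i, j] = values[j, i] = oracle._D[i, j]
    return rho, delta, nhd, DistanceMatrix(values, status)


def tadpole(
    X: np.ndarray,
    k: int,
    cutoff: float,
    window: int,
    prune: bool = True,
    oracle: DtwOracle | None = None,
    score: bool = True,
) -> ClusterModel:
    """Cluster the rows of ``X`` into ``k`` density-peak clusters.

    Centers are the ``k`` series maximising rho * delta (ties by larger
    delta, then smaller index); remaining series are assigned, in decreasing
    density order, to the cluster of their nearest higher-density neighbour.
    Deterministic for fixed input.
    """
    X = np.ascontiguousarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    if oracle is None:
        oracle = DtwOracle(X, window, D=None if prune else pairwise_dtw(X, window))
    rho, delta, nhd, dmat = density_and_separation(oracle, cutoff)

    gamma = rho * delta
    center_order = np.lexsort((np.arange(n), -delta, -gamma))
    centers = [int(i) for i in center_order[:k]]

    assignment = np.full(n, -1, dtype=int)
    for cid, c in enumerate(centers):
        assignment[c] = cid
    density_order = np.lexsort((np.arange(n), -rho))
    for i in density_order:
        if assignment[i] >= 0:
            continue
        if nhd[i] >= 0 and assignment[nhd[i]] >= 0:
            assignment[i] = assignment[nhd[i]]
        else:  # no denser neighbour outside the centers: join nearest center
            assignment[i] = int(
                min(range(k), key=lambda c: (oracle.exact(i, centers[c]), c))
            )

    medoids = [medoid(np.flatnonzero(assignment == cid), oracle) for cid in range(k)]
    sil = None
    if score and k >= 2:
        D = np.array(
            [[oracle.exact(i, j) if i != j else 0.0 for j in range(n)] for i in range(n)]
        )
        sil = silhouette_index(D, assignment)
    return ClusterModel(
        k=k,
        cutoff=float(cutoff),
        window=int(window),
        assignment=assignment,
        centers=centers,
        medoids=medoids,
        rho=rho,
        delta=delta,
        silhouette=sil,
        distances=dmat,
    )


def medoid(members: np.ndarray, dist: DtwOracle | np.ndarray) -> int:
    """PAM prototype: member minimising summed within-cluster distance.

    Ties go to the smallest series index.
    """
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise ValueError("empty cluster has no medoid")
    if isinstance(dist, np.ndarray):
        sub = dist[np.ix_(members, members)]
        sums = sub.sum(axis=1)
    else:
        sums = np.array(
            [sum(dist.exact(i, j) for j in members if j != i) for i in members]
        )
    return int(members[int(np.argmin(sums))])


def silhouette_index(D: np.ndarray, assignment: np.ndarray) -> float:
    """Mean silhouette over all series from a precomputed distance matrix.

    s(i) = (b_i - a_i) / max(a_i, b_i) with a_i the mean distance to the
    other members of i's cluster and b_i the smallest mean distance to any
    other cluster; members of singleton clusters score 0.
    """
    D = np.asarray(D, dtype=float)
    assignment = np.asarray(assignment)
    labels = np.unique(assignment)
    if labels.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = D.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = np.flatnonzero((assignment == assignment[i]) & (np.arange(n) != i))
        if own.size == 0:
            continue  # singleton: s = 0
        a = D[i, own].mean()
        b = min(
            D[i, assignment == lab].mean() for lab in labels if lab != assignment[i]
        )
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


def select_model(
    X: np.ndarray,
    k_grid: list[int] | None = None,
    cutoff_grid: list[float] | None = None,
    window: int = 14,
    cutoff_quantiles: list[float] | None = None,
) -> ClusterModel:
    """Grid search over (k, cutoff); return the model with highest silhouette.

    The DTW matrix is computed once and shared across grid cells, since every
    cell's silhouette needs it anyway.  The default cutoff grid is the
    {0.05, 0.10, ..., 0.50} quantiles of the off-diagonal pairwise
    upper bounds.  Ties go to smaller k, then smaller cutoff; the full grid
    of scores is attached to the returned model as ``model.grid``.
    """
    X = np.ascontiguousarray(X, dtype=float)
    n = X.shape[0]
    if k_grid is None:
        k_grid = [2, 3, 4, 5, 6]
    if any(k < 2 for k in k_grid):
        raise ValueError("model selection requires k >= 2 (silhouette undefined at k=1)")
    k_grid = [k for k in k_grid if k <= n]
    if not k_grid:
        raise ValueError("all k in grid exceed the number of series")

    D = pairwise_dtw(X, window)
    if cutoff_grid is None:
        if cutoff_quantiles is None:
            cutoff_quantiles = [0.05 * q for q in range(1, 11)]
        _, ub = pairwise_bounds(X, window)
        off = ub[np.triu_indices(n, k=1)]
        cutoff_grid = sorted({float(np.quantile(off, q)) for q in cutoff_quantiles})
        cutoff_grid = [c for c in cutoff_grid if c > 0]
        if not cutoff_grid:
            raise ValueError("degenerate data: all pairwise upper bounds are zero")

    oracle = DtwOracle(X, window, D=D)
    rows = []
    best = None
    for k in sorted(k_grid):
        for cutoff in sorted(cutoff_grid):
            try:
                model = tadpole(X, k, cutoff, window, oracle=oracle, score=False)
                sil = silhouette_index(D, model.assignment)
                model.silhouette = sil
                rows.append({"k": k, "cutoff": cutoff, "silhouette": sil, "error": ""})
            except Exception as exc:  # noqa: BLE001 - per-cell diagnostics
                rows.append(
                    {"k": k, "cutoff": cutoff, "silhouette": np.nan, "error": str(exc)}
                )
                continue
            if best is None or model.silhouette > best.silhouette:
                best = model
    grid = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError(f"every grid cell failed:\n{grid.to_string(index=False)}")
    best.grid = grid
    return best
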