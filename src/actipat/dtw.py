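"""Dynamic time warping under a Sakoe–Chiba band, with admissible bounds.

The distance between two equal-length series is the minimum, over monotone
contiguous warping paths constrained to ``|i - j| <= window``, of the summed
local cost ``|x_i - y_j|`` (L1, symmetric unit-slope steps, both endpoints
matched).  With ``window = 0`` the path is forced onto the diagonal and the
distance reduces to the Manhattan distance — a convenient sanity anchor.

Two cheap admissible bounds bracket the distance for pruning:

* ``lb_keogh(x, y, w)`` — the envelope lower bound: the part of ``x``
  sticking out of the running min/max envelope of ``y`` over the band.
* ``upper_bound(x, y)`` — the diagonal-path cost, an upper bound because the
  diagonal is one feasible warping path.

Kernels are numba-compiled when numba is importable, with equivalent pure
Python fallbacks.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def _dtw_band(x: np.ndarray, y: np.ndarray, window: int) -> float:
    n = x.shape[0]
    inf = np.inf
    prev = np.full(n + 1, inf)
    cur = np.full(n + 1, inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[:] = inf
        lo = max(1, i - window)
        hi = min(n, i + window)
        for j in range(lo, hi + 1):
            cost = abs(x[i - 1] - y[j - 1])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = cost + best
        prev, cur = cur, prev
    return prev[n]


@njit(cache=False)
def _l1_seq(x: np.ndarray, y: np.ndarray) -> float:
    # sequential accumulation, matching the DP kernel's order bit for bit:
    # when the diagonal path is optimal, upper bound == DTW exactly
    total = 0.0
    for i in range(x.shape[0]):
        total += abs(x[i] - y[i])
    return total


@njit(cache=False)
def _envelope(y: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    n = y.shape[0]
    upper = np.empty(n)
    lower = np.empty(n)
    for i in range(n):
        lo = max(0, i - window)
        hi = min(n, i + window + 1)
        u = y[lo]
        l = y[lo]
        for j in range(lo + 1, hi):
            if y[j] > u:
                u = y[j]
            if y[j] < l:
                l = y[j]
        upper[i] = u
        lower[i] = l
    return upper, lower


@njit(cache=False)
def _lb_keogh(x: np.ndarray, upper: np.ndarray, lower: np.ndarray) -> float:
    total = 0.0
    for i in range(x.shape[0]):
        if x[i] > upper[i]:
            total += x[i] - upper[i]
        elif x[i] < lower[i]:
            total += lower[i] - x[i]
    return total


def _check_pair(x: np.ndarray, y: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("series must be 1-D and of equal length")
    if x.size == 0:
        raise ValueError("series must be non-empty")
    if window < 0:
        raise ValueError("window must be >= 0")
    return x, y


def dtw_distance(x, y, window: int) -> float:
    """Band-constrained DTW distance with L1 local cost."""
    x, y = _check_pair(x, y, window)
    return float(_dtw_band(x, y, int(window)))


def lb_keogh(x, y, window: int) -> float:
    """Envelope lower bound: ``lb_keogh(x, y, w) <= dtw_distance(x, y, w)``."""
    x, y = _check_pair(x, y, window)
    upper, lower = _envelope(y, int(window))
    return float(_lb_keogh(x, upper, lower))


def upper_bound(x, y) -> float:
    """Diagonal-path cost: ``dtw_distance(x, y, w) <= upper_bound(x, y)``."""
    x, y = _check_pair(x, y, 0)
    return float(_l1_seq(x, y))


def pairwise_dtw(X: np.ndarray, window: int) -> np.ndarray:
    """Full symmetric DTW distance matrix for the rows of ``X``."""
    X = np.ascontiguousarray(X, dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _dtw_band(X[i], X[j], int(window))
    return D


def pairwise_bounds(X: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Symmetrised (LB, UB) matrices for the rows of ``X``.

    The lower bound is ``max(lb_keogh(x_i, x_j), lb_keogh(x_j, x_i))`` — the
    tighter of the two admissible one-sided envelopes; the upper bound is the
    diagonal-path cost, symmetric by construction.
    """
    X = np.ascontiguousarray(X, dtype=float)
    n = X.shape[0]
    LB = np.zeros((n, n))
    UB = np.zeros((n, n))
    envs = [_envelope(X[i], int(window)) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            lb = max(
                _lb_keogh(X[i], envs[j][0], envs[j][1]),
                _lb_keogh(X[j], envs[i][0], envs[i][1]),
            )
            LB[i, j] = LB[j, i] = lb
            UB[i, j] = UB[j, i] = _l1_seq(X[i], X[j])
    return LB, UB
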