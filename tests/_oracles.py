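"""Independent brute-force oracles used to check the implementation.

Each oracle takes the slow-but-obviously-correct route: exhaustive warping
path enumeration for DTW, a plain density-peaks pass over a full distance
matrix, margin-fixed table enumeration for the Fisher test, a direct
textbook silhouette, the Mann-Whitney formulation of the AUC, and a grid
search over the logistic likelihood.  None of them share code with the
package paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def dtw_enumerate(x, y, window: int) -> float:
    """Minimum path cost by enumerating every monotone warping path."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    best = [np.inf]

    def walk(i: int, j: int, cost: float) -> None:
        cost += abs(x[i] - y[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == n - 1:
            best[0] = cost
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ii, jj = i + di, j + dj
            if ii < n and jj < n and abs(ii - jj) <= window:
                walk(ii, jj, cost)

    walk(0, 0, 0.0)
    return best[0]


def density_peaks_full(D: np.ndarray, k: int, cutoff: float):
    """Plain density-peaks clustering from a full distance matrix.

    Same tie rules as the package (density ties to the smaller index,
    centers by rho*delta then delta then index) but written independently
    as a direct pass over the matrix.
    """
    D = np.asarray(D, float)
    n = D.shape[0]
    rho = np.array([(np.delete(D[i], i) < cutoff).sum() for i in range(n)])

    def denser(i):
        return [j for j in range(n) if (rho[j] > rho[i]) or (rho[j] == rho[i] and j < i)]

    delta = np.zeros(n)
    nhd = np.full(n, -1)
    for i in range(n):
        cand = denser(i)
        if not cand:
            delta[i] = max(D[i, j] for j in range(n) if j != i) if n > 1 else 0.0
        else:
            dists = [(D[i, j], j) for j in cand]
            delta[i], nhd[i] = min(dists)
    order = sorted(range(n), key=lambda i: (-rho[i] * delta[i], -delta[i], i))
    centers = order[:k]
    labels = {c: ci for ci, c in enumerate(centers)}
    for i in sorted(range(n), key=lambda i: (-rho[i], i)):
        if i in labels:
            continue
        j = nhd[i]
        if j >= 0 and j in labels:
            labels[i] = labels[j]
        else:
            labels[i] = min(range(k), key=lambda c: (D[i, centers[c]], c))
    return rho, delta, np.array([labels[i] for i in range(n)])


def fisher_enumerate(table) -> float:
    """Two-sided Fisher p by summing over all tables with the same margins."""
    t = np.asarray(table, int)
    r1, r2 = t.sum(axis=1)
    c1 = t[:, 0].sum()
    n = t.sum()
    rv = hypergeom(n, r1, c1)
    p_obs = rv.pmf(t[0, 0])
    p = 0.0
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        pa = rv.pmf(a)
        if pa <= p_obs * (1 + 1e-7):
            p += pa
    return min(p, 1.0)


def silhouette_brute(D: np.ndarray, labels: np.ndarray) -> float:
    """Textbook silhouette, one point at a time."""
    D = np.asarray(D, float)
    labels = np.asarray(labels)
    vals = []
    for i in range(len(labels)):
        same = [j for j in range(len(labels)) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([D[i, j] for j in same])
        b = min(
            np.mean([D[i, j] for j in range(len(labels)) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def auc_mann_whitney(y, scores) -> float:
    """AUC as the probability a positive outscores a negative (ties count half)."""
    y, scores = np.asarray(y), np.asarray(scores, float)
    pos, neg = scores[y == 1], scores[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return float(wins / (len(pos) * len(neg)))


def logit_grid_search(x, y, b0_range, b1_range, steps: int = 201):
    """Maximize the Bernoulli log-likelihood of logistic(b0 + b1 x) on a grid."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = (-np.inf, None, None)
    for b0 in np.linspace(*b0_range, steps):
        for b1 in np.linspace(*b1_range, steps):
            eta = b0 + b1 * x
            ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
            if ll > best[0]:
                best = (ll, b0, b1)
    return best
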