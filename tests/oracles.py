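"""Independent brute-force reference implementations.

Deliberately naive (double loops, exhaustive enumeration) and kept free of
any rangeshift internals, so they can serve as oracles for the vectorized
production code.
"""

from itertools import combinations

import numpy as np


def moran_i_double_loop(z, points, lag):
    """Moran's I = (n/W) ΣΣ w_ij (z_i−z̄)(z_j−z̄) / Σ(z_i−z̄)² with binary
    weights w_ij = 1 iff 0 < dist(i,j) <= lag."""
    z = np.asarray(z, dtype=float)
    pts = np.asarray(points, dtype=float)
    n = len(z)
    zbar = z.mean()
    num = 0.0
    W = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1])
            if d <= lag:
                W += 1
                num += (z[i] - zbar) * (z[j] - zbar)
    if W == 0:
        return float("nan")
    denom = ((z - zbar) ** 2).sum()
    return (n / W) * num / denom


def pearson_double_loop(X):
    """Pairwise Pearson r over columns by the textbook sum formulas."""
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = X[:, i], X[:, j]
            di, dj = xi - xi.mean(), xj - xj.mean()
            r[i, j] = r[j, i] = (di * dj).sum() / np.sqrt((di**2).sum() * (dj**2).sum())
    return r


def summed_distance_double_loop(centers, occ_points):
    """Cumulative Euclidean distance from each cell center to all occurrences."""
    out = np.zeros(len(centers))
    for i, c in enumerate(centers):
        for p in occ_points:
            out[i] += np.hypot(c[0] - p[0], c[1] - p[1])
    return out


def sorensen_set_form(pred, obs):
    """2|A∩B| / (|A|+|B|) on the index sets of positives."""
    A = {i for i, v in enumerate(pred) if v}
    B = {i for i, v in enumerate(obs) if v}
    return 2 * len(A & B) / (len(A) + len(B))


def best_threshold_sweep(scores, obs):
    """Exhaustive sweep over unique scores; ties toward larger threshold."""
    best = None
    for t in sorted(set(float(s) for s in scores)):
        pred = [s >= t for s in scores]
        tp = sum(p and o for p, o in zip(pred, obs))
        fp = sum(p and not o for p, o in zip(pred, obs))
        fn = sum((not p) and o for p, o in zip(pred, obs))
        val = 2 * tp / (2 * tp + fp + fn)
        if best is None or val > best[0] or (val == best[0] and t > best[1]):
            best = (val, t)
    return best


def max_independent_set_size(points, min_distance):
    """Exhaustive maximum subset with all pairwise distances >= min_distance."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    conflict = [
        [np.hypot(*(pts[i] - pts[j])) < min_distance for j in range(n)] for i in range(n)
    ]
    for size in range(n, 0, -1):
        for combo in combinations(range(n), size):
            if all(
                not conflict[a][b] for a, b in combinations(combo, 2)
            ):
                return size
    return 0
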