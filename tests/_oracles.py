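"""Independent test oracles, kept deliberately naive.

These implementations are never used by the library; they exist so the
production code paths can be checked against brute force.
"""

from __future__ import annotations

import numpy as np


def kmeans_1d_exact(y, c):
    """Optimal 1-D k-means by dynamic programming over contiguous partitions.

    In one dimension the optimal k-means clusters are contiguous in sorted
    order, so exact minimization is a DP over split points.  Returns
    ``(labels, wcss)`` with labels 1..c in ascending value order, in
    original sample order.  O(n^2 c); intended for n <= ~200.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    order = np.argsort(y, kind="stable")
    ys = y[order]
    s1 = np.concatenate([[0.0], np.cumsum(ys)])
    s2 = np.concatenate([[0.0], np.cumsum(ys**2)])

    def cost(i, j):  # sum of squares about the mean of ys[i:j]
        m = j - i
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / m

    big = np.inf
    dp = np.full((c + 1, n + 1), big)
    back = np.zeros((c + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for k in range(1, c + 1):
        for j in range(k, n + 1):
            best, arg = big, k - 1
            for i in range(k - 1, j):
                val = dp[k - 1, i] + cost(i, j)
                if val < best:
                    best, arg = val, i
            dp[k, j] = best
            back[k, j] = arg
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for k in range(c, 0, -1):
        i = back[k, j]
        labels_sorted[i:j] = k
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, float(dp[c, n])


def verify_smote_rows(X_minority, synthetic, k, atol=1e-9):
    """Check every synthetic row is x + u*(x' - x) for a minority row x and
    one of its k nearest minority neighbours x', with u in [0, 1].

    Exhaustive search over all (x, x') pairs; returns the largest residual
    over synthetic rows (0.0 when all rows verify) or raises AssertionError
    naming the first offending row.
    """
    X_min = np.asarray(X_minority, dtype=float)
    synth = np.asarray(synthetic, dtype=float)
    m = X_min.shape[0]
    # k-NN sets by brute force (self excluded)
    d2 = ((X_min[:, None, :] - X_min[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    knn = np.argsort(d2, axis=1, kind="stable")[:, :k]
    worst = 0.0
    for r, s in enumerate(synth):
        best = np.inf
        for i in range(m):
            for j in knn[i]:
                x, xp = X_min[i], X_min[j]
                diff = xp - x
                denom = float(diff @ diff)
                if denom == 0.0:
                    resid = float(np.abs(s - x).max())
                    if resid < best:
                        best = resid
                    continue
                u = float((s - x) @ diff) / denom
                u_clipped = min(max(u, 0.0), 1.0)
                resid = float(np.abs(s - (x + u_clipped * diff)).max())
                if resid < best:
                    best = resid
        assert best < atol, f"synthetic row {r} is not a minority-pair interpolation (residual {best})"
        worst = max(worst, best)
    return worst
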