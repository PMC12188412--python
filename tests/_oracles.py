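"""Independent brute-force oracles used by the tests.

These deliberately re-derive results by the slowest, most transparent route
available (plain Bellman recursion, exhaustive enumeration, per-pixel loops)
and share no code with the package implementations they check.
"""

from itertools import combinations

import numpy as np


def dp_optimal_wcss(values, k: int) -> float:
    """Textbook O(k n^2) dynamic program for optimal 1-D k-means WCSS."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    pre = np.concatenate([[0.0], np.cumsum(x)])
    pre2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i, j):  # inclusive segment [i, j]
        w = j - i + 1
        s = pre[j + 1] - pre[i]
        return (pre2[j + 1] - pre2[i]) - s * s / w

    INF = float("inf")
    D = [[INF] * n for _ in range(k)]
    for j in range(n):
        D[0][j] = sse(0, j)
    for m in range(1, k):
        for j in range(m, n):
            best = INF
            for i in range(m, j + 1):
                c = D[m - 1][i - 1] + sse(i, j)
                if c < best:
                    best = c
            D[m][j] = best
    return D[k - 1][n - 1]


def brute_force_wcss(values, k: int) -> float:
    """Exhaustive enumeration over all contiguous split points (tiny n only)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size

    def sse(seg):
        return float(np.sum((seg - seg.mean()) ** 2)) if seg.size else 0.0

    best = float("inf")
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        total = sum(sse(x[bounds[i] : bounds[i + 1]]) for i in range(k))
        best = min(best, total)
    return best


def per_pixel_cell_sums(mass_grid, labels):
    """Mass per label by an explicit per-pixel loop."""
    sums = {}
    h, w = labels.shape
    for r in range(h):
        for c in range(w):
            lab = int(labels[r, c])
            if lab > 0:
                sums[lab] = sums.get(lab, 0.0) + float(mass_grid[r, c])
    return sums


def pearson_direct(x, y) -> float:
    """Pearson r straight from the definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
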