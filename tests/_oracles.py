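"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where feasible, the library
routines) they verify: the OLS slope is solved from the normal equations,
the U statistic is an exhaustive pairwise count, and Spearman's rho is
mid-ranking followed by an explicit Pearson formula.
"""

import numpy as np


def ols_slope(x, y):
    """Least-squares slope of y on x via the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    design = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    return beta[1]


def u_statistic(a, b):
    """Mann-Whitney U of sample ``a``: pairwise wins plus half-ties."""
    return float(sum((x > y) + 0.5 * (x == y) for x in a for y in b))


def midranks(v):
    """Average ranks (1-based) with ties sharing their mid-rank."""
    v = np.asarray(v, float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size)
    sv = v[order]
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y):
    """Pearson correlation of mid-ranks, written out explicitly."""
    rx = midranks(x)
    ry = midranks(y)
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx ** 2) * np.sum(dy ** 2)))


def trilinear(volume, point):
    """Trilinear interpolation of ``volume`` at fractional voxel ``point``."""
    volume = np.asarray(volume, float)
    out = 0.0
    base = np.floor(point).astype(int)
    frac = np.asarray(point) - base
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                idx = np.clip(base + [dx, dy, dz], 0,
                              np.asarray(volume.shape) - 1)
                w = ((frac[0] if dx else 1 - frac[0])
                     * (frac[1] if dy else 1 - frac[1])
                     * (frac[2] if dz else 1 - frac[2]))
                out += w * volume[tuple(idx)]
    return out
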