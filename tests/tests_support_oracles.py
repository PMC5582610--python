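"""Independent brute-force oracles used by the end-to-end checks."""

import numpy as np


def brute_force_mi(x, y):
    """Double loop over the contingency table, in bits."""
    x, y = np.asarray(x), np.asarray(y)
    total = 0.0
    for xv in set(x.tolist()):
        for yv in set(y.tolist()):
            pxy = np.mean((x == xv) & (y == yv))
            px, py = np.mean(x == xv), np.mean(y == yv)
            if pxy > 0:
                total += pxy * np.log2(pxy / (px * py))
    return total


def brute_force_cmi(x, y, z):
    """sum_z p(z) MI(x; y | z), each stratum by brute force."""
    x, y, z = np.asarray(x), np.asarray(y), np.asarray(z)
    total = 0.0
    for zv in set(z.tolist()):
        sel = z == zv
        total += np.mean(sel) * brute_force_mi(x[sel], y[sel])
    return total


def brute_force_hypergeom_upper(k, a, b, universe):
    """P(|A & B| >= k) by enumerating draws of B over the universe.

    Exact combinatorial sum: P(X = j) = C(a, j) C(u-a, b-j) / C(u, b).
    """
    from math import comb

    denom = comb(universe, b)
    total = 0
    for j in range(k, min(a, b) + 1):
        if b - j <= universe - a:
            total += comb(a, j) * comb(universe - a, b - j)
    return total / denom
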