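"""Brute-force reference implementations used only by the test suite.

Everything here is deliberately naive (exhaustive enumeration, direct
summation) and shares no code with the package.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def monotone_paths(T: int, U: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """All monotone warping paths from (0,0) to (T-1,U-1) with steps
    (1,0), (0,1), (1,1)."""
    if T == 1 and U == 1:
        return (((0, 0),),)
    paths = []
    if T > 1:
        for p in monotone_paths(T - 1, U):
            paths.append(p + ((T - 1, U - 1),))
    if U > 1:
        for p in monotone_paths(T, U - 1):
            paths.append(p + ((T - 1, U - 1),))
    if T > 1 and U > 1:
        for p in monotone_paths(T - 1, U - 1):
            paths.append(p + ((T - 1, U - 1),))
    return tuple(paths)


def dtw_bruteforce(x, y) -> float:
    """Minimum over all monotone paths of the summed |x_i - y_j| cost."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = np.inf
    for path in monotone_paths(len(x), len(y)):
        cost = sum(abs(x[i] - y[j]) for i, j in path)
        best = min(best, cost)
    return best


def frechet_bruteforce(x, y) -> float:
    """Minimum over all monotone couplings of the maximum |x_i - y_j| cost."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = np.inf
    for path in monotone_paths(len(x), len(y)):
        width = max(abs(x[i] - y[j]) for i, j in path)
        best = min(best, width)
    return best


def tam_of_path(path) -> float:
    """TAM of one warping path: n_h/p + n_v/p + (1 - n_d/p)."""
    n_d = n_v = n_h = 0
    for (i0, j0), (i1, j1) in zip(path[:-1], path[1:]):
        if i1 > i0 and j1 > j0:
            n_d += 1
        elif i1 > i0:
            n_v += 1
        else:
            n_h += 1
    p = n_d + n_v + n_h
    return n_h / p + n_v / p + (1 - n_d / p)


def tam_optimal_values(x, y) -> set[float]:
    """TAM values of every cost-optimal warping path (either argument order)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    values = set()
    for a, b in ((x, y), (y, x)):
        costs = {
            path: sum(abs(a[i] - b[j]) for i, j in path)
            for path in monotone_paths(len(a), len(b))
        }
        best = min(costs.values())
        for path, cost in costs.items():
            if cost == best:
                values.add(round(tam_of_path(path), 12))
    return values


def sample_variance(values) -> float:
    """Two-pass sample variance with denominator n-1, by direct summation."""
    values = list(map(float, values))
    n = len(values)
    mean = sum(values) / n
    return sum((v - mean) ** 2 for v in values) / (n - 1)


def acf_direct(z, max_lag: int) -> list[float]:
    """Biased sample autocorrelations by direct summation."""
    z = list(map(float, z))
    n = len(z)
    mean = sum(z) / n
    denom = sum((v - mean) ** 2 for v in z)
    if denom == 0:
        return [0.0] * max_lag
    out = []
    for k in range(1, max_lag + 1):
        num = sum((z[t] - mean) * (z[t + k] - mean) for t in range(n - k))
        out.append(num / denom)
    return out


def dft_direct(z) -> list[complex]:
    """Unnormalized DFT by direct summation."""
    z = list(map(float, z))
    n = len(z)
    return [
        sum(z[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n)) for k in range(n)
    ]


def periodogram_direct(z, n_freq: int) -> list[float]:
    Z = dft_direct(z)
    n = len(z)
    return [abs(Z[k]) ** 2 / n for k in range(1, n_freq + 1)]


def ks_statistic_uniform(values) -> float:
    """Kolmogorov-Smirnov statistic against U(0,1), by the direct formula."""
    v = sorted(values)
    n = len(v)
    return max(max(abs((i + 1) / n - v[i]), abs(v[i] - i / n)) for i in range(n))
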