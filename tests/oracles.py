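"""Independent brute-force reference implementations used as test oracles.

Deliberately naive, loop-based transcriptions of the entropy definitions:
no sliding windows, no vectorized pairwise kernels, no shared code with
the package beyond numpy scalars.  They share only the convention that
template distances are measured in units of the image SD (the package's
tolerance convention).
"""

from __future__ import annotations

import math

import numpy as np


def fuzzy_en2d_naive(img, m: int, n: float, r: float) -> float:
    """Quadruple-loop bidimensional fuzzy entropy."""
    x = np.asarray(img, dtype=float)
    h, w = x.shape
    sigma = x.std()
    u = (x - x.mean()) / sigma
    ni, nj = h - m, w - m  # shared origin grid for both template sizes

    def phi(size: int) -> float:
        outer = 0.0
        for i in range(ni):
            for j in range(nj):
                s = 0.0
                for a in range(ni):
                    for b in range(nj):
                        if (a, b) == (i, j):
                            continue
                        dmax = 0.0
                        for k in range(size):
                            for l in range(size):
                                diff = abs(u[i + k, j + l] - u[a + k, b + l])
                                if diff > dmax:
                                    dmax = diff
                        s += math.exp(-(dmax**n) / r)
                outer += s / (ni * nj - 1)
        return outer / (ni * nj)

    return math.log(phi(m) / phi(m + 1))


def _ncdf(t: float) -> float:
    return 0.5 * (1.0 + math.erf(t / math.sqrt(2.0)))


def class_map_naive(img, c: int):
    """Per-pixel NCDF class mapping with scalar math only."""
    x = np.asarray(img, dtype=float)
    mu, sigma = x.mean(), x.std()
    z = np.empty(x.shape, dtype=int)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            y = _ncdf((x[i, j] - mu) / sigma)
            # round half away from zero, then clamp into 1..c
            zij = math.floor(c * y + 0.5 + 0.5)
            z[i, j] = min(c, max(1, zij))
    return z


def pattern_counts_naive(class_map, m: int) -> dict[tuple[int, ...], int]:
    """Dictionary tally of row-major flattened m×m windows."""
    z = np.asarray(class_map)
    h, w = z.shape
    counts: dict[tuple[int, ...], int] = {}
    for k in range(h - m + 1):
        for l in range(w - m + 1):
            pat = []
            for a in range(m):
                for b in range(m):
                    pat.append(int(z[k + a, l + b]))
            key = tuple(pat)
            counts[key] = counts.get(key, 0) + 1
    return counts


def disp_en2d_naive(img, m: int, c: int) -> float:
    """Dispersion entropy via the naive class map and dictionary tally."""
    counts = pattern_counts_naive(class_map_naive(img, c), m)
    total = sum(counts.values())
    return -sum((k / total) * math.log(k / total) for k in counts.values())
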