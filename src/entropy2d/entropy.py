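"""Single-scale bidimensional fuzzy and dispersion entropy.

Both measures quantify the irregularity of a grayscale image ``U = {u(i,j)}``
of size H×W: repeating periodic texture gives low entropy, unpredictable
texture gives high entropy.

FuzzyEn2D
    The negative log of the conditional probability that two pixel
    templates similar at size m×m remain similar at size (m+1)×(m+1).
    Template similarity is graded by the fuzzy membership
    ``exp(−d^n / r)`` applied to the Chebyshev (max-component) distance
    ``d`` between templates; ``n`` sets the gradient of the similarity
    boundary and ``r`` its width.  Distances are measured in units of the
    image standard deviation, so ``r`` is a dimensionless fraction of σ
    and the measure is invariant under positive affine intensity
    transforms.  Template origins range over ``i ≤ H−m, j ≤ W−m`` for
    BOTH template sizes (``N_m = (H−m)(W−m)``); this keeps the two origin
    sets identical, which guarantees Φ^(m+1) ≤ Φ^m and hence a
    non-negative entropy.

DispEn2D
    Shannon entropy of the distribution of m×m "dispersion patterns".
    Pixels are first standardized through the normal CDF and rounded
    into ``c`` classes (``z = round(c·y + 0.5)``, clamped to [1, c]);
    every m×m window of the class map, flattened row-major, is one
    pattern out of ``c^(m²)`` possibilities, and the entropy of the
    empirical pattern frequencies is returned.  Range [0, m²·ln c].

A perfectly constant image is completely regular: both measures return
0.0 with the ``degenerate`` flag set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import norm

__all__ = [
    "FuzzyParams",
    "DispParams",
    "EntropyResult",
    "PatternDistribution",
    "fuzzy_en2d",
    "fuzzy_en2d_grid",
    "ncdf_class_map",
    "dispersion_patterns",
    "disp_en2d",
]

# Pairwise template distances are evaluated in row blocks of this many
# origins, bounding peak memory at ~chunk × N_m doubles.
_CHUNK = 2048


@dataclass(frozen=True)
class FuzzyParams:
    """FuzzyEn2D parameters.

    m : int
        Embedding dimension — side of the square template ([m, m]).
    n : float
        Fuzzy power, gradient of the exponential similarity boundary.
    r : float
        Tolerance, width of the similarity boundary as a fraction of the
        image standard deviation.
    """

    m: int = 1
    n: float = 2.0
    r: float = 0.36

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"m must be an integer ≥ 1, got {self.m}")
        if self.n < 1:
            raise ValueError(f"fuzzy power n must be ≥ 1, got {self.n}")
        if self.r <= 0:
            raise ValueError(f"tolerance r must be > 0, got {self.r}")


@dataclass(frozen=True)
class DispParams:
    """DispEn2D parameters.

    m : int
        Embedding dimension — side of the square window ([m, m]), ≥ 2.
    c : int
        Number of quantization classes, an integer from 3 to 9.
    """

    m: int = 2
    c: int = 3

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 2:
            raise ValueError(f"m must be an integer ≥ 2, got {self.m}")
        if int(self.c) != self.c or not 3 <= self.c <= 9:
            raise ValueError(f"c must be an integer in 3..9, got {self.c}")


@dataclass
class EntropyResult:
    """A single entropy evaluation: value in nats plus provenance."""

    value: float
    algorithm: str
    params: FuzzyParams | DispParams
    tau: int = 1
    degenerate: bool = False

    def as_row(self) -> dict:
        """Flatten to a CSV-friendly record."""
        row = {"algorithm": self.algorithm, "m": self.params.m}
        if isinstance(self.params, FuzzyParams):
            row.update(n=self.params.n, r=self.params.r, c=None)
        else:
            row.update(n=None, r=None, c=self.params.c)
        row.update(tau=self.tau, value=self.value, degenerate=self.degenerate)
        return row


@dataclass
class PatternDistribution:
    """Empirical distribution of dispersion patterns.

    counts maps each observed length-m² pattern tuple (row-major window
    flattening, entries in 1..c) to its occurrence count; total is the
    number of windows ``(h−m+1)·(w−m+1)``.
    """

    counts: dict[tuple[int, ...], int]
    total: int
    m: int
    c: int

    def probabilities(self) -> np.ndarray:
        return np.array(sorted(self.counts.values()), dtype=np.float64) / self.total


# ---------------------------------------------------------------------------
# FuzzyEn2D
# ---------------------------------------------------------------------------


def _template_components(x: np.ndarray, m: int, origin_shape: tuple[int, int]) -> np.ndarray:
    """Stack m×m windows at the shared origin grid as an (N, m²) matrix."""
    wins = sliding_window_view(x, (m, m))[: origin_shape[0], : origin_shape[1]]
    return wins.reshape(-1, m * m)


def _ipow(d: np.ndarray, n: float, out: np.ndarray) -> np.ndarray:
    """d**n into ``out``, via repeated multiplication for small integer n."""
    if float(n).is_integer() and 1 <= n <= 8:
        np.copyto(out, d)
        for _ in range(int(n) - 1):
            out *= d
        return out
    return np.power(d, n, out=out)


def _phi_sums(comps: np.ndarray, nr_pairs: Sequence[tuple[float, float]]) -> np.ndarray:
    """Sum of pairwise similarities exp(−d^n / r) over ordered origin pairs.

    The Chebyshev distance matrix is symmetric, so only column blocks
    ``j > i`` are evaluated: within each row chunk the distances at
    ``j ≤ i`` are set to +inf, whose similarity exp(−inf^n/r) underflows
    to exactly 0 and drops out of the sum.  Upper-triangle sums are then
    doubled and the N self-pairs (each contributing exp(0) = 1) added
    back; the caller removes the self-pairs again when normalizing.
    """
    n_origins, k = comps.shape
    upper = np.zeros(len(nr_pairs))
    cols = [np.ascontiguousarray(comps[:, c]) for c in range(k)]
    rows = min(_CHUNK, n_origins)
    d_buf = np.empty((rows, n_origins))
    dn_buf = np.empty_like(d_buf)
    work = np.empty_like(d_buf)
    for start in range(0, n_origins, _CHUNK):
        stop = min(start + _CHUNK, n_origins)
        width, span = stop - start, n_origins - start
        d = d_buf[:width, :span]
        np.subtract(cols[0][start:stop, None], cols[0][None, start:], out=d)
        np.abs(d, out=d)
        db = work[:width, :span]
        for c in range(1, k):
            np.subtract(cols[c][start:stop, None], cols[c][None, start:], out=db)
            np.abs(db, out=db)
            np.maximum(d, db, out=d)
        for i in range(width):  # mask j ≤ i; exp(−inf) = 0 removes the pair
            d[i, : i + 1] = np.inf
        dn = dn_buf[:width, :span]
        e = work[:width, :span]
        last_n = None
        for idx, (n, r) in enumerate(nr_pairs):
            if n != last_n:
                _ipow(d, n, out=dn)
                last_n = n
            np.multiply(dn, -1.0 / r, out=e)
            np.exp(e, out=e)
            upper[idx] += e.sum()
    return 2.0 * upper + n_origins


def fuzzy_en2d(img: np.ndarray, params: FuzzyParams = FuzzyParams()) -> EntropyResult:
    """Bidimensional fuzzy entropy of a grayscale image.

    Parameters
    ----------
    img
        2D real-valued pixel matrix.
    params
        Embedding dimension ``m``, fuzzy power ``n`` and tolerance ``r``
        (fraction of the image SD).

    Returns
    -------
    EntropyResult
        ``ln(Φ^m / Φ^(m+1)) ≥ 0`` in nats; a constant image yields 0.0
        with the degenerate flag set.
    """
    res = fuzzy_en2d_grid(img, [params])
    return res[0]


def fuzzy_en2d_grid(
    img: np.ndarray, grid: Iterable[FuzzyParams]
) -> list[EntropyResult]:
    """Evaluate FuzzyEn2D for several parameter bundles on one image.

    Pairwise template distances depend only on ``m``, so combinations
    sharing an embedding dimension reuse one distance computation; the
    full parameter sweep costs barely more than a single evaluation per
    distinct ``m``.  Results are returned in grid order.
    """
    grid = list(grid)
    x = np.asarray(img, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {x.shape}")
    h, w = x.shape

    sigma = x.std()  # population SD, divisor H·W
    if sigma == 0.0:
        return [
            EntropyResult(0.0, "fuzzy", p, degenerate=True) for p in grid
        ]
    xs = (x - x.mean()) / sigma  # distances in units of σ

    results: dict[int, EntropyResult] = {}
    by_m: dict[int, list[int]] = {}
    for i, p in enumerate(grid):
        by_m.setdefault(p.m, []).append(i)

    for m, idxs in by_m.items():
        n_i, n_j = h - m, w - m
        n_origins = n_i * n_j
        if n_i < 1 or n_j < 1 or n_origins < 2:
            raise ValueError(
                f"image {h}×{w} too small for FuzzyEn2D with m={m} "
                f"(needs (H−m)(W−m) ≥ 2)"
            )
        idxs = sorted(idxs, key=lambda i: (grid[i].n, grid[i].r))  # maximize d^n reuse
        nr = [(grid[i].n, grid[i].r) for i in idxs]
        comps_m = _template_components(xs, m, (n_i, n_j))
        comps_m1 = _template_components(xs, m + 1, (n_i, n_j))
        sums_m = _phi_sums(comps_m, nr)
        sums_m1 = _phi_sums(comps_m1, nr)
        # drop the N self-pairs, normalize by N(N−1) — the normalization
        # cancels in the ratio but keeps Φ interpretable
        denom = n_origins * (n_origins - 1)
        for k, i in enumerate(idxs):
            phi_m = (sums_m[k] - n_origins) / denom
            phi_m1 = (sums_m1[k] - n_origins) / denom
            value = float(np.log(phi_m / phi_m1))
            results[i] = EntropyResult(value, "fuzzy", grid[i])
    return [results[i] for i in range(len(grid))]


# ---------------------------------------------------------------------------
# DispEn2D
# ---------------------------------------------------------------------------


def ncdf_class_map(img: np.ndarray, c: int) -> tuple[np.ndarray, bool]:
    """Map pixels to classes 1..c through the normal CDF.

    ``y = Φ((u − μ)/σ)`` with μ, σ the image mean and population SD,
    then ``z = round(c·y + 0.5)`` (round half away from zero, matching
    MATLAB's ``round``) clamped to [1, c].  The sigmoid mapping keeps
    extreme pixels from collapsing most of the image into the end
    classes.

    Returns the integer class map and a degenerate flag (True when
    σ = 0, in which case the map is all ones).
    """
    if not 3 <= c <= 9:
        raise ValueError(f"number of classes c must be in 3..9, got {c}")
    x = np.asarray(img, dtype=np.float64)
    mu, sigma = x.mean(), x.std()
    if sigma == 0.0:
        return np.ones(x.shape, dtype=np.int64), True
    y = norm.cdf((x - mu) / sigma)
    # round-half-away-from-zero on a positive argument is floor(t + 0.5)
    z = np.floor(c * y + 0.5 + 0.5).astype(np.int64)
    np.clip(z, 1, c, out=z)
    return z, False


def dispersion_patterns(class_map: np.ndarray, m: int, c: int) -> PatternDistribution:
    """Tally the m×m dispersion patterns of a class map.

    Windows are taken at every origin ``k ≤ h−m+1, l ≤ w−m+1`` and
    flattened row-major into length-m² tuples over {1..c}.
    """
    z = np.asarray(class_map)
    h, w = z.shape
    if h < m or w < m:
        raise ValueError(f"class map {h}×{w} smaller than window m={m}")
    wins = sliding_window_view(z, (m, m)).reshape(-1, m * m)
    total = wins.shape[0]
    # encode each pattern as a base-c integer for fast unique counting
    weights = (c ** np.arange(m * m, dtype=np.int64))[::-1]
    codes = (wins - 1) @ weights
    uniq, cnt = np.unique(codes, return_counts=True)
    counts: dict[tuple[int, ...], int] = {}
    for code, k in zip(uniq.tolist(), cnt.tolist()):
        digits = []
        for wgt in weights:
            digits.append(int(code // wgt) + 1)
            code %= wgt
        counts[tuple(digits)] = int(k)
    return PatternDistribution(counts, total, m, c)


def disp_en2d(
    img: np.ndarray, params: DispParams = DispParams(), normalized: bool = False
) -> EntropyResult:
    """Bidimensional dispersion entropy of a grayscale image.

    Shannon entropy ``−Σ p(π)·ln p(π)`` over the empirical dispersion
    pattern frequencies; unobserved patterns contribute nothing
    (0·ln 0 := 0).  With ``normalized=True`` the value is divided by the
    maximum ``ln(c^(m²))``.
    """
    x = np.asarray(img, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {x.shape}")
    m, c = params.m, params.c
    if x.shape[0] < m or x.shape[1] < m:
        raise ValueError(f"image {x.shape} smaller than window m={m}")
    z, degen = ncdf_class_map(x, c)
    if degen:
        return EntropyResult(0.0, "dispersion", params, degenerate=True)
    dist = dispersion_patterns(z, m, c)
    p = np.array(list(dist.counts.values()), dtype=np.float64) / dist.total
    value = float(-(p * np.log(p)).sum())
    if normalized:
        value /= m * m * np.log(c)
    return EntropyResult(value, "dispersion", params)
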