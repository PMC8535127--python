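"""Coarse-graining and multiscale entropy profiles.

Irregularity at a single scale and complexity across scales are distinct
texture properties: white noise is maximally irregular at scale 1 but
its entropy collapses under coarse-graining, whereas structurally
complex images keep a flat entropy profile across scales.  The scale-τ
image replaces every non-overlapping τ×τ pixel block by its arithmetic
mean; trailing rows/columns that do not fill a block are dropped, so the
output is ⌊H/τ⌋ × ⌊W/τ⌋.  Each scale is computed independently from the
original image (no recursive coarse-graining).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .entropy import (
    DispParams,
    EntropyResult,
    FuzzyParams,
    disp_en2d,
    fuzzy_en2d_grid,
)

__all__ = ["ScaleProfile", "coarse_grain", "multiscale_profile", "fuzzy_profiles_grid"]


@dataclass
class ScaleProfile:
    """Entropy values over scales τ = 1..τ_max for one image.

    ``values[k]`` is the entropy of the scale-(k+1) coarse-grained
    image; the feature vector "scales 1 to n" is ``values[:n]``.
    """

    values: np.ndarray
    algorithm: str
    params: FuzzyParams | DispParams
    degenerate: np.ndarray  # bool per scale

    @property
    def tau_max(self) -> int:
        return len(self.values)

    def prefix(self, n: int) -> np.ndarray:
        if not 1 <= n <= self.tau_max:
            raise ValueError(f"prefix length {n} outside 1..{self.tau_max}")
        return self.values[:n]


def coarse_grain(img: np.ndarray, tau: int) -> np.ndarray:
    """Average non-overlapping τ×τ blocks of an image.

    τ=1 returns the input unchanged.  Raises if τ < 1 or if either
    output dimension ⌊H/τ⌋, ⌊W/τ⌋ would be zero.
    """
    x = np.asarray(img, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {x.shape}")
    if int(tau) != tau or tau < 1:
        raise ValueError(f"scale factor tau must be an integer ≥ 1, got {tau}")
    h, w = x.shape
    hs, ws = h // tau, w // tau
    if hs < 1 or ws < 1:
        raise ValueError(f"tau={tau} collapses image {h}×{w} to zero size")
    if tau == 1:
        return x
    return x[: hs * tau, : ws * tau].reshape(hs, tau, ws, tau).mean(axis=(1, 3))


def multiscale_profile(
    img: np.ndarray,
    algorithm: str,
    params: FuzzyParams | DispParams,
    tau_max: int = 10,
) -> ScaleProfile:
    """Entropy of every coarse-grained version of an image, τ = 1..τ_max.

    ``algorithm`` is ``"fuzzy"`` or ``"dispersion"``.  A precondition
    failure at some scale (image too small after coarse-graining) raises
    an error naming that scale.
    """
    if algorithm not in ("fuzzy", "dispersion"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    values = np.empty(tau_max)
    degen = np.zeros(tau_max, dtype=bool)
    for tau in range(1, tau_max + 1):
        try:
            cg = coarse_grain(img, tau)
            if algorithm == "fuzzy":
                res: EntropyResult = fuzzy_en2d_grid(cg, [params])[0]
            else:
                res = disp_en2d(cg, params)
        except ValueError as exc:
            raise ValueError(f"multiscale profile failed at scale tau={tau}: {exc}") from exc
        values[tau - 1] = res.value
        degen[tau - 1] = res.degenerate
    return ScaleProfile(values, algorithm, params, degen)


def fuzzy_profiles_grid(
    img: np.ndarray, grid: list[FuzzyParams], tau_max: int = 10
) -> dict[FuzzyParams, ScaleProfile]:
    """Multiscale FuzzyEn2D profiles for a whole parameter grid at once.

    Shares the pairwise-distance computation across all (n, r)
    combinations with the same embedding dimension at every scale —
    the cost driver of a full parameter sweep.
    """
    values = {p: np.empty(tau_max) for p in grid}
    degen = {p: np.zeros(tau_max, dtype=bool) for p in grid}
    for tau in range(1, tau_max + 1):
        try:
            cg = coarse_grain(img, tau)
            results = fuzzy_en2d_grid(cg, grid)
        except ValueError as exc:
            raise ValueError(f"multiscale profile failed at scale tau={tau}: {exc}") from exc
        for p, res in zip(grid, results):
            values[p][tau - 1] = res.value
            degen[p][tau - 1] = res.degenerate
    return {p: ScaleProfile(values[p], "fuzzy", p, degen[p]) for p in grid}
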