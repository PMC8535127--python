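"""Seeded synthetic texture generation.

Class-structured texture datasets (periodic patterns, band-limited
noise, white noise) in the spirit of material-texture benchmarks, so the
whole entropy/classification pipeline can be exercised without any
download.  Every generator is a pure function of its spec: the seed
fully determines the output.

Kinds
-----
checkerboard
    Alternating ``period×period`` blocks of two intensities — the
    canonical fully regular texture (low entropy at every scale).
grating
    Horizontal sinusoid ``127.5·(1 + sin(2π·j/period))``, optionally
    plus clipped Gaussian noise — periodic with tunable corruption.
white_noise
    iid uniform(0, 255) (or Gaussian around 127.5) pixels — maximal
    irregularity at scale 1, collapsing under coarse-graining.
smoothed_noise
    White noise convolved with a normalized box kernel of side
    ``cutoff`` — band-limited irregularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["TextureSpec", "make_texture", "make_two_class_dataset"]

KINDS = ("checkerboard", "grating", "white_noise", "smoothed_noise")


@dataclass(frozen=True)
class TextureSpec:
    """Recipe for one synthetic texture image.

    period doubles as the box-kernel side ("cutoff") for smoothed_noise;
    noise_sd is the SD of additive Gaussian noise for gratings, or
    selects Gaussian (``> 0``) vs uniform (``0``) pixels for
    white_noise.
    """

    kind: str
    size: int = 64
    period: int = 4
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown texture kind {self.kind!r}; choose from {KINDS}")
        if self.size < 16:
            raise ValueError(f"size must be ≥ 16, got {self.size}")
        if self.kind in ("checkerboard", "grating", "smoothed_noise") and self.period < 2:
            raise ValueError(f"period must be ≥ 2 for {self.kind}, got {self.period}")

    def with_seed(self, seed: int) -> "TextureSpec":
        return TextureSpec(self.kind, self.size, self.period, self.noise_sd, seed)


def make_texture(spec: TextureSpec) -> np.ndarray:
    """Render a texture spec to a float64 image in [0, 255]."""
    rng = np.random.default_rng(spec.seed)
    s, p = spec.size, spec.period

    if spec.kind == "checkerboard":
        idx = np.arange(s)
        block = (idx // p) % 2
        img = 255.0 * np.logical_xor.outer(block, block).astype(np.float64)
    elif spec.kind == "grating":
        j = np.arange(s)
        row = 127.5 * (1.0 + np.sin(2.0 * np.pi * j / p))
        img = np.tile(row, (s, 1))
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=(s, s))
    elif spec.kind == "white_noise":
        if spec.noise_sd > 0:
            img = rng.normal(127.5, spec.noise_sd, size=(s, s))
        else:
            img = rng.uniform(0.0, 255.0, size=(s, s))
    else:  # smoothed_noise
        img = uniform_filter(rng.uniform(0.0, 255.0, size=(s, s)), size=p, mode="wrap")

    return np.clip(img, 0.0, 255.0)


def make_two_class_dataset(
    n_per_class: int,
    spec_a: TextureSpec,
    spec_b: TextureSpec,
    seed: int = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Balanced two-class image set from two texture recipes.

    Image ``i`` of class A uses seed ``seed + i``; class B continues the
    sequence, so every image has an independent, reproducible stream.
    Returns ``(images, labels)`` with labels 0 (A) and 1 (B).
    """
    if n_per_class < 4:
        raise ValueError(
            f"n_per_class must be ≥ 4 for a 75/25 split, got {n_per_class}"
        )
    if spec_a.with_seed(0) == spec_b.with_seed(0):
        warnings.warn(
            "spec_a and spec_b are structurally identical — the classes are "
            "indistinguishable by construction",
            stacklevel=2,
        )
    images: list[np.ndarray] = []
    labels = np.repeat([0, 1], n_per_class)
    for i, base in enumerate([spec_a] * n_per_class + [spec_b] * n_per_class):
        images.append(make_texture(base.with_seed(seed + i)))
    return images, labels
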