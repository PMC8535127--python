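"""Image loading and preprocessing for 2D entropy analysis.

Entropy measures operate on a single-channel real-valued pixel matrix.
This module brings arbitrary raster inputs (PNG/TIFF/JPEG, RGB or gray,
8- or 16-bit) into that form: grayscale conversion with ITU-R BT.601 luma
weights, center cropping to a fixed square analysis size, and enumeration
of class-labelled image directories into a flat manifest.

Images are represented as plain 2D ``numpy.ndarray`` of float64 in the
native 8-bit range [0, 255]; no rescaling is applied beyond mapping
16-bit inputs into that range.  Both entropy measures downstream are
invariant to positive affine intensity changes, so the range choice is
inert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights (the convention used by MATLAB's rgb2gray).
LUMA_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to grayscale with BT.601 luma weights.

    Parameters
    ----------
    img
        ``H×W×3`` RGB array (an ``H×W×4`` RGBA alpha channel is dropped),
        or an already-grayscale ``H×W`` array which passes through
        unchanged (idempotent).

    Returns
    -------
    numpy.ndarray
        ``H×W`` float64 array, ``0.2989·R + 0.5870·G + 0.1140·B``.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr @ LUMA_WEIGHTS
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0]
    raise ValueError(
        f"expected H×W, H×W×1, H×W×3 or H×W×4 image, got shape {arr.shape}"
    )


def center_crop(img: np.ndarray, size: int) -> np.ndarray:
    """Crop a ``size×size`` square around the image center.

    The crop offset is ``floor((dim − size) / 2)`` in each axis, i.e. for
    an odd remainder the extra pixel is left on the bottom/right edge.

    Raises
    ------
    ValueError
        If ``size`` exceeds either image dimension.
    """
    arr = np.asarray(img)
    h, w = arr.shape[:2]
    if size < 1 or size > h or size > w:
        raise ValueError(f"crop size {size} incompatible with image {h}×{w}")
    i0 = (h - size) // 2
    j0 = (w - size) // 2
    return arr[i0 : i0 + size, j0 : j0 + size]


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file and return it as a float64 grayscale matrix.

    RGB inputs are converted with :func:`to_grayscale`; 16-bit inputs are
    linearly mapped onto [0, 255] so that all images share one internal
    intensity range.
    """
    raw = iio.imread(Path(path))
    arr = np.asarray(raw)
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) * (255.0 / 65535.0)
    gray = to_grayscale(arr)
    return np.ascontiguousarray(gray, dtype=np.float64)


@dataclass
class DatasetManifest:
    """Flat listing of a class-per-directory image dataset.

    Attributes
    ----------
    records
        ``(path, label)`` pairs in deterministic lexicographic order.
    classes
        Ordered unique class labels.
    """

    records: list[tuple[Path, str]] = field(default_factory=list)

    @property
    def classes(self) -> list[str]:
        return sorted({label for _, label in self.records})

    def __len__(self) -> int:
        return len(self.records)

    @property
    def usable_for_classification(self) -> bool:
        return len(self.classes) >= 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(str(p), lab) for p, lab in self.records], columns=["path", "label"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        df = pd.read_csv(path)
        return cls([(Path(p), str(lab)) for p, lab in zip(df["path"], df["label"])])


IMAGE_PATTERNS: Sequence[str] = ("*.png", "*.tif", "*.tiff", "*.jpg", "*.jpeg")


def scan_dataset(
    root: str | Path, patterns: Sequence[str] = IMAGE_PATTERNS
) -> DatasetManifest:
    """Enumerate a class-per-subdirectory image tree.

    Each immediate subdirectory of ``root`` is one class; files matching
    any glob in ``patterns`` become records labelled with the directory
    name.  Ordering is lexicographic by (label, filename), so the same
    tree always yields a byte-identical manifest.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    records: list[tuple[Path, str]] = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        files: set[Path] = set()
        for pat in patterns:
            files.update(sub.glob(pat))
        for f in sorted(files):
            records.append((f, sub.name))
    manifest = DatasetManifest(records)
    if not records:
        logger.warning("scan_dataset: no images found under %s", root)
    elif not manifest.usable_for_classification:
        logger.warning(
            "scan_dataset: single class %r — unusable for classification",
            manifest.classes,
        )
    return manifest
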