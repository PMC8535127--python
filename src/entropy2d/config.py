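"""Run configuration: one YAML/JSON file drives a full sweep.

Every field has a documented default; unknown or malformed keys raise a
schema error that names them.  A run takes its images either from a
class-per-directory tree (``input``) or from an inline synthetic
dataset description (``synthetic``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classify import SweepConfig
from .images import center_crop, load_image, scan_dataset
from .textures import TextureSpec, make_texture

_TOP_KEYS = {
    "input",
    "synthetic",
    "crop_size",
    "algorithms",
    "fuzzy",
    "dispersion",
    "taus",
    "split_ratio",
    "split_seed",
    "standardize",
    "output_dir",
    "pairwise",
}


class ConfigError(ValueError):
    """Raised for unknown, missing or ill-typed configuration keys."""


@dataclass
class RunConfig:
    """Resolved configuration of one experiment run."""

    input: str | None = None
    synthetic: dict | None = None
    crop_size: int | None = None
    sweep: SweepConfig = field(default_factory=SweepConfig)
    pairwise: bool | None = None
    output_dir: str = "entropy2d_results"

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if ("input" in raw) == ("synthetic" in raw):
            raise ConfigError("config needs exactly one of: input, synthetic")

        algorithms = tuple(raw.get("algorithms", ("fuzzy", "dispersion")))
        bad = [a for a in algorithms if a not in ("fuzzy", "dispersion")]
        if bad:
            raise ConfigError(f"unknown algorithms: {bad}")
        fuzzy = raw.get("fuzzy", {})
        disp = raw.get("dispersion", {})
        for name, grid, keys in (("fuzzy", fuzzy, {"m", "n", "r"}),
                                 ("dispersion", disp, {"m", "c"})):
            extra = set(grid) - keys
            if extra:
                raise ConfigError(f"unknown {name} grid keys: {sorted(extra)}")
        try:
            sweep = SweepConfig(
                fuzzy_ms=tuple(fuzzy.get("m", (1, 2))),
                fuzzy_ns=tuple(fuzzy.get("n", (2, 3, 4, 5))),
                fuzzy_rs=tuple(fuzzy.get("r", (0.12, 0.24, 0.36, 0.48))),
                disp_ms=tuple(disp.get("m", (2, 3))),
                disp_cs=tuple(disp.get("c", (3, 4, 5, 6))),
                taus=tuple(raw.get("taus", range(1, 11))),
                split_ratio=float(raw.get("split_ratio", 0.75)),
                split_seed=int(raw.get("split_seed", 0)),
                standardize=bool(raw.get("standardize", False)),
                algorithms=algorithms,
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid sweep settings: {exc}") from exc
        cfg = cls(
            input=raw.get("input"),
            synthetic=raw.get("synthetic"),
            crop_size=raw.get("crop_size"),
            sweep=sweep,
            pairwise=raw.get("pairwise"),
            output_dir=str(raw.get("output_dir", "entropy2d_results")),
        )
        if cfg.synthetic is not None:
            _validate_synthetic(cfg.synthetic)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_mapping(raw)


def _validate_synthetic(syn: dict) -> None:
    extra = set(syn) - {"n_per_class", "seed", "classes"}
    if extra:
        raise ConfigError(f"unknown synthetic keys: {sorted(extra)}")
    classes = syn.get("classes")
    if not classes or len(classes) < 2:
        raise ConfigError("synthetic.classes needs at least 2 entries")
    if int(syn.get("n_per_class", 0)) < 4:
        raise ConfigError("synthetic.n_per_class must be ≥ 4")
    for entry in classes:
        extra = set(entry) - {"name", "kind", "size", "period", "noise_sd"}
        if extra:
            raise ConfigError(f"unknown synthetic class keys: {sorted(extra)}")
        if "name" not in entry or "kind" not in entry:
            raise ConfigError("each synthetic class needs name and kind")


def synthetic_dataset(syn: dict) -> tuple[list[np.ndarray], np.ndarray]:
    """Render the inline synthetic dataset of a run config.

    Image ``i`` (in global enumeration order over classes) uses seed
    ``seed + i``, so a master seed reproduces the whole tree.
    """
    n = int(syn.get("n_per_class", 40))
    seed = int(syn.get("seed", 0))
    images: list[np.ndarray] = []
    labels: list[str] = []
    idx = 0
    for entry in syn["classes"]:
        spec = TextureSpec(
            kind=entry["kind"],
            size=int(entry.get("size", 64)),
            period=int(entry.get("period", 4)),
            noise_sd=float(entry.get("noise_sd", 0.0)),
        )
        for _ in range(n):
            images.append(make_texture(spec.with_seed(seed + idx)))
            labels.append(str(entry["name"]))
            idx += 1
    return images, np.asarray(labels)


def load_run_images(cfg: RunConfig) -> tuple[list[np.ndarray], np.ndarray]:
    """Materialize the images and labels a run config points at."""
    if cfg.synthetic is not None:
        return synthetic_dataset(cfg.synthetic)
    manifest = scan_dataset(cfg.input)
    if not manifest.usable_for_classification:
        raise ConfigError(f"dataset under {cfg.input} has fewer than 2 classes")
    images, labels = [], []
    for path, label in manifest.records:
        img = load_image(path)
        if cfg.crop_size:
            img = center_crop(img, cfg.crop_size)
        images.append(img)
        labels.append(label)
    return images, np.asarray(labels)
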