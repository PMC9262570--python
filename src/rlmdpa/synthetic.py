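"""Seeded generator of imbalanced two-class grayscale image datasets.

Emulates the structure of a two-class cardiac MR screening set: the
majority class ("sick", label 1) shows a bright localized lesion-like
patch on a smooth textured background, while the minority class
("healthy", label 0) is background texture only.  The imbalance ratio,
lesion contrast (via ``separability``), noise level and image size are
all controllable, and generation is fully determined by the seed.

What this emulates -- and what it does not -- is discussed in the methods
note: real CMR slices have anatomy, acquisition artifacts and
patient-level correlation that this generator deliberately omits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .env import LabeledImageSet
from .exceptions import ConfigurationError

__all__ = ["SyntheticSpec", "generate", "write_dataset", "read_dataset"]

_BASE_INTENSITY = 0.35      # background mean gray level
_TEXTURE_AMPLITUDE = 0.08   # sd of the smoothed background texture


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    ``separability`` in [0, 1] scales the lesion contrast: 1 gives
    classes separable by a max-pixel threshold at zero noise, 0 makes the
    two classes identically distributed.  Default sizes mirror a ~0.52
    minority:majority ratio at one tenth of the clinical dataset's scale.
    """

    n_minority: int = 245
    n_majority: int = 469
    image_size: int = 100
    lesion_intensity: float = 0.6
    lesion_radius: float | None = None  # default: 12% of image size
    background_noise_sd: float = 0.03
    texture_scale: float = 4.0          # gaussian smoothing sigma, pixels
    separability: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_minority < 1 or self.n_majority < 1:
            raise ConfigurationError("class sizes must be positive")
        if self.n_minority > self.n_majority:
            raise ConfigurationError("n_minority must not exceed n_majority")
        if self.image_size < 4:
            raise ConfigurationError("image_size must be >= 4")
        if not 0.0 < self.lesion_intensity <= 1.0:
            raise ConfigurationError("lesion_intensity must be in (0, 1]")
        if not 0.0 <= self.separability <= 1.0:
            raise ConfigurationError("separability must be in [0, 1]")
        if self.background_noise_sd < 0.0:
            raise ConfigurationError("background_noise_sd must be >= 0")

    @property
    def radius(self) -> float:
        return self.lesion_radius if self.lesion_radius is not None else 0.12 * self.image_size


def _background(rng: np.random.Generator, size: int, spec: SyntheticSpec) -> np.ndarray:
    texture = gaussian_filter(rng.standard_normal((size, size)), sigma=spec.texture_scale)
    sd = texture.std()
    if sd > 0:
        texture = (texture - texture.mean()) / sd * _TEXTURE_AMPLITUDE
    img = _BASE_INTENSITY + texture
    if spec.background_noise_sd > 0:
        img = img + rng.normal(0.0, spec.background_noise_sd, size=(size, size))
    return img


def _add_lesion(img: np.ndarray, rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    size = img.shape[0]
    r = spec.radius
    margin = min(r, size / 2 - 1)
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    ry = r * rng.uniform(0.7, 1.3)
    rx = r * rng.uniform(0.7, 1.3)
    theta = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    u = (np.cos(theta) * dx + np.sin(theta) * dy) / rx
    v = (-np.sin(theta) * dx + np.cos(theta) * dy) / ry
    d2 = u**2 + v**2
    bump = np.where(d2 < 1.0, (1.0 - d2) ** 2, 0.0)  # smooth compact profile
    amplitude = spec.lesion_intensity * spec.separability
    return img + amplitude * bump


def generate(spec: SyntheticSpec) -> LabeledImageSet:
    """Draw the full dataset: minority first (label 0), then majority."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_minority + spec.n_majority
    images = np.empty((n, spec.image_size, spec.image_size))
    labels = np.concatenate(
        [np.zeros(spec.n_minority, dtype=np.int64), np.ones(spec.n_majority, dtype=np.int64)]
    )
    for i in range(n):
        img = _background(rng, spec.image_size, spec)
        if labels[i] == 1:
            img = _add_lesion(img, rng, spec)
        images[i] = np.clip(img, 0.0, 1.0)
    return LabeledImageSet(images=images, labels=labels, original_minority_label=0)


def write_dataset(data: LabeledImageSet, directory) -> Path:
    """Write 8-bit grayscale PNGs plus a path,label manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(data)):
        name = f"img_{i:05d}.png"
        arr = np.round(np.clip(data.images[i], 0.0, 1.0) * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(directory / name)
        rows.append({"path": name, "label": int(data.labels[i])})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest, image_size: int | None = None) -> LabeledImageSet:
    """Load a manifest CSV: grayscale, optionally resized, scaled to [0, 1].

    Labels are remapped so that 0 is the minority class.
    """
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    root = manifest.parent
    missing = [str(p) for p in table["path"] if not (root / p).is_file()]
    if missing:
        raise IOError(f"missing image files: {', '.join(missing[:10])}")
    images = []
    for p in table["path"]:
        img = Image.open(root / p).convert("L")
        if image_size is not None and img.size != (image_size, image_size):
            img = img.resize((image_size, image_size), Image.BILINEAR)
        images.append(np.asarray(img, dtype=np.float64) / 255.0)
    return LabeledImageSet.from_arrays(np.stack(images), table["label"].to_numpy())
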