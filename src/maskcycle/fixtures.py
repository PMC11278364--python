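"""Procedural stand-ins for the field data the pipeline was designed for.

The real study material — a wheat-field video with one hand-annotated frame,
background-only videos, and unannotated real field frames — is emulated
with fully seeded procedural renders so every stage of the pipeline can run
with no downloads:

* **annotated source frames**: a band-limited green/brown background plus
  textured elliptical blobs (wheat-head analogues) with an exact binary
  mask over the union of their footprints;
* **background frames**: the same texture with no blobs;
* **real-domain frames**: annotated renders pushed through a global
  appearance shift (hue rotation, Gaussian blur, additive noise), with the
  internally known mask withheld for the unlabeled pool and retained for
  held-out test frames.

The appearance shift plays the role of the synthetic-to-real domain gap:
a segmenter trained on unshifted renders degrades on shifted ones, and the
translation model is expected to close part of that gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.filters import gaussian
from skimage.transform import resize

from .imgio import require_binary, require_same_shape, write_image, write_mask
from .manifest import DatasetManifest

# fixed procedural palette (kept in code so renders are reproducible)
_SOIL = np.array([0.37, 0.28, 0.17])
_CANOPY = np.array([0.27, 0.43, 0.19])
_HEAD_DARK = np.array([0.55, 0.44, 0.20])
_HEAD_LIGHT = np.array([0.86, 0.76, 0.42])

_MAX_BLOB_TRIES = 100


@dataclass(frozen=True)
class DomainShift:
    """Global appearance change defining the 'real' domain.

    hue_shift in degrees, blur_sigma in pixels, noise_sd in [0,1] intensity
    units; all zero means the identity transform.
    """
    hue_shift: float = 50.0
    blur_sigma: float = 1.5
    noise_sd: float = 0.05


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    image_height: int = 256
    image_width: int = 256
    n_background_frames: int = 8
    n_real_frames: int = 20
    n_test_frames: int = 5
    blobs_per_frame: tuple[int, int] = (6, 14)
    blob_axes: tuple[float, float] = (8.0, 28.0)
    texture_scale: float = 24.0
    domain_shift: DomainShift = field(default_factory=DomainShift)

    def validate(self) -> None:
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("image dims must be >= 32")
        for name in ("n_background_frames", "n_real_frames", "n_test_frames"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.blobs_per_frame
        if lo < 0 or hi < lo:
            raise ValueError("blobs_per_frame must be a non-negative [min,max]")
        if self.blob_axes[0] < 2:
            raise ValueError("blob_axes minimum must be >= 2 px")
        if self.blob_axes[1] < self.blob_axes[0]:
            raise ValueError("blob_axes must be an increasing range")
        if self.texture_scale <= 0:
            raise ValueError("texture_scale must be positive")

    def scaled_for(self, height: int, width: int) -> "FixtureConfig":
        """Convenience: same recipe at another resolution."""
        return replace(self, image_height=height, image_width=width)


@dataclass
class AnnotatedSample:
    """An RGB image with a same-sized strictly binary mask."""
    image: np.ndarray  # H×W×3 uint8
    mask: np.ndarray   # H×W uint8 in {0,1}

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.uint8)
        self.mask = require_binary(self.mask)
        require_same_shape(self.image, self.mask)


@dataclass(frozen=True)
class Ellipse:
    """A blob: center (row, col), semi-axes (a along theta, b across), theta in radians."""
    center: tuple[float, float]
    axes: tuple[float, float]
    theta: float

    def contains(self, row: float, col: float) -> bool:
        dy = row - self.center[0]
        dx = col - self.center[1]
        u = dx * math.cos(self.theta) + dy * math.sin(self.theta)
        v = -dx * math.sin(self.theta) + dy * math.cos(self.theta)
        a, b = self.axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def footprint(self, height: int, width: int) -> np.ndarray:
        rows, cols = np.mgrid[0:height, 0:width].astype(np.float64)
        dy = rows - self.center[0]
        dx = cols - self.center[1]
        u = dx * math.cos(self.theta) + dy * math.sin(self.theta)
        v = -dx * math.sin(self.theta) + dy * math.cos(self.theta)
        a, b = self.axes
        return ((u / a) ** 2 + (v / b) ** 2 <= 1.0)


def _value_noise(rng: np.random.Generator, height: int, width: int,
                 scale: float) -> np.ndarray:
    """Band-limited noise: a coarse random grid upsampled bilinearly.

    ``scale`` is the cell size in pixels; scale >= the frame size collapses
    the grid to a single cell, i.e. a constant field.
    """
    ch = max(1, int(math.ceil(height / scale)))
    cw = max(1, int(math.ceil(width / scale)))
    grid = rng.uniform(0.0, 1.0, size=(ch, cw))
    if ch == 1 and cw == 1:
        return np.full((height, width), grid[0, 0])
    return resize(grid, (height, width), order=1, mode="edge",
                  anti_aliasing=False)


def _background_float(config: FixtureConfig, rng: np.random.Generator) -> np.ndarray:
    H, W = config.image_height, config.image_width
    coarse = _value_noise(rng, H, W, config.texture_scale)
    fine = _value_noise(rng, H, W, max(config.texture_scale / 4.0, 1.0))
    t = 0.7 * coarse + 0.3 * fine
    img = _SOIL[None, None, :] + t[..., None] * (_CANOPY - _SOIL)[None, None, :]
    # mild brightness modulation so the texture is visible in all channels
    img *= (0.85 + 0.3 * fine)[..., None]
    return np.clip(img, 0.0, 1.0)


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)


def make_background(config: FixtureConfig, rng: np.random.Generator) -> np.ndarray:
    """Render one blob-free background frame (uint8 H×W×3)."""
    config.validate()
    return _quantize(_background_float(config, rng))


def _sample_blobs(config: FixtureConfig, rng: np.random.Generator) -> list[Ellipse]:
    H, W = config.image_height, config.image_width
    lo, hi = config.blobs_per_frame
    k = int(rng.integers(lo, hi + 1))
    blobs: list[Ellipse] = []
    for _ in range(k):
        for attempt in range(_MAX_BLOB_TRIES + 1):
            if attempt == _MAX_BLOB_TRIES:
                raise RuntimeError(
                    f"could not place a blob inside a {H}x{W} frame after "
                    f"{_MAX_BLOB_TRIES} attempts; blob_axes {config.blob_axes} "
                    "too large for the frame")
            a = rng.uniform(*config.blob_axes)
            b = rng.uniform(config.blob_axes[0], a)
            theta = rng.uniform(0.0, math.pi)
            cy = rng.uniform(0.0, H - 1.0)
            cx = rng.uniform(0.0, W - 1.0)
            r = max(a, b)  # bounding radius; keeps footprints unclipped
            if cy - r >= 0 and cy + r <= H - 1 and cx - r >= 0 and cx + r <= W - 1:
                blobs.append(Ellipse((cy, cx), (a, b), theta))
                break
    return blobs


def _render_annotated_float(config: FixtureConfig, rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray, list[Ellipse]]:
    H, W = config.image_height, config.image_width
    img = _background_float(config, rng)
    blobs = _sample_blobs(config, rng)
    mask = np.zeros((H, W), dtype=bool)
    rows, cols = np.mgrid[0:H, 0:W].astype(np.float64)
    for blob in blobs:
        inside = blob.footprint(H, W)
        if not inside.any():
            mask |= inside
            continue
        # awn-like speckle texture over a radial shading ramp
        tex = _value_noise(rng, H, W, 3.0)
        dy = rows - blob.center[0]
        dx = cols - blob.center[1]
        rad = np.sqrt((dx / max(blob.axes)) ** 2 + (dy / max(blob.axes)) ** 2)
        shade = np.clip(1.0 - 0.5 * rad, 0.3, 1.0)
        color = (_HEAD_DARK[None, None, :]
                 + tex[..., None] * (_HEAD_LIGHT - _HEAD_DARK)[None, None, :])
        color *= shade[..., None]
        img[inside] = color[inside]
        mask |= inside
    return img, mask.astype(np.uint8), blobs


def make_annotated_frame(config: FixtureConfig, rng: np.random.Generator,
                         return_blobs: bool = False):
    """Render an annotated frame: textured blobs on a background.

    The mask is exactly 1 on the union of the generating ellipse footprints.
    With ``return_blobs=True`` also returns the ellipse parameters so the
    rasterization can be checked against a per-pixel oracle.
    """
    config.validate()
    img, mask, blobs = _render_annotated_float(config, rng)
    sample = AnnotatedSample(_quantize(img), mask)
    if return_blobs:
        return sample, blobs
    return sample


def rotate_hue(image_float: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate hue of an RGB image in [0,1] by ``degrees`` on the HSV circle."""
    if degrees % 360.0 == 0.0:
        return image_float
    hsv = rgb2hsv(image_float)
    hsv[..., 0] = (hsv[..., 0] + degrees / 360.0) % 1.0
    return hsv2rgb(hsv)


def apply_domain_shift(image: np.ndarray, shift: DomainShift,
                       rng: np.random.Generator) -> np.ndarray:
    """Apply hue rotation, Gaussian blur and additive noise to a uint8 image."""
    img = image.astype(np.float64) / 255.0
    img = rotate_hue(img, shift.hue_shift)
    if shift.blur_sigma > 0:
        img = gaussian(img, sigma=shift.blur_sigma, channel_axis=-1)
    if shift.noise_sd > 0:
        img = img + rng.normal(0.0, shift.noise_sd, size=img.shape)
    return _quantize(img)


def make_real_domain_frame(config: FixtureConfig, rng: np.random.Generator,
                           with_mask: bool = False):
    """Render a 'real-domain' frame: annotated content under the domain shift.

    By default only the image is returned (the unlabeled pool withholds the
    mask); ``with_mask=True`` retains it for held-out test frames.
    """
    config.validate()
    img, mask, _ = _render_annotated_float(config, rng)
    shifted = apply_domain_shift(_quantize(img), config.domain_shift, rng)
    if with_mask:
        return AnnotatedSample(shifted, mask)
    return shifted


def generate_fixture_corpus(config: FixtureConfig, out_dir) -> dict[str, DatasetManifest]:
    """Write the full fixture corpus and its manifests under ``out_dir``.

    Produces one annotated source frame, blob-free backgrounds, unlabeled
    real-domain frames, and real-domain test frames with retained masks.
    Everything is a pure function of (config, config.seed).
    """
    config.validate()
    out_dir = Path(out_dir)
    rng = np.random.default_rng(config.seed)
    manifests: dict[str, DatasetManifest] = {}

    src_dir = out_dir / "source"
    src_dir.mkdir(parents=True, exist_ok=True)
    sample = make_annotated_frame(config, rng)
    ipath, mpath = src_dir / "source_0000.png", src_dir / "source_0000_mask.png"
    write_image(ipath, sample.image)
    write_mask(mpath, sample.mask)
    m = DatasetManifest()
    m.append(ipath, mpath, "train")
    manifests["source"] = m

    bg_dir = out_dir / "backgrounds"
    bg_dir.mkdir(parents=True, exist_ok=True)
    m = DatasetManifest()
    for i in range(config.n_background_frames):
        p = bg_dir / f"background_{i:04d}.png"
        write_image(p, make_background(config, rng))
        m.append(p, "", "train")
    manifests["backgrounds"] = m

    real_dir = out_dir / "real"
    real_dir.mkdir(parents=True, exist_ok=True)
    m = DatasetManifest()
    for i in range(config.n_real_frames):
        p = real_dir / f"real_{i:04d}.png"
        write_image(p, make_real_domain_frame(config, rng))
        m.append(p, "", "train")
    manifests["real"] = m

    test_dir = out_dir / "test"
    test_dir.mkdir(parents=True, exist_ok=True)
    m = DatasetManifest()
    for i in range(config.n_test_frames):
        s = make_real_domain_frame(config, rng, with_mask=True)
        ipath = test_dir / f"test_{i:04d}.png"
        mpath = test_dir / f"test_{i:04d}_mask.png"
        write_image(ipath, s.image)
        write_mask(mpath, s.mask)
        m.append(ipath, mpath, "test")
    manifests["test"] = m

    for name, man in manifests.items():
        man.to_csv(out_dir / f"{name}.csv")
    return manifests
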