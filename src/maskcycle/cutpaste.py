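"""Cut-and-paste synthesis of exactly-annotated images.

Foreground cutouts (connected components of an annotated image's mask) are
randomly transformed and composited onto background frames.  Because the
emitted mask is the union of the pasted footprints, every synthesized image
comes with a pixel-exact annotation for free — the trade-off being that the
composites look collage-like; making them realistic is the translation
model's job, not this module's.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.measure import label, regionprops

from .fixtures import AnnotatedSample
from .imgio import (read_image, require_binary, require_same_shape,
                    write_image, write_mask)
from .manifest import DatasetManifest


@dataclass
class Cutout:
    """A tight bounding-box crop of one foreground component.

    ``alpha`` is the component's binary footprint within the crop; pixels
    outside it belong to whatever surrounded the component in the source
    image and are never pasted.
    """
    patch: np.ndarray      # h×w×3 uint8
    alpha: np.ndarray      # h×w uint8 in {0,1}
    source_id: str = ""
    origin: tuple[int, int] = (0, 0)   # top-left (row, col) in the source frame

    def __post_init__(self):
        self.patch = np.asarray(self.patch, dtype=np.uint8)
        self.alpha = require_binary(self.alpha, "alpha")
        require_same_shape(self.patch, self.alpha)


@dataclass(frozen=True)
class PasteInstance:
    """One placement: which cutout goes where, at what scale/rotation/flip.

    ``center`` is the 0-based (row, col) the transformed cutout's center
    lands on; rotation is in degrees, counter-clockwise, applied about the
    cutout center after any flips.
    """
    cutout_index: int
    center: tuple[float, float]
    scale: float = 1.0
    rotation: float = 0.0
    hflip: bool = False
    vflip: bool = False

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


@dataclass(frozen=True)
class SynthesisConfig:
    n_images: int = 11_000
    heads_per_image: tuple[int, int] = (10, 30)
    scale_range: tuple[float, float] = (0.7, 1.3)
    rotation_range: tuple[float, float] = (-180.0, 180.0)
    seed: int = 0
    train_fraction: float = 10_000 / 11_000
    flip_prob: float = 0.5
    min_area: int = 16

    def validate(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if not (0.0 <= self.train_fraction <= 1.0):
            raise ValueError("train_fraction must be in [0,1]")
        if self.heads_per_image[1] < self.heads_per_image[0] or self.heads_per_image[0] < 0:
            raise ValueError("heads_per_image must be a non-negative [min,max]")
        if self.scale_range[0] <= 0 or self.scale_range[1] < self.scale_range[0]:
            raise ValueError("scale_range must be positive and increasing")
        if self.rotation_range[1] < self.rotation_range[0]:
            raise ValueError("rotation_range must be increasing")


def extract_cutouts(sample: AnnotatedSample, min_area: int = 16) -> list[Cutout]:
    """One cutout per 8-connected component of the mask with area >= min_area."""
    mask = require_binary(sample.mask)
    require_same_shape(sample.image, mask)
    labeled = label(mask, connectivity=2)   # 2 = 8-connectivity in 2-D
    cutouts: list[Cutout] = []
    for region in regionprops(labeled):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        alpha = (labeled[r0:r1, c0:c1] == region.label).astype(np.uint8)
        cutouts.append(Cutout(sample.image[r0:r1, c0:c1].copy(), alpha,
                              source_id=f"component_{region.label}",
                              origin=(r0, c0)))
    return cutouts


def sample_instances(config: SynthesisConfig, n_cutouts: int,
                     dims: tuple[int, int], rng: np.random.Generator
                     ) -> list[PasteInstance]:
    """Draw one image's worth of random placements."""
    config.validate()
    if n_cutouts == 0:
        warnings.warn("sample_instances called with zero cutouts; "
                      "returning an empty placement list")
        return []
    H, W = dims
    k = int(rng.integers(config.heads_per_image[0], config.heads_per_image[1] + 1))
    instances = []
    for _ in range(k):
        idx = int(rng.integers(0, n_cutouts))
        center = (float(rng.uniform(0, H - 1)), float(rng.uniform(0, W - 1)))
        scale = float(rng.uniform(*config.scale_range))
        rotation = float(rng.uniform(*config.rotation_range))
        hflip = bool(rng.random() < config.flip_prob)
        vflip = bool(rng.random() < config.flip_prob)
        instances.append(PasteInstance(idx, center, scale, rotation, hflip, vflip))
    return instances


def _transform_params(h: int, w: int, scale: float, rotation: float):
    """Output-patch geometry for a rotation+scale about the patch center.

    Returns (out_h, out_w, inverse 2x2 matrix, source center, output center).
    """
    theta = math.radians(rotation)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    # transformed bounding box of the scaled, rotated patch
    out_h = int(math.ceil((h * abs(cos_t) + w * abs(sin_t)) * scale)) + 1
    out_w = int(math.ceil((w * abs(cos_t) + h * abs(sin_t)) * scale)) + 1
    # forward map: p_out = R(theta) * s * (p_src - c_src) + c_out, in (row, col)
    # inverse map: p_src = R(-theta)/s * (p_out - c_out) + c_src
    inv = np.array([[cos_t, sin_t], [-sin_t, cos_t]], dtype=np.float64) / scale
    c_src = ((h - 1) / 2.0, (w - 1) / 2.0)
    c_out = ((out_h - 1) / 2.0, (out_w - 1) / 2.0)
    return out_h, out_w, inv, c_src, c_out


def bilinear_sample(channel: np.ndarray, row: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Bilinear interpolation with zero fill outside the array."""
    h, w = channel.shape
    r0 = np.floor(row).astype(np.int64)
    c0 = np.floor(col).astype(np.int64)
    fr = row - r0
    fc = col - c0
    out = np.zeros(np.shape(row), dtype=np.float64)
    for dr in (0, 1):
        for dc in (0, 1):
            rr = r0 + dr
            cc = c0 + dc
            weight = (fr if dr else 1.0 - fr) * (fc if dc else 1.0 - fc)
            valid = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            vals = np.where(valid, channel[np.clip(rr, 0, h - 1),
                                           np.clip(cc, 0, w - 1)], 0.0)
            out = out + weight * vals
    return out


def _warp_cutout(cutout: Cutout, instance: PasteInstance
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Transformed RGB patch (float) and binarized alpha for one instance."""
    patch = cutout.patch.astype(np.float64)
    alpha = cutout.alpha.astype(np.float64)
    if instance.hflip:
        patch, alpha = patch[:, ::-1], alpha[:, ::-1]
    if instance.vflip:
        patch, alpha = patch[::-1, :], alpha[::-1, :]
    h, w = alpha.shape
    if instance.scale == 1.0 and instance.rotation == 0.0:
        return patch, cutout_alpha_binarize(alpha)
    out_h, out_w, inv, c_src, c_out = _transform_params(
        h, w, instance.scale, instance.rotation)
    rows, cols = np.mgrid[0:out_h, 0:out_w].astype(np.float64)
    dy, dx = rows - c_out[0], cols - c_out[1]
    src_r = inv[0, 0] * dy + inv[0, 1] * dx + c_src[0]
    src_c = inv[1, 0] * dy + inv[1, 1] * dx + c_src[1]
    rgb = np.stack([bilinear_sample(patch[..., ch], src_r, src_c)
                    for ch in range(3)], axis=-1)
    a = cutout_alpha_binarize(bilinear_sample(alpha, src_r, src_c))
    return rgb, a


def cutout_alpha_binarize(alpha_float: np.ndarray) -> np.ndarray:
    """Resampled alpha -> binary footprint; threshold 0.5, ties to foreground."""
    return (np.asarray(alpha_float) >= 0.5).astype(np.uint8)


def render_paste(background: np.ndarray, cutouts: list[Cutout],
                 instances: list[PasteInstance]) -> AnnotatedSample:
    """Composite instances onto a background in list order.

    RGB is resampled bilinearly; alpha is resampled then binarized at 0.5.
    Later pastes occlude earlier ones in RGB; the mask is the union of all
    footprints.  Out-of-frame portions are clipped; a fully off-frame
    instance contributes nothing.
    """
    background = np.asarray(background, dtype=np.uint8)
    H, W = background.shape[:2]
    image = background.astype(np.float64).copy()
    mask = np.zeros((H, W), dtype=np.uint8)
    for inst in instances:
        if not (0 <= inst.cutout_index < len(cutouts)):
            raise ValueError(f"cutout_index {inst.cutout_index} out of range")
        rgb, alpha = _warp_cutout(cutouts[inst.cutout_index], inst)
        th, tw = alpha.shape
        top = int(round(inst.center[0] - (th - 1) / 2.0))
        left = int(round(inst.center[1] - (tw - 1) / 2.0))
        r0, r1 = max(top, 0), min(top + th, H)
        c0, c1 = max(left, 0), min(left + tw, W)
        if r0 >= r1 or c0 >= c1:
            continue
        sub = alpha[r0 - top:r1 - top, c0 - left:c1 - left].astype(bool)
        image[r0:r1, c0:c1][sub] = rgb[r0 - top:r1 - top, c0 - left:c1 - left][sub]
        mask[r0:r1, c0:c1][sub] = 1
    return AnnotatedSample(np.round(np.clip(image, 0, 255)).astype(np.uint8), mask)


def synthesize_dataset(config: SynthesisConfig, cutouts: list[Cutout],
                       backgrounds: DatasetManifest, out_dir) -> DatasetManifest:
    """Write ``config.n_images`` composites and their manifest.

    Backgrounds are sampled with replacement; the split column assigns the
    first round(n*train_fraction) rows to train and the rest to val.
    """
    config.validate()
    if not cutouts:
        raise ValueError("cannot synthesize: empty cutout list")
    if len(backgrounds) == 0:
        raise ValueError("cannot synthesize: empty background manifest")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    bg_images = [read_image(r.image_path) for r in backgrounds]
    n_train = int(round(config.n_images * config.train_fraction))
    manifest = DatasetManifest()
    for i in range(config.n_images):
        bg = bg_images[int(rng.integers(0, len(bg_images)))]
        instances = sample_instances(config, len(cutouts), bg.shape[:2], rng)
        sample = render_paste(bg, cutouts, instances)
        ipath = out_dir / f"synth_{i:05d}.png"
        mpath = out_dir / f"synth_{i:05d}_mask.png"
        write_image(ipath, sample.image)
        write_mask(mpath, sample.mask)
        manifest.append(ipath, mpath, "train" if i < n_train else "val")
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
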