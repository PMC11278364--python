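"""PNG image and binary-mask I/O.

On disk: images are 8-bit RGB PNG; masks are single-channel PNG with values
in {0, 255}.  In memory: images are uint8 H×W×3 arrays; masks are uint8 H×W
arrays with values in {0, 1}.
"""

from __future__ import annotations

import numpy as np
from PIL import Image


def read_image(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("RGB"))
    return arr.astype(np.uint8)


def write_image(path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {image.shape}")
    Image.fromarray(image.astype(np.uint8), mode="RGB").save(path, format="PNG")


def read_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    vals = np.unique(arr)
    if not np.isin(vals, (0, 255)).all():
        raise ValueError(f"mask file {path} is not binary {{0,255}}: values {vals}")
    return (arr > 0).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected HxW mask, got shape {mask.shape}")
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask is not binary {{0,1}}: values {vals}")
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(path, format="PNG")


def require_binary(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary {{0,1}}; found values {vals}")
    return mask.astype(np.uint8)


def require_same_shape(image: np.ndarray, mask: np.ndarray) -> None:
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape[:2]} dims differ")
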