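"""Small image helpers shared across modules.

Images travel as float32 arrays in [0, 1] with shape (H, W, 3) at rest
(PNG on disk) and are transposed to (C, H, W) only at the network boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image


def to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def to_float(img: np.ndarray) -> np.ndarray:
    if img.dtype == np.uint8:
        return img.astype(np.float32) / 255.0
    return img.astype(np.float32)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG as float32 (H, W, 3) in [0, 1]."""
    with Image.open(path) as im:
        return to_float(np.asarray(im.convert("RGB")))


def save_image(img: np.ndarray, path: str | Path) -> None:
    arr = img if img.dtype == np.uint8 else to_uint8(img)
    Image.fromarray(arr, mode="RGB").save(path)


def resize(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of a float (H, W, 3) image to size x size."""
    pil = Image.fromarray(to_uint8(img), mode="RGB")
    return to_float(np.asarray(pil.resize((size, size), Image.BILINEAR)))


def nchw(img: np.ndarray) -> np.ndarray:
    """(H, W, 3) float -> (3, H, W) float32."""
    return np.ascontiguousarray(img.transpose(2, 0, 1).astype(np.float32))


def hwc(img: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(img.transpose(1, 2, 0))


def luminance(img: np.ndarray) -> np.ndarray:
    return 0.2126 * img[..., 0] + 0.7152 * img[..., 1] + 0.0722 * img[..., 2]
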