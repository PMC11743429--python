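"""Small image helpers: load/save PNG-JPEG, resize, dtype conversion."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["load_rgb", "save_rgb", "resize_rgb", "to_float", "to_uint8", "hflip"]


def load_rgb(path: str | Path) -> np.ndarray:
    """Read an image file as an HxWx3 uint8 array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def save_rgb(arr: np.ndarray, path: str | Path) -> None:
    Image.fromarray(to_uint8(arr)).save(path)


def to_uint8(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
    return np.clip(arr, 0, 255).astype(np.uint8)


def to_float(arr: np.ndarray) -> np.ndarray:
    """Convert to float32 intensities in [0, 1]."""
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float32)
    return (arr.astype(np.float32) / 255.0).astype(np.float32)


def resize_rgb(arr: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to ``(height, width)``; dtype preserved (uint8/float)."""
    h, w = size
    was_float = np.issubdtype(np.asarray(arr).dtype, np.floating)
    img = Image.fromarray(to_uint8(arr)).resize((w, h), Image.BILINEAR)
    out = np.asarray(img)
    return to_float(out) if was_float else out


def hflip(arr: np.ndarray) -> np.ndarray:
    """Horizontal (left-right) flip of an HxWx3 array."""
    return np.ascontiguousarray(arr[:, ::-1, :])
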