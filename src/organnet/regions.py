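"""Deterministic tongue-region partitioning.

In TCM tongue inspection the tongue surface is read region by region: the tip
(region A) reflects heart and lung, the lateral margins (region B) the liver,
the center (region C) the spleen, and the root (region D) the kidney.  This
module tiles a pre-segmented tongue photograph into those four regions using
fixed proportions of the image dimensions:

* A — the bottom fifth of the image, full width;
* B — two vertical strips, each one fifth of the image width, spanning the
  rows above A (returned concatenated left strip then right strip);
* C — the central 60% of columns between the top two-fifths and the bottom
  fifth;
* D — the top two-fifths of the central 60% of columns.

Coordinates are 0-based, rows increase downward, and all intervals are
half-open ``[start, stop)``.  Fractional boundaries are resolved by
round-half-up so the four regions tile the image exactly for every size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegionBounds",
    "RegionPartition",
    "compute_bounds",
    "partition",
    "reassemble",
    "overlay",
    "region_masks",
    "REGIONS",
]

REGIONS = ("A", "B", "C", "D")

MIN_SIZE = 5  # below this some region would be empty


class DegenerateImageError(ValueError):
    """Raised when an image is too small for a non-empty four-region tiling."""


def _round_half_up(num: int, den: int) -> int:
    """round(num/den) with halves rounded up, in exact integer arithmetic."""
    return (2 * num + den) // (2 * den)


@dataclass(frozen=True)
class RegionBounds:
    """Integer crop boundaries of the four tongue regions.

    Attributes
    ----------
    r_mid : int
        Top row of region C (bottom of region D).
    r_tip : int
        Top row of region A (bottom of regions B, C).
    c_left : int
        Right edge (exclusive) of the left margin strip.
    c_right : int
        Left edge (inclusive) of the right margin strip; always ``W - c_left``
        so the tiling is left/right symmetric.
    height, width : int
        Dimensions of the source image.
    """

    r_mid: int
    r_tip: int
    c_left: int
    c_right: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if not (0 < self.r_mid < self.r_tip < self.height):
            raise ValueError(f"invalid row bounds: {self}")
        if not (0 < self.c_left < self.c_right < self.width):
            raise ValueError(f"invalid column bounds: {self}")
        if self.c_right != self.width - self.c_left:
            raise ValueError("column bounds are not symmetric")


@dataclass(frozen=True)
class RegionPartition:
    """The four region crops plus the bounds that produced them.

    ``region_B`` holds the left and right margin strips concatenated side by
    side (left first); the other regions are single contiguous crops.
    """

    region_A: np.ndarray
    region_B: np.ndarray
    region_C: np.ndarray
    region_D: np.ndarray
    bounds: RegionBounds

    def crop(self, region: str) -> np.ndarray:
        return getattr(self, f"region_{region}")


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB array, got shape {image.shape}")
    if image.shape[0] < MIN_SIZE or image.shape[1] < MIN_SIZE:
        raise DegenerateImageError(
            f"image {image.shape[0]}x{image.shape[1]} is below the "
            f"{MIN_SIZE}x{MIN_SIZE} minimum for a four-region tiling"
        )
    return image


def compute_bounds(height: int, width: int) -> RegionBounds:
    """Region boundaries for an ``height x width`` image.

    ``r_tip = H - round(H/5)`` (top of the tip band), ``r_mid = round(2H/5)``
    (bottom of the root band), ``c_left = round(W/5)`` and
    ``c_right = W - c_left`` (the margin strip edges).
    """
    if height < MIN_SIZE or width < MIN_SIZE:
        raise DegenerateImageError(
            f"{height}x{width} is below the {MIN_SIZE}x{MIN_SIZE} minimum"
        )
    r_tip = height - _round_half_up(height, 5)
    r_mid = _round_half_up(2 * height, 5)
    c_left = _round_half_up(width, 5)
    return RegionBounds(
        r_mid=r_mid,
        r_tip=r_tip,
        c_left=c_left,
        c_right=width - c_left,
        height=height,
        width=width,
    )


def partition(image: np.ndarray) -> RegionPartition:
    """Split ``image`` into the four tongue regions.

    Pixel values are copied unchanged; reassembling the crops at their bounds
    reproduces the input bit-exactly (see :func:`reassemble`).
    """
    image = _validate_image(image)
    h, w = image.shape[:2]
    b = compute_bounds(h, w)
    region_a = image[b.r_tip:h, :, :].copy()
    left = image[0:b.r_tip, 0:b.c_left, :]
    right = image[0:b.r_tip, b.c_right:w, :]
    region_b = np.concatenate([left, right], axis=1)
    region_c = image[b.r_mid:b.r_tip, b.c_left:b.c_right, :].copy()
    region_d = image[0:b.r_mid, b.c_left:b.c_right, :].copy()
    return RegionPartition(region_a, region_b, region_c, region_d, b)


def reassemble(parts: RegionPartition) -> np.ndarray:
    """Inverse of :func:`partition`: paste the four crops back at their bounds."""
    b = parts.bounds
    out = np.empty((b.height, b.width) + parts.region_A.shape[2:], parts.region_A.dtype)
    out[b.r_tip:, :, :] = parts.region_A
    out[:b.r_tip, :b.c_left, :] = parts.region_B[:, :b.c_left, :]
    out[:b.r_tip, b.c_right:, :] = parts.region_B[:, b.c_left:, :]
    out[b.r_mid:b.r_tip, b.c_left:b.c_right, :] = parts.region_C
    out[:b.r_mid, b.c_left:b.c_right, :] = parts.region_D
    return out


def region_masks(bounds: RegionBounds) -> dict[str, np.ndarray]:
    """Boolean H x W membership mask for each region; masks tile the image."""
    h, w = bounds.height, bounds.width
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    in_a = np.broadcast_to(rows >= bounds.r_tip, (h, w))
    in_margin = np.broadcast_to(
        (cols < bounds.c_left) | (cols >= bounds.c_right), (h, w))
    in_b = ~in_a & in_margin
    central = ~in_a & ~in_margin
    in_d = central & (rows < bounds.r_mid)
    in_c = central & (rows >= bounds.r_mid)
    return {"A": in_a, "B": in_b, "C": in_c, "D": in_d}


def overlay(image: np.ndarray, bounds: RegionBounds,
            color: tuple[int, int, int] = (0, 255, 0)) -> np.ndarray:
    """Copy of ``image`` with the region boundary lines drawn.

    Lines are drawn at rows ``r_mid`` and ``r_tip`` and columns ``c_left``
    and ``c_right``.  The input is never mutated.
    """
    image = _validate_image(image)
    if image.shape[:2] != (bounds.height, bounds.width):
        raise ValueError("bounds do not match image dimensions")
    out = image.copy()
    col = np.asarray(color, dtype=out.dtype)
    if np.issubdtype(out.dtype, np.floating):
        col = np.asarray(color, dtype=out.dtype) / 255.0
    out[bounds.r_mid, :, :] = col
    out[bounds.r_tip, :, :] = col
    out[:, bounds.c_left, :] = col
    out[:, bounds.c_right, :] = col
    return out
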