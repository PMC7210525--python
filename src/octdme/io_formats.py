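"""Raster I/O for OCT B-scans and binary masks.

Images are single-channel PNG or TIFF (8- or 16-bit); intensities are
normalized to [0, 1] by dividing by the container type's maximum, which
preserves the raw intensity order across images. Masks are written as
lossless 8-bit PNG with foreground 255 / background 0 and round-trip
bit-exactly. Coordinates are (row, col), 0-based, origin top-left.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import ContractError, FormatError

#: smallest side length accepted — level-set stencils need a neighborhood
MIN_SIDE = 8

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-neighbor structure


@dataclass(frozen=True)
class OCTImage:
    """A 2-D grayscale B-scan with intensities in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ContractError(f"image must be 2-D, got ndim={px.ndim}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise ContractError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {px.shape}"
            )
        if not np.isfinite(px).all():
            raise ContractError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ContractError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _collapse_channels(arr: np.ndarray, path) -> np.ndarray:
    """Reduce an RGB(A) array to one channel, requiring identical channels."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3]
        if not ((rgb[..., 0] == rgb[..., 1]).all() and (rgb[..., 0] == rgb[..., 2]).all()):
            raise FormatError(
                f"{path}: multi-channel image with unequal R/G/B channels; "
                "expected a single-channel grayscale raster"
            )
        return rgb[..., 0]
    raise FormatError(f"{path}: unsupported array shape {arr.shape}")


def read_image(path) -> OCTImage:
    """Load a PNG/TIFF B-scan and normalize intensities to [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    arr = iio.imread(path)
    arr = _collapse_channels(arr, path)
    if np.issubdtype(arr.dtype, np.integer):
        denom = float(np.iinfo(arr.dtype).max)
        px = arr.astype(np.float64) / denom
    elif np.issubdtype(arr.dtype, np.floating):
        px = arr.astype(np.float64)
        if px.size and (px.min() < 0.0 or px.max() > 1.0):
            raise FormatError(f"{path}: float image with intensities outside [0, 1]")
    else:
        raise FormatError(f"{path}: unsupported pixel dtype {arr.dtype}")
    return OCTImage(px)


def write_image(image: OCTImage, path) -> None:
    """Write a [0,1] intensity field as 16-bit grayscale PNG/TIFF."""
    arr = np.clip(np.rint(image.pixels * 65535), 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), arr)


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.dtype != bool:
        raise ContractError("mask must be a 2-D boolean grid")
    return mask


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as 0/255 8-bit PNG."""
    mask = _check_mask(mask)
    iio.imwrite(Path(path), np.where(mask, 255, 0).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    """Read a 0/255 mask PNG back into a boolean grid (nonzero → True)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    arr = _collapse_channels(iio.imread(path), path)
    return arr > 0


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Boolean grid of mask pixels with at least one background 4-neighbor.

    Pixels outside the grid count as background, so a full-frame mask has
    the image border ring as its boundary.
    """
    mask = _check_mask(mask)
    return mask & ~ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)


def render_overlay(image: OCTImage, roi: np.ndarray, dme: np.ndarray, path) -> None:
    """Write an RGB overlay: ROI boundary pure red, fluid boundary pure green.

    Where the two boundaries coincide the fluid (green) wins, since the
    fluid contour is the finding of interest.
    """
    roi = _check_mask(roi)
    dme = _check_mask(dme)
    if roi.shape != image.shape or dme.shape != image.shape:
        raise ContractError(
            f"mask shapes {roi.shape}/{dme.shape} do not match image {image.shape}"
        )
    gray = np.clip(np.rint(image.pixels * 255), 0, 255).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    rgb[boundary_pixels(roi)] = (255, 0, 0)
    rgb[boundary_pixels(dme)] = (0, 255, 0)
    iio.imwrite(Path(path), rgb)
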