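"""Raster image reading, writing, and greyscale conversion.

Microarray scans arrive as 8-bit grey, 8-bit RGB, or 16-bit grey rasters
(TIFF, PNG, or JPEG).  Everything downstream of this module operates on a
single-channel :class:`RasterImage`; colour scans are reduced to luminance
with the classic 0.3/0.59/0.11 RGB weights.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RasterImage",
    "FormatError",
    "read_image",
    "write_image",
    "to_grey",
    "rescale_to_8bit",
    "round_half_up",
]

#: Luminance weights for R, G, B when collapsing colour scans to grey.
GREY_WEIGHTS = (0.3, 0.59, 0.11)


class FormatError(ValueError):
    """Raised when an image file has an unsupported sample format."""


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round to nearest integer with halves going up (0.5 -> 1, 1.5 -> 2).

    numpy's default rounding is banker's rounding; intensity quantisation
    here uses the deterministic half-up convention instead.
    """
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclass(frozen=True)
class RasterImage:
    """A 2-D intensity lattice (row 0 = top) with an explicit bit depth.

    ``pixels`` is ``(H, W)`` for grey images or ``(H, W, 3)`` for RGB.
    All values lie in ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.ndim == 3 and px.shape[2] != 3:
            raise ValueError(f"colour images must have 3 channels, got {px.shape[2]}")
        if px.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2-D grey or 3-D RGB, got ndim={px.ndim}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        maxval = 2 ** self.bit_depth - 1
        if px.min() < 0 or px.max() > maxval:
            raise ValueError(f"intensities outside [0, {maxval}] for {self.bit_depth}-bit image")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_colour(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def max_value(self) -> int:
        """Largest representable intensity (255 or 65535)."""
        return 2 ** self.bit_depth - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


_SUPPORTED_SUFFIXES = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}


def read_image(path: str | os.PathLike) -> RasterImage:
    """Read a TIFF/PNG/JPEG file into a :class:`RasterImage`.

    Native bit depth is preserved (8-bit uint8 or 16-bit uint16).  The
    first page of a multi-page TIFF is used.  RGBA images have their alpha
    channel dropped with a logged warning.

    Raises
    ------
    IOError
        If the file does not exist or cannot be decoded.
    FormatError
        If the sample format is not 8- or 16-bit integer.
    """
    path = os.fspath(path)
    if not os.path.isfile(path):
        raise IOError(f"image file not found: {path}")
    suffix = os.path.splitext(path)[1].lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path, key=0)  # page 0 of multi-page files
        else:
            arr = iio.imread(path)
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap decoder errors uniformly
        raise IOError(f"cannot read image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        logger.warning("%s has an alpha channel; it is ignored", path)
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 2:  # grey + alpha
        logger.warning("%s has an alpha channel; it is ignored", path)
        arr = arr[:, :, 0]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise FormatError(f"unsupported image layout {arr.shape} in {path}")

    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise FormatError(
            f"unsupported sample format {arr.dtype} in {path}; expected uint8 or uint16"
        )
    return RasterImage(pixels=arr, bit_depth=bit_depth)


def write_image(path: str | os.PathLike, img: RasterImage) -> None:
    """Write an image as TIFF or PNG (lossless; JPEG is read-only here)."""
    path = os.fspath(path)
    suffix = os.path.splitext(path)[1].lower()
    if suffix not in (".tif", ".tiff", ".png"):
        raise FormatError(f"write_image supports TIFF/PNG, not {suffix!r}")
    iio.imwrite(path, img.pixels.astype(img.dtype))


def to_grey(img: RasterImage) -> RasterImage:
    """Collapse an RGB image to grey with weights 0.3 R + 0.59 G + 0.11 B.

    The weighted sum is computed in floating point and rounded half-up to
    the integer range of the input bit depth.  Grey input is returned
    unchanged (idempotent).
    """
    if not img.is_colour:
        return img
    wr, wg, wb = GREY_WEIGHTS
    px = img.pixels.astype(np.float64)
    grey = wr * px[:, :, 0] + wg * px[:, :, 1] + wb * px[:, :, 2]
    grey = np.clip(round_half_up(grey), 0, img.max_value).astype(img.dtype)
    return RasterImage(pixels=grey, bit_depth=img.bit_depth)


def rescale_to_8bit(img: RasterImage) -> RasterImage:
    """Linearly rescale a 16-bit grey image to the full 8-bit range.

    The minimum and maximum actually present map to 0 and 255; a constant
    image maps to all zeros.  This mirrors how high-depth scanner output is
    commonly reduced before 8-bit analysis; it is opt-in — the pipeline
    also accepts 16-bit input natively.
    """
    if img.bit_depth != 16:
        raise ValueError(f"rescale_to_8bit expects a 16-bit image, got {img.bit_depth}-bit")
    if img.is_colour:
        raise ValueError("rescale_to_8bit expects a grey image; call to_grey first")
    px = img.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros_like(px, dtype=np.uint8)
    else:
        out = round_half_up((px - lo) * 255.0 / (hi - lo)).astype(np.uint8)
    return RasterImage(pixels=out, bit_depth=8)
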