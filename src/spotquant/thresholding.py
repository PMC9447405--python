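"""Histogram-based binarization of array images.

The production path is Otsu's method applied *locally*: the image is split
into grid cells (one spot each) and a threshold is chosen independently in
every cell, which rescues faint spots sitting on a strong or non-uniform
background that a single global threshold would erase.  A small suite of
classic automatic threshold selectors (mean, isodata, triangle, li, yen)
is provided alongside Otsu so the methods can be compared on the same
histograms.

Conventions fixed here and used everywhere downstream:

* Histograms have 256 bins.  8-bit data maps one value per bin; 16-bit
  data is binned into 256 equal-width bins over [0, 65535].
* A threshold ``t`` (native intensity units) labels pixels with value
  ``> t`` foreground and ``<= t`` background.
* Ties between equally good thresholds are broken toward the smallest.
* A histogram with a single occupied bin has no valid two-class split and
  yields ``None`` (degenerate) instead of a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gridding import Cell
from .image_io import RasterImage

__all__ = [
    "Histogram",
    "BinaryMask",
    "CellMask",
    "THRESHOLD_METHODS",
    "otsu_threshold",
    "threshold_suite",
    "binarize_global",
    "binarize_local",
]

N_BINS = 256

#: Cells whose Otsu foreground has fewer pixels than this are declared
#: empty: a genuine spot at the default geometry covers tens of pixels.
DEFAULT_MIN_AREA = 4

#: Cells whose foreground-background mean contrast (in 8-bit grey levels)
#: falls below this are declared empty.  Otsu always finds *some* split,
#: even in a cell of pure noise, where the split's class-mean separation is
#: about 1.6 sigma; 8 grey levels rejects noise-only cells for noise up to
#: sigma ~ 5 while keeping spots of amplitude >= ~10.
DEFAULT_MIN_CONTRAST = 8.0


@dataclass(frozen=True)
class Histogram:
    """A 256-bin intensity histogram.

    ``bin_width`` is 1 for 8-bit data and 256 for 16-bit data, so bin ``i``
    covers native intensities ``[i * bin_width, (i + 1) * bin_width - 1]``.
    """

    counts: np.ndarray
    bin_width: int = 1

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_BINS,):
            raise ValueError(f"histogram must have {N_BINS} bins, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("histogram counts must be non-negative")
        if counts.sum() < 1:
            raise ValueError("histogram must contain at least one pixel")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_pixels(cls, pixels: np.ndarray, bit_depth: int) -> "Histogram":
        """Histogram of a grey pixel array at the given bit depth."""
        if bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
        bin_width = 1 if bit_depth == 8 else 256
        idx = np.asarray(pixels).ravel() // bin_width
        counts = np.bincount(idx.astype(np.int64), minlength=N_BINS)
        return cls(counts=counts, bin_width=bin_width)

    @classmethod
    def from_image(cls, img: RasterImage) -> "Histogram":
        if img.is_colour:
            raise ValueError("histogram requires a grey image; call to_grey first")
        return cls.from_pixels(img.pixels, img.bit_depth)

    def bin_to_intensity(self, t_bin: int) -> int:
        """Native-intensity threshold equivalent to bin threshold ``t_bin``.

        Pixels in bins ``> t_bin`` are exactly the pixels with native value
        greater than the returned intensity.
        """
        return (t_bin + 1) * self.bin_width - 1


@dataclass(frozen=True)
class BinaryMask:
    """Foreground/background labels for one region, plus provenance."""

    pixels: np.ndarray  # 2-D bool, True = foreground
    threshold_used: int | None  # native intensity units; None if degenerate
    method: str
    flags: frozenset = field(default_factory=frozenset)

    @property
    def foreground_area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class CellMask:
    """A per-cell binary mask paired with the grid cell it belongs to."""

    cell: Cell
    mask: BinaryMask

    @property
    def is_empty(self) -> bool:
        return "empty" in self.mask.flags


# ---------------------------------------------------------------------------
# Threshold selectors.  All take a Histogram, return a bin index in
# [0, 254] (pixels in bins > index are foreground) or None if degenerate.
# ---------------------------------------------------------------------------


def _occupied(counts: np.ndarray) -> np.ndarray:
    return np.flatnonzero(counts)


def otsu_threshold(h: Histogram) -> int | None:
    """Otsu's threshold: maximize the between-class variance.

    For a split at bin ``t`` (bins <= t background, > t foreground) the
    between-class variance is ``sigma_B^2(t) = w0 w1 (mu0 - mu1)^2`` with
    class probabilities ``w`` and class means ``mu``.  The smallest
    maximizing ``t`` is returned; a single-class histogram returns None.
    """
    counts = h.counts.astype(np.float64)
    occ = _occupied(h.counts)
    if occ.size < 2:
        return None
    values = np.arange(N_BINS, dtype=np.float64)
    w0 = np.cumsum(counts)[:-1]                      # pixels in bins <= t
    w1 = h.total - w0
    s0 = np.cumsum(counts * values)[:-1]             # intensity mass <= t
    mu0 = np.divide(s0, w0, out=np.zeros_like(s0), where=w0 > 0)
    mu1 = np.divide(counts @ values - s0, w1, out=np.zeros_like(s0), where=w1 > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(sigma_b))  # argmax takes the first (smallest) maximizer


def _mean_threshold(h: Histogram) -> int | None:
    if _occupied(h.counts).size < 2:
        return None
    values = np.arange(N_BINS, dtype=np.float64)
    return int(np.floor(h.counts @ values / h.total))


def _class_means(counts: np.ndarray, t: int) -> tuple[float, float]:
    values = np.arange(N_BINS, dtype=np.float64)
    lo, hi = counts[: t + 1], counts[t + 1 :]
    m0 = float(lo @ values[: t + 1] / lo.sum()) if lo.sum() else 0.0
    m1 = float(hi @ values[t + 1 :] / hi.sum()) if hi.sum() else 0.0
    return m0, m1


def _isodata_threshold(h: Histogram) -> int | None:
    """Ridler-Calvard iteration: t converges to the mean of class means."""
    counts = h.counts.astype(np.float64)
    occ = _occupied(h.counts)
    if occ.size < 2:
        return None
    first, last = int(occ[0]), int(occ[-1])
    t = _mean_threshold(h)
    t = min(max(t, first), last - 1)  # both classes must be non-empty
    seen = set()
    while t not in seen:
        seen.add(t)
        m0, m1 = _class_means(counts, t)
        t_new = int(np.floor((m0 + m1) / 2.0))
        t = min(max(t_new, first), last - 1)
    return t


def _triangle_threshold(h: Histogram) -> int | None:
    """Triangle method: farthest histogram point below the peak-to-tail line.

    The histogram is mirrored if needed so the long tail lies to the left
    of the peak; the threshold is the bin maximizing the perpendicular
    distance to the line from the tail end to the peak.
    """
    counts = h.counts.astype(np.float64)
    occ = _occupied(h.counts)
    if occ.size < 2:
        return None
    arg_low, arg_high = int(occ[0]), int(occ[-1])
    arg_peak = int(np.argmax(counts))
    peak_height = counts[arg_peak]
    flip = (arg_peak - arg_low) < (arg_high - arg_peak)  # long tail on the right
    if flip:
        counts = counts[::-1]
        arg_low = N_BINS - 1 - arg_high
        arg_peak = N_BINS - 1 - arg_peak
    width = arg_peak - arg_low
    if width == 0:
        return None
    x = np.arange(width, dtype=np.float64)
    y = counts[arg_low : arg_peak]
    norm = np.hypot(peak_height, width)
    distance = (peak_height / norm) * x - (width / norm) * y
    t = int(np.argmax(distance)) + arg_low
    if flip:
        t = N_BINS - 1 - t
    return min(max(t, 0), N_BINS - 2)


def _li_threshold(h: Histogram) -> int | None:
    """Li's minimum cross-entropy threshold, fixed-point iteration."""
    counts = h.counts.astype(np.float64)
    occ = _occupied(h.counts)
    if occ.size < 2:
        return None
    values = np.arange(N_BINS, dtype=np.float64)
    t = float(counts @ values / counts.sum())
    for _ in range(N_BINS):
        ti = int(np.floor(t))
        ti = min(max(ti, int(occ[0])), int(occ[-1]) - 1)
        m0, m1 = _class_means(counts, ti)
        # log of a zero mean is undefined; half a grey level is below any
        # occupied bin and keeps the iteration well-defined
        m0 = max(m0, 0.5)
        m1 = max(m1, 0.5)
        if m0 == m1:
            break
        t_new = (m1 - m0) / (np.log(m1) - np.log(m0))
        if abs(t_new - t) < 0.5:
            t = t_new
            break
        t = t_new
    ti = int(np.floor(t))
    return min(max(ti, int(occ[0])), int(occ[-1]) - 1)


def _yen_threshold(h: Histogram) -> int | None:
    """Yen's maximum-correlation criterion threshold."""
    occ = _occupied(h.counts)
    if occ.size < 2:
        return None
    pmf = h.counts / h.total
    p1 = np.cumsum(pmf)
    p1_sq = np.cumsum(pmf**2)
    p2_sq = np.cumsum(pmf[::-1] ** 2)[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = np.log(
            (p1[:-1] * (1.0 - p1[:-1])) ** 2 / (p1_sq[:-1] * p2_sq[1:])
        )
    crit[~np.isfinite(crit)] = -np.inf
    return int(np.argmax(crit))


THRESHOLD_METHODS = {
    "otsu": otsu_threshold,
    "mean": _mean_threshold,
    "isodata": _isodata_threshold,
    "triangle": _triangle_threshold,
    "li": _li_threshold,
    "yen": _yen_threshold,
}


def threshold_suite(h: Histogram, method: str) -> int | None:
    """Compute a threshold with the named method.

    All methods share the interface and conventions of
    :func:`otsu_threshold`: bin-index result, ``> t`` is foreground,
    smallest tie-broken, ``None`` when degenerate.
    """
    try:
        fn = THRESHOLD_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown threshold method {method!r}; available: {sorted(THRESHOLD_METHODS)}"
        ) from None
    return fn(h)


# ---------------------------------------------------------------------------
# Application modes.
# ---------------------------------------------------------------------------


def binarize_global(img: RasterImage, method: str = "otsu") -> BinaryMask:
    """One threshold from the whole-image histogram, applied everywhere.

    A degenerate (constant) image yields an all-background mask flagged
    ``degenerate``.
    """
    if img.is_colour:
        raise ValueError("binarize_global requires a grey image; call to_grey first")
    h = Histogram.from_image(img)
    t_bin = threshold_suite(h, method)
    if t_bin is None:
        return BinaryMask(
            pixels=np.zeros((img.height, img.width), dtype=bool),
            threshold_used=None,
            method=method,
            flags=frozenset({"degenerate"}),
        )
    t = h.bin_to_intensity(t_bin)
    return BinaryMask(pixels=img.pixels > t, threshold_used=t, method=method)


def _resolve_min_contrast(min_contrast: float | None, bit_depth: int) -> float:
    if min_contrast is not None:
        return float(min_contrast)
    # default stated in 8-bit grey levels; scale for native 16-bit data
    return DEFAULT_MIN_CONTRAST * (1 if bit_depth == 8 else 256)


def binarize_local(
    img: RasterImage,
    cells: list[Cell],
    method: str = "otsu",
    min_area: int = DEFAULT_MIN_AREA,
    min_contrast: float | None = None,
) -> list[CellMask]:
    """Threshold each grid cell independently.

    A cell is declared *empty* (all-background mask, flag ``empty``) when
    its histogram is degenerate, its foreground covers fewer than
    ``min_area`` pixels, or the foreground/background mean contrast falls
    below ``min_contrast`` grey levels — the latter rejects noise-only
    cells, where any histogram split produces a small spurious foreground.
    """
    if img.is_colour:
        raise ValueError("binarize_local requires a grey image; call to_grey first")
    contrast_floor = _resolve_min_contrast(min_contrast, img.bit_depth)
    out: list[CellMask] = []
    for cell in cells:
        region = cell.extract(img.pixels)
        h = Histogram.from_pixels(region, img.bit_depth)
        t_bin = threshold_suite(h, method)
        empty_reason = None
        t = None
        fg = np.zeros(region.shape, dtype=bool)
        if t_bin is None:
            empty_reason = "degenerate"
        else:
            t = h.bin_to_intensity(t_bin)
            fg = region > t
            area = int(fg.sum())
            if area < min_area:
                empty_reason = "min_area"
            else:
                contrast = float(region[fg].mean()) - float(region[~fg].mean())
                if contrast < contrast_floor:
                    empty_reason = "min_contrast"
        if empty_reason is not None:
            mask = BinaryMask(
                pixels=np.zeros(region.shape, dtype=bool),
                threshold_used=t,
                method=method,
                flags=frozenset({"empty"}),
            )
        else:
            mask = BinaryMask(pixels=fg, threshold_used=t, method=method)
        out.append(CellMask(cell=cell, mask=mask))
    return out
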