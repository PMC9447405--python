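"""Synthetic fluorescence-array images with exact ground truth.

Emulates a scanned spotted array: a rows x columns lattice of roughly
circular (optionally irregular) bright spots of varying amplitude, sitting
on a spatially non-uniform background, with additive Gaussian noise and a
Gaussian edge blur standing in for the scanner's point-spread function.
Every generated image carries a ground-truth table of per-spot amplitudes,
masks, and an analyte/dilution layout, so the full pipeline can be
validated with no external data.

All randomness flows from the single seed in the spec; a fixed seed
reproduces the image bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_io import RasterImage, round_half_up

__all__ = [
    "LayoutEntry",
    "ArrayLayout",
    "Background",
    "SyntheticSpec",
    "GroundTruthRecord",
    "GroundTruth",
    "default_antigen_layout",
    "amplitudes_from_layout",
    "render_array",
    "render_antigen_array",
    "render_cd14_panel",
    "render_gradient_demo",
]


@dataclass(frozen=True)
class LayoutEntry:
    row: int  # 0-based grid position
    col: int
    analyte: str
    concentration: float  # ug/mL; 0 for buffer-only controls
    replicate: int = 0


@dataclass(frozen=True)
class ArrayLayout:
    """Assignment of an analyte/concentration to every grid position."""

    n_rows: int
    n_cols: int
    entries: tuple

    def __post_init__(self) -> None:
        positions = {(e.row, e.col) for e in self.entries}
        expected = {(r, c) for r in range(self.n_rows) for c in range(self.n_cols)}
        if positions != expected:
            raise ValueError("layout entries must cover every grid position exactly once")
        if len(self.entries) != self.n_rows * self.n_cols:
            raise ValueError("duplicate layout entries")

    @property
    def n_conditions(self) -> int:
        """Number of distinct (analyte, concentration) conditions."""
        return len({(e.analyte, e.concentration) for e in self.entries})

    def entry_at(self, row: int, col: int) -> LayoutEntry:
        for e in self.entries:
            if e.row == row and e.col == col:
                return e
        raise KeyError((row, col))


# The six probes spotted on the autoantigen array, each as a 5-step
# two-fold dilution series (top concentration, ug/mL).  IgG is the
# positive control; PBS buffer is the negative control.
ANTIGEN_SERIES = {
    "CENP-B": 50.0,
    "Cytokeratin-6": 12.5,
    "GPC": 12.5,
    "P2": 100.0,
    "Proteoglycan": 50.0,
    "IgG": 50.0,
}
DILUTION_STEPS = 5


def default_antigen_layout() -> ArrayLayout:
    """The autoantigen panel: 6 analytes x 5 two-fold dilutions + PBS.

    30 analyte/concentration pairs plus the PBS negative control make 31
    distinct conditions, laid out on a 7 x 5 grid: one analyte per row,
    concentrations descending left to right, and a final row of 5 PBS
    replicates.
    """
    entries = []
    for r, (analyte, top) in enumerate(ANTIGEN_SERIES.items()):
        for c in range(DILUTION_STEPS):
            entries.append(
                LayoutEntry(row=r, col=c, analyte=analyte, concentration=top / 2**c)
            )
    for c in range(DILUTION_STEPS):
        entries.append(
            LayoutEntry(row=len(ANTIGEN_SERIES), col=c, analyte="PBS", concentration=0.0, replicate=c)
        )
    return ArrayLayout(n_rows=7, n_cols=5, entries=tuple(entries))


@dataclass(frozen=True)
class Background:
    """Background field model: base level plus an optional spatial term.

    ``linear-gradient`` rises linearly left to right by ``amplitude`` grey
    levels; ``quadratic`` is a centred bowl reaching ``amplitude`` at the
    corners.
    """

    kind: str = "uniform"  # uniform | linear-gradient | quadratic
    base: float = 20.0
    amplitude: float = 0.0

    def render(self, height: int, width: int) -> np.ndarray:
        if self.kind == "uniform":
            return np.full((height, width), self.base, dtype=np.float64)
        x = np.linspace(0.0, 1.0, width)[None, :]
        y = np.linspace(0.0, 1.0, height)[:, None]
        if self.kind == "linear-gradient":
            return self.base + self.amplitude * (x + 0.0 * y)
        if self.kind == "quadratic":
            r2 = (x - 0.5) ** 2 + (y - 0.5) ** 2
            return self.base + self.amplitude * r2 / 0.5
        raise ValueError(f"unknown background kind {self.kind!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic scan."""

    layout: ArrayLayout
    amplitude_map: np.ndarray  # (n_rows, n_cols) true spot amplitudes, grey levels
    cell_size: int = 40
    spot_radius_range: tuple = (8.0, 12.0)
    shape: str = "disc"  # disc | ellipse | irregular-blob
    psf_sigma: float = 1.0
    background: Background = field(default_factory=Background)
    noise_sigma: float = 0.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude_map, dtype=np.float64)
        if amp.shape != (self.layout.n_rows, self.layout.n_cols):
            raise ValueError(
                f"amplitude_map shape {amp.shape} does not match layout "
                f"{self.layout.n_rows}x{self.layout.n_cols}"
            )
        if (amp < 0).any():
            raise ValueError("amplitudes must be non-negative")
        if self.shape not in ("disc", "ellipse", "irregular-blob"):
            raise ValueError(f"unknown spot shape {self.shape!r}")
        object.__setattr__(self, "amplitude_map", amp)


@dataclass(frozen=True)
class GroundTruthRecord:
    row: int  # 1-based, matching SpotMeasurement
    col: int
    analyte: str
    concentration: float
    replicate: int
    true_amplitude: float
    mask: np.ndarray  # cell-local bool spot mask (pre-blur)


@dataclass(frozen=True)
class GroundTruth:
    records: tuple

    @property
    def amplitudes(self) -> np.ndarray:
        """True amplitudes in row-major grid order."""
        return np.array([r.true_amplitude for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "row": r.row,
                    "col": r.col,
                    "analyte": r.analyte,
                    "concentration": r.concentration,
                    "replicate": r.replicate,
                    "true_amplitude": r.true_amplitude,
                }
                for r in self.records
            ]
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def amplitudes_from_layout(
    layout: ArrayLayout, top_amplitude: float = 200.0, bit_depth: int = 8
) -> np.ndarray:
    """Map concentrations to spot amplitudes, proportionally per analyte.

    Within each analyte the amplitude is proportional to concentration,
    scaled so the analyte's top concentration reaches ``top_amplitude``,
    then capped at 90% of the bit-depth maximum so default renders stay
    unsaturated.  Zero-concentration (buffer) positions get amplitude 0.
    """
    cap = 0.9 * (2**bit_depth - 1)
    tops: dict[str, float] = {}
    for e in layout.entries:
        tops[e.analyte] = max(tops.get(e.analyte, 0.0), e.concentration)
    amp = np.zeros((layout.n_rows, layout.n_cols))
    for e in layout.entries:
        if e.concentration > 0 and tops[e.analyte] > 0:
            amp[e.row, e.col] = min(cap, top_amplitude * e.concentration / tops[e.analyte])
    return amp


def _spot_mask(shape: str, size: int, radius: float, cy: float, cx: float, rng) -> np.ndarray:
    """Boolean spot mask of one cell.  The centre pixel is always inside."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    if shape == "disc":
        return dy**2 + dx**2 <= radius**2
    if shape == "ellipse":
        ratio = rng.uniform(0.6, 1.0)
        theta = rng.uniform(0.0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        return (u / radius) ** 2 + (v / (radius * ratio)) ** 2 <= 1.0
    # irregular-blob: star-convex disc with a low-order harmonic boundary
    angles = np.arctan2(dy, dx)
    pert = np.ones_like(angles)
    for k in range(2, 6):
        a_k = rng.normal(0.0, 0.08)
        phi_k = rng.uniform(0.0, 2 * np.pi)
        pert += a_k * np.cos(k * angles + phi_k)
    pert = np.clip(pert, 0.6, 1.35)
    return np.sqrt(dy**2 + dx**2) <= radius * pert


def render_array(spec: SyntheticSpec) -> tuple[RasterImage, GroundTruth]:
    """Render one synthetic scan and its ground truth.

    image = background + sum over spots of amplitude * blurred shape mask
    + Gaussian noise, rounded half-up and clipped to the bit depth.  The
    blurred mask is renormalised to unit peak, so with zero noise the
    centre of a disc spot equals background + amplitude exactly.

    Raises
    ------
    ValueError
        If the spot radius range cannot fit inside a cell.
    """
    layout = spec.layout
    cs = spec.cell_size
    r_lo, r_hi = spec.spot_radius_range
    # 1.35: worst-case irregular-blob boundary excursion; 0.05*cs: centre jitter
    if 1.35 * r_hi + 0.05 * cs > cs / 2.0:
        raise ValueError(
            f"spot radius up to {r_hi} px cannot fit in a {cs} px cell"
        )
    rng = np.random.default_rng(spec.seed)
    height, width = layout.n_rows * cs, layout.n_cols * cs
    field_img = spec.background.render(height, width)
    records = []
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            entry = layout.entry_at(r, c)
            amplitude = float(spec.amplitude_map[r, c])
            radius = rng.uniform(r_lo, r_hi)
            cy = cs / 2.0 + rng.uniform(-0.05 * cs, 0.05 * cs)
            cx = cs / 2.0 + rng.uniform(-0.05 * cs, 0.05 * cs)
            mask = _spot_mask(spec.shape, cs, radius, cy, cx, rng)
            if amplitude > 0:
                soft = mask.astype(np.float64)
                if spec.psf_sigma > 0:
                    soft = gaussian_filter(soft, spec.psf_sigma)
                    peak = soft.max()
                    if peak > 0:
                        soft = soft / peak
                field_img[r * cs : (r + 1) * cs, c * cs : (c + 1) * cs] += amplitude * soft
            records.append(
                GroundTruthRecord(
                    row=r + 1,
                    col=c + 1,
                    analyte=entry.analyte,
                    concentration=entry.concentration,
                    replicate=entry.replicate,
                    true_amplitude=amplitude,
                    mask=mask if amplitude > 0 else np.zeros_like(mask),
                )
            )
    if spec.noise_sigma > 0:
        field_img = field_img + rng.normal(0.0, spec.noise_sigma, size=field_img.shape)
    maxval = 2**spec.bit_depth - 1
    pixels = np.clip(round_half_up(field_img), 0, maxval)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    img = RasterImage(pixels=pixels.astype(dtype), bit_depth=spec.bit_depth)
    return img, GroundTruth(records=tuple(records))


# ---------------------------------------------------------------------------
# Canned study-condition renders.
# ---------------------------------------------------------------------------


def render_antigen_array(seed: int = 0, noise_sigma: float = 2.0) -> tuple[RasterImage, GroundTruth]:
    """The 31-condition autoantigen panel on a uniform background.

    Amplitudes follow each analyte's dilution series (top of series ->
    200 grey levels, two-fold steps down to 12.5); PBS spots are blank.
    """
    layout = default_antigen_layout()
    spec = SyntheticSpec(
        layout=layout,
        amplitude_map=amplitudes_from_layout(layout),
        background=Background(kind="uniform", base=30.0),
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return render_array(spec)


def render_gradient_demo(seed: int = 42) -> tuple[RasterImage, GroundTruth]:
    """A 7 x 10 demonstration array on a strongly non-uniform background.

    70 spots with amplitudes evenly spanning 15-220 grey levels (shuffled
    across the grid by the seed), a left-to-right linear background
    gradient of 40 grey levels on a base of 10, and noise sigma 3.  Nine
    of the spot amplitudes fall below the gradient amplitude, which is
    what defeats a single global threshold while per-cell thresholds
    retain every spot.
    """
    n_rows, n_cols = 7, 10
    entries = tuple(
        LayoutEntry(row=r, col=c, analyte="probe", concentration=0.0, replicate=r * n_cols + c)
        for r in range(n_rows)
        for c in range(n_cols)
    )
    layout = ArrayLayout(n_rows=n_rows, n_cols=n_cols, entries=entries)
    rng = np.random.default_rng(seed)
    amplitudes = rng.permutation(np.linspace(15.0, 220.0, n_rows * n_cols))
    spec = SyntheticSpec(
        layout=layout,
        amplitude_map=amplitudes.reshape(n_rows, n_cols),
        background=Background(kind="linear-gradient", base=10.0, amplitude=40.0),
        noise_sigma=3.0,
        seed=seed,
    )
    return render_array(spec)


# CD14 sandwich-assay panel conditions: (analyte, concentration ng/mL,
# mean amplitude in grey levels).  Standards are a two-fold dilution
# series; the two patient-like samples sit high, the two control-like
# samples low, mirroring elevated soluble CD14 in active disease.
CD14_CONDITIONS = (
    ("CD14-std", 400.0, 200.0),
    ("CD14-std", 200.0, 100.0),
    ("CD14-std", 100.0, 50.0),
    ("CD14-std", 50.0, 25.0),
    ("CD14-std", 25.0, 12.5),
    ("LN-1", 320.0, 160.0),
    ("LN-2", 280.0, 140.0),
    ("HC-1", 90.0, 45.0),
    ("HC-2", 70.0, 35.0),
)
CD14_REPLICATES = 5


def render_cd14_panel(seed: int = 7, noise_sigma: float = 2.0) -> tuple[RasterImage, GroundTruth]:
    """An antibody-array panel with five replicate spots per condition.

    One row per condition (5 dilution standards, two high "LN-like"
    samples, two low "HC-like" samples), five replicates across each row
    with a 4% replicate-to-replicate amplitude jitter, on a uniform
    background with low noise.  True per-replicate amplitudes are
    recorded in the ground truth.
    """
    n_rows, n_cols = len(CD14_CONDITIONS), CD14_REPLICATES
    rng = np.random.default_rng(seed)
    entries = []
    amp = np.zeros((n_rows, n_cols))
    for r, (analyte, conc, level) in enumerate(CD14_CONDITIONS):
        for c in range(n_cols):
            entries.append(
                LayoutEntry(row=r, col=c, analyte=analyte, concentration=conc, replicate=c)
            )
            amp[r, c] = max(0.0, level * (1.0 + 0.04 * rng.standard_normal()))
    layout = ArrayLayout(n_rows=n_rows, n_cols=n_cols, entries=tuple(entries))
    spec = SyntheticSpec(
        layout=layout,
        amplitude_map=amp,
        background=Background(kind="uniform", base=25.0),
        noise_sigma=noise_sigma,
        seed=seed + 1,  # image noise stream distinct from the jitter stream
    )
    return render_array(spec)
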