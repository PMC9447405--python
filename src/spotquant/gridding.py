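"""Partition an array image into a user-declared rows x columns grid.

The analysis model is the one spotted arrays use in practice: the user
states how many rows and columns of spots the scan contains, and the image
is split into that many rectangular cells, each expected to hold exactly
one spot.  No automatic grid detection or rotation correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

from .image_io import RasterImage

__all__ = ["GridSpec", "Cell", "make_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Grid dimensions plus optional pixel margins excluded from the grid."""

    n_rows: int
    n_cols: int
    margin_top: int = 0
    margin_left: int = 0
    margin_bottom: int = 0
    margin_right: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid must have at least one row and column, got {self.n_rows}x{self.n_cols}")
        for name in ("margin_top", "margin_left", "margin_bottom", "margin_right"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class Cell:
    """One rectangular grid cell, half-open pixel bounds [y0,y1) x [x0,x1)."""

    row_index: int  # 0-based
    col_index: int  # 0-based
    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self) -> None:
        if self.y1 <= self.y0 or self.x1 <= self.x0:
            raise ValueError("cell bounds must be non-empty half-open intervals")

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def area(self) -> int:
        return self.height * self.width

    def extract(self, pixels):
        """Slice this cell's region out of a 2-D pixel array."""
        return pixels[self.y0 : self.y1, self.x0 : self.x1]


def _edges(start: int, length: int, n: int) -> list[int]:
    """Integer partition of [start, start+length) into n contiguous runs.

    The base run length is length // n; the remainder is distributed one
    pixel each to the trailing runs, so run sizes differ by at most one.
    """
    base, rem = divmod(length, n)
    edges = [start]
    for i in range(n):
        edges.append(edges[-1] + base + (1 if i >= n - rem else 0))
    return edges


def make_grid(img: RasterImage, spec: GridSpec) -> list[Cell]:
    """Tile the usable region of ``img`` into ``n_rows * n_cols`` cells.

    Cells are returned in row-major order: cell ``k`` has
    ``row_index = k // n_cols`` and ``col_index = k % n_cols``.  The cells
    tile the usable region (image minus margins) exactly: no overlap, no
    gap.

    Raises
    ------
    ValueError
        If the usable region is smaller than the grid in either dimension.
    """
    usable_h = img.height - spec.margin_top - spec.margin_bottom
    usable_w = img.width - spec.margin_left - spec.margin_right
    if usable_h < spec.n_rows:
        raise ValueError(
            f"usable height {usable_h} px cannot hold {spec.n_rows} rows"
        )
    if usable_w < spec.n_cols:
        raise ValueError(
            f"usable width {usable_w} px cannot hold {spec.n_cols} columns"
        )

    y_edges = _edges(spec.margin_top, usable_h, spec.n_rows)
    x_edges = _edges(spec.margin_left, usable_w, spec.n_cols)
    cells = []
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            cells.append(
                Cell(
                    row_index=r,
                    col_index=c,
                    y0=y_edges[r],
                    y1=y_edges[r + 1],
                    x0=x_edges[c],
                    x1=x_edges[c + 1],
                )
            )
    return cells
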