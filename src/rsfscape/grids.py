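"""Raster grid containers shared by the whole pipeline.

Everything operates on one projected equal-area grid (north-up, row 0 at
top). Pixel ``(i, j)`` covers the half-open square
``[origin_x + j*res, origin_x + (j+1)*res) x (origin_y - (i+1)*res, origin_y - i*res]``
so a point maps to exactly one pixel. Nodata is represented in memory as
NaN; on disk as -9999.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0

__all__ = ["GridSpec", "CovariateStack", "SmoothedStack", "NODATA"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the shared analysis grid.

    ``origin_x``/``origin_y`` are the projected coordinates (metres) of the
    top-left corner. ``resolution`` is the pixel edge in metres (500 m is
    the native analysis resolution).
    """

    origin_x: float
    origin_y: float
    n_rows: int
    n_cols: int
    resolution: float = 500.0
    crs_id: str = "synthetic-equal-area-m"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def width_m(self) -> float:
        return self.n_cols * self.resolution

    @property
    def height_m(self) -> float:
        return self.n_rows * self.resolution

    @property
    def cell_area_km2(self) -> float:
        return (self.resolution / 1000.0) ** 2

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.origin_x,
            self.origin_y - self.height_m,
            self.origin_x + self.width_m,
            self.origin_y,
        )

    def contains(self, x, y):
        xmin, ymin, xmax, ymax = self.extent()
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def cell_index(self, x, y):
        """Row/col of the pixel containing each point (half-open rule).

        Points outside the grid raise ``ValueError``.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.contains(x, y)
        if not np.all(inside):
            bad = np.flatnonzero(~np.atleast_1d(inside))
            raise ValueError(f"{bad.size} point(s) outside grid extent (rows {bad[:10].tolist()}...)")
        j = np.floor((x - self.origin_x) / self.resolution).astype(np.int64)
        i = np.floor((self.origin_y - y) / self.resolution).astype(np.int64)
        # top edge of the grid belongs to row 0; the floor above would give -1
        # only for y == origin_y exactly, handled by clip
        i = np.clip(i, 0, self.n_rows - 1)
        j = np.clip(j, 0, self.n_cols - 1)
        return i, j

    def cell_center(self, i, j):
        i = np.asarray(i, dtype=float)
        j = np.asarray(j, dtype=float)
        x = self.origin_x + (j + 0.5) * self.resolution
        y = self.origin_y - (i + 0.5) * self.resolution
        return x, y

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (n_rows, n_cols) arrays of cell-center coordinates."""
        jj, ii = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        return self.cell_center(ii, jj)


@dataclass
class CovariateStack:
    """Named covariate layers on a shared grid.

    ``times`` optionally maps a layer name to a decimal-year label (e.g.
    2019.0 or 2019.5 for a season); ``groups`` maps a covariate variable to
    the ordered list of its time-labelled layers. A layer absent from any
    group is its own single-layer variable.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    times: dict[str, float] = field(default_factory=dict)
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, arr in self.layers.items():
            if name in seen:
                raise ValueError(f"duplicate layer name {name!r}")
            seen.add(name)
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} != grid shape {self.grid.shape}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def variables(self) -> dict[str, list[str]]:
        """Variable -> ordered member layers (singletons for ungrouped)."""
        grouped = {m for members in self.groups.values() for m in members}
        out: dict[str, list[str]] = dict(self.groups)
        for name in self.layers:
            if name not in grouped:
                out[name] = [name]
        return out


@dataclass
class SmoothedStack:
    """Kernel-smoothed layers keyed by (layer name, scale in km)."""

    grid: GridSpec
    layers: dict[tuple[str, float], np.ndarray] = field(default_factory=dict)
    times: dict[str, float] = field(default_factory=dict)
    groups: dict[str, list[str]] = field(default_factory=dict)

    def scales_for(self, name: str) -> list[float]:
        return [s for (n, s) in self.layers if n == name]
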