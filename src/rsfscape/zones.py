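"""Vector zones (protected areas, ecoregions, countries, range polygons)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .grids import GridSpec

ZONE_TYPES = ("PA", "JCU", "ecoregion", "country", "non_designated", "current_range")

__all__ = ["Zone", "ZoneSet", "ZONE_TYPES", "zone_cell_mask", "repair_polygon"]


def repair_polygon(geom: BaseGeometry) -> BaseGeometry:
    """Return a valid geometry, repairing self-intersections if needed."""
    if geom.is_valid:
        return geom
    fixed = make_valid(geom)
    if not fixed.is_valid or fixed.is_empty:
        raise ValueError("unrepairable geometry")
    return fixed


@dataclass
class Zone:
    zone_id: str
    zone_type: str
    name: str
    polygon: BaseGeometry
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zone_type not in ZONE_TYPES:
            raise ValueError(f"unknown zone_type {self.zone_type!r}")
        self.polygon = repair_polygon(self.polygon)

    @property
    def area_km2(self) -> float:
        return self.polygon.area / 1e6


@dataclass
class ZoneSet:
    zones: list[Zone] = field(default_factory=list)

    def of_type(self, zone_type: str) -> list[Zone]:
        return [z for z in self.zones if z.zone_type == zone_type]

    def one(self, zone_type: str) -> Zone:
        found = self.of_type(zone_type)
        if len(found) != 1:
            raise ValueError(f"expected exactly one {zone_type!r} zone, found {len(found)}")
        return found[0]

    def __iter__(self) -> Iterable[Zone]:
        return iter(self.zones)

    def __len__(self) -> int:
        return len(self.zones)


def zone_cell_mask(grid: GridSpec, polygon: BaseGeometry) -> np.ndarray:
    """Boolean raster: True where the cell center lies inside the polygon.

    Cell membership is by center point (half-open pixel rule), so masks of a
    polygon partition are disjoint and their union is the partition's mask.
    """
    xs, ys = grid.center_grids()
    out = np.zeros(grid.shape, dtype=bool)
    # restrict the point-in-polygon test to the polygon's bounding window
    xmin, ymin, xmax, ymax = polygon.bounds
    cols = (xs[0] >= xmin - grid.resolution) & (xs[0] <= xmax + grid.resolution)
    rows = (ys[:, 0] >= ymin - grid.resolution) & (ys[:, 0] <= ymax + grid.resolution)
    if not rows.any() or not cols.any():
        return out
    sub = shapely.contains_xy(polygon, xs[np.ix_(rows, cols)], ys[np.ix_(rows, cols)])
    out[np.ix_(rows, cols)] = sub
    return out
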