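"""Used/available design preparation from raw telemetry.

The design follows the second-order used/available logic: fixes are
spatially rarefied to one per 500 m pixel per individual; each individual's
availability domain is the union of discs around its retained fixes with
radius 7 * sqrt(home-range area) — the isometric approximation to median
mammalian dispersal distance; background (available) points are drawn
uniformly within that domain at a fixed ratio (default 10 per fix),
temporally matched to the month of their fix, and never sharing a pixel
with any other point of the same individual; finally the presences are
split 80/20 into training and validation, stratified by individual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .grids import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "AvailabilityDomain",
    "availability_radius",
    "rarefy",
    "build_availability_domain",
    "sample_background",
    "split_train_validate",
]

#: Isometric dispersal multiplier: radius_km = 7 * sqrt(area_km2).
DISPERSAL_MULTIPLIER = 7.0

#: Rejection-sampling attempt cap for background draws.
MAX_REJECTION_ATTEMPTS = 1_000_000

USE_AVAILABLE_COLUMNS = ["case", "individual_id", "month", "x", "y", "stratum"]


@dataclass
class AvailabilityDomain:
    individual_id: str
    polygon: BaseGeometry
    radius_km: float

    @property
    def area_km2(self) -> float:
        return self.polygon.area / 1e6


def availability_radius(home_range_area_km2: float) -> float:
    """Potential dispersal distance (km): 7 * sqrt(home-range area)."""
    if home_range_area_km2 <= 0:
        raise ValueError("home range area must be positive")
    return DISPERSAL_MULTIPLIER * float(np.sqrt(home_range_area_km2))


def rarefy(telemetry: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Keep at most one fix per pixel per individual (chronologically first).

    Input order is preserved; with timestamps non-decreasing within an
    individual, first-in-order is first-in-time. Ties share a pixel index,
    so only the first is retained.
    """
    if telemetry.empty:
        return telemetry.copy()
    i, j = grid.cell_index(telemetry["x"].to_numpy(), telemetry["y"].to_numpy())
    key = pd.DataFrame(
        {"individual_id": telemetry["individual_id"].to_numpy(), "i": i, "j": j}
    )
    keep = ~key.duplicated()
    return telemetry.loc[keep.to_numpy()].reset_index(drop=True)


def build_availability_domain(
    ind_locs: pd.DataFrame, d_km: float, grid: GridSpec, *, quad_segs: int = 32
) -> AvailabilityDomain:
    """Union of discs of radius ``d_km`` around fixes, clipped to the grid."""
    if d_km <= 0:
        raise ValueError("availability radius must be positive")
    if ind_locs.empty:
        raise ValueError("no locations to buffer")
    ids = ind_locs["individual_id"].unique()
    if len(ids) != 1:
        raise ValueError("build_availability_domain expects one individual at a time")
    pts = shapely.points(ind_locs["x"].to_numpy(), ind_locs["y"].to_numpy())
    discs = shapely.buffer(pts, d_km * 1000.0, quad_segs=quad_segs)
    poly = unary_union(discs).intersection(box(*_extent_box(grid)))
    if poly.is_empty:
        raise ValueError("availability domain empty after clipping to grid")
    return AvailabilityDomain(individual_id=str(ids[0]), polygon=poly, radius_km=float(d_km))


def _extent_box(grid: GridSpec):
    xmin, ymin, xmax, ymax = grid.extent()
    return xmin, ymin, xmax, ymax


def _month_of(timestamps: pd.Series) -> pd.Series:
    return pd.to_datetime(timestamps).dt.strftime("%Y-%m")


def sample_background(
    used: pd.DataFrame,
    domain: AvailabilityDomain,
    grid: GridSpec,
    ratio: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Temporally matched background points, ``ratio`` per used fix.

    Points are uniform over the domain polygon by rejection sampling; a
    draw is rejected if its pixel already holds a used fix or an accepted
    background point of this individual (points "do not overlap" at the
    500 m pixel level, the analysis unit). Each background point inherits
    the calendar month of its matched fix.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if used.empty:
        raise ValueError("no used locations")
    n_used = len(used)
    n_bg = ratio * n_used

    # feasibility: count free pixels whose center is inside the domain
    iu, ju = grid.cell_index(used["x"].to_numpy(), used["y"].to_numpy())
    used_pixels = set(zip(iu.tolist(), ju.tolist()))
    n_candidate = _count_domain_pixels(grid, domain.polygon)
    free = n_candidate - len(used_pixels)
    if free < n_bg:
        raise ValueError(
            f"availability domain of {domain.individual_id} has only {free} free "
            f"pixel(s) but {n_bg} background points are required (deficit {n_bg - free})"
        )

    rng = np.random.default_rng(seed)
    months = _month_of(used["timestamp"]) if "timestamp" in used else used["month"]
    occupied = set(used_pixels)
    xmin, ymin, xmax, ymax = domain.polygon.bounds
    accepted_x = np.empty(n_bg)
    accepted_y = np.empty(n_bg)
    n_acc = 0
    attempts = 0
    batch = max(4 * n_bg, 1024)
    while n_acc < n_bg:
        if attempts >= MAX_REJECTION_ATTEMPTS:
            raise RuntimeError(
                f"background sampling exceeded {MAX_REJECTION_ATTEMPTS} attempts "
                f"for {domain.individual_id}"
            )
        cx = rng.uniform(xmin, xmax, batch)
        cy = rng.uniform(ymin, ymax, batch)
        attempts += batch
        inside = shapely.contains_xy(domain.polygon, cx, cy)
        ib, jb = (np.empty(0), np.empty(0))
        if inside.any():
            ib, jb = grid.cell_index(cx[inside], cy[inside])
        for x, y, i, j in zip(cx[inside], cy[inside], np.atleast_1d(ib), np.atleast_1d(jb)):
            pix = (int(i), int(j))
            if pix in occupied:
                continue
            occupied.add(pix)
            accepted_x[n_acc] = x
            accepted_y[n_acc] = y
            n_acc += 1
            if n_acc == n_bg:
                break

    ind = domain.individual_id
    strata = np.arange(n_used)
    used_rows = pd.DataFrame(
        {
            "case": 1,
            "individual_id": ind,
            "month": months.to_numpy(),
            "x": used["x"].to_numpy(),
            "y": used["y"].to_numpy(),
            "stratum": strata,
        }
    )
    bg_rows = pd.DataFrame(
        {
            "case": 0,
            "individual_id": ind,
            "month": np.repeat(months.to_numpy(), ratio),
            "x": accepted_x,
            "y": accepted_y,
            "stratum": np.repeat(strata, ratio),
        }
    )
    out = pd.concat([used_rows, bg_rows], ignore_index=True)
    out.attrs["ratio"] = int(ratio)
    return out


def _count_domain_pixels(grid: GridSpec, polygon: BaseGeometry) -> int:
    from .zones import zone_cell_mask

    return int(zone_cell_mask(grid, polygon).sum())


def split_train_validate(
    table: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """80/20 split of presences, stratified by individual.

    Only used rows are randomized; each background row follows its matched
    used row (same individual, same stratum), so strata stay intact.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be strictly between 0 and 1")
    used = table[table["case"] == 1]
    if len(used) < 5:
        raise ValueError("need at least 5 used rows to split")
    rng = np.random.default_rng(seed)
    assign = pd.Series("validate", index=table.index, dtype=object)
    for _ind, grp in used.groupby("individual_id", sort=True):
        idx = grp.index.to_numpy()
        perm = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        train_strata = set(grp.loc[idx[perm[:n_train]], "stratum"])
        in_ind = table["individual_id"] == grp["individual_id"].iloc[0]
        follow = in_ind & table["stratum"].isin(train_strata)
        assign[follow.to_numpy()] = "train"
    out = table.copy()
    out["split"] = assign.to_numpy()
    train = out[out["split"] == "train"].reset_index(drop=True)
    validate = out[out["split"] == "validate"].reset_index(drop=True)
    return train, validate
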