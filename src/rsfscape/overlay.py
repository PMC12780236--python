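"""Conservation assessment of a suitability surface against zone polygons.

Two complementary readings of the surface: (1) continuous — the share of
the range-wide summed suitability captured by each zone; (2) categorical —
"highly suitable" habitat is the upper quartile (top 25%) of the surface,
computed either over the whole current range (range-based scenario) or
separately within each ecoregion (ecoregion-based scenario, which stops a
single dominant biome from absorbing all high-suitability area). Zones are
then reported with their high-suitability proportion and one of five
categories (100-75%, 75-50%, 50-25%, 25-0%, 0%).

Protected areas enter the assessment only after merging adjacent units in
the same country into blocks and filtering blocks to those larger than
100 km^2, below 3000 m elevation, and intersecting the (100 km buffered)
current range. Cell membership everywhere is by cell center (half-open
pixel rule), so partition sums are exact; areas are cell counts times the
cell area (0.25 km^2 at 500 m).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .validation import SuitabilitySurface
from .zones import Zone, ZoneSet, repair_polygon, zone_cell_mask

logger = logging.getLogger(__name__)

__all__ = [
    "HighSuitabilityMask",
    "CATEGORIES",
    "buffer_current_range",
    "filter_protected_areas",
    "summed_share",
    "classify_high",
    "proportion_category",
    "zone_report",
    "country_report",
]

CATEGORIES = ("100–75%", "75–50%", "50–25%", "25–0%", "0%")


def buffer_current_range(
    range_polygon: BaseGeometry,
    buffer_km: float = 100.0,
    exclusions: list[BaseGeometry] | None = None,
    *,
    quad_segs: int = 32,
) -> BaseGeometry:
    """Outward buffer of the current range, minus any excluded zones."""
    poly = repair_polygon(range_polygon)
    out = poly.buffer(buffer_km * 1000.0, quad_segs=quad_segs) if buffer_km > 0 else poly
    for ex in exclusions or []:
        out = out.difference(repair_polygon(ex))
    return out


def filter_protected_areas(
    pas: ZoneSet | list[Zone],
    buffered_range: BaseGeometry,
    min_area_km2: float = 100.0,
    max_elev_m: float = 3000.0,
) -> ZoneSet:
    """Merge adjacent same-country PAs into blocks, then filter blocks.

    A block survives if it is strictly larger than ``min_area_km2``,
    entirely below ``max_elev_m`` (unit-level maximum elevation), and
    intersects the buffered current range. Each surviving block records the
    ids of its member PAs.
    """
    pa_list = pas.of_type("PA") if isinstance(pas, ZoneSet) else list(pas)
    by_country: dict[str, list[Zone]] = {}
    for z in pa_list:
        by_country.setdefault(str(z.attributes.get("country", "")), []).append(z)

    blocks: list[Zone] = []
    for country, members in sorted(by_country.items()):
        merged = unary_union([z.polygon for z in members])
        parts = list(getattr(merged, "geoms", [merged]))
        parts.sort(key=lambda g: (g.centroid.x, g.centroid.y))
        for part in parts:
            ids = [z.zone_id for z in members if z.polygon.intersects(part)]
            max_elev = max(
                float(z.attributes.get("max_elevation_m", 0.0))
                for z in members
                if z.zone_id in ids
            )
            block = Zone(
                zone_id="+".join(ids),
                zone_type="PA",
                name=f"PA block {'+'.join(ids)}",
                polygon=part,
                attributes={
                    "country": country,
                    "max_elevation_m": max_elev,
                    "members": ids,
                },
            )
            if block.area_km2 <= min_area_km2:
                continue
            if max_elev >= max_elev_m:
                continue
            if not part.intersects(buffered_range):
                continue
            blocks.append(block)
    if not blocks:
        logger.info("no protected-area blocks survive the filters")
    return ZoneSet(blocks)


def summed_share(
    surface: SuitabilitySurface, zones: ZoneSet | list[Zone], range_mask: np.ndarray | None = None
) -> pd.Series:
    """Per-zone percentage of the range-wide summed suitability.

    ``share(z) = 100 * sum_{cells in z} w / sum_{cells in range} w`` with
    cells assigned by center. A zone outside the raster gets share 0 with a
    warning.
    """
    w = surface.values
    valid = np.isfinite(w)
    if range_mask is None:
        range_mask = valid
    total = np.nansum(w[range_mask & valid])
    shares = {}
    for z in zones:
        m = zone_cell_mask(surface.grid, z.polygon) & valid & range_mask
        if not m.any():
            warnings.warn(f"zone {z.zone_id} covers no valid raster cells", stacklevel=2)
            shares[z.zone_id] = 0.0
        else:
            shares[z.zone_id] = float(100.0 * np.nansum(w[m]) / total)
    return pd.Series(shares, name="summed_share_pct")


@dataclass
class HighSuitabilityMask:
    """Top-quartile ("highly suitable") cells under one scenario."""

    scenario: str  # 'range_based' | 'ecoregion_based'
    mask: np.ndarray
    thresholds: dict[str, float] = field(default_factory=dict)


def classify_high(
    surface: SuitabilitySurface,
    scenario: str = "range_based",
    ecoregions: ZoneSet | None = None,
    quartile: float = 0.25,
) -> HighSuitabilityMask:
    """Flag cells in the upper quartile of suitability, per stratum.

    The threshold is the (1 - quartile) percentile of valid cell values in
    each stratum (the whole range, or each ecoregion); cells >= threshold
    are flagged, so ties are included and the flagged fraction equals
    ``quartile`` when values are distinct. Strata with fewer than 4 valid
    cells are skipped (logged); constant strata flag everything (warned).
    """
    if scenario not in ("range_based", "ecoregion_based"):
        raise ValueError(f"unknown scenario {scenario!r}")
    w = surface.values
    valid = np.isfinite(w)
    mask = np.zeros(surface.grid.shape, dtype=bool)
    thresholds: dict[str, float] = {}

    if scenario == "range_based":
        strata = [("range", valid)]
    else:
        if ecoregions is None:
            raise ValueError("ecoregion_based scenario requires an ecoregion ZoneSet")
        strata = [
            (z.zone_id, zone_cell_mask(surface.grid, z.polygon) & valid)
            for z in ecoregions.of_type("ecoregion")
        ]

    for sid, smask in strata:
        n = int(smask.sum())
        if n < 4:
            logger.warning("stratum %s has %d valid cells; skipped", sid, n)
            continue
        vals = w[smask]
        if np.ptp(vals) == 0:
            warnings.warn(
                f"stratum {sid} is constant: all cells tie at the threshold", stacklevel=2
            )
            thr = float(vals[0])
        else:
            thr = float(np.quantile(vals, 1.0 - quartile))
        thresholds[sid] = thr
        mask |= smask & (w >= thr)
    return HighSuitabilityMask(scenario=scenario, mask=mask, thresholds=thresholds)


def proportion_category(pct: float) -> str:
    """Five-category rule; boundaries go to the upper class, 0 is its own."""
    if not 0.0 <= pct <= 100.0:
        raise ValueError("proportion must be within [0, 100]")
    if pct == 0.0:
        return CATEGORIES[4]
    if pct >= 75.0:
        return CATEGORIES[0]
    if pct >= 50.0:
        return CATEGORIES[1]
    if pct >= 25.0:
        return CATEGORIES[2]
    return CATEGORIES[3]


def zone_report(
    masks: dict[str, HighSuitabilityMask],
    surface: SuitabilitySurface,
    zones: ZoneSet | list[Zone],
) -> pd.DataFrame:
    """Per-zone area, summed-suitability share, and high-suitability stats."""
    cell_area = surface.grid.cell_area_km2
    valid = np.isfinite(surface.values)
    shares = summed_share(surface, zones)
    rows = []
    for z in zones:
        zmask = zone_cell_mask(surface.grid, z.polygon) & valid
        n_cells = int(zmask.sum())
        row = {
            "zone_id": z.zone_id,
            "zone_type": z.zone_type,
            "name": z.name,
            "area_km2": n_cells * cell_area,
            "summed_share_pct": shares[z.zone_id],
        }
        for scen, hsm in masks.items():
            n_high = int((zmask & hsm.mask).sum())
            pct = 100.0 * n_high / n_cells if n_cells else 0.0
            row[f"high_area_km2_{scen}"] = n_high * cell_area
            row[f"high_pct_{scen}"] = pct
            row[f"category_{scen}"] = proportion_category(pct)
        rows.append(row)
    return pd.DataFrame(rows)


def country_report(
    masks: dict[str, HighSuitabilityMask],
    surface: SuitabilitySurface,
    countries: ZoneSet | list[Zone],
    filtered_pas: ZoneSet | list[Zone],
) -> pd.DataFrame:
    """Country-wise high-suitability tabulation with PA protection shares.

    Per country and scenario: current-range area inside the country, the
    highly suitable area and its percentage of the country's range, and
    the percentage of that highly suitable area lying inside the filtered
    protected-area blocks.
    """
    cell_area = surface.grid.cell_area_km2
    valid = np.isfinite(surface.values)
    pa_list = filtered_pas.zones if isinstance(filtered_pas, ZoneSet) else list(filtered_pas)
    pa_mask = np.zeros(surface.grid.shape, dtype=bool)
    for z in pa_list:
        pa_mask |= zone_cell_mask(surface.grid, z.polygon)
    rows = []
    for c in countries.of_type("country") if isinstance(countries, ZoneSet) else countries:
        cmask = zone_cell_mask(surface.grid, c.polygon) & valid
        n_range = int(cmask.sum())
        row = {
            "country": c.name,
            "zone_id": c.zone_id,
            "range_area_km2": n_range * cell_area,
        }
        for scen, hsm in masks.items():
            high = cmask & hsm.mask
            n_high = int(high.sum())
            row[f"high_area_km2_{scen}"] = n_high * cell_area
            row[f"high_pct_{scen}"] = 100.0 * n_high / n_range if n_range else 0.0
            row[f"protected_pct_{scen}"] = (
                100.0 * int((high & pa_mask).sum()) / n_high if n_high else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)
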