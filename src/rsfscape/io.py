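"""Readers and writers for the pipeline's on-disk artifacts.

Rasters are float32 multiband TIFFs with a JSON sidecar
(``<file>.aux.json``) holding the grid georeferencing, band names, time
labels and nodata value (-9999). Vector zones are GeoJSON. Tables are
plain CSV. All spatial files must share one projected equal-area CRS
token; mismatches are refused rather than reprojected.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping, shape

from .grids import NODATA, CovariateStack, GridSpec, SmoothedStack
from .zones import Zone, ZoneSet

__all__ = [
    "write_raster",
    "read_raster",
    "write_stack",
    "read_stack",
    "write_smoothed_stack",
    "read_smoothed_stack",
    "write_zones",
    "read_zones",
    "read_telemetry",
    "write_telemetry",
    "write_table",
    "read_table",
]


def _grid_dict(grid: GridSpec) -> dict:
    return {
        "origin_x": grid.origin_x,
        "origin_y": grid.origin_y,
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "resolution": grid.resolution,
        "crs_id": grid.crs_id,
    }


def write_raster(path, grid: GridSpec, bands: dict[str, np.ndarray], times=None) -> None:
    path = Path(path)
    names = list(bands)
    data = np.stack([bands[n] for n in names]).astype(np.float32)
    data = np.where(np.isfinite(data), data, np.float32(NODATA))
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "grid": _grid_dict(grid),
        "bands": names,
        "nodata": NODATA,
        "times": times or {},
    }
    Path(str(path) + ".aux.json").write_text(json.dumps(sidecar, indent=1))


def read_raster(path) -> tuple[GridSpec, dict[str, np.ndarray], dict]:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".aux.json").read_text())
    grid = GridSpec(**sidecar["grid"])
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    data[data == sidecar["nodata"]] = np.nan
    bands = {n: data[k] for k, n in enumerate(sidecar["bands"])}
    return grid, bands, sidecar.get("times", {})


def write_stack(path, stack: CovariateStack) -> None:
    write_raster(path, stack.grid, stack.layers, times=stack.times)
    aux = json.loads(Path(str(path) + ".aux.json").read_text())
    aux["groups"] = stack.groups
    Path(str(path) + ".aux.json").write_text(json.dumps(aux, indent=1))


def read_stack(path) -> CovariateStack:
    grid, bands, times = read_raster(path)
    aux = json.loads(Path(str(path) + ".aux.json").read_text())
    return CovariateStack(grid=grid, layers=bands, times=times, groups=aux.get("groups", {}))


def write_smoothed_stack(path_prefix, smoothed: SmoothedStack) -> list[Path]:
    """One multiband file per scale, band names ``<covariate>__<scale>km``."""
    paths = []
    scales = sorted({s for (_n, s) in smoothed.layers})
    for s in scales:
        bands = {
            f"{n}__{s:g}km": arr for (n, sc), arr in smoothed.layers.items() if sc == s
        }
        p = Path(f"{path_prefix}_scale{s:g}km.tif")
        write_raster(p, smoothed.grid, bands, times=smoothed.times)
        paths.append(p)
    return paths


def read_smoothed_stack(paths) -> SmoothedStack:
    out = None
    for p in paths:
        grid, bands, times = read_raster(p)
        if out is None:
            out = SmoothedStack(grid=grid, times=times)
        elif grid != out.grid:
            raise ValueError(f"CRS/grid mismatch between smoothed rasters at {p}")
        for band, arr in bands.items():
            name, stag = band.rsplit("__", 1)
            out.layers[(name, float(stag[:-2]))] = arr
    return out


def write_zones(path, zones: ZoneSet, crs_id: str = "synthetic-equal-area-m") -> None:
    features = []
    for z in zones:
        props = {"zone_id": z.zone_id, "zone_type": z.zone_type, "name": z.name}
        props.update(z.attributes)
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(z.polygon)}
        )
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs_id}},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def read_zones(path, expect_crs: str | None = None) -> ZoneSet:
    doc = json.loads(Path(path).read_text())
    crs = doc.get("crs", {}).get("properties", {}).get("name")
    if expect_crs is not None and crs != expect_crs:
        raise ValueError(f"zone CRS {crs!r} does not match expected {expect_crs!r}")
    zones = []
    for feat in doc["features"]:
        props = dict(feat["properties"])
        zones.append(
            Zone(
                zone_id=props.pop("zone_id"),
                zone_type=props.pop("zone_type"),
                name=props.pop("name"),
                polygon=shape(feat["geometry"]),
                attributes=props,
            )
        )
    return ZoneSet(zones)


TELEMETRY_COLUMNS = ["individual_id", "sex", "region", "timestamp", "x", "y"]


def read_telemetry(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str})
    missing = set(TELEMETRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"telemetry CSV missing column(s): {sorted(missing)}")
    parsed = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad = parsed.isna() & df["timestamp"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"non-ISO timestamp at line {line}: {df.loc[bad.idxmax(), 'timestamp']!r}")
    if parsed.isna().any():
        line = int(parsed.isna().idxmax()) + 2
        raise ValueError(f"missing timestamp at line {line}")
    return df


def write_telemetry(path, telemetry: pd.DataFrame) -> None:
    telemetry.to_csv(path, index=False, float_format="%.6f")


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
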