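"""Stage orchestration: simulate -> prep -> scale -> fit -> predict -> validate -> assess.

Every stage reads its inputs from and persists its outputs to the run
directory, so stages can be re-run individually and a manifest records a
content hash of every artifact. Per-stage random seeds are derived from
the master seed by hashing the stage name (stable across runs and
platforms), so a rerun with the same config and seed reproduces identical
artifacts byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .config import RunConfig
from .grids import GridSpec
from .model import fit_final_model, mrmr_select, optimize_scales, spearman_matrix
from .overlay import (
    buffer_current_range,
    classify_high,
    country_report,
    filter_protected_areas,
    zone_report,
)
from .prep import (
    availability_radius,
    build_availability_domain,
    rarefy,
    sample_background,
    split_train_validate,
)
from .scaling import build_smoothed_stack, extract_covariates
from .synthetic import (
    TruthBundle,
    generate_covariate_stack,
    generate_zone_set,
    simulate_population,
    simulate_telemetry,
)
from .validation import boyce_index, predict_surface, raster_correlation, roc_metrics

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prep", "scale", "fit", "predict", "validate", "assess")

__all__ = ["STAGES", "stage_seed", "run_pipeline"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage child seed below 2^31."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Run:
    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"stages": {}, "artifacts": {}}
        self.manifest["config"] = config.to_dict()
        self.manifest["config_hash"] = hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def record(self, stage: str, artifacts: list[Path], info: dict) -> None:
        self.manifest["stages"][stage] = {
            "seed": stage_seed(self.cfg.seed, stage),
            **info,
        }
        for p in artifacts:
            self.manifest["artifacts"][p.name] = _hash_file(p)
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))

    def need(self, stage: str, *paths: str) -> list[Path]:
        missing = [p for p in paths if not (self.out / p).exists()]
        if missing:
            raise FileNotFoundError(
                f"missing upstream artifact(s) {missing}; run the "
                f"'{_producer_of(missing[0])}' stage first"
            )
        return [self.out / p for p in paths]


_PRODUCERS = {
    "covariates.tif": "simulate",
    "zones.geojson": "simulate",
    "telemetry.csv": "simulate",
    "truth.json": "simulate",
    "use_available.csv": "prep",
    "design.csv": "scale",
    "final_model.json": "fit",
    "scale_selection.csv": "fit",
    "suitability.tif": "predict",
}


def _producer_of(artifact: str) -> str:
    return _PRODUCERS.get(artifact, "an earlier")


def _stage_simulate(run: _Run) -> None:
    cfg = run.cfg
    seed = stage_seed(cfg.seed, "simulate")
    rng = np.random.default_rng(seed)
    grid = GridSpec(
        origin_x=0.0,
        origin_y=cfg.grid_rows * cfg.resolution_m,
        n_rows=cfg.grid_rows,
        n_cols=cfg.grid_cols,
        resolution=cfg.resolution_m,
    )
    stack = generate_covariate_stack(grid, cfg.n_covariates, cfg.autocorr_range_m, seed)
    zones = generate_zone_set(
        grid, cfg.n_ecoregions, cfg.n_pas, seed + 1, n_countries=cfg.n_countries
    )
    names = stack.names
    signs = np.where(np.arange(len(names)) % 2 == 0, 1.0, -1.0)
    truth = TruthBundle(
        true_beta={n: float(s * cfg.true_beta_magnitude) for n, s in zip(names, signs)},
        true_scale={n: float(rng.choice(cfg.true_scales)) for n in names},
        rng_seed=seed,
    )
    hr = {("region0", "F"): cfg.home_range_km2, ("region0", "M"): cfg.home_range_km2}
    individuals = simulate_population(cfg.n_individuals, cfg.sex_ratio, hr, grid, seed + 2)
    telemetry = simulate_telemetry(
        stack, individuals, truth, cfg.n_locs_per_individual, seed + 3
    )
    rio.write_stack(run.out / "covariates.tif", stack)
    rio.write_zones(run.out / "zones.geojson", zones, crs_id=grid.crs_id)
    rio.write_telemetry(run.out / "telemetry.csv", telemetry)
    (run.out / "truth.json").write_text(
        json.dumps(
            {
                "true_beta": truth.true_beta,
                "true_scale": truth.true_scale,
                "rng_seed": truth.rng_seed,
            },
            indent=1,
        )
    )
    run.record(
        "simulate",
        [run.out / p for p in ("covariates.tif", "zones.geojson", "telemetry.csv", "truth.json")],
        {"n_fixes": len(telemetry), "n_individuals": cfg.n_individuals},
    )


def _stage_prep(run: _Run) -> None:
    cfg = run.cfg
    run.need("prep", "telemetry.csv", "covariates.tif")
    seed = stage_seed(cfg.seed, "prep")
    stack = rio.read_stack(run.out / "covariates.tif")
    telemetry = rio.read_telemetry(run.out / "telemetry.csv")
    rare = rarefy(telemetry, stack.grid)
    tables = []
    for k, (_ind, grp) in enumerate(rare.groupby("individual_id", sort=True)):
        d_km = availability_radius(cfg.home_range_km2)
        domain = build_availability_domain(grp, d_km, stack.grid)
        tables.append(
            sample_background(
                grp, domain, stack.grid, ratio=cfg.background_ratio, seed=seed + k
            )
        )
    table = pd.concat(tables, ignore_index=True)
    train, validate = split_train_validate(table, cfg.train_fraction, seed=seed)
    out = pd.concat([train, validate], ignore_index=True)
    rio.write_table(run.out / "use_available.csv", out)
    run.record(
        "prep",
        [run.out / "use_available.csv"],
        {"n_used": int((out["case"] == 1).sum()), "n_available": int((out["case"] == 0).sum())},
    )


def _stage_scale(run: _Run) -> None:
    cfg = run.cfg
    run.need("scale", "covariates.tif", "use_available.csv")
    stack = rio.read_stack(run.out / "covariates.tif")
    table = rio.read_table(run.out / "use_available.csv")
    smoothed = build_smoothed_stack(stack, cfg.scales)
    # scales whose kernel exceeds the mapped extent produce mostly-nodata
    # layers; exclude scales lacking majority-valid coverage (logged)
    usable = []
    for s in cfg.scales:
        fracs = [
            np.isfinite(smoothed.layers[(n, float(s))]).mean() for n in stack.names
        ]
        if min(fracs) >= 0.5:
            usable.append(float(s))
        else:
            logger.warning(
                "scale %s km unsupported on this grid (valid fraction %.2f); excluded",
                s,
                min(fracs),
            )
    smoothed.layers = {k: v for k, v in smoothed.layers.items() if k[1] in usable}
    design = extract_covariates(table, smoothed)
    rio.write_table(run.out / "design.csv", design)
    paths = rio.write_smoothed_stack(run.out / "smoothed", smoothed)
    (run.out / "scales_used.json").write_text(json.dumps(usable))
    run.record(
        "scale",
        paths + [run.out / "design.csv", run.out / "scales_used.json"],
        {"n_rows": len(design), "scales_used": usable},
    )


def _stage_fit(run: _Run) -> None:
    cfg = run.cfg
    run.need("fit", "design.csv", "scales_used.json")
    design = rio.read_table(run.out / "design.csv")
    design["individual_id"] = design["individual_id"].astype(str)
    scales = json.loads((run.out / "scales_used.json").read_text())
    covs = sorted({c.rsplit("@", 1)[0] for c in design.columns if "@" in c})
    train = design[design["split"] == "train"].reset_index(drop=True)

    selection = optimize_scales(train, covs, scales)
    kept = [c for c in covs if c in selection.chosen_scale]
    from .scaling import column_key

    opt_cols = [column_key(c, selection.chosen_scale[c]) for c in kept]
    corr = spearman_matrix(train, opt_cols)
    n_keep = min(cfg.n_keep, len(opt_cols))
    mrmr = mrmr_select(corr, n_keep=n_keep)
    chosen_names = [c.rsplit("@", 1)[0] for c in mrmr.selected]
    final = fit_final_model(design, chosen_names, selection, quad_points=cfg.quad_points)

    rio.write_table(run.out / "scale_selection.csv", selection.to_frame())
    rio.write_table(run.out / "mrmr_trace.csv", mrmr.trace)
    rio.write_table(run.out / "final_model.csv", final.to_table())
    (run.out / "final_model.json").write_text(
        json.dumps(
            {
                "covariates": final.covariates,
                "beta": final.beta,
                "se": final.se,
                "z": final.z,
                "p": final.p,
                "sigma2_id": final.sigma2_id,
                "loglik": final.loglik,
                "k": final.k,
                "n": final.n,
                "aicc": final.aicc,
                "converged": final.converged,
                "standardization": final.standardization,
                "scale_km": final.scale_km,
            },
            indent=1,
        )
    )
    run.record(
        "fit",
        [
            run.out / p
            for p in ("scale_selection.csv", "mrmr_trace.csv", "final_model.csv", "final_model.json")
        ],
        {"n_selected": len(final.covariates), "aicc": final.aicc},
    )


def _load_final_model(run: _Run):
    from .model import FittedRSF

    d = json.loads((run.out / "final_model.json").read_text())
    d["standardization"] = {k: tuple(v) for k, v in d["standardization"].items()}
    return FittedRSF(**d)


def _stage_predict(run: _Run) -> None:
    cfg = run.cfg
    run.need("predict", "final_model.json", "scales_used.json")
    scales = json.loads((run.out / "scales_used.json").read_text())
    paths = [run.out / f"smoothed_scale{s:g}km.tif" for s in scales]
    smoothed = rio.read_smoothed_stack(paths)
    model = _load_final_model(run)
    surface = predict_surface(model, smoothed, n_bins=cfg.n_bins)
    rio.write_raster(
        run.out / "suitability.tif",
        surface.grid,
        {"suitability": surface.values, "bins": surface.bins.astype(float)},
    )
    run.record(
        "predict",
        [run.out / "suitability.tif"],
        {"n_valid_cells": int(np.isfinite(surface.values).sum())},
    )


def _load_surface(run: _Run):
    from .validation import SuitabilitySurface

    grid, bands, _ = rio.read_raster(run.out / "suitability.tif")
    bins = np.nan_to_num(bands["bins"], nan=0.0).astype(int)
    return SuitabilitySurface(
        grid=grid, values=bands["suitability"], bins=bins, n_bins=run.cfg.n_bins
    )


def _stage_validate(run: _Run) -> None:
    run.need("validate", "suitability.tif", "design.csv")
    surface = _load_surface(run)
    design = rio.read_table(run.out / "design.csv")
    held = design[(design["split"] == "validate") & (design["case"] == 1)]
    report: dict[str, float] = {}
    boyce = boyce_index(surface, held[["x", "y"]].to_numpy())
    report["boyce_index"] = boyce.index
    held_all = design[design["split"] == "validate"].rename(columns={"case": "label"})
    roc = roc_metrics(surface, held_all)
    report.update(
        {
            "auc": roc.auc,
            "roc_threshold": roc.threshold,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }
    )
    truth_path = run.out / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        stack = rio.read_stack(run.out / "covariates.tif")
        from .scaling import build_gaussian_kernel, smooth_covariate
        from scipy.special import expit

        eta = np.zeros(stack.grid.shape)
        for cov, beta in truth["true_beta"].items():
            kern = build_gaussian_kernel(truth["true_scale"][cov], stack.grid.resolution)
            z = smooth_covariate(stack.layers[cov], kern)
            eta = eta + beta * z
        report["pearson_r_vs_truth"] = raster_correlation(surface.values, expit(eta))
    (run.out / "validation.json").write_text(json.dumps(report, indent=1))
    run.record("validate", [run.out / "validation.json"], report)


def _stage_assess(run: _Run) -> None:
    cfg = run.cfg
    run.need("assess", "suitability.tif", "zones.geojson")
    surface = _load_surface(run)
    zones = rio.read_zones(run.out / "zones.geojson")
    current = zones.one("current_range")
    buffered = buffer_current_range(current.polygon, cfg.buffer_km)
    pas = filter_protected_areas(zones, buffered, cfg.min_pa_area_km2, cfg.max_pa_elev_m)
    masks = {
        scen: classify_high(
            surface,
            scen,
            ecoregions=zones if scen == "ecoregion_based" else None,
            quartile=cfg.quartile,
        )
        for scen in cfg.assess_scenarios
    }
    report_zones = [z for z in zones if z.zone_type in ("ecoregion", "PA")] + list(pas)
    zrep = zone_report(masks, surface, report_zones)
    crep = country_report(masks, surface, zones, pas)
    rio.write_table(run.out / "zone_report.csv", zrep)
    rio.write_table(run.out / "country_report.csv", crep)
    run.record(
        "assess",
        [run.out / "zone_report.csv", run.out / "country_report.csv"],
        {"n_pa_blocks": len(pas)},
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "prep": _stage_prep,
    "scale": _stage_scale,
    "fit": _stage_fit,
    "predict": _stage_predict,
    "validate": _stage_validate,
    "assess": _stage_assess,
}


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stages in canonical order; return the manifest."""
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    ordered = [s for s in STAGES if s in stages]
    run = _Run(config)
    for stage in ordered:
        t0 = time.perf_counter()
        _STAGE_FUNCS[stage](run)
        logger.info("stage %-9s finished in %.1f s", stage, time.perf_counter() - t0)
    return run.manifest
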