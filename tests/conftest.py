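"""Shared fixtures: small grids, stacks, and the ground-truth recovery harness."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rsfscape import (
    GridSpec,
    TruthBundle,
    availability_radius,
    build_availability_domain,
    build_smoothed_stack,
    extract_covariates,
    generate_covariate_stack,
    rarefy,
    sample_background,
    simulate_population,
    simulate_telemetry,
    split_train_validate,
)
from rsfscape.scaling import DEFAULT_SCALES


def make_grid(n: int = 50, resolution: float = 500.0) -> GridSpec:
    return GridSpec(origin_x=0.0, origin_y=n * resolution, n_rows=n, n_cols=n, resolution=resolution)


@pytest.fixture
def grid50() -> GridSpec:
    return make_grid(50)


@pytest.fixture
def grid200() -> GridSpec:
    return make_grid(200)


def simulate_design(
    seed: int,
    *,
    grid_cells: int = 300,
    n_cov: int = 5,
    n_individuals: int = 30,
    n_locs: int = 200,
    ratio: int = 10,
    autocorr_m: float = 1000.0,
    true_scales=(1.0, 2.0, 4.0, 8.0),
    beta_mag: float = 1.0,
    ladder=DEFAULT_SCALES,
    hr_km2: float = 25.0,
    true_scale_fixed: float | None = None,
    split: bool = False,
):
    """End-to-end synthetic design with known truth.

    Generates a landscape, simulates a population and selection-driven
    telemetry, prepares the used/available table, smooths covariates over
    the ladder (dropping scales without majority-valid coverage on the
    grid) and extracts the design matrix. Returns
    (design, truth, usable_scales, smoothed, stack).
    """
    grid = make_grid(grid_cells)
    stack = generate_covariate_stack(grid, n_cov, autocorr_m, seed)
    rng = np.random.default_rng(seed + 1)
    truth = TruthBundle(
        true_beta={
            n: beta_mag * (1.0 if k % 2 == 0 else -1.0) for k, n in enumerate(stack.names)
        },
        true_scale={
            n: (true_scale_fixed if true_scale_fixed is not None else float(rng.choice(true_scales)))
            for n in stack.names
        },
        rng_seed=seed,
    )
    hr = {("r", "F"): hr_km2, ("r", "M"): hr_km2}
    individuals = simulate_population(n_individuals, 0.5, hr, grid, seed + 2)
    telemetry = simulate_telemetry(stack, individuals, truth, n_locs, seed + 3)
    rare = rarefy(telemetry, grid)
    tables = []
    for k, (_ind, grp) in enumerate(rare.groupby("individual_id", sort=True)):
        domain = build_availability_domain(grp, availability_radius(hr_km2), grid)
        tables.append(sample_background(grp, domain, grid, ratio=ratio, seed=seed + 10 + k))
    table = pd.concat(tables, ignore_index=True)
    if split:
        train, validate = split_train_validate(table, 0.8, seed=seed + 5)
        table = pd.concat([train, validate], ignore_index=True)
    smoothed = build_smoothed_stack(stack, ladder)
    usable = [
        float(s)
        for s in ladder
        if all(np.isfinite(smoothed.layers[(n, float(s))]).mean() >= 0.5 for n in stack.names)
    ]
    smoothed.layers = {k2: v for k2, v in smoothed.layers.items() if k2[1] in usable}
    design = extract_covariates(table, smoothed)
    return design, truth, usable, smoothed, stack
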