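"""Run configuration: validated parameters with field defaults.

Defaults are the workflow's canonical constants: the seven-scale ladder
0.5–32 km, 10 background points per fix, 80% training fraction, 10
suitability bins, 15 retained covariates, top-25% quartile, 100 km range
buffer, and protected-area filters of 100 km^2 / 3000 m.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # paths
    output_dir: str = "rsfscape_run"
    telemetry_path: str | None = None
    covariates_path: str | None = None
    zones_path: str | None = None

    # analysis constants
    scales: list[float] = field(default_factory=lambda: [0.5, 1, 2, 4, 8, 16, 32])
    background_ratio: int = 10
    train_fraction: float = 0.8
    n_bins: int = 10
    n_keep: int = 15
    quartile: float = 0.25
    buffer_km: float = 100.0
    min_pa_area_km2: float = 100.0
    max_pa_elev_m: float = 3000.0
    seed: int = 0

    # synthetic-stage parameters
    grid_rows: int = 100
    grid_cols: int = 100
    resolution_m: float = 500.0
    n_covariates: int = 5
    autocorr_range_m: float = 1000.0
    n_individuals: int = 30
    n_locs_per_individual: int = 200
    sex_ratio: float = 0.5
    home_range_km2: float = 25.0
    n_ecoregions: int = 4
    n_pas: int = 6
    n_countries: int = 3
    true_scales: list[float] = field(default_factory=lambda: [1, 2, 4, 8])
    true_beta_magnitude: float = 1.0
    quad_points: int = 7
    assess_scenarios: list[str] = field(
        default_factory=lambda: ["range_based", "ecoregion_based"]
    )

    def __post_init__(self) -> None:
        from .scaling import ScaleSet

        self.scales = list(ScaleSet(self.scales))
        checks = [
            ("background_ratio", self.background_ratio >= 1, ">= 1"),
            ("train_fraction", 0 < self.train_fraction < 1, "in (0, 1)"),
            ("n_bins", self.n_bins >= 2, ">= 2"),
            ("n_keep", self.n_keep >= 1, ">= 1"),
            ("quartile", 0 < self.quartile < 1, "in (0, 1)"),
            ("buffer_km", self.buffer_km >= 0, ">= 0"),
            ("min_pa_area_km2", self.min_pa_area_km2 >= 0, ">= 0"),
            ("max_pa_elev_m", self.max_pa_elev_m > 0, "> 0"),
            ("resolution_m", self.resolution_m > 0, "> 0"),
            ("n_covariates", self.n_covariates >= 1, ">= 1"),
            ("n_individuals", self.n_individuals >= 0, ">= 0"),
            ("sex_ratio", 0 <= self.sex_ratio <= 1, "in [0, 1]"),
            ("home_range_km2", self.home_range_km2 > 0, "> 0"),
            ("quad_points", self.quad_points >= 1, ">= 1"),
            (
                "assess_scenarios",
                bool(self.assess_scenarios)
                and set(self.assess_scenarios) <= {"range_based", "ecoregion_based"},
                "a non-empty subset of {range_based, ecoregion_based}",
            ),
        ]
        for name, ok, rule in checks:
            if not ok:
                raise ValueError(f"config field {name!r} must be {rule}, got {getattr(self, name)}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected, defaults filled in."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**data)
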