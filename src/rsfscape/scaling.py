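"""Multi-scale Gaussian smoothing of covariates and point extraction.

Habitat selection is scale-dependent: an animal may respond to forest cover
averaged over its immediate surroundings or over a much broader landscape
context ("scale of effect"). Each covariate is therefore smoothed with an
isotropic Gaussian focal mean at a ladder of candidate scales — by default
0.5, 1, 2, 4, 8, 16 and 32 km — and the model-selection stage picks the
best-supported scale per covariate. The kernel bandwidth sigma equals the
scale distance, truncated at 3*sigma and renormalized to sum one.

Edges and nodata are handled by valid-mass renormalization: the weighted
mean is taken over the valid cells the kernel actually covers, and the
output is nodata where less than half the kernel mass falls on valid cells.
This avoids biasing cells near coasts or range edges toward zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .grids import CovariateStack, GridSpec, SmoothedStack

logger = logging.getLogger(__name__)

#: Candidate scales (km) used throughout the workflow.
DEFAULT_SCALES: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)

#: Minimum fraction of kernel mass on valid cells for a smoothed value.
VALID_MASS_THRESHOLD = 0.5

__all__ = [
    "DEFAULT_SCALES",
    "KernelMatrix",
    "ScaleSet",
    "build_gaussian_kernel",
    "smooth_covariate",
    "build_smoothed_stack",
    "extract_covariates",
]


def ScaleSet(scales) -> tuple[float, ...]:
    """Validate an ordered scale ladder (km): strictly increasing, positive."""
    scales = tuple(float(s) for s in scales)
    if not scales:
        raise ValueError("scale set must not be empty")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    if any(b <= a for a, b in zip(scales, scales[1:])):
        raise ValueError("scales must be strictly increasing")
    return scales


@dataclass(frozen=True)
class KernelMatrix:
    """Normalized square Gaussian weight matrix for one scale."""

    scale_km: float
    resolution_m: float
    weights: np.ndarray

    @property
    def side(self) -> int:
        return self.weights.shape[0]


def build_gaussian_kernel(scale_km: float, resolution_m: float) -> KernelMatrix:
    """Isotropic Gaussian kernel with sigma = scale, truncated at 3*sigma.

    The half-width is ``ceil(3*sigma / resolution)`` pixels, so the side is
    always odd and the 0.5 km scale at 500 m resolution is a 7x7 kernel.
    """
    if scale_km <= 0 or resolution_m <= 0:
        raise ValueError("scale and resolution must be positive")
    sigma_m = 1000.0 * scale_km
    half = int(np.ceil(3.0 * sigma_m / resolution_m))
    offsets = np.arange(-half, half + 1) * resolution_m
    d2 = offsets[:, None] ** 2 + offsets[None, :] ** 2
    w = np.exp(-d2 / (2.0 * sigma_m**2))
    w[np.sqrt(d2) > 3.0 * sigma_m] = 0.0
    w /= w.sum()
    return KernelMatrix(scale_km=float(scale_km), resolution_m=float(resolution_m), weights=w)


def _clip_kernel(kernel: KernelMatrix, shape: tuple[int, int]) -> np.ndarray:
    w = kernel.weights
    limit = 4 * max(shape)
    if w.shape[0] > limit:
        # clip to the grid dimension so interior cells keep valid kernel mass
        target = max(shape) if max(shape) % 2 == 1 else max(shape) - 1
        half = target // 2
        c = w.shape[0] // 2
        w = w[c - half : c + half + 1, c - half : c + half + 1]
        w = w / w.sum()
        warnings.warn(
            f"kernel side {kernel.weights.shape[0]} exceeds 4x grid extent; "
            f"clipped to {w.shape[0]}",
            stacklevel=3,
        )
    return w


def smooth_covariate(
    layer: np.ndarray, kernel: KernelMatrix, *, boundary: str = "renormalize"
) -> np.ndarray:
    """Gaussian focal mean with valid-mass renormalization.

    ``boundary='wrap'`` treats the grid as a torus (periodic boundary);
    useful for stationarity checks, not for real landscapes.
    """
    layer = np.asarray(layer, dtype=float)
    w = _clip_kernel(kernel, layer.shape)
    valid = np.isfinite(layer)
    filled = np.where(valid, layer, 0.0)
    if boundary == "wrap":
        from scipy.ndimage import convolve

        num = convolve(filled, w, mode="wrap")
        den = convolve(valid.astype(float), w, mode="wrap")
    elif boundary == "renormalize":
        num = fftconvolve(filled, w, mode="same")
        den = fftconvolve(valid.astype(float), w, mode="same")
    else:
        raise ValueError(f"unknown boundary mode {boundary!r}")
    out = np.full(layer.shape, np.nan)
    ok = den >= VALID_MASS_THRESHOLD
    np.divide(num, den, out=out, where=ok)
    out[~ok] = np.nan
    return out


def build_smoothed_stack(stack: CovariateStack, scales=DEFAULT_SCALES) -> SmoothedStack:
    """Smooth every layer at every scale: n_layers x n_scales outputs."""
    scales = ScaleSet(scales)
    kernels = {s: build_gaussian_kernel(s, stack.grid.resolution) for s in scales}
    out = SmoothedStack(
        grid=stack.grid, times=dict(stack.times), groups=dict(stack.groups)
    )
    for name, layer in stack.layers.items():
        for s in scales:
            out.layers[(name, s)] = smooth_covariate(layer, kernels[s])
    return out


def _month_to_year(month: str) -> float:
    ts = pd.Period(month, freq="M")
    return ts.year + (ts.month - 0.5) / 12.0


def column_key(variable: str, scale_km: float) -> str:
    """Design-matrix column name for a (covariate, scale) pair."""
    return f"{variable}@{scale_km:g}"


def extract_covariates(
    points: pd.DataFrame,
    smoothed: SmoothedStack,
    *,
    time_matching: str = "nearest",
) -> pd.DataFrame:
    """Sample smoothed values at each point's containing pixel.

    Returns the input rows with one added column per (variable, scale),
    named ``variable@scale``. For variables with several time-labelled
    layers the layer with the nearest label to the row's month is used
    (ties broken toward the earlier label). Rows hitting nodata in any
    required layer are dropped and the count logged.
    """
    if time_matching not in ("nearest",):
        raise ValueError(f"unknown time_matching policy {time_matching!r}")
    grid: GridSpec = smoothed.grid
    i, j = grid.cell_index(points["x"].to_numpy(), points["y"].to_numpy())

    variables = _variables_of(smoothed)
    out = points.reset_index(drop=True).copy()

    row_year = None
    if "month" in out.columns and any(len(m) > 1 for m in variables.values()):
        row_year = out["month"].map(_month_to_year).to_numpy()

    for var, members in variables.items():
        for scale in smoothed.scales_for(members[0]):
            if len(members) == 1:
                vals = smoothed.layers[(members[0], scale)][i, j]
            else:
                labels = np.array([smoothed.times[m] for m in members])
                if row_year is None:
                    raise ValueError(
                        f"variable {var!r} has time-labelled layers but points lack a month"
                    )
                # nearest label; distance ties (to float tolerance) resolved
                # to the earlier label
                dist = np.abs(row_year[:, None] - labels[None, :])
                order = np.argsort(labels, kind="stable")
                d_sorted = dist[:, order]
                tie = d_sorted <= d_sorted.min(axis=1, keepdims=True) + 1e-9
                pick = order[np.argmax(tie, axis=1)]
                stacked = np.stack([smoothed.layers[(m, scale)] for m in members])
                vals = stacked[pick, i, j]
            out[column_key(var, scale)] = vals

    cov_cols = [c for c in out.columns if "@" in c]
    keep = out[cov_cols].notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("extract_covariates: dropped %d row(s) hitting nodata", n_drop)
    return out.loc[keep].reset_index(drop=True)


def _variables_of(smoothed: SmoothedStack) -> dict[str, list[str]]:
    layer_names = {n for (n, _s) in smoothed.layers}
    grouped = {m for members in smoothed.groups.values() for m in members}
    out: dict[str, list[str]] = {}
    for var, members in smoothed.groups.items():
        out[var] = [m for m in members if m in layer_names]
    for name in sorted(layer_names):
        if name not in grouped:
            out[name] = [name]
    return out
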