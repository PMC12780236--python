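"""Suitability prediction and presence-only model validation.

Because used/available RSFs estimate *relative* selection strength, the
continuous surface is the inverse-logit of the fixed-effect linear
predictor (random intercept at zero) — a strictly monotone transform of
the selection score, which leaves every rank-based instrument downstream
(quantile bins, Boyce index, quartile masks) invariant.

Validation instruments:

* Boyce index — Spearman correlation between the predicted-to-expected
  frequency ratio of evaluation presences across 10 equal-frequency
  suitability bins and the bin rank; in [-1, 1], ~0 for a random model.
* ROC/AUC with the optimal threshold at the point closest to (0, 1).
* Linear regression of independent density estimates on mean suitability
  within a 100 km^2 circular buffer around each estimate.
* Pearson correlation between two co-registered rasters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_curve

from .grids import GridSpec, SmoothedStack
from .model import INTERCEPT, FittedRSF
from .scaling import column_key

__all__ = [
    "SuitabilitySurface",
    "BoyceResult",
    "RocResult",
    "DensityRegressionResult",
    "predict_surface",
    "quantile_bins",
    "boyce_index",
    "roc_metrics",
    "density_regression",
    "raster_correlation",
]

#: Circular-buffer radius (km) whose disc has an area of 100 km^2.
DENSITY_BUFFER_RADIUS_KM = float(np.sqrt(100.0 / np.pi))


@dataclass
class SuitabilitySurface:
    grid: GridSpec
    values: np.ndarray  # continuous relative suitability in (0, 1)
    bins: np.ndarray  # 1..n_bins, 0 where nodata
    n_bins: int = 10

    def value_at(self, x, y):
        i, j = self.grid.cell_index(x, y)
        return self.values[i, j]

    def bin_at(self, x, y):
        i, j = self.grid.cell_index(x, y)
        return self.bins[i, j]


def quantile_bins(layer: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency bins (1..n_bins); ties share the lower bin.

    Cells are ranked by value; rank r (0-based, stable) maps to bin
    ``r * n_bins // n + 1``, and runs of equal values are collapsed to the
    lowest bin of the run, so bin counts are equal up to tie spill-over.
    Nodata cells get bin 0.
    """
    vals = np.asarray(layer, dtype=float)
    flat = vals.ravel()
    valid = np.isfinite(flat)
    n = int(valid.sum())
    if n < n_bins:
        raise ValueError(f"only {n} valid cells for {n_bins} bins")
    v = flat[valid]
    if np.ptp(v) == 0:
        warnings.warn("constant layer: all cells fall in one degenerate bin", stacklevel=2)
        out = np.zeros(flat.shape, dtype=int)
        out[valid] = 1
        return out.reshape(vals.shape)
    order = np.argsort(v, kind="stable")
    bins_sorted = (np.arange(n) * n_bins) // n + 1
    # collapse ties to the lower bin: first occurrence of each distinct value
    sv = v[order]
    first = np.concatenate(([True], sv[1:] != sv[:-1]))
    run_start = np.maximum.accumulate(np.where(first, np.arange(n), 0))
    bins_sorted = bins_sorted[run_start]
    binned = np.empty(n, dtype=int)
    binned[order] = bins_sorted
    out = np.zeros(flat.shape, dtype=int)
    out[valid] = binned
    return out.reshape(vals.shape)


def predict_surface(
    model: FittedRSF,
    smoothed: SmoothedStack,
    *,
    n_bins: int = 10,
) -> SuitabilitySurface:
    """Project the fixed effects of a fitted RSF onto the grid.

    ``w = logistic(b0 + sum_c b_c * z_c)`` cellwise, where each ``z_c`` is
    the covariate's smoothed layer at its retained scale, standardized with
    the training-set record stored in the model. Nodata propagates from any
    input layer.
    """
    if model.standardization is None:
        raise ValueError("model carries no standardization record")
    eta = np.full(smoothed.grid.shape, model.beta[INTERCEPT])
    valid = np.ones(smoothed.grid.shape, dtype=bool)
    for col in model.covariates:
        layer = _layer_for_column(smoothed, col, model)
        mu, sd = model.standardization[col]
        z = (layer - mu) / sd
        valid &= np.isfinite(z)
        eta = eta + model.beta[col] * np.where(np.isfinite(z), z, 0.0)
    w = expit(eta)
    w[~valid] = np.nan
    bins = quantile_bins(w, n_bins)
    return SuitabilitySurface(grid=smoothed.grid, values=w, bins=bins, n_bins=n_bins)


def _layer_for_column(smoothed: SmoothedStack, col: str, model: FittedRSF) -> np.ndarray:
    if "@" in col:
        name, s = col.rsplit("@", 1)
        key = (name, float(s))
    else:
        key = (col, model.scale_km.get(col, np.nan))
    if key not in smoothed.layers:
        raise ValueError(f"smoothed layer for covariate/scale {key} not available")
    return smoothed.layers[key]


@dataclass
class BoyceResult:
    predicted: np.ndarray  # P_i, share of evaluation points per bin
    expected: np.ndarray  # E_i, share of valid cells per bin
    ratio: np.ndarray  # F_i = P_i / E_i
    index: float  # Spearman rho(F_i, i)


def boyce_index(surface: SuitabilitySurface, eval_xy: np.ndarray) -> BoyceResult:
    """Presence-only Boyce index over the surface's equal-frequency bins."""
    eval_xy = np.asarray(eval_xy, dtype=float)
    if eval_xy.ndim != 2 or eval_xy.shape[1] != 2:
        raise ValueError("eval_xy must be (n, 2)")
    inside = surface.grid.contains(eval_xy[:, 0], eval_xy[:, 1])
    if not inside.any():
        raise ValueError("all evaluation points fall outside the grid")
    pts = eval_xy[inside]
    b = surface.bin_at(pts[:, 0], pts[:, 1])
    b = b[b > 0]  # drop points on nodata cells
    if b.size < 10:
        raise ValueError("need at least 10 evaluation points on valid cells")
    nb = surface.n_bins
    counts = np.bincount(b, minlength=nb + 1)[1:]
    P = counts / counts.sum()
    cell_counts = np.bincount(surface.bins.ravel(), minlength=nb + 1)[1:]
    E = cell_counts / cell_counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(E > 0, P / E, np.nan)
    ok = np.isfinite(F)
    rho = stats.spearmanr(F[ok], np.arange(1, nb + 1)[ok]).statistic
    return BoyceResult(predicted=P, expected=E, ratio=F, index=float(rho))


@dataclass
class RocResult:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float


def roc_from_scores(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """AUC and the threshold closest to the top-left corner of ROC space."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both presence and absence labels are required")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    d2 = (1.0 - tpr) ** 2 + fpr**2
    k = int(np.argmin(d2))
    return RocResult(
        auc=auc,
        threshold=float(thr[k]),
        sensitivity=float(tpr[k]),
        specificity=float(1.0 - fpr[k]),
    )


def roc_metrics(surface: SuitabilitySurface, labelled: pd.DataFrame) -> RocResult:
    """ROC of surface values at labelled presence/absence points."""
    scores = surface.value_at(labelled["x"].to_numpy(), labelled["y"].to_numpy())
    ok = np.isfinite(scores)
    return roc_from_scores(scores[ok], labelled["label"].to_numpy()[ok])


@dataclass
class DensityRegressionResult:
    slope: float
    se: float
    t: float
    p: float
    ci_low: float
    ci_high: float
    r2: float
    intercept: float
    n: int
    buffer_radius_km: float = DENSITY_BUFFER_RADIUS_KM


def density_regression(
    surface: SuitabilitySurface, records: pd.DataFrame
) -> DensityRegressionResult:
    """OLS of density estimates on mean suitability in 100 km^2 buffers."""
    if len(records) < 3:
        raise ValueError("need at least 3 density records")
    r_m = DENSITY_BUFFER_RADIUS_KM * 1000.0
    xs, ys = surface.grid.center_grids()
    means = np.empty(len(records))
    for k, row in enumerate(records.itertuples(index=False)):
        d2 = (xs - row.x) ** 2 + (ys - row.y) ** 2
        sel = (d2 <= r_m**2) & np.isfinite(surface.values)
        if not sel.any():
            raise ValueError(f"density record {k} has no valid cells in its buffer")
        means[k] = surface.values[sel].mean()
    if np.ptp(means) == 0:
        raise ValueError("zero-variance predictor: all buffers have equal mean suitability")
    X = sm.add_constant(means)
    fit = sm.OLS(records["density"].to_numpy(dtype=float), X).fit()
    ci = fit.conf_int(alpha=0.05)[1]
    return DensityRegressionResult(
        slope=float(fit.params[1]),
        se=float(fit.bse[1]),
        t=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        r2=float(fit.rsquared),
        intercept=float(fit.params[0]),
        n=len(records),
    )


def raster_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r over jointly valid cells of two co-registered rasters."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"rasters not co-registered: {a.shape} vs {b.shape}")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly valid cells")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])
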