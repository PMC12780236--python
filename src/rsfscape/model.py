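"""Mixed-effects resource-selection modelling and covariate selection.

The selection model is a used/available logistic GLMM: row ``j`` of
individual ``i`` has ``y_ij ~ Bernoulli(logit^{-1}(x_ij' beta + u_i))``
with a per-individual random intercept ``u_i ~ N(0, sigma_id^2)`` that
absorbs behavioural differences among animals. The marginal likelihood

    L(beta, sigma) = prod_i  ∫ prod_j p_ij(u)^y (1-p_ij(u))^(1-y) phi(u; 0, sigma^2) du

factorizes over individuals and each one-dimensional integral is evaluated
by adaptive Gauss–Hermite quadrature: the integrand is re-centred at its
mode (found by a vectorized Newton iteration across all individuals at
once) and scaled by its curvature before applying the Hermite rule, so a
handful of nodes suffices even for large, sharply peaked clusters.
Maximization is quasi-Newton (L-BFGS-B) over (beta, log sigma); Wald
standard errors come from the numerically differentiated observed
information of the marginal log-likelihood.

Workflow around the fit:

* ``optimize_scales`` — per covariate, a univariate GLMM at each candidate
  smoothing scale; the scale with the lowest AICc is retained.
* ``spearman_matrix`` / ``mrmr_select`` — minimum-redundancy
  maximum-relevance selection of covariates at their optimal scales, with
  Spearman rank correlation as both relevance (|rho| with the response) and
  redundancy (mean |rho| with already-selected covariates).
* ``fit_final_model`` — the multivariable GLMM on standardized covariates,
  reported as a coefficient table (covariate, scale, beta, SE, z, p).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logsumexp

from .scaling import column_key

logger = logging.getLogger(__name__)

__all__ = [
    "FittedRSF",
    "ScaleSelection",
    "MRMRResult",
    "aicc",
    "fit_rsf_glmm",
    "optimize_scales",
    "spearman_matrix",
    "mrmr_select",
    "standardize",
    "fit_final_model",
]

INTERCEPT = "(Intercept)"

#: |beta| beyond which a standardized fit is treated as separated.
SEPARATION_BETA = 15.0


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: -2l + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class FittedRSF:
    """A fitted used/available GLMM (fixed effects + random-intercept variance)."""

    covariates: list[str]
    beta: dict[str, float]
    se: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    sigma2_id: float
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    standardization: dict[str, tuple[float, float]] | None = None
    scale_km: dict[str, float] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for name in [INTERCEPT] + self.covariates:
            rows.append(
                {
                    "covariate": name,
                    "scale_km": self.scale_km.get(name, np.nan),
                    "beta": self.beta[name],
                    "se": self.se.get(name, np.nan),
                    "z": self.z.get(name, np.nan),
                    "p": self.p.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)


def _design_arrays(design: pd.DataFrame, covariates: list[str]):
    missing = [c for c in covariates if c not in design.columns]
    if missing:
        raise ValueError(f"covariates not in design: {missing}")
    y = design["case"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("case must be 0/1")
    X = np.column_stack(
        [np.ones(len(design))] + [design[c].to_numpy(dtype=float) for c in covariates]
    )
    for c in covariates:
        col = design[c].to_numpy(dtype=float)
        if np.ptp(col) == 0.0:
            raise ValueError(f"degenerate (constant) covariate column: {c!r}")
    groups, g = np.unique(design["individual_id"].to_numpy(), return_inverse=True)
    if len(groups) < 2:
        raise ValueError("mixed fit requires at least 2 individuals")
    return y, X, g, len(groups)


def _logit_start(y: np.ndarray, X: np.ndarray, iters: int = 8) -> np.ndarray:
    """Cheap Newton/IRLS plain-logistic start values."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-6) / max(1 - y.mean(), 1e-6))
    for _ in range(iters):
        eta = X @ beta
        p = expit(eta)
        W = p * (1 - p) + 1e-10
        grad = X.T @ (y - p)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        if np.abs(step).max() > 5:
            step *= 5 / np.abs(step).max()
        beta = beta + step
        if np.abs(grad).max() < 1e-6:
            break
    return beta


class _MarginalLoglik:
    """Adaptive Gauss–Hermite marginal log-likelihood, warm-started modes."""

    def __init__(self, y, X, g, n_groups, quad_points=7):
        self.y, self.X, self.g, self.G = y, X, g, n_groups
        self.nodes, self.wts = np.polynomial.hermite.hermgauss(quad_points)
        self.log_wts = np.log(self.wts)
        self.u = np.zeros(n_groups)  # warm-started conditional modes

    def _modes(self, eta, inv_s2):
        """Vectorized Newton for the per-group posterior modes of u."""
        y, g, G = self.y, self.g, self.G
        u = self.u.copy()
        for _ in range(60):
            p = expit(eta + u[g])
            grad = np.bincount(g, weights=y - p, minlength=G) - u * inv_s2
            curv = np.bincount(g, weights=p * (1 - p), minlength=G) + inv_s2
            step = grad / curv
            np.clip(step, -5.0, 5.0, out=step)
            u += step
            if np.abs(step).max() < 1e-9:
                break
        self.u = u
        p = expit(eta + u[g])
        curv = np.bincount(g, weights=p * (1 - p), minlength=G) + inv_s2
        return u, curv

    def __call__(self, theta) -> float:
        beta, log_sigma = theta[:-1], theta[-1]
        sigma2 = np.exp(2.0 * log_sigma)
        inv_s2 = 1.0 / sigma2
        y, X, g, G = self.y, self.X, self.g, self.G
        eta = X @ beta
        u_hat, curv = self._modes(eta, inv_s2)
        s_star = 1.0 / np.sqrt(curv)  # Laplace scale per group
        log_norm = -0.5 * np.log(2 * np.pi * sigma2)
        vals = np.empty((len(self.nodes), G))
        for t, (x_t, lw) in enumerate(zip(self.nodes, self.log_wts)):
            u_t = u_hat + np.sqrt(2.0) * s_star * x_t
            eta_t = eta + u_t[g]
            ll_rows = y * eta_t - np.logaddexp(0.0, eta_t)
            f = (
                np.bincount(g, weights=ll_rows, minlength=G)
                - 0.5 * u_t**2 * inv_s2
                + log_norm
            )
            vals[t] = f + x_t**2 + lw
        li = logsumexp(vals, axis=0) + np.log(np.sqrt(2.0) * s_star)
        return float(li.sum())


def fit_rsf_glmm(
    design: pd.DataFrame,
    covariates: list[str],
    *,
    quad_points: int = 7,
    compute_se: bool = True,
    start: np.ndarray | None = None,
) -> FittedRSF:
    """Fit the random-intercept logistic RSF by marginal maximum likelihood.

    Parameters
    ----------
    design
        Rows with ``case`` (1 used / 0 available), ``individual_id`` and the
        listed covariate columns.
    covariates
        Column names entering as fixed effects (intercept always included).
    quad_points
        Gauss–Hermite nodes for the adaptive quadrature (1 = Laplace).
    compute_se
        Skip the numerical-Hessian standard errors when False (cheaper;
        used by the univariate scale scan, which only needs AICc).
    """
    y, X, g, G = _design_arrays(design, covariates)
    n, p1 = X.shape
    ll_fun = _MarginalLoglik(y, X, g, G, quad_points=quad_points)

    if start is None:
        beta0 = _logit_start(y, X)
        theta0 = np.append(beta0, np.log(0.5))
    else:
        theta0 = np.asarray(start, dtype=float)
    bounds = [(None, None)] * p1 + [(np.log(1e-3), np.log(50.0))]

    res = optimize.minimize(
        lambda th: -ll_fun(th),
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-6},
    )
    theta = res.x
    loglik = -float(res.fun)
    beta_hat = theta[:-1]
    sigma2 = float(np.exp(2.0 * theta[-1]))
    converged = bool(res.success)

    sep = np.abs(beta_hat[1:]) > SEPARATION_BETA
    if sep.any():
        bad = [covariates[k] for k in np.flatnonzero(sep)]
        raise ValueError(f"possible complete separation on covariate(s): {bad}")

    names = [INTERCEPT] + list(covariates)
    se = {}
    if compute_se:
        from statsmodels.tools.numdiff import approx_hess1

        H = approx_hess1(theta, lambda th: -ll_fun(th))
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)[:p1]
            if np.any(d <= 0):
                raise np.linalg.LinAlgError("non-PD information")
            se = {nm: float(np.sqrt(v)) for nm, v in zip(names, d)}
        except np.linalg.LinAlgError:
            converged = False
            se = {nm: np.nan for nm in names}
    zstat = {nm: (beta_hat[k] / se[nm] if se else np.nan) for k, nm in enumerate(names)} if se else {}
    pval = {nm: float(2 * stats.norm.sf(abs(z))) for nm, z in zstat.items()} if se else {}

    k = len(covariates) + 2  # intercept + random-intercept variance
    return FittedRSF(
        covariates=list(covariates),
        beta={nm: float(b) for nm, b in zip(names, beta_hat)},
        se=se,
        z=zstat,
        p=pval,
        sigma2_id=sigma2,
        loglik=loglik,
        k=k,
        n=n,
        aicc=aicc(loglik, k, n),
        converged=converged,
    )


@dataclass
class ScaleSelection:
    """Per-covariate AICc profile over scales and the retained scale."""

    aicc_by_scale: dict[str, dict[float, float]]
    chosen_scale: dict[str, float]
    excluded: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cov, prof in self.aicc_by_scale.items():
            for s, a in prof.items():
                rows.append(
                    {
                        "covariate": cov,
                        "scale_km": s,
                        "aicc": a,
                        "chosen": s == self.chosen_scale.get(cov),
                    }
                )
        return pd.DataFrame(rows)


def optimize_scales(
    design: pd.DataFrame,
    covariates: list[str],
    scales,
    *,
    quad_points: int = 1,
) -> ScaleSelection:
    """Retain, per covariate, the smoothing scale with the lowest AICc.

    Each candidate model is univariate: intercept + random intercept + the
    covariate at one scale, so AICc differences reflect only the scale.
    Columns are standardized internally (AICc is invariant to linear
    rescaling and the fits are better conditioned); the quadrature defaults
    to the Laplace approximation, which preserves AICc rankings at a
    fraction of the cost of the full quadrature used for final inference.
    Ties go to the smaller scale; covariates whose fits all fail are
    excluded (logged).
    """
    scales = [float(s) for s in scales]
    profiles: dict[str, dict[float, float]] = {}
    chosen: dict[str, float] = {}
    excluded: list[str] = []
    for cov in covariates:
        prof: dict[float, float] = {}
        start = None
        for s in scales:
            col = column_key(cov, s)
            try:
                sub = design[["case", "individual_id", col]]
                std, _ = standardize(sub, [col])
                fit = fit_rsf_glmm(
                    std, [col], quad_points=quad_points, compute_se=False, start=start
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("scale fit failed for %s at %s km: %s", cov, s, exc)
                continue
            prof[s] = fit.aicc
            start = np.array(
                [fit.beta[INTERCEPT], fit.beta[col], 0.5 * np.log(max(fit.sigma2_id, 1e-6))]
            )
        if not prof:
            excluded.append(cov)
            logger.warning("covariate %s excluded: no convergent scale fit", cov)
            continue
        profiles[cov] = prof
        best = min(prof.values())
        chosen[cov] = min(s for s, a in prof.items() if a == best)
    return ScaleSelection(aicc_by_scale=profiles, chosen_scale=chosen, excluded=excluded)


def spearman_matrix(
    design: pd.DataFrame, columns: list[str], response: str = "case"
) -> pd.DataFrame:
    """Spearman rank correlations among covariates and with the response.

    Constant columns get correlation 0 (with a warning) rather than NaN.
    """
    if len(design) < 3:
        raise ValueError("need at least 3 rows for rank correlation")
    cols = [response] + [c for c in columns if c != response]
    data = design[cols].to_numpy(dtype=float)
    const = np.ptp(data, axis=0) == 0
    if const.any():
        warnings.warn(
            f"constant column(s) {list(np.array(cols)[const])}: Spearman set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        rho = stats.spearmanr(data).statistic
    if np.isscalar(rho) or np.ndim(rho) == 0:  # spearmanr collapses 2 columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=cols, columns=cols)


@dataclass
class MRMRResult:
    """Greedy mRMR selection order with per-step scores."""

    selected: list[str]
    trace: pd.DataFrame  # step, covariate, relevance, redundancy, score


def mrmr_select(
    corr: pd.DataFrame, n_keep: int = 15, response: str = "case"
) -> MRMRResult:
    """Minimum-redundancy maximum-relevance forward selection.

    Step 1 picks the covariate with the largest |rho(x, response)|; step t
    maximizes |rho(x, response)| minus the mean |rho(x, selected)|
    (difference criterion). Deterministic: ties break alphabetically.
    """
    candidates = sorted(c for c in corr.columns if c != response)
    if n_keep > len(candidates):
        raise ValueError(f"n_keep={n_keep} exceeds {len(candidates)} candidates")
    relevance = corr.loc[candidates, response].abs()
    selected: list[str] = []
    rows = []
    remaining = list(candidates)
    for step in range(n_keep):
        best_name, best_score, best_red = None, -np.inf, 0.0
        for c in remaining:  # alphabetical order => ties go to the first seen
            red = float(np.mean([abs(corr.loc[c, s]) for s in selected])) if selected else 0.0
            score = float(relevance[c]) - red
            if score > best_score + 1e-15:
                best_name, best_score, best_red = c, score, red
        selected.append(best_name)
        remaining.remove(best_name)
        rows.append(
            {
                "step": step + 1,
                "covariate": best_name,
                "relevance": float(relevance[best_name]),
                "redundancy": best_red,
                "score": best_score,
            }
        )
    return MRMRResult(selected=selected, trace=pd.DataFrame(rows))


def standardize(
    design: pd.DataFrame,
    columns: list[str],
    reference_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Center/scale columns using reference rows (training set) only."""
    out = design.copy()
    record: dict[str, tuple[float, float]] = {}
    ref = design if reference_mask is None else design.loc[reference_mask]
    for c in columns:
        mu = float(ref[c].mean())
        sd = float(ref[c].std(ddof=0))
        if sd == 0:
            raise ValueError(f"cannot standardize constant column {c!r}")
        out[c] = (design[c] - mu) / sd
        record[c] = (mu, sd)
    return out, record


def fit_final_model(
    design: pd.DataFrame,
    selection: MRMRResult | list[str],
    scales: ScaleSelection | None = None,
    *,
    quad_points: int = 7,
) -> FittedRSF:
    """Multivariable standardized GLMM on the selected covariates.

    ``selection`` gives covariate names; with a ``ScaleSelection`` the
    design columns are looked up at each covariate's retained scale,
    otherwise the names are taken as design columns directly. Covariates
    are standardized on training rows (the ``split == 'train'`` subset when
    present) and the record is stored for prediction.
    """
    names = selection.selected if isinstance(selection, MRMRResult) else list(selection)
    if scales is not None:
        cols = [column_key(nm, scales.chosen_scale[nm]) for nm in names]
        scale_of = {c: scales.chosen_scale[nm] for c, nm in zip(cols, names)}
    else:
        cols = names
        scale_of = {}
    if "split" in design.columns:
        fit_rows = design["split"] == "train"
        sub = design.loc[fit_rows].reset_index(drop=True)
    else:
        sub = design
    std, record = standardize(sub, cols)
    fit = fit_rsf_glmm(std, cols, quad_points=quad_points)
    fit.standardization = record
    fit.scale_km = scale_of
    return fit
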