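"""Case-control comparison pipelines for multi-site ROI data.

Three ways to estimate the per-ROI case-control difference across sites:

* **RE-Meta** — fit an OLS per site (diagnosis + covariates), convert the
  diagnosis coefficient to a Hedges' g per site, then pool across sites by
  a random-effects meta-analysis with between-site heterogeneity tau^2
  (REML by default, DerSimonian-Laird selectable).
* **ME-Mega** — pool the individual data and fit, per ROI, a linear
  mixed-effects model with a random site intercept (REML).
* **ComBat-Mega** — harmonize the data with ComBat first, then fit a plain
  OLS per ROI with no site term.

Every pipeline reports Hedges' g (small-sample corrected standardized mean
difference), its sampling variance, a 95% CI, and raw + Holm-adjusted
two-sided p-values over the full ROI family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .combat import combat_fit
from .data import CovariateTable, DataValidationError, DesignMatrix, ROIMatrix, build_design

PIPELINES = ("RE-Meta", "ME-Mega", "ComBat-Mega")

_ALIASES = {
    "remeta": "RE-Meta", "re-meta": "RE-Meta", "RE-Meta": "RE-Meta",
    "memega": "ME-Mega", "me-mega": "ME-Mega", "ME-Mega": "ME-Mega",
    "combatmega": "ComBat-Mega", "combat-mega": "ComBat-Mega",
    "ComBat-Mega": "ComBat-Mega",
}


def canonical_pipeline(name: str) -> str:
    try:
        return _ALIASES[name.lower()] if name.lower() in _ALIASES else _ALIASES[name]
    except KeyError:
        raise ValueError(f"unknown pipeline {name!r}; choose from {PIPELINES}") from None


# ---------------------------------------------------------------------------
# elementary fits
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with coefficient covariance; returns (beta, se, df, sd_resid)."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    s2 = resid @ resid / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(XtX_inv) * s2)
    return beta, se, df, np.sqrt(s2)


def site_linear_model(y: np.ndarray, X: DesignMatrix):
    """Per-site OLS of one ROI on [intercept, diagnosis, covariates].

    Returns ``(coef, se, df, n_case, n_control, sd_resid)`` where ``coef``
    is the diagnosis coefficient. Requires both diagnosis levels and more
    observations than design columns.
    """
    M = X.matrix
    n, p = M.shape
    if n <= p:
        raise DataValidationError(f"need more than {p} observations, got {n}")
    dx = M[:, 1]
    n_case, n_control = int((dx == 1).sum()), int((dx == 0).sum())
    if n_case == 0 or n_control == 0:
        raise DataValidationError("both diagnosis levels must be present")
    if np.linalg.matrix_rank(M) < p:
        raise DataValidationError("rank-deficient design")
    beta, se, df, sd_resid = _ols(y, M)
    return beta[1], se[1], df, n_case, n_control, sd_resid


def hedges_g(coef: float, sd_pooled: float, n1: int, n2: int, n_covariates: int = 0):
    """Hedges' g and its sampling variance from a model coefficient.

    d = coef / sd_pooled is corrected by J = 1 - 3/(4 df - 1) with
    df = n1 + n2 - 2 - n_covariates (covariate-adjusted models lose df);
    var_g = J^2 [ (n1+n2)/(n1 n2) + d^2 / (2 (n1+n2)) ].
    """
    if sd_pooled <= 0:
        raise ValueError("sd_pooled must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    df = n1 + n2 - 2 - n_covariates
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    d = coef / sd_pooled
    g = J * d
    var_g = J**2 * ((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    return g, var_g


# ---------------------------------------------------------------------------
# random-effects pooling
# ---------------------------------------------------------------------------

def tau2_dersimonian_laird(y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian-Laird moment estimator of between-site heterogeneity."""
    w = 1.0 / v
    mu_fe = (w * y).sum() / w.sum()
    Q = (w * (y - mu_fe) ** 2).sum()
    df = len(y) - 1
    denom = w.sum() - (w**2).sum() / w.sum()
    return max(0.0, (Q - df) / denom) if denom > 0 else 0.0


def tau2_reml(y: np.ndarray, v: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> float:
    """REML estimate of tau^2 by the standard fixed-point iteration."""
    tau2 = tau2_dersimonian_laird(y, v)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = (w * y).sum() / w.sum()
        num = (w**2 * ((y - mu) ** 2 - v)).sum()
        new = num / (w**2).sum() + 1.0 / w.sum()
        new = max(0.0, new)
        if abs(new - tau2) < tol * (1.0 + tau2):
            return new
        tau2 = new
    return tau2


def re_meta_pool(g: np.ndarray, var_g: np.ndarray, method: str = "reml"):
    """Random-effects pooling of per-site effect sizes.

    Weights are inverse of (within-site variance + tau^2); the pooled
    variance is 1 / sum(weights) and the p-value uses a two-sided normal
    reference, as in standard meta-analysis software.

    Returns ``(g_pooled, var_pooled, tau2, p)``.
    """
    g = np.asarray(g, dtype=float)
    var_g = np.asarray(var_g, dtype=float)
    if g.size == 0:
        raise ValueError("no site effects to pool")
    if g.size == 1:
        tau2 = 0.0
    elif method == "dl":
        tau2 = tau2_dersimonian_laird(g, var_g)
    elif method == "reml":
        tau2 = tau2_reml(g, var_g)
    else:
        raise ValueError(f"unknown tau2 method {method!r}")
    w = 1.0 / (var_g + tau2)
    pooled = (w * g).sum() / w.sum()
    var_pooled = 1.0 / w.sum()
    z = pooled / np.sqrt(var_pooled)
    p = 2.0 * stats.norm.sf(abs(z))
    return pooled, var_pooled, tau2, p


# ---------------------------------------------------------------------------
# mega-analysis fits
# ---------------------------------------------------------------------------

def mixed_effects_model(y: np.ndarray, X: DesignMatrix, site: np.ndarray):
    """Random-site-intercept model for one ROI across all subjects (REML).

    Returns ``(coef, se, p, sd_resid)`` for the diagnosis coefficient.
    The p-value uses a t reference with df = n - p - 1 (one df spent on
    the site variance component). A fit with the site variance estimated
    at the zero boundary is kept as-is, which coincides with pooled OLS.
    """
    n, p = X.matrix.shape
    if len(np.unique(site)) < 2:
        raise DataValidationError("mixed model needs >= 2 sites")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary/singular fits are expected under H0
        try:
            res = MixedLM(y, X.matrix, groups=site).fit(reml=True, method="lbfgs")
            coef, se = res.params[1], res.bse[1]
            sd_resid = float(np.sqrt(res.scale))
        except (np.linalg.LinAlgError, ValueError):
            beta, ses, df, sd_resid = _ols(y, X.matrix)
            coef, se = beta[1], ses[1]
    df = n - p - 1
    t = coef / se
    p_val = 2.0 * stats.t.sf(abs(t), df)
    return float(coef), float(se), float(p_val), sd_resid


def pooled_linear_model(y: np.ndarray, X: DesignMatrix):
    """Plain OLS across all subjects (for ComBat-harmonized data).

    Returns ``(coef, se, p, sd_resid)`` for the diagnosis coefficient,
    with a two-sided t p-value on the residual df.
    """
    beta, se, df, sd_resid = _ols(y, X.matrix)
    t = beta[1] / se[1]
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(beta[1]), float(se[1]), float(p), float(sd_resid)


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw p elementwise)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# full pipelines
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Per-ROI effect estimates from one pipeline run.

    ``table`` columns: roi, pipeline, g, var_g, ci_low, ci_high, p, p_holm,
    tau2 (NaN outside RE-Meta), n.
    """

    pipeline: str
    table: pd.DataFrame
    tau2_method: str = "reml"
    skipped_rois: list = field(default_factory=list)

    def summary(self) -> str:
        t = self.table
        n_sig = int((t["p_holm"] < 0.05).sum())
        lines = [
            f"{self.pipeline} case-control comparison",
            "=" * 40,
            f"ROIs analyzed:      {len(t)}",
            f"Holm p < 0.05:      {n_sig}",
            f"median |g|:         {t['g'].abs().median():.3f}",
            f"median 95% CI width: {(t['ci_high'] - t['ci_low']).median():.3f}",
        ]
        if self.skipped_rois:
            lines.append(f"skipped ROIs:       {len(self.skipped_rois)}")
        return "\n".join(lines)


def _result_row(roi, pipeline, g, var_g, p, tau2, n):
    half = 1.96 * np.sqrt(var_g)
    return dict(
        roi=roi, pipeline=pipeline, g=g, var_g=var_g,
        ci_low=g - half, ci_high=g + half, p=p, tau2=tau2, n=n,
    )


def _included_rois(data: ROIMatrix) -> np.ndarray:
    ok = np.zeros(data.n_rois, dtype=bool)
    for j in range(data.n_rois):
        v = data.values[data.observed[:, j], j]
        ok[j] = v.size > 1 and np.ptp(v) > 0
    return ok


def _re_meta(data: ROIMatrix, cov: CovariateTable, tau2_method: str):
    site = np.asarray(data.site)
    X_all = build_design(cov, include_diagnosis=True)
    ncov = X_all.n_covariates
    p_cols = X_all.matrix.shape[1]
    rows, skipped = [], []
    for j in np.flatnonzero(_included_rois(data)):
        gs, vs = [], []
        for s in data.site_levels:
            sel = (site == s) & data.observed[:, j]
            if sel.sum() <= p_cols:
                continue
            M = X_all.matrix[sel]
            dx = M[:, 1]
            n1, n0 = int((dx == 1).sum()), int((dx == 0).sum())
            if n1 < 2 or n0 < 2:
                continue  # per-site g variance undefined
            if np.linalg.matrix_rank(M) < p_cols:
                continue
            beta, se, dfree, sd_resid = _ols(data.values[sel, j], M)
            if sd_resid <= 0:
                continue
            g, v = hedges_g(beta[1], sd_resid, n1, n0, ncov)
            gs.append(g)
            vs.append(v)
        if not gs:
            skipped.append(data.roi_names[j])
            continue
        pooled, var_pooled, tau2, p = re_meta_pool(np.array(gs), np.array(vs), tau2_method)
        rows.append(_result_row(data.roi_names[j], "RE-Meta", pooled, var_pooled, p,
                                tau2, len(gs)))
    return rows, skipped


def _mega(data: ROIMatrix, cov: CovariateTable, pipeline: str):
    """Shared driver for ME-Mega (mixed model) and ComBat-Mega (plain OLS)."""
    site = np.asarray(data.site)
    dx_all = cov.diagnosis
    rows, skipped = [], []
    for j in np.flatnonzero(_included_rois(data)):
        sel = data.observed[:, j]
        y = data.values[sel, j]
        n1 = int((dx_all[sel] == 1).sum())
        n0 = int((dx_all[sel] == 0).sum())
        if n1 < 2 or n0 < 2:
            skipped.append(data.roi_names[j])
            continue
        sub_cov = CovariateTable(cov.table.loc[sel].reset_index(drop=True),
                                 cov.diagnosis_column)
        X = build_design(sub_cov, include_diagnosis=True)
        if len(y) <= X.matrix.shape[1]:
            skipped.append(data.roi_names[j])
            continue
        if pipeline == "ME-Mega":
            coef, se, p, sd_resid = mixed_effects_model(y, X, site[sel])
        else:
            coef, se, p, sd_resid = pooled_linear_model(y, X)
        g, var_g = hedges_g(coef, sd_resid, n1, n0, X.n_covariates)
        rows.append(_result_row(data.roi_names[j], pipeline, g, var_g, p, np.nan,
                                n1 + n0))
    return rows, skipped


def run_pipeline(
    data: ROIMatrix,
    cov: CovariateTable,
    pipeline: str,
    tau2_method: str = "reml",
    harmonized: bool = False,
) -> PipelineResult:
    """Run one full comparison pipeline and Holm-adjust over all ROIs.

    For ComBat-Mega the data are harmonized internally (single ComBat fit
    over all ROIs, diagnosis protected as a covariate) unless
    ``harmonized=True`` signals the caller already did so.
    """
    pipeline = canonical_pipeline(pipeline)
    if pipeline == "RE-Meta":
        rows, skipped = _re_meta(data, cov, tau2_method)
    elif pipeline == "ME-Mega":
        rows, skipped = _mega(data, cov, "ME-Mega")
    else:
        if not harmonized:
            model = combat_fit(data, cov)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                data = model.transform(data, cov)
        rows, skipped = _mega(data, cov, "ComBat-Mega")
    if not rows:
        raise DataValidationError("no analyzable ROI (all constant or too few subjects)")
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p"].to_numpy())
    cols = ["roi", "pipeline", "g", "var_g", "ci_low", "ci_high", "p", "p_holm",
            "tau2", "n"]
    return PipelineResult(pipeline, table[cols], tau2_method, skipped)
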