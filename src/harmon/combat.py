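"""Missing-data-tolerant ComBat harmonization with separate fit and apply.

ComBat models each ROI measurement as

    y_rij = alpha_r + X_ij . beta_r + gamma_ri + delta_ri * eps_rij

where ``gamma_ri`` is an additive and ``delta_ri`` a multiplicative
(residual-SD scaling) effect of site ``i`` on ROI ``r``. Per-site effects
are assumed to share a distribution across ROIs — additive effects a
normal prior, squared multiplicative effects an inverse-gamma prior — and
are shrunk toward those priors by parametric empirical Bayes with
method-of-moments hyperparameters and the standard fixed-point iteration.
Harmonized data put back everything except the site effects:

    y_combat = alpha_r + X_ij . beta_r + (y - alpha_r - X.beta_r - gamma*_ri) / delta*_ri

Covariate effects (including diagnosis, which is passed to the fit so the
disease signal is protected from removal) are therefore retained.

The fit tolerates missing cells by temporarily imputing them from
per-site, per-ROI linear models of the observed cells on the covariates;
imputations exist only inside the fit and are never written back. Applying
a fitted model never imputes: cells missing on input are missing on output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .data import CovariateTable, DataValidationError, ROIMatrix, build_design

__all__ = [
    "ComBat", "CombatModel", "combat_fit", "combat_apply",
    "impute_for_fit", "harmonize_groups",
]

EB_TOL = 1e-4
EB_MAX_ITER = 1000


class CombatError(RuntimeError):
    pass


def impute_for_fit(data: ROIMatrix, cov: CovariateTable) -> ROIMatrix:
    """Return a fully observed copy of ``data`` for parameter fitting.

    Each missing cell is replaced by the fitted value of an OLS of the
    observed cells of that ROI in that site on [intercept, diagnosis,
    covariates]. If the local design is rank-deficient (e.g. a single-sex
    site) the site/ROI observed mean is used instead. A site/ROI pair with
    fewer observed cells than covariates + 2 cannot support the local
    model and raises, naming the pair.

    The caller's matrix is untouched; the imputations are temporary.
    """
    if not np.any(~data.observed):
        return data.copy()
    out = data.copy()
    design = build_design(cov, include_diagnosis=True).matrix
    p = design.shape[1]
    site = np.asarray(data.site)
    for s in data.site_levels:
        rows = np.flatnonzero(site == s)
        missing_any = np.flatnonzero(~data.observed[rows].all(axis=0))
        for j in missing_any:
            obs = rows[data.observed[rows, j]]
            mis = rows[~data.observed[rows, j]]
            if len(obs) < p + 1:
                raise CombatError(
                    f"cannot impute ROI {data.roi_names[j]!r} at site {s!r}: "
                    f"only {len(obs)} observed cells (need >= {p + 1})"
                )
            Xo = design[obs]
            if np.linalg.matrix_rank(Xo) < p:
                out.values[mis, j] = data.values[obs, j].mean()
            else:
                beta, *_ = np.linalg.lstsq(Xo, data.values[obs, j], rcond=None)
                out.values[mis, j] = design[mis] @ beta
    out.observed[:] = True
    return out


@dataclass
class CombatModel:
    """Fitted harmonization parameters (the result object of :class:`ComBat`).

    Attributes
    ----------
    alpha : ndarray (n_rois,)
        Grand intercept per ROI (sample-size-weighted mean of site intercepts).
    beta : ndarray (n_covariates, n_rois)
        Covariate coefficients, rows ordered as ``covariate_names``.
    sigma2 : ndarray (n_rois,)
        Pooled residual variance used for standardization.
    gamma_star, delta_star : ndarray (n_sites, n_rois)
        EB-shrunk additive and multiplicative (residual-SD scale, > 0)
        site effects on the standardized scale; NaN for excluded ROIs.
    hyper : dict
        Per-site prior hyperparameters: ``gamma_bar``, ``tau2`` (normal
        prior on additive effects), ``a_prior``, ``b_prior``
        (inverse-gamma prior on squared multiplicative effects).
    included_rois : ndarray of bool (n_rois,)
        False for ROIs dropped because their observed values had no variance.
    """

    alpha: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray
    gamma_star: np.ndarray
    delta_star: np.ndarray
    hyper: dict
    included_rois: np.ndarray
    roi_names: list[str]
    site_levels: list[str]
    covariate_names: list[str]

    def transform(self, data: ROIMatrix, cov: CovariateTable) -> ROIMatrix:
        """Apply the fitted parameters to ``data`` (see :func:`combat_apply`)."""
        return combat_apply(self, data, cov)

    # -- serialization (JSON, row-major lists) -------------------------------
    def to_json(self) -> str:
        d = {
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "sigma2": self.sigma2.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "hyper": {k: np.asarray(v).tolist() for k, v in self.hyper.items()},
            "included_rois": self.included_rois.astype(int).tolist(),
            "roi_names": self.roi_names,
            "site_levels": self.site_levels,
            "covariate_names": self.covariate_names,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CombatModel":
        d = json.loads(text)
        return cls(
            alpha=np.array(d["alpha"]),
            beta=np.array(d["beta"]),
            sigma2=np.array(d["sigma2"]),
            gamma_star=np.array(d["gamma_star"]),
            delta_star=np.array(d["delta_star"]),
            hyper={k: np.array(v) for k, v in d["hyper"].items()},
            included_rois=np.array(d["included_rois"], dtype=bool),
            roi_names=d["roi_names"],
            site_levels=d["site_levels"],
            covariate_names=d["covariate_names"],
        )

    def summary(self) -> str:
        n_inc = int(self.included_rois.sum())
        lines = [
            "ComBat harmonization model",
            "==========================",
            f"sites:            {len(self.site_levels)}",
            f"ROIs:             {len(self.roi_names)} ({n_inc} included, "
            f"{len(self.roi_names) - n_inc} zero-variance excluded)",
            f"covariates:       {', '.join(self.covariate_names)}",
            "",
            f"{'site':<16}{'gamma_bar':>12}{'tau2':>12}{'a_prior':>12}{'b_prior':>12}",
        ]
        for i, s in enumerate(self.site_levels):
            lines.append(
                f"{s:<16}{self.hyper['gamma_bar'][i]:>12.4f}{self.hyper['tau2'][i]:>12.4f}"
                f"{self.hyper['a_prior'][i]:>12.4f}{self.hyper['b_prior'][i]:>12.4f}"
            )
        return "\n".join(lines)


class ComBat:
    """Empirical-Bayes site-effect model for a multi-site ROI matrix.

    Statsmodels-style usage::

        model = ComBat(data, cov)
        fitted = model.fit()            # -> CombatModel
        harmonized = fitted.transform(data, cov)

    Diagnosis and all covariates in ``cov`` enter the mean model so their
    effects are estimated jointly with the site effects and are preserved
    in the harmonized output.
    """

    def __init__(self, data: ROIMatrix, cov: CovariateTable):
        if len(cov) != data.n_subjects:
            raise DataValidationError("covariate table and ROI matrix differ in length")
        if len(data.site_levels) < 2:
            raise CombatError("ComBat needs at least 2 sites")
        counts = {s: int((data.site == s).sum()) for s in data.site_levels}
        small = [s for s, c in counts.items() if c < 2]
        if small:
            raise CombatError(f"sites with fewer than 2 subjects: {small}")
        self.data = data
        self.cov = cov

    def fit(self) -> CombatModel:
        data, cov = self.data, self.cov
        n, R = data.values.shape
        site = np.asarray(data.site)
        levels = data.site_levels
        S = len(levels)

        # 1) zero-variance screen on the *observed* cells only
        included = np.zeros(R, dtype=bool)
        for j in range(R):
            v = data.values[data.observed[:, j], j]
            included[j] = v.size > 1 and np.ptp(v) > 0
        if not included.any():
            raise CombatError("no ROI with positive variance")

        # 2) temporary imputation so every included ROI is fully observed
        sub = ROIMatrix(
            data.values[:, included],
            [data.roi_names[j] for j in np.flatnonzero(included)],
            data.subject_ids, site, data.observed[:, included],
        )
        full = impute_for_fit(sub, cov)
        Y = full.values  # n x R_inc

        # 3) pooled least squares: site indicators (all levels) + covariates
        onehot = np.column_stack([(site == s).astype(float) for s in levels])
        Xcov = build_design(cov, include_diagnosis=True).matrix[:, 1:]  # drop intercept
        design = np.column_stack([onehot, Xcov])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise CombatError("site indicators and covariates are confounded")
        B, *_ = np.linalg.lstsq(design, Y, rcond=None)
        n_per = onehot.sum(axis=0)
        alpha = (n_per / n) @ B[:S]           # weighted-sum-to-zero identifiability
        beta = B[S:]
        resid = Y - design @ B
        sigma2 = np.mean(resid**2, axis=0)    # pooled variance, divisor n

        # 4) standardize
        stand_mean = alpha[None, :] + Xcov @ beta
        z = (Y - stand_mean) / np.sqrt(sigma2)

        # 5) per-site location/scale estimates
        gamma_hat = np.vstack([z[site == s].mean(axis=0) for s in levels])
        delta_hat = np.vstack([z[site == s].var(axis=0, ddof=1) for s in levels])

        # 6) parametric EB shrinkage, per site across ROIs
        gamma_bar = gamma_hat.mean(axis=1)
        tau2 = gamma_hat.var(axis=1, ddof=1)
        m = delta_hat.mean(axis=1)
        s2 = delta_hat.var(axis=1, ddof=1)
        a_prior = (2 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2

        gamma_star = np.empty_like(gamma_hat)
        delta2_star = np.empty_like(delta_hat)
        for i, s in enumerate(levels):
            zi = z[site == s]
            ni = zi.shape[0]
            g_old, d_old = gamma_hat[i].copy(), delta_hat[i].copy()
            for it in range(EB_MAX_ITER):
                g_new = (tau2[i] * ni * gamma_hat[i] + d_old * gamma_bar[i]) / (
                    tau2[i] * ni + d_old
                )
                sum2 = ((zi - g_new) ** 2).sum(axis=0)
                d_new = (0.5 * sum2 + b_prior[i]) / (ni / 2 + a_prior[i] - 1)
                change = max(
                    np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                    np.max(np.abs(d_new - d_old) / d_old),
                )
                g_old, d_old = g_new, d_new
                if change < EB_TOL:
                    break
            else:
                raise CombatError(f"EB iteration did not converge for site {s!r}")
            gamma_star[i] = g_old
            delta2_star[i] = d_old

        def expand(arr, fill=np.nan):
            out = np.full(arr.shape[:-1] + (R,), fill)
            out[..., included] = arr
            return out

        return CombatModel(
            alpha=expand(alpha),
            beta=expand(beta),
            sigma2=expand(sigma2),
            gamma_star=expand(gamma_star),
            delta_star=expand(np.sqrt(delta2_star)),
            hyper={
                "gamma_bar": gamma_bar, "tau2": tau2,
                "a_prior": a_prior, "b_prior": b_prior,
            },
            included_rois=included,
            roi_names=list(data.roi_names),
            site_levels=list(levels),
            covariate_names=list(cov.covariate_names),
        )


def combat_fit(data: ROIMatrix, cov: CovariateTable) -> CombatModel:
    """Fit harmonization parameters (functional form of ``ComBat(...).fit()``)."""
    return ComBat(data, cov).fit()


def combat_apply(model: CombatModel, data: ROIMatrix, cov: CovariateTable) -> ROIMatrix:
    """Harmonize ``data`` with previously fitted parameters.

    Works cell-wise on observed cells only — missing values are not
    imputed and stay missing. ROIs excluded at fit time pass through
    unchanged (with a warning). All sites present in ``data`` must have
    been seen by the fit.
    """
    unseen = set(data.site_levels) - set(model.site_levels)
    if unseen:
        raise CombatError(
            f"sites not present at fit time: {sorted(unseen)}; "
            "refit with all sites that need harmonization"
        )
    if list(cov.covariate_names) != list(model.covariate_names):
        raise CombatError(
            f"covariate mismatch: model has {model.covariate_names}, "
            f"data has {cov.covariate_names}"
        )
    if list(data.roi_names) != list(model.roi_names):
        raise CombatError("ROI roster differs from the fitted model")
    excluded = [r for r, ok in zip(model.roi_names, model.included_rois) if not ok]
    if excluded:
        warnings.warn(
            f"{len(excluded)} zero-variance ROI(s) pass through unharmonized: "
            f"{excluded[:5]}", stacklevel=2,
        )

    Xcov = build_design(cov, include_diagnosis=True).matrix[:, 1:]
    inc = model.included_rois
    stand_mean = model.alpha[inc][None, :] + Xcov @ model.beta[:, inc]
    sd = np.sqrt(model.sigma2[inc])

    out = data.copy()
    site_index = {s: i for i, s in enumerate(model.site_levels)}
    idx = np.array([site_index[s] for s in data.site])
    y = data.values[:, inc]
    z = (y - stand_mean) / sd
    adj = (z - model.gamma_star[idx][:, inc]) / model.delta_star[idx][:, inc]
    harmonized = adj * sd + stand_mean
    obs = data.observed[:, inc]
    block = out.values[:, inc]
    block[obs] = harmonized[obs]
    out.values[:, inc] = block
    return out


def harmonize_groups(
    data: ROIMatrix, cov: CovariateTable, groups: dict[str, list[str]] | None = None
) -> ROIMatrix:
    """Fit + apply ComBat independently per ROI group and rebind columns.

    ``groups`` maps a group name (e.g. ``"thickness"``) to its ROI names
    and must partition the full ROI set. With ``groups=None`` a single
    harmonization over all ROIs is run.
    """
    if groups is None:
        return combat_fit(data, cov).transform(data, cov)
    all_rois = [r for g in groups.values() for r in g]
    if len(all_rois) != len(set(all_rois)) or set(all_rois) != set(data.roi_names):
        raise DataValidationError("groups must partition the ROI set exactly")
    out = data.copy()
    col = {r: j for j, r in enumerate(data.roi_names)}
    for name, rois in groups.items():
        jj = np.array([col[r] for r in rois])
        sub = ROIMatrix(
            data.values[:, jj], rois, data.subject_ids, data.site, data.observed[:, jj]
        )
        h = combat_fit(sub, cov).transform(sub, cov)
        out.values[:, jj] = h.values
        out.observed[:, jj] = h.observed
    return out
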