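"""Method-comparison machinery: permutation tests, power, FWER, diagnostics.

The comparisons between pipelines follow a Draper-Stoneman scheme: the
diagnosis labels are permuted *within each site* while measurements,
covariates and design stay fixed, and the identical permuted dataset is
fed to every pipeline so that differences between methods cannot be
confounded by differences in the permuted data.

Significance is compared on the logit scale, logit(p) = ln(p / (1 - p)),
which is similarly sensitive to differences among large and among small
p-values; only the ROI-median logit-p difference is kept per permutation,
which avoids any multiplicity correction in the comparison itself.

All randomness derives from a master seed through counter-based
``numpy.random.SeedSequence`` spawn keys, so nested loops are reproducible
independent of execution order, and the FWER computation reuses the same
permutation draws as the significance comparison when given the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CovariateTable, DataValidationError, ROIMatrix, build_design
from .pipelines import PIPELINES, canonical_pipeline, run_pipeline

EPS_LOGIT = 1e-15

# spawn-key namespaces for the master seed
_KEY_PERM = 1      # within-site label permutations (shared by FWER)
_KEY_SUBSET = 2    # site subsampling for power


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def logit(p):
    """ln(p / (1-p)) with p clipped to [1e-15, 1 - 1e-15]."""
    p = np.clip(np.asarray(p, dtype=float), EPS_LOGIT, 1.0 - EPS_LOGIT)
    return np.log(p / (1.0 - p))


def permute_within_site(
    cov: CovariateTable, site: np.ndarray, rng: np.random.Generator
) -> CovariateTable:
    """Shuffle diagnosis labels independently within each site.

    Per-site case counts are preserved exactly; all other covariates and
    the measurements (held elsewhere) are untouched.
    """
    site = np.asarray(site)
    dx = cov.diagnosis.copy()
    for s in dict.fromkeys(site):
        rows = np.flatnonzero(site == s)
        dx[rows] = dx[rows[rng.permutation(len(rows))]]
    return cov.replace_diagnosis(dx)


def _pvalues(data, cov, pipeline, tau2_method):
    r = run_pipeline(data, cov, pipeline, tau2_method=tau2_method)
    return r.table.set_index("roi")["p"], r.table.set_index("roi")["p_holm"]


@dataclass
class PermutationComparison:
    """Observed vs null ROI-median logit-p differences between two pipelines.

    ``prob`` is the one-sided permutation probability that pipeline A is
    as or more significant than observed relative to B, with +1 smoothing
    (its floor is 1 / (n_perm + 1), the permutation granularity).
    """

    pipeline_a: str
    pipeline_b: str
    observed_median: float
    null_medians: np.ndarray
    n_perm: int
    prob: float

    def summary(self) -> str:
        lo, hi = np.percentile(self.null_medians, [2.5, 97.5])
        return "\n".join([
            f"Significance comparison: {self.pipeline_a} vs {self.pipeline_b}",
            "=" * 50,
            f"observed median logit-p difference: {self.observed_median:.3f}",
            f"null medians (95% central range):   [{lo:.3f}, {hi:.3f}]",
            f"permutations:                       {self.n_perm}",
            f"one-sided probability (A <= B):     {self.prob:.4g}",
            "(negative difference = pipeline A more significant)",
        ])


def compare_significance(
    data: ROIMatrix,
    cov: CovariateTable,
    pipeline_a: str,
    pipeline_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    tau2_method: str = "reml",
) -> PermutationComparison:
    """Permutation comparison of statistical significance between pipelines.

    The observed statistic is the ROI-median of logit(p_A) - logit(p_B)
    under the true labels; each permutation reruns *both* pipelines on the
    same within-site label shuffle and stores only the median difference.
    """
    pipeline_a = canonical_pipeline(pipeline_a)
    pipeline_b = canonical_pipeline(pipeline_b)

    def median_diff(c: CovariateTable) -> float:
        pa, _ = _pvalues(data, c, pipeline_a, tau2_method)
        pb, _ = _pvalues(data, c, pipeline_b, tau2_method)
        common = pa.index.intersection(pb.index)
        if len(common) == 0:
            raise DataValidationError("pipelines share no analyzable ROI")
        return float(np.median(logit(pa[common]) - logit(pb[common])))

    observed = median_diff(cov)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = permute_within_site(cov, data.site, _rng(seed, _KEY_PERM, k))
        null[k] = median_diff(perm)
    prob = (1 + int((null <= observed).sum())) / (n_perm + 1)
    return PermutationComparison(pipeline_a, pipeline_b, observed, null, n_perm, prob)


@dataclass
class FwerResult:
    """Per-pipeline proportion of permutations with any Holm p < 0.05."""

    fwer: dict
    n_perm: int

    def summary(self) -> str:
        lines = ["Empirical familywise error rate", "=" * 35,
                 f"permutations: {self.n_perm}"]
        for k, v in self.fwer.items():
            lines.append(f"{k:<14} {v:.3f}")
        return "\n".join(lines)


def empirical_fwer(
    data: ROIMatrix,
    cov: CovariateTable,
    pipelines=PIPELINES,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    tau2_method: str = "reml",
) -> FwerResult:
    """Proportion of within-site permutations with >= 1 Holm-adjusted p < alpha.

    Uses the same permutation stream as :func:`compare_significance` for
    the same master seed, so the two evaluations share their null draws
    when run jointly.
    """
    pipelines = [canonical_pipeline(p) for p in pipelines]
    hits = {p: 0 for p in pipelines}
    for k in range(n_perm):
        perm = permute_within_site(cov, data.site, _rng(seed, _KEY_PERM, k))
        for p in pipelines:
            _, p_holm = _pvalues(data, perm, p, tau2_method)
            hits[p] += int((p_holm < alpha).any())
    return FwerResult({p: hits[p] / n_perm for p in pipelines}, n_perm)


@dataclass
class PowerResult:
    """Small-subset statistical power per pipeline.

    ``power`` maps pipeline -> per-ROI detection proportions over the
    replicates (indexed by ROI); ``wilcoxon_p`` holds signed-rank p-values
    for paired per-ROI power comparisons against the first pipeline.
    """

    power: dict
    roi_filter: list
    subset_size: int
    n_reps: int
    wilcoxon_p: dict = field(default_factory=dict)

    def mean_power(self) -> dict:
        return {k: float(np.mean(v)) for k, v in self.power.items()}

    def summary(self) -> str:
        lines = [
            "Small-subset power evaluation", "=" * 35,
            f"replicates: {self.n_reps}, sites per subset: {self.subset_size}",
            f"ROIs with strong full-data effects: {len(self.roi_filter)}",
        ]
        for k, v in self.mean_power().items():
            lines.append(f"power {k:<14} {100 * v:5.1f}%")
        for k, v in self.wilcoxon_p.items():
            lines.append(f"Wilcoxon {k}: p = {v:.4g}")
        return "\n".join(lines)


def subset_power(
    data: ROIMatrix,
    cov: CovariateTable,
    subset_size: int = 10,
    n_reps: int = 500,
    fwer_threshold: float = 0.001,
    detect_threshold: float = 0.05,
    seed: int = 0,
    pipelines=PIPELINES,
    tau2_method: str = "reml",
) -> PowerResult:
    """Detection power when only a random subset of sites is available.

    The ROI filter is the intersection of ROIs that are strongly
    significant (Holm p < ``fwer_threshold``) under *every* pipeline on
    the full data — these are taken to carry true effects. Each replicate
    samples ``subset_size`` sites without replacement, reruns all
    pipelines, and marks a detection when Holm p < ``detect_threshold``.
    Per-ROI powers are compared across pipelines by Wilcoxon signed-rank
    tests against the first pipeline listed.
    """
    pipelines = [canonical_pipeline(p) for p in pipelines]
    levels = data.site_levels
    if len(levels) <= subset_size:
        raise DataValidationError("subset_size must be smaller than the number of sites")

    full = {p: _pvalues(data, cov, p, tau2_method)[1] for p in pipelines}
    keep = None
    for p, holm in full.items():
        sig = set(holm.index[holm < fwer_threshold])
        keep = sig if keep is None else keep & sig
    roi_filter = sorted(keep)
    if not roi_filter:
        raise DataValidationError(
            "ROI filter is empty: no ROI passes the full-data significance "
            f"threshold {fwer_threshold} under all pipelines"
        )

    site = np.asarray(data.site)
    detect = {p: np.zeros((n_reps, len(roi_filter))) for p in pipelines}
    for rep in range(n_reps):
        rng = _rng(seed, _KEY_SUBSET, rep)
        chosen = set(rng.choice(levels, size=subset_size, replace=False))
        sel = np.isin(site, list(chosen))
        sub = ROIMatrix(
            data.values[sel], data.roi_names,
            [data.subject_ids[i] for i in np.flatnonzero(sel)],
            site[sel], data.observed[sel],
        )
        sub_cov = CovariateTable(cov.table.loc[sel].reset_index(drop=True),
                                 cov.diagnosis_column)
        for p in pipelines:
            _, holm = _pvalues(sub, sub_cov, p, tau2_method)
            holm = holm.reindex(roi_filter)
            detect[p][rep] = (holm < detect_threshold).fillna(False).to_numpy()

    power = {p: pd.Series(detect[p].mean(axis=0), index=roi_filter) for p in pipelines}
    wilcoxon = {}
    ref = pipelines[0]
    for p in pipelines[1:]:
        diff = power[ref].to_numpy() - power[p].to_numpy()
        if np.all(diff == 0):
            wilcoxon[f"{ref} vs {p}"] = float("nan")  # degenerate: all ties
        else:
            wilcoxon[f"{ref} vs {p}"] = float(
                stats.wilcoxon(power[ref], power[p], zero_method="wilcox").pvalue
            )
    return PowerResult(power, roi_filter, subset_size, n_reps, wilcoxon)


def variance_ratio(data: ROIMatrix, cov: CovariateTable) -> pd.Series:
    """Per-ROI intra-site / total residual variance ratio (in (0, 1]).

    Both variances are covariate-adjusted: the denominator is the residual
    variance of an OLS on [intercept, diagnosis, covariates] ignoring
    site; the numerator adds site indicators (pooled within-site residual
    variance). A ratio near 1 means site explains nothing; low ratios mark
    ROIs with strong site effects, where harmonization has the most to
    gain. Degenerate ROIs are skipped.
    """
    if len(data.site_levels) < 2:
        raise DataValidationError("variance ratio needs >= 2 sites")
    X = build_design(cov, include_diagnosis=True).matrix
    site = np.asarray(data.site)
    onehot = np.column_stack([(site == s).astype(float) for s in data.site_levels])
    out = {}
    for j in range(data.n_rois):
        sel = data.observed[:, j]
        y = data.values[sel, j]
        if y.size < X.shape[1] + len(data.site_levels) + 1 or np.ptp(y) == 0:
            continue
        Xt = X[sel]
        Xw = np.column_stack([onehot[sel], Xt[:, 1:]])
        r_tot = y - Xt @ np.linalg.lstsq(Xt, y, rcond=None)[0]
        r_win = y - Xw @ np.linalg.lstsq(Xw, y, rcond=None)[0]
        v_tot = r_tot @ r_tot / (y.size - Xt.shape[1])
        v_win = r_win @ r_win / (y.size - np.linalg.matrix_rank(Xw))
        if v_tot <= 0:
            continue
        out[data.roi_names[j]] = min(1.0, v_win / v_tot)
    return pd.Series(out, name="variance_ratio")
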