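"""Harmonization: imputation, fit/apply contract, EB shrinkage, oracle match."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from harmon.combat import (
    CombatError,
    CombatModel,
    combat_apply,
    combat_fit,
    harmonize_groups,
    impute_for_fit,
)
from harmon.data import CovariateTable, DataValidationError, ROIMatrix, load_dataset
from harmon.pipelines import run_pipeline
from harmon.synthetic import SyntheticConfig, generate

DATA_DIR = Path(__file__).parent / "data"


def _toy(values, site, dx=None, age=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ids = [f"s{i}" for i in range(n)]
    data = ROIMatrix(values, [f"r{j}" for j in range(values.shape[1])], ids,
                     np.asarray(site, dtype=object))
    dx = dx if dx is not None else ([0, 1] * n)[:n]
    age = age if age is not None else np.linspace(20, 60, n)
    cov = CovariateTable(pd.DataFrame({"dx": dx, "age": age}))
    return data, cov


# ---------------------------------------------------------------------------
# impute_for_fit
# ---------------------------------------------------------------------------

class TestImputeForFit:
    def test_no_missing_is_identity(self, complete_dataset):
        data, cov, _ = complete_dataset
        out = impute_for_fit(data, cov)
        np.testing.assert_array_equal(out.values, data.values)

    def test_noiseless_linear_function_recovered(self):
        """A cell missing from an exactly-linear ROI is imputed on the line."""
        rng = np.random.default_rng(1)
        n = 16
        age = rng.uniform(20, 60, n)
        dx = np.tile([0, 1], n // 2)
        y = 1.0 + 0.5 * dx + 0.1 * age           # exact linear model, no noise
        vals = np.column_stack([y, rng.normal(size=n)])
        vals[3, 0] = np.nan
        data, cov = _toy(vals, ["A"] * (n // 2) + ["B"] * (n // 2), dx, age)
        out = impute_for_fit(data, cov)
        expected = 1.0 + 0.5 * dx[3] + 0.1 * age[3]
        assert out.values[3, 0] == pytest.approx(expected, abs=1e-8)
        # observed cells untouched, caller's matrix untouched
        assert np.isnan(data.values[3, 0])
        np.testing.assert_array_equal(out.values[4:, 0], data.values[4:, 0])

    def test_all_missing_site_roi_errors_with_names(self):
        vals = np.random.default_rng(2).normal(size=(12, 2))
        vals[:6, 1] = np.nan
        data, cov = _toy(vals, ["A"] * 6 + ["B"] * 6)
        with pytest.raises(CombatError, match=r"r1.*site 'A'"):
            impute_for_fit(data, cov)

    def test_rank_deficient_local_design_falls_back_to_mean(self):
        # site A has cases only -> dx column constant -> site/ROI mean fallback
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(14, 1))
        vals[0, 0] = np.nan
        dx = [1] * 7 + [0, 1, 0, 1, 0, 1, 0]
        data, cov = _toy(vals, ["A"] * 7 + ["B"] * 7, dx)
        out = impute_for_fit(data, cov)
        assert out.values[0, 0] == pytest.approx(np.nanmean(vals[1:7, 0]))


# ---------------------------------------------------------------------------
# combat_fit / combat_apply
# ---------------------------------------------------------------------------

class TestFitApply:
    def test_requires_two_sites_and_two_subjects(self):
        data, cov = _toy(np.random.default_rng(0).normal(size=(8, 2)), ["A"] * 8)
        with pytest.raises(CombatError, match="2 sites"):
            combat_fit(data, cov)
        data, cov = _toy(np.random.default_rng(0).normal(size=(7, 2)),
                         ["A"] * 6 + ["B"])
        with pytest.raises(CombatError, match="fewer than 2"):
            combat_fit(data, cov)

    def test_constant_roi_excluded_not_fatal(self, complete_dataset):
        data, cov, _ = complete_dataset
        vals = np.column_stack([data.values, np.full(data.n_subjects, 7.0)])
        data2 = ROIMatrix(vals, data.roi_names + ["flat"], data.subject_ids, data.site)
        model = combat_fit(data2, cov)
        assert not model.included_rois[-1]
        assert model.included_rois[:-1].all()
        with pytest.warns(UserWarning, match="zero-variance"):
            h = model.transform(data2, cov)
        np.testing.assert_array_equal(h.values[:, -1], 7.0)  # passed through
        assert np.isfinite(model.delta_star[:, :-1]).all()
        assert (model.delta_star[:, :-1] > 0).all()

    def test_missing_cells_stay_missing_after_apply(self, small_dataset):
        data, cov, _ = small_dataset
        h = combat_fit(data, cov).transform(data, cov)
        np.testing.assert_array_equal(h.observed, data.observed)
        assert np.isnan(h.values[~h.observed]).all()
        # observed cells were actually adjusted
        assert not np.allclose(h.values[h.observed], data.values[data.observed])

    def test_complete_path_bit_identical_to_masked_path(self, complete_dataset):
        """With nothing missing, the tolerant path equals the plain path bit-for-bit."""
        data, cov, _ = complete_dataset
        h1 = combat_fit(data, cov).transform(data, cov)
        # same data but with an explicitly all-True mask object
        data2 = ROIMatrix(data.values.copy(), data.roi_names, data.subject_ids,
                          data.site, np.ones_like(data.observed))
        h2 = combat_fit(data2, cov).transform(data2, cov)
        np.testing.assert_array_equal(h1.values, h2.values)

    def test_unseen_site_rejected(self, complete_dataset):
        data, cov, _ = complete_dataset
        model = combat_fit(data, cov)
        data2 = data.copy()
        data2.site[:10] = "new_site"
        with pytest.raises(CombatError, match="new_site"):
            model.transform(data2, cov)

    def test_covariate_mismatch_rejected(self, complete_dataset):
        data, cov, _ = complete_dataset
        model = combat_fit(data, cov)
        cov2 = CovariateTable(cov.table.rename(columns={"age": "years"}))
        with pytest.raises(CombatError, match="covariate mismatch"):
            model.transform(data, cov2)

    def test_null_site_effects_leave_data_nearly_unchanged(self, no_site_effect_dataset):
        """gamma = 0, delta = 1: harmonization is a near-identity at large n."""
        data, cov, _ = no_site_effect_dataset
        h = combat_fit(data, cov).transform(data, cov)
        sd = np.nanstd(data.values, axis=0)
        rms = np.sqrt(np.nanmean((h.values - data.values) ** 2, axis=0))
        # estimated site effects are O(1/sqrt(n)) noise, EB-shrunk further
        assert (rms / sd < 0.1).all()

    def test_serialization_roundtrip(self, small_dataset, tmp_path):
        data, cov, _ = small_dataset
        model = combat_fit(data, cov)
        model2 = CombatModel.from_json(model.to_json())
        h1 = model.transform(data, cov)
        h2 = model2.transform(data, cov)
        np.testing.assert_array_equal(h1.values[h1.observed], h2.values[h2.observed])
        assert "sites:" in model.summary()


# ---------------------------------------------------------------------------
# statistical properties on planted site effects
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def planted():
    cfg = SyntheticConfig(
        n_sites=6, site_sizes=80, roi_counts=(10, 0, 0), effect_g=0.2,
        gamma_spread=0.8, gamma_tau=0.5, delta_shape=4, delta_scale=3, seed=77,
    )
    data, cov, truth = generate(cfg)
    h = combat_fit(data, cov).transform(data, cov)
    return data, cov, truth, h


class TestHarmonizationProperties:

    @staticmethod
    def _site_resid_stats(data, cov):
        from harmon.data import build_design
        X = build_design(cov).matrix
        means, varis = [], []
        for j in range(data.n_rois):
            y = data.values[:, j]
            r = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            m = [r[data.site == s].mean() for s in data.site_levels]
            v = [r[data.site == s].var(ddof=1) for s in data.site_levels]
            means.append(m)
            varis.append(v)
        return np.array(means), np.array(varis)

    def test_site_residual_means_shrink(self, planted):
        data, cov, _, h = planted
        m_raw, _ = self._site_resid_stats(data, cov)
        m_har, _ = self._site_resid_stats(h, cov)
        # mean |per-site residual mean| strictly reduced for every ROI
        assert (np.abs(m_har).mean(axis=1) < np.abs(m_raw).mean(axis=1)).all()

    def test_site_variance_ratio_shrinks(self, planted):
        data, cov, _, h = planted
        _, v_raw = self._site_resid_stats(data, cov)
        _, v_har = self._site_resid_stats(h, cov)
        ratio_raw = v_raw.max(axis=1) / v_raw.min(axis=1)
        ratio_har = v_har.max(axis=1) / v_har.min(axis=1)
        assert (ratio_har < ratio_raw).all()

    def test_diagnosis_effect_unbiased_after_harmonization(self):
        """Replicated fit+apply keeps the planted case-control effect unbiased."""
        from harmon.data import build_design
        biases = []
        for rep in range(200):
            cfg = SyntheticConfig(
                n_sites=4, site_sizes=30, roi_counts=(3, 0, 0), effect_g=0.4,
                gamma_spread=0.6, gamma_tau=0.4, delta_shape=6, delta_scale=5,
                seed=1000 + rep,
            )
            data, cov, truth = generate(cfg)
            h = combat_fit(data, cov).transform(data, cov)
            X = build_design(cov).matrix
            for j in range(3):
                beta = np.linalg.lstsq(X, h.values[:, j], rcond=None)[0]
                biases.append(beta[1] - truth.beta[0, j])
        biases = np.asarray(biases)
        se = biases.std(ddof=1) / np.sqrt(len(biases))
        assert abs(biases.mean()) < 2 * se + 1e-12


# ---------------------------------------------------------------------------
# grouped harmonization
# ---------------------------------------------------------------------------

class TestHarmonizeGroups:
    def test_single_group_equals_plain(self, complete_dataset):
        data, cov, _ = complete_dataset
        h_plain = combat_fit(data, cov).transform(data, cov)
        h_grp = harmonize_groups(data, cov, {"all": list(data.roi_names)})
        np.testing.assert_array_equal(h_plain.values, h_grp.values)

    def test_groups_match_separate_runs(self, complete_dataset):
        data, cov, _ = complete_dataset
        split = {"first": data.roi_names[:3], "second": data.roi_names[3:]}
        h = harmonize_groups(data, cov, split)
        for rois in split.values():
            jj = [data.roi_names.index(r) for r in rois]
            sub = ROIMatrix(data.values[:, jj], rois, data.subject_ids, data.site)
            h_sub = combat_fit(sub, cov).transform(sub, cov)
            np.testing.assert_array_equal(h.values[:, jj], h_sub.values)

    def test_bad_partition_rejected(self, complete_dataset):
        data, cov, _ = complete_dataset
        with pytest.raises(DataValidationError, match="partition"):
            harmonize_groups(data, cov, {"some": data.roi_names[:3]})
        overlap = {"a": data.roi_names[:4], "b": data.roi_names[3:]}
        with pytest.raises(DataValidationError, match="partition"):
            harmonize_groups(data, cov, overlap)

    def test_per_type_harmonization_matches_single_g(self):
        """Separate thickness/area/volume harmonization: g within +/-0.02 of single."""
        cfg = SyntheticConfig(
            n_sites=8, site_sizes=80, roi_counts=(8, 8, 4), effect_g=(-0.4, 0.3),
            gamma_spread=0.5, gamma_tau=0.3, delta_shape=6, delta_scale=5, seed=88,
        )
        data, cov, _ = generate(cfg)
        g_single = run_pipeline(data, cov, "ComBat-Mega").table.set_index("roi")["g"]
        groups = {
            "thickness": [r for r in data.roi_names if r.startswith("thick")],
            "area": [r for r in data.roi_names if r.startswith("area")],
            "volume": [r for r in data.roi_names if r.startswith("vol")],
        }
        h = harmonize_groups(data, cov, groups)
        g_split = run_pipeline(h, cov, "ComBat-Mega", harmonized=True) \
            .table.set_index("roi")["g"]
        assert (g_single - g_split.loc[g_single.index]).abs().max() < 0.02


# ---------------------------------------------------------------------------
# oracle agreement with an independent reference implementation
# ---------------------------------------------------------------------------

def test_matches_reference_eb_combat():
    """Complete 3-site data: agree with sva::ComBat output to <= 1e-6 relative.

    The reference file was produced by the Bioconductor sva package
    (parametric priors, covariates protected); see tests/data/make_reference.R.
    """
    data, cov = load_dataset(DATA_DIR / "oracle_measurements.csv",
                             DATA_DIR / "oracle_covariates.csv")
    h = combat_fit(data, cov).transform(data, cov)
    ref = pd.read_csv(DATA_DIR / "oracle_reference_sva.csv", index_col=0)
    assert list(ref.columns) == data.roi_names
    rel = np.abs(h.values - ref.to_numpy()) / np.maximum(np.abs(ref.to_numpy()), 1e-12)
    assert rel.max() <= 1e-6
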