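"""GLM fitting, contrasts, conjunctions, tSNR, preference maps, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fullfield import analysis as az
from fullfield import design as dz
from fullfield import synthetic as sy
from fullfield.analysis import (
    BOLDSeries,
    ROIMask,
    build_design_matrix,
    canonical_hrf,
    compute_tsnr,
    conjunction_mask,
    contrast_tmap,
    fit_glm,
    preference_map,
    roi_anova,
    subtract_overlap,
)

EXP2_SORTED = tuple(sorted(dz.EXP2_CONDITIONS))
AMP = np.array([1.0, 0.5, 2.0, 0.2, 1.5, 0.8, 0.3])


@pytest.fixture(scope="module")
def exp2_run():
    des, events = dz.build_run("exp2", np.random.default_rng(2))
    ntr = dz.compute_run_timing(des)["TRs"]
    return des, events, ntr


@pytest.fixture(scope="module")
def exp2_design_matrix(exp2_run):
    _, events, ntr = exp2_run
    return build_design_matrix(events, 2.0, ntr)


class TestHRF:
    def test_zero_at_onset_and_late_tail(self):
        assert canonical_hrf(0.0) == 0.0
        assert abs(canonical_hrf(31.0)) < 1e-3

    def test_peak_near_five_seconds(self):
        t = np.linspace(0, 30, 6001)
        h = canonical_hrf(t)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.2)

    def test_undershoot_present(self):
        t = np.linspace(8, 25, 500)
        assert canonical_hrf(t).min() < -0.01


class TestDesignMatrix:
    def test_single_block_support_is_local(self):
        ev = pd.DataFrame({
            "onset": [60.0], "duration": [12.0], "trial_type": ["a"],
            "stim_file": [""], "is_target": [False],
        })
        dm = build_design_matrix(ev, 2.0, 100)
        col = dm.X[:, 0]
        t = np.arange(100) * 2.0
        inside = (t >= 30.0) & (t <= 102.0)
        assert np.sum(np.abs(col[inside])) / np.sum(np.abs(col)) > 0.99

    def test_nonoverlapping_blocks_weakly_correlated(self, exp2_design_matrix):
        nc = exp2_design_matrix.n_conditions
        corr = np.corrcoef(exp2_design_matrix.X[:, :nc].T)
        off = corr[np.triu_indices(nc, 1)]
        assert np.abs(off).max() < 0.3

    def test_full_rank_with_nuisance(self, exp2_run):
        _, events, ntr = exp2_run
        rng = np.random.default_rng(0)
        motion = rng.normal(0, 0.1, (ntr, 6))
        dm = build_design_matrix(events, 2.0, ntr, motion)
        assert dm.X.shape[1] == 7 + 6 + 1
        assert np.linalg.matrix_rank(dm.X) == dm.X.shape[1]

    def test_retinotopy_design_full_rank(self):
        des, events = dz.build_run("retinotopy", np.random.default_rng(5))
        ntr = dz.compute_run_timing(des)["TRs"]
        motion = np.random.default_rng(1).normal(0, 0.1, (ntr, 6))
        dm = build_design_matrix(events, 2.0, ntr, motion)
        assert ntr == 174
        assert np.linalg.matrix_rank(dm.X) == dm.X.shape[1] == 14

    def test_zero_motion_columns_dropped_with_warning(self, exp2_run):
        _, events, ntr = exp2_run
        motion = np.zeros((ntr, 6))
        with pytest.warns(UserWarning):
            dm = build_design_matrix(events, 2.0, ntr, motion)
        assert not any(lab.startswith("motion") for lab in dm.labels)

    def test_collinear_conditions_rejected(self):
        ev = pd.DataFrame({
            "onset": [20.0, 20.0], "duration": [12.0, 12.0],
            "trial_type": ["a", "b"], "stim_file": ["", ""],
            "is_target": [False, False],
        })
        with pytest.raises(np.linalg.LinAlgError):
            build_design_matrix(ev, 2.0, 60)


class TestGLM:
    def test_noiseless_exact_recovery(self, exp2_run, exp2_design_matrix):
        _, events, ntr = exp2_run
        spec = sy.SimSpec(np.tile(AMP, (5, 1)), EXP2_SORTED,
                          sigma=0.0, phi=0.0, drift_scale=0.0)
        bold, _ = sy.synth_bold(spec, events, n_scans=ntr)
        bm = fit_glm(bold, exp2_design_matrix)
        assert np.abs(bm.betas - AMP).max() < 1e-8

    def test_ar1_noise_small_bias(self, exp2_run, exp2_design_matrix):
        """Mean beta error stays below 2% of the planted amplitude."""
        _, events, ntr = exp2_run
        amp = np.full((500, 7), 1.5)
        spec = sy.SimSpec(amp, EXP2_SORTED, sigma=0.5, phi=0.4,
                          drift_scale=0.0, seed=7)
        bold, _ = sy.synth_bold(spec, events, n_scans=ntr)
        bm = fit_glm(bold, exp2_design_matrix)
        bias = np.abs(bm.betas.mean(axis=0) - 1.5)
        assert bias.max() < 0.02 * 1.5

    def test_ar1_coefficient_estimated(self, exp2_run, exp2_design_matrix):
        _, events, ntr = exp2_run
        spec = sy.SimSpec(np.zeros((300, 7)), EXP2_SORTED, sigma=1.0,
                          phi=0.4, drift_scale=0.0, seed=3)
        bold, _ = sy.synth_bold(spec, events, n_scans=ntr)
        bm = fit_glm(bold, exp2_design_matrix)
        assert np.nanmean(bm.ar1) == pytest.approx(0.4, abs=0.07)

    def test_time_permuted_input_gives_null_t(self, exp2_run, exp2_design_matrix):
        _, events, ntr = exp2_run
        spec = sy.SimSpec(np.tile(AMP, (200, 1)), EXP2_SORTED, sigma=1.0,
                          phi=0.3, drift_scale=0.0, seed=5)
        bold, _ = sy.synth_bold(spec, events, n_scans=ntr)
        perm = np.random.default_rng(9).permutation(ntr)
        bold_perm = BOLDSeries(bold.data[:, perm], tr_s=2.0)
        bm = fit_glm(bold_perm, exp2_design_matrix)
        c = np.zeros(7)
        c[0], c[1] = 1, -1
        t = contrast_tmap(bm, c)
        assert np.median(np.abs(t)) < 1.0

    def test_zero_mean_voxels_masked_with_warning(self, exp2_design_matrix):
        ntr = exp2_design_matrix.X.shape[0]
        data = np.vstack([np.zeros(ntr), 100 + np.random.default_rng(0).normal(size=ntr)])
        with pytest.warns(UserWarning):
            bm = fit_glm(BOLDSeries(data), exp2_design_matrix)
        assert not bm.mask[0] and bm.mask[1]
        assert np.isnan(bm.betas[0]).all()


@pytest.fixture(scope="module")
def fitted(exp2_run, exp2_design_matrix):
    _, events, ntr = exp2_run
    amp = np.zeros((2000, 7))
    amp[:1000, 2] = 1.0  # planted effect in half the voxels
    spec = sy.SimSpec(amp, EXP2_SORTED, sigma=1.0, phi=0.3,
                      drift_scale=0.0, seed=11)
    bold, _ = sy.synth_bold(spec, events, n_scans=ntr)
    return fit_glm(bold, exp2_design_matrix)


@pytest.fixture(scope="module")
def fitted_margins(exp2_run, exp2_design_matrix):
    _, events, ntr = exp2_run
    rng = np.random.default_rng(13)
    amp = rng.normal(0.5, 0.5, (800, 7))
    amp[:200, 0] += 3.0  # clear winners on condition 0
    amp[200:260, 0] = amp[200:260, 1:4].max(axis=1) + 0.1  # beats some only
    spec = sy.SimSpec(amp, EXP2_SORTED, sigma=0.8, phi=0.2,
                      drift_scale=0.0, seed=17)
    bold, _ = sy.synth_bold(spec, events, n_scans=ntr)
    return fit_glm(bold, exp2_design_matrix), amp


class TestContrast:
    def test_negated_contrast_negates_map(self, fitted):
        c = np.zeros(7)
        c[2], c[3] = 1, -1
        assert np.allclose(contrast_tmap(fitted, c),
                           -contrast_tmap(fitted, -c), equal_nan=True)

    def test_null_voxel_type_one_rate(self, fitted):
        c = np.zeros(7)
        c[4], c[5] = 1, -1  # no planted difference anywhere
        t = contrast_tmap(fitted, c)
        thr = stats.t.isf(0.01, fitted.dof)
        rate = np.mean(t > thr)
        assert 0.005 <= rate <= 0.02

    def test_planted_effect_detected(self, fitted):
        c = np.zeros(7)
        c[2] = 1
        c[[0, 1, 3, 4, 5, 6]] = -1 / 6
        t = contrast_tmap(fitted, c)
        thr = stats.t.isf(0.0001, fitted.dof)
        assert np.mean(t[:1000] > thr) > 0.9
        assert np.mean(t[1000:] > thr) < 0.01

    def test_zero_contrast_rejected(self, fitted):
        with pytest.raises(ValueError):
            contrast_tmap(fitted, np.zeros(7))


class TestConjunction:
    def test_equals_bruteforce_intersection(self, fitted_margins):
        bm, _ = fitted_margins
        roi = conjunction_mask(bm, 0, alpha=0.01)
        thr = stats.t.isf(0.01, bm.dof)
        brute = np.ones(bm.betas.shape[0], dtype=bool)
        for o in range(1, 7):
            c = np.zeros(7)
            c[0], c[o] = 1, -1
            brute &= contrast_tmap(bm, c) > thr
        assert np.array_equal(roi.mask, brute)

    def test_subset_of_each_pairwise_mask(self, fitted_margins):
        bm, _ = fitted_margins
        roi = conjunction_mask(bm, 0, alpha=0.01)
        thr = stats.t.isf(0.01, bm.dof)
        for o in range(1, 7):
            c = np.zeros(7)
            c[0], c[o] = 1, -1
            pair = contrast_tmap(bm, c) > thr
            assert np.all(pair[roi.mask])

    def test_clear_margin_included_partial_margin_excluded(self, fitted_margins):
        bm, _ = fitted_margins
        roi = conjunction_mask(bm, 0, alpha=0.001)
        assert roi.mask[:200].mean() > 0.95
        # voxels beating only 3 of 6 competitors must not survive
        assert roi.mask[200:260].mean() < 0.2


class TestPreferenceMap:
    def test_direct_example(self):
        pm = preference_map(np.array([[1.0, 2.0, 5.0, 3.0, 1.0]]))
        assert pm.index[0] == 2  # third condition (0-based)
        assert pm.strength[0] == 2.0

    def test_permutation_equivariance(self, rng):
        m = rng.normal(size=(50, 5))
        perm = rng.permutation(5)
        pm1 = preference_map(m)
        pm2 = preference_map(m[:, perm])
        assert np.array_equal(perm[pm2.index], pm1.index)
        assert np.allclose(pm1.strength, pm2.strength)

    def test_tie_takes_lowest_index_with_zero_strength(self):
        pm = preference_map(np.array([[2.0, 2.0, 1.0]]))
        assert pm.index[0] == 0
        assert pm.strength[0] == 0.0

    def test_planted_preferences_recovered(self, rng):
        n = 1000
        pref = rng.integers(0, 5, n)
        m = rng.normal(0, 0.1, (n, 5))
        m[np.arange(n), pref] += 1.0  # margin 10 sigma
        pm = preference_map(m)
        assert np.mean(pm.index == pref) > 0.99


class TestTSNR:
    def test_known_mean_and_sd(self):
        rng = np.random.default_rng(0)
        data = rng.normal(100.0, 10.0, (200, 2000))
        tsnr = compute_tsnr(BOLDSeries(data))
        assert np.mean(tsnr) == pytest.approx(10.0, rel=0.02)

    def test_scale_invariance(self, rng):
        data = 100 + rng.normal(0, 5, (20, 100))
        a = compute_tsnr(BOLDSeries(data))
        b = compute_tsnr(BOLDSeries(3.7 * data))
        assert np.allclose(a, b)

    def test_constant_series_warns_infinite(self):
        data = np.vstack([np.full(50, 10.0), 10 + np.arange(50.0) % 3])
        with pytest.warns(UserWarning):
            tsnr = compute_tsnr(BOLDSeries(data))
        assert np.isinf(tsnr[0])

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            compute_tsnr(BOLDSeries(np.ones((5, 1))))


class TestROIOps:
    def test_disjoint_unchanged(self):
        a = ROIMask(np.array([1, 1, 0, 0], bool))
        b = ROIMask(np.array([0, 0, 1, 0], bool))
        out, frac = subtract_overlap(a, b)
        assert np.array_equal(out.mask, a.mask) and frac == 0.0

    def test_identical_empties(self):
        a = ROIMask(np.array([1, 0, 1], bool))
        out, frac = subtract_overlap(a, a)
        assert out.n_voxels == 0 and frac == 1.0

    def test_random_masks_match_bruteforce_fraction(self, rng):
        a = ROIMask(rng.random(500) < 0.3)
        b = ROIMask(rng.random(500) < 0.4)
        out, frac = subtract_overlap(a, b)
        assert frac == (a.mask & b.mask).sum() / a.mask.sum()
        assert np.array_equal(out.mask, a.mask & ~b.mask)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_overlap(ROIMask(np.ones(3, bool)), ROIMask(np.ones(4, bool)))


class TestROIAnova:
    @staticmethod
    def _table(rng, size_eff=0.0, content_eff=0.0, inter_eff=0.0, n_sub=10,
               noise=0.5):
        rows = []
        for s in range(n_sub):
            for size in (-0.5, 0.5):
                for content in (-0.5, 0.5):
                    beta = (size * size_eff + content * content_eff
                            + size * content * inter_eff
                            + rng.normal(0, noise))
                    rows.append({"subject": s, "size": size,
                                 "content": content, "beta": beta})
        return pd.DataFrame(rows)

    def test_planted_main_effect_eta_squared(self, rng):
        tab = self._table(rng, size_eff=4.0, noise=0.3)
        out = roi_anova(tab)
        y = tab["beta"].values
        size = tab["size"].values
        # analytic SS ratio cross-check via direct computation
        ss_size = sum(
            (size == v).sum() * (y[size == v].mean() - y.mean()) ** 2
            for v in (-0.5, 0.5)
        )
        ss_total = ((y - y.mean()) ** 2).sum()
        assert out.loc["size", "eta_sq"] == pytest.approx(ss_size / ss_total,
                                                          abs=0.01)
        assert out.loc["size", "df"] == 1
        assert out.loc["residual", "df"] == 36

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(0)
        ps = [roi_anova(self._table(rng))["PR(>F)"]["size"] for _ in range(300)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_unbalanced_rejected(self, rng):
        tab = self._table(rng).iloc[:-1]
        with pytest.raises(ValueError):
            roi_anova(tab)

    def test_zero_variance_flagged(self):
        tab = self._table(np.random.default_rng(0), noise=0.0)
        with pytest.raises(ValueError):
            roi_anova(tab)


class TestNiftiIO:
    def test_bold_and_map_roundtrip(self, tmp_path, rng):
        import nibabel as nib

        vol = rng.normal(100, 5, (4, 5, 3, 40))
        path = tmp_path / "bold.nii.gz"
        nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
        series, shape = az.load_bold_nifti(path, tr_s=2.0)
        assert shape == (4, 5, 3) and series.n_scans == 40
        tsnr = compute_tsnr(series)
        out = tmp_path / "tsnr.nii.gz"
        az.save_map_nifti(tsnr, shape, out)
        back = np.asarray(nib.load(str(out)).dataobj)
        assert back.shape == (4, 5, 3)
        assert np.allclose(back.ravel(), tsnr)
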