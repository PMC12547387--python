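"""Smoothing, GLM fitting, contrasts and run pooling."""

import numpy as np
import pytest
from scipy import stats

from mionmap import firstlevel, hemodynamics, phantom_sim
from mionmap.firstlevel import (
    ContrastMap,
    combine_runs,
    compute_contrast,
    fit_run_glm,
    percent_signal_change,
    smooth_volumes,
)


class TestSmoothVolumes:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((8, 8, 8, 3))
        assert np.array_equal(smooth_volumes(data, 0.0, 1.5), data)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_volumes(np.zeros((8, 8, 8, 1)), -1.0, 1.5)

    def test_delta_image_kernel_fwhm(self):
        """The smoothed delta's measured FWHM is 2 voxels at 3 mm / 1.5 mm."""
        data = np.zeros((21, 21, 21, 1))
        data[10, 10, 10, 0] = 1.0
        sm = smooth_volumes(data, 3.0, 1.5)[..., 0]
        profile = sm[:, 10, 10]
        half = profile.max() / 2.0
        above = np.where(profile >= half)[0]
        # linear interpolation of the half crossings
        lo = above[0] - (profile[above[0]] - half) / (profile[above[0]] - profile[above[0] - 1])
        hi = above[-1] + (profile[above[-1]] - half) / (profile[above[-1]] - profile[above[-1] + 1])
        assert (hi - lo) == pytest.approx(2.0, rel=0.05)

    def test_constant_image_preserved(self):
        data = np.full((10, 10, 10, 2), 7.0)
        assert np.allclose(smooth_volumes(data, 3.0, 1.5), 7.0, atol=1e-6)

    def test_matches_nilearn_oracle(self):
        nilearn_image = pytest.importorskip("nilearn.image")
        import nibabel as nib

        rng = np.random.default_rng(1)
        data = rng.standard_normal((12, 12, 12, 2))
        ours = smooth_volumes(data, 3.0, 1.5)
        img = nib.Nifti1Image(data, np.diag([1.5, 1.5, 1.5, 1.0]))
        theirs = np.asarray(
            nilearn_image.smooth_img(img, fwhm=3.0).dataobj, dtype=float
        )
        # interior agreement (boundary conventions may differ)
        sl = (slice(3, 9),) * 3
        assert np.allclose(ours[sl], theirs[sl], atol=1e-6)


class TestPercentSignalChange:
    def test_global_reference_uniform_baseline(self):
        data = np.full((4, 4, 4, 10), 200.0)
        data[1, 1, 1, :] += 2.0
        mask = np.ones((4, 4, 4), bool)
        pct = percent_signal_change(data, mask)
        assert pct[1, 1, 1, 0] == pytest.approx(100 * 202 / data.mean() - 100)

    def test_voxel_reference_centers_each_voxel(self):
        rng = np.random.default_rng(0)
        data = 100 + rng.random((4, 4, 4, 20))
        pct = percent_signal_change(data, reference="voxel")
        assert np.allclose(pct.mean(axis=-1), 0.0, atol=1e-10)

    def test_background_stays_zero(self):
        data = np.zeros((4, 4, 4, 5))
        data[2, 2, 2] = 100.0
        pct = percent_signal_change(data)
        assert np.all(pct[0, 0, 0] == 0)


def _design_from_run(design, rf, catalog, drift_order=3, conditions=None):
    conditions = conditions or list(phantom_sim.MAIN_CATEGORIES)
    label_map = catalog.main_of if conditions == list(phantom_sim.MAIN_CATEGORIES) else None
    task, names, ts = hemodynamics.build_task_regressors(
        design, rf, conditions, label_map=label_map
    )
    return hemodynamics.assemble_design_matrix(task, names, ts, drift_order), names


class TestFitRunGlm:
    def test_ar0_matches_normal_equations_oracle(self, design, rf, catalog):
        """Direct (X'X)^-1 X'y linear-algebra oracle, 50 voxels x 336 vols."""
        X_dm, names = _design_from_run(design, rf, catalog)
        X = X_dm.matrix
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((50, X.shape[0]))
        fit = fit_run_glm(Y, X_dm, ar_order=0)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ Y.T)
        assert np.allclose(fit.beta, beta_oracle, atol=1e-8)
        resid = Y.T - X @ beta_oracle
        s2 = np.sum(resid**2, axis=0) / (X.shape[0] - X.shape[1])
        assert np.allclose(fit.sigma2, s2, atol=1e-8)
        w = np.array([1.0, 0.0])
        cmap = compute_contrast(fit, w)
        wf = np.zeros(X.shape[1]); wf[0] = 1.0
        sd_oracle = np.sqrt(s2 * (wf @ np.linalg.inv(X.T @ X) @ wf))
        assert np.allclose(cmap.t.ravel(), (beta_oracle[0] / sd_oracle), atol=1e-8)

    def test_noise_free_recovery_exact(self, atlas, design, rf, catalog, noise_free_truth):
        img, _ = phantom_sim.simulate_run(atlas, design, noise_free_truth, rf, 0)
        X_dm, names = _design_from_run(design, rf, catalog, conditions=catalog.subcategories)
        fit = fit_run_glm(img.data, X_dm, ar_order=0)
        a1 = atlas.region_mask("A1-like").reshape(-1)
        baseline = noise_free_truth.baseline
        for j, sub in enumerate(names):
            expected = baseline * noise_free_truth.amplitude("A1-like", sub) / 100.0
            assert np.allclose(fit.beta[j, a1], expected, atol=1e-8)

    def test_ar1_coefficient_recovery(self, design, rf, catalog):
        X_dm, _ = _design_from_run(design, rf, catalog)
        rng = np.random.default_rng(3)
        n_t = X_dm.n_volumes
        eps = rng.standard_normal((400, n_t + 50))
        from scipy.signal import lfilter

        y = lfilter([1.0], [1.0, -0.4], eps, axis=-1)[:, 50:]
        fit = fit_run_glm(y, X_dm, ar_order=1)
        assert np.mean(fit.rho) == pytest.approx(0.4, abs=0.05)

    def test_shape_and_rank_errors(self, design, rf, catalog):
        X_dm, _ = _design_from_run(design, rf, catalog)
        with pytest.raises(ValueError, match="volumes"):
            fit_run_glm(np.zeros((5, 10)), X_dm)

    def test_null_t_distribution_calibrated(self, design, rf, catalog):
        """Pooled voxelwise t on pure-noise runs: the empirical 95th
        percentile matches the theoretical t quantile."""
        X_dm, names = _design_from_run(design, rf, catalog)
        rng = np.random.default_rng(7)
        from scipy.signal import lfilter

        ts = []
        w = firstlevel.sound_vs_silence_weights(names)
        for _ in range(60):
            eps = rng.standard_normal((300, X_dm.n_volumes + 50))
            y = np.sqrt(1 - 0.3**2) * lfilter([1.0], [1.0, -0.3], eps, axis=-1)[:, 50:]
            fit = fit_run_glm(y, X_dm, ar_order=1)
            ts.append(compute_contrast(fit, w).t.ravel())
        pooled = np.concatenate(ts)
        q95 = np.quantile(pooled, 0.95)
        assert q95 == pytest.approx(stats.t.ppf(0.95, X_dm.n_volumes - X_dm.n_columns), abs=0.15)


class TestComputeContrast:
    def test_zero_weights_rejected(self, design, rf, catalog):
        X_dm, _ = _design_from_run(design, rf, catalog)
        fit = fit_run_glm(np.random.default_rng(0).standard_normal((10, 336)), X_dm, 0)
        with pytest.raises(ValueError, match="zero"):
            compute_contrast(fit, [0.0, 0.0])

    def test_sign_flip_negates_t_map(self, design, rf, catalog):
        X_dm, _ = _design_from_run(design, rf, catalog)
        fit = fit_run_glm(np.random.default_rng(1).standard_normal((20, 336)), X_dm, 0)
        a = compute_contrast(fit, [1.0, -1.0])
        b = compute_contrast(fit, [-1.0, 1.0])
        assert np.allclose(a.t, -b.t, equal_nan=True)
        assert np.allclose(a.effect, -b.effect)

    def test_null_category_contrast_centered(self, atlas, rf, catalog):
        """Equal amplitudes for both categories: the category contrast in
        that region stays within 3 SE of zero across seeds."""
        truth = phantom_sim.GroundTruth(
            amplitudes={"A1-like": {"*": 1.0}},
            drift_coeffs_pct=(0.0,),
            n_white_components=0,
            n_csf_components=0,
        )
        a1 = atlas.region_mask("A1-like")
        w_cat = None
        means = []
        for seed in range(8):
            design = phantom_sim.make_run_design(seed, catalog=catalog)
            img, _ = phantom_sim.simulate_run(atlas, design, truth, rf, seed)
            pct = percent_signal_change(img.data, atlas.brain_mask)
            X_dm, names = _design_from_run(design, rf, catalog)
            fit = fit_run_glm(pct, X_dm)
            w_cat = firstlevel.category_contrast_weights(names, catalog.main_of)
            means.append(np.nanmean(compute_contrast(fit, w_cat).t[a1]))
        mean = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(mean) <= 3 * se + 0.2

    def test_effect_invariant_to_rf_rescaling(self, atlas, design, rf, catalog, noise_free_truth):
        """Scaling the response function down and the weights up leaves the
        contrast effect unchanged."""
        img, _ = phantom_sim.simulate_run(atlas, design, noise_free_truth, rf, 0)
        X_dm, names = _design_from_run(design, rf, catalog)
        fit = fit_run_glm(img.data, X_dm, 0)
        base = compute_contrast(fit, [1.0, 1.0]).effect

        scaled = hemodynamics.ResponseFunction(
            k=rf.k, theta_s=rf.theta_s, duration_s=rf.duration_s, step_s=rf.step_s,
            normalization=rf.normalization, t=rf.t, h=rf.h * 0.5,
        )
        task, names2, ts = hemodynamics.build_task_regressors(
            design, scaled, list(phantom_sim.MAIN_CATEGORIES), label_map=catalog.main_of
        )
        X2 = hemodynamics.assemble_design_matrix(task, names2, ts, 3)
        fit2 = fit_run_glm(img.data, X2, 0)
        rescaled = compute_contrast(fit2, [0.5, 0.5]).effect
        assert np.allclose(base, rescaled, atol=1e-6)


class TestCombineRuns:
    def _cmap(self, effect, sd, df=100):
        effect = np.asarray(effect, float)
        sd = np.asarray(sd, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / sd
        return ContrastMap(effect=effect, sd=sd, t=t, df=df)

    def test_single_run_identity(self):
        m = self._cmap([[1.0, 2.0]], [[0.5, 0.5]])
        out = combine_runs([m])
        assert np.allclose(out.effect, m.effect)
        assert np.allclose(out.sd, m.sd)
        assert out.df == m.df

    def test_identical_runs_shrink_sd_by_sqrt_n(self):
        m = self._cmap([[1.0]], [[0.6]])
        out = combine_runs([m] * 4)
        assert np.allclose(out.effect, 1.0)
        assert np.allclose(out.sd, 0.6 / 2.0)
        assert out.df == 400

    def test_inverse_variance_weights_hand_computed(self):
        a = self._cmap([[2.0]], [[1.0]])
        b = self._cmap([[6.0]], [[2.0]])
        out = combine_runs([a, b])
        # weights 1 and 1/4 -> (2 + 6/4) / (1 + 1/4) = 2.8
        assert out.effect[0, 0] == pytest.approx(2.8, abs=1e-12)
        assert out.sd[0, 0] == pytest.approx((1 + 0.25) ** -0.5, abs=1e-12)

    def test_grid_mismatch_errors(self):
        a = self._cmap(np.ones((2, 2)), np.ones((2, 2)))
        b = self._cmap(np.ones((3, 3)), np.ones((3, 3)))
        with pytest.raises(ValueError, match="grids"):
            combine_runs([a, b])

    def test_invalid_sd_voxels_excluded(self):
        a = self._cmap([[1.0, 1.0]], [[1.0, 0.0]])
        b = self._cmap([[3.0, 3.0]], [[1.0, 1.0]])
        out = combine_runs([a, b])
        assert out.effect[0, 0] == pytest.approx(2.0)
        assert out.effect[0, 1] == pytest.approx(3.0)  # only run b contributes
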