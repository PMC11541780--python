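"""Design matrices, weighted least squares, contrasts, BOLD forward model."""

import numpy as np
import pytest
from scipy import stats

from sentspec.bold import DriftSpec, MotionSpec, simulate_bold_run
from sentspec.design import GRAMMATICALITY, build_task_design
from sentspec.glm import (
    FirstLevelGLM,
    RankDeficientDesignError,
    all_sentences_vs_control_contrast,
    build_design_matrix,
    condition_contrast,
    dct_basis,
    dct_drift_count,
    fit_weighted_glm,
    hrf,
)

CONDS = ("Gram", "FVio", "PVio", "PC")


@pytest.fixture(scope="module")
def run_design():
    return build_task_design(GRAMMATICALITY, seed=31)[0]


@pytest.fixture(scope="module")
def noiseless_fit(run_design):
    rng = np.random.default_rng(8)
    betas = {c: rng.normal(0.0, 2.0, 40) for c in CONDS}
    series, _ = simulate_bold_run(run_design, betas, noise_sd=0.0, seed=8)
    X = build_design_matrix(run_design, n_volumes=series.n_volumes)
    fit = FirstLevelGLM().fit(series.data, X)
    return betas, X, fit


class TestHrfAndDrift:
    def test_hrf_peaks_about_five_seconds_after_onset(self):
        t = np.arange(0.0, 32.0, 0.01)
        assert t[np.argmax(hrf(t))] == pytest.approx(5.0, abs=0.5)

    def test_hrf_matches_external_double_gamma(self):
        """Cross-check against an independent canonical-HRF implementation."""
        nilearn_glm = pytest.importorskip("nilearn.glm.first_level")
        dt = 0.1
        ref = nilearn_glm.spm_hrf(dt, oversampling=1, time_length=32)
        ours = hrf(np.arange(0, 32, dt))
        n = min(len(ref), len(ours))
        assert np.corrcoef(ref[:n], ours[:n])[0, 1] > 0.999

    @pytest.mark.parametrize("duration, expected", [(270.0, 4), (128.0, 2), (60.0, 0)])
    def test_dct_count_formula(self, duration, expected):
        assert dct_drift_count(duration, 128.0) == expected

    def test_dct_columns_orthonormal(self):
        basis = dct_basis(135, 2.0, 128.0)
        assert basis.shape == (135, 4)
        np.testing.assert_allclose(basis.T @ basis, np.eye(4), atol=1e-10)


class TestDesignMatrix:
    def test_columns_and_shape(self, run_design):
        X = build_design_matrix(run_design, n_volumes=run_design.n_volumes)
        assert X.condition_columns == run_design.conditions
        assert "intercept" in X.columns
        assert X.values.shape[0] == run_design.n_volumes
        k = dct_drift_count(run_design.n_volumes * run_design.repetition_time)
        assert sum(c.startswith("drift_") for c in X.columns) == k

    def test_condition_regressors_peak_positive(self, run_design):
        """Each condition regressor is clearly positive at stimulation peaks
        (the HRF undershoot makes small negative excursions legitimate)."""
        X = build_design_matrix(run_design, n_volumes=run_design.n_volumes)
        for c in X.condition_columns:
            col = X.frame[c]
            assert col.max() > 0.1
            assert col.min() > -0.5 * col.max()

    def test_constant_motion_columns_dropped(self, run_design):
        n = run_design.n_volumes
        motion = np.ones((n, 6)) * 0.3  # constant: collinear with intercept
        X = build_design_matrix(run_design, motion_trace=motion, n_volumes=n)
        assert set(X.dropped_columns) == {
            "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"}
        assert "intercept" in X.columns

    def test_varying_motion_columns_kept(self, run_design):
        n = run_design.n_volumes
        rng = np.random.default_rng(0)
        X = build_design_matrix(run_design, motion_trace=rng.normal(size=(n, 6)),
                                n_volumes=n)
        assert X.dropped_columns == ()
        assert "trans_x" in X.columns

    def test_series_shorter_than_design_raises(self, run_design):
        with pytest.raises(ValueError, match="beyond"):
            build_design_matrix(run_design, n_volumes=10)

    def test_motion_rows_must_match(self, run_design):
        with pytest.raises(ValueError, match="rows"):
            build_design_matrix(run_design, motion_trace=np.zeros((5, 6)),
                                n_volumes=run_design.n_volumes)


class TestWeightedGLM:
    def test_noiseless_beta_recovery(self, noiseless_fit):
        """Forward BOLD model round-trips through the GLM to 1e-8 relative."""
        betas, X, fit = noiseless_fit
        scale = max(np.abs(b).max() for b in betas.values())
        for cond in CONDS:
            est = fit.betas_[list(X.columns).index(cond)]
            np.testing.assert_allclose(est, betas[cond], atol=1e-8 * scale)

    def test_null_signal_constant_series(self, run_design):
        series, _ = simulate_bold_run(run_design, {"Gram": np.zeros(5)}, noise_sd=0.0,
                                      seed=1)
        np.testing.assert_array_equal(series.data, np.full_like(series.data, 100.0))

    def test_weights_one_equals_ols(self, run_design, rng):
        n = run_design.n_volumes
        series = rng.normal(100, 3, (n, 20))
        X = build_design_matrix(run_design, n_volumes=n)
        wls = fit_weighted_glm(series, X, np.ones(n))
        ols_beta = np.linalg.lstsq(X.values, series, rcond=None)[0]
        np.testing.assert_allclose(wls.betas_, ols_beta, atol=1e-9)

    def test_deweighted_fit_close_to_leave_out_fit(self, run_design, rng):
        """Weight 0.01 on a corrupted volume ~ excluding it (1% tolerance)."""
        n = run_design.n_volumes
        X = build_design_matrix(run_design, n_volumes=n)
        rng_local = np.random.default_rng(77)
        beta_true = rng_local.normal(0, 1, (X.values.shape[1], 15))
        series = X.values @ beta_true + rng_local.normal(0, 0.5, (n, 15))
        bad = 50
        series[bad] += 20.0  # corrupted volume
        w = np.ones(n)
        w[bad] = 0.01
        fit_w = fit_weighted_glm(series, X, w)
        keep = np.arange(n) != bad
        from sentspec.glm import DesignMatrix
        X_loo = DesignMatrix(frame=X.frame.iloc[keep].reset_index(drop=True),
                             condition_columns=X.condition_columns)
        fit_loo = fit_weighted_glm(series[keep], X_loo)
        scale = np.abs(fit_loo.betas_).max()
        assert np.abs(fit_w.betas_ - fit_loo.betas_).max() <= 0.01 * scale

    def test_t_statistic_matches_manual_formula(self):
        """3-regressor toy fit: t = c'b / sqrt(c'(X'WX)^-1 c sigma2)."""
        rng = np.random.default_rng(5)
        n = 30
        X_arr = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        import pandas as pd
        from sentspec.glm import DesignMatrix
        X = DesignMatrix(frame=pd.DataFrame(X_arr, columns=["a", "b", "c"]),
                         condition_columns=("a", "b", "c"))
        y = rng.normal(size=(n, 1))
        w = rng.uniform(0.5, 1.0, n)
        fit = fit_weighted_glm(y, X, w)
        c = np.array([0.0, 1.0, -1.0])
        tmap = fit.contrast(c)
        # manual computation
        W = np.diag(w)
        xtwx_inv = np.linalg.inv(X_arr.T @ W @ X_arr)
        b = xtwx_inv @ X_arr.T @ W @ y
        resid = y - X_arr @ b
        sigma2 = (w[:, None] * resid**2).sum(0) / (n - 3)
        t_manual = (c @ b) / np.sqrt(c @ xtwx_inv @ c * sigma2)
        mask = y.mean(0) > 0.5 * y.mean()
        if mask[0]:
            np.testing.assert_allclose(tmap.t[0], t_manual[0], rtol=1e-12)
        else:
            assert np.isnan(tmap.t[0])

    def test_df_equals_rows_minus_rank(self, noiseless_fit):
        _, X, fit = noiseless_fit
        assert fit.df_ == X.values.shape[0] - np.linalg.matrix_rank(X.values)

    def test_rank_deficient_design_names_columns(self, run_design, rng):
        import pandas as pd
        from sentspec.glm import DesignMatrix
        n = 20
        a = rng.normal(size=n)
        frame = pd.DataFrame({"a": a, "b": 2 * a, "intercept": np.ones(n)})
        X = DesignMatrix(frame=frame, condition_columns=("a", "b"))
        with pytest.raises(RankDeficientDesignError, match="b"):
            fit_weighted_glm(rng.normal(size=(n, 3)), X)

    def test_drift_columns_leave_condition_betas_unchanged_without_drift(self, run_design):
        """With no drift in the signal, adding DCT columns moves betas < 1e-6."""
        rng = np.random.default_rng(12)
        betas = {c: rng.normal(0, 2, 10) for c in CONDS}
        series, _ = simulate_bold_run(run_design, betas, noise_sd=0.0, seed=2)
        X_drift = build_design_matrix(run_design, n_volumes=series.n_volumes)
        X_plain = build_design_matrix(run_design, n_volumes=series.n_volumes,
                                      highpass_cutoff=np.inf)
        assert not any(c.startswith("drift_") for c in X_plain.columns)
        fit_d = FirstLevelGLM().fit(series.data, X_drift)
        fit_p = FirstLevelGLM().fit(series.data, X_plain)
        for cond in CONDS:
            bd = fit_d.betas_[list(X_drift.columns).index(cond)]
            bp = fit_p.betas_[list(X_plain.columns).index(cond)]
            np.testing.assert_allclose(bd, bp, atol=1e-6)


class TestContrasts:
    def test_simple_contrast_vector(self, noiseless_fit):
        _, X, fit = noiseless_fit
        c = condition_contrast(X, "Gram", "PC")
        assert c[list(X.columns).index("Gram")] == 1.0
        assert c[list(X.columns).index("PC")] == -1.0
        assert np.count_nonzero(c) == 2

    def test_negated_contrast_negates_t(self, run_design, rng):
        n = run_design.n_volumes
        series = rng.normal(100, 3, (n, 25))
        X = build_design_matrix(run_design, n_volumes=n)
        fit = FirstLevelGLM().fit(series, X)
        c = condition_contrast(X, "Gram", "PC")
        np.testing.assert_allclose(fit.contrast(c).t, -fit.contrast(-c).t,
                                   rtol=1e-12, atol=1e-12)

    def test_all_sentences_contrast_weights(self, noiseless_fit):
        _, X, fit = noiseless_fit
        c = all_sentences_vs_control_contrast(X)
        idx = {name: i for i, name in enumerate(X.columns)}
        assert c[idx["PC"]] == -1.0
        for cond in ("Gram", "FVio", "PVio"):
            assert c[idx[cond]] == pytest.approx(1 / 3)
        assert c.sum() == pytest.approx(0.0)

    def test_zero_contrast_rejected(self, noiseless_fit):
        _, X, fit = noiseless_fit
        with pytest.raises(ValueError, match="zero"):
            fit.contrast(np.zeros(X.values.shape[1]))

    def test_null_regressor_t_follows_student_t(self):
        """Unit contrast on a null regressor over pure-noise voxels ~ t(df)."""
        rng = np.random.default_rng(99)
        n, v = 60, 4000
        import pandas as pd
        from sentspec.glm import DesignMatrix
        X_arr = np.column_stack([np.ones(n), rng.normal(size=n)])
        X = DesignMatrix(frame=pd.DataFrame(X_arr, columns=["intercept", "null"]),
                         condition_columns=("null",))
        y = 100.0 + rng.normal(size=(n, v))
        fit = FirstLevelGLM().fit(y, X)
        t = fit.contrast(np.array([0.0, 1.0])).t
        assert np.isfinite(t).all()
        df = n - 2
        assert np.std(t) == pytest.approx(np.sqrt(df / (df - 2)), abs=0.05)
        ks = stats.kstest(t, "t", args=(df,))
        assert ks.pvalue > 1e-3


class TestBoldForwardModel:
    def test_drift_adds_low_frequency_component(self, run_design):
        plain, _ = simulate_bold_run(run_design, {"Gram": np.zeros(3)}, seed=4)
        drifted, _ = simulate_bold_run(run_design, {"Gram": np.zeros(3)},
                                       drift_spec=DriftSpec(amplitudes=(5.0,)), seed=4)
        assert not np.allclose(plain.data, drifted.data)
        assert np.allclose(drifted.data.std(axis=1), 0.0)  # spatially constant drift

    def test_determinism(self, run_design):
        a, ta = simulate_bold_run(run_design, {"Gram": np.ones(4)}, noise_sd=1.0,
                                  motion_spec=MotionSpec(), seed=21)
        b, tb = simulate_bold_run(run_design, {"Gram": np.ones(4)}, noise_sd=1.0,
                                  motion_spec=MotionSpec(), seed=21)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(ta, tb)

    def test_mismatched_beta_lengths_rejected(self, run_design):
        with pytest.raises(ValueError, match="same length"):
            simulate_bold_run(run_design, {"Gram": np.ones(4), "PC": np.ones(5)})
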