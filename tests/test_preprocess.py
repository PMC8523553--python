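"""Unit tests for the pre-MVCS cleaning chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mvcs.containers import FdTrace, MotionParams, NuisanceMatrix, RoiTimeSeries
from mvcs.exceptions import ConfigError, PairUnusableError, RoiUnusableError, RunUnusableError
from mvcs.preprocess import (
    build_motion_regressors,
    censor_frames,
    compute_fd,
    detrend_highpass,
    extract_tissue_components,
    match_volumes,
    regress_nuisance,
    resample_to_tr,
    select_voxels_gm,
)


def _run(data, tr=1.0, **kw):
    return RoiTimeSeries(np.asarray(data, dtype=float), tr=tr, **kw)


class TestDetrendHighpass:
    def test_constant_series_becomes_zero(self):
        run = _run(np.full((50, 4), 3.7))
        out = detrend_highpass(run)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    @pytest.mark.parametrize(
        "period_s,max_resid,min_resid",
        [(256.0, 0.01, 0.0), (32.0, 1.0, 0.99)],
    )
    def test_filter_passband(self, period_s, max_resid, min_resid):
        # a slow sinusoid (period > 128 s) is removed, a fast one kept
        t = np.arange(300) * 2.0
        x = np.sin(2 * np.pi * t / period_s)[:, None]
        out = detrend_highpass(_run(x, tr=2.0))
        frac = float((out.data**2).sum() / (x**2).sum())
        assert min_resid <= frac <= max_resid

    def test_projection_never_increases_variance(self, rng):
        x = rng.standard_normal((120, 6))
        out = detrend_highpass(_run(x, tr=2.0))
        assert np.all(out.data.var(axis=0) <= x.var(axis=0) + 1e-12)

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ConfigError):
            detrend_highpass(_run(np.zeros((5, 2))))

    def test_cutoff_sanity_checked(self):
        run = _run(np.random.default_rng(0).standard_normal((60, 2)), tr=1.0)
        with pytest.raises(ConfigError):
            detrend_highpass(run, cutoff_hz=0.0)  # no passband at all
        with pytest.raises(ConfigError):
            detrend_highpass(run, cutoff_hz=0.49)  # full basis

    def test_short_run_reduces_to_detrending(self):
        # a run shorter than the cutoff period has no drift mode to
        # remove; mean and linear trend still go
        t = np.arange(20, dtype=float)
        x = (2.0 + 0.5 * t)[:, None]
        out = detrend_highpass(_run(x, tr=1.0))
        assert np.allclose(out.data, 0.0, atol=1e-10)


class TestFramewiseDisplacement:
    def test_zero_motion_zero_fd(self):
        fd = compute_fd(MotionParams(np.zeros((20, 6))))
        assert np.all(fd.fd == 0)

    def test_sustained_translation_step(self):
        vals = np.zeros((10, 6))
        vals[5:, 0] = 0.3
        fd = compute_fd(MotionParams(vals))
        expected = np.zeros(10)
        expected[5] = 0.3
        assert np.allclose(fd.fd, expected)

    def test_transient_translation_step_hits_twice(self):
        vals = np.zeros((10, 6))
        vals[5, 0] = 0.3
        fd = compute_fd(MotionParams(vals))
        assert fd.fd[5] == pytest.approx(0.3)
        assert fd.fd[6] == pytest.approx(0.3)

    def test_rotation_converted_on_50mm_sphere(self):
        vals = np.zeros((6, 6))
        vals[3:, 3] = 0.01  # sustained 0.01 rad pitch step
        fd = compute_fd(MotionParams(vals))
        assert fd.fd[3] == pytest.approx(0.5)
        assert np.all(fd.fd[[0, 1, 2, 4, 5]] == 0)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ConfigError):
            MotionParams(np.zeros((5, 4)))


class TestCensorFrames:
    def test_rule_enumeration(self):
        # exceedances at 2 and 5 remove {2,3} and {5,6}
        fd = FdTrace(np.array([0, 0.2, 0.6, 0.3, 0.2, 0.55, 0.1]))
        run = _run(np.arange(21).reshape(7, 3))
        out = censor_frames(run, fd)
        assert out.frame_index.tolist() == [0, 1, 4]

    def test_all_below_threshold_is_identity(self):
        fd = FdTrace(np.full(8, 0.1) * np.arange(8) / 8)
        run = _run(np.arange(16).reshape(8, 2))
        out = censor_frames(run, fd)
        assert np.array_equal(out.data, run.data)

    def test_exceedance_at_last_volume(self):
        fd = FdTrace(np.array([0, 0.1, 0.1, 0.9]))
        out = censor_frames(_run(np.zeros((4, 3))), fd)
        assert out.frame_index.tolist() == [0, 1, 2]

    def test_all_censored_signals_unusable(self):
        # FD[0] is 0 by construction, so only the first volume survives
        # continuous exceedance ...
        fd = FdTrace(np.array([0.0, 2.0, 2.0, 2.0]))
        out = censor_frames(_run(np.zeros((4, 3))), fd)
        assert out.frame_index.tolist() == [0]
        # ... and a threshold below 0 censors everything
        with pytest.raises(RunUnusableError):
            censor_frames(_run(np.zeros((4, 3))), fd, threshold_mm=-1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            censor_frames(_run(np.zeros((5, 2))), FdTrace(np.zeros(4)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1.2), min_size=2, max_size=40))
    def test_frame_index_strictly_increasing(self, fd_vals):
        fd_vals[0] = 0.0
        fd = FdTrace(np.array(fd_vals))
        run = _run(np.zeros((len(fd_vals), 3)))
        try:
            out = censor_frames(run, fd)
        except RunUnusableError:
            return
        assert np.all(np.diff(out.frame_index) > 0)


class TestResample:
    def test_300_at_1s_gives_150_at_2s(self):
        run = _run(np.random.default_rng(1).standard_normal((300, 4)), tr=1.0)
        out = resample_to_tr(run, 2.0)
        assert out.n_volumes == 150
        assert out.tr == 2.0

    def test_constant_series_unchanged(self):
        run = _run(np.full((40, 2), 5.0), tr=1.0)
        out = resample_to_tr(run, 2.0)
        assert np.allclose(out.data, 5.0)

    def test_integer_ratio_lands_on_samples(self):
        data = np.random.default_rng(2).standard_normal((60, 3))
        out = resample_to_tr(_run(data, tr=1.0), 2.0)
        assert np.allclose(out.data, data[::2])

    def test_upsampling_rejected(self):
        with pytest.raises(ConfigError):
            resample_to_tr(_run(np.zeros((30, 2)), tr=2.0), 1.0)


class TestMotionRegressors:
    def test_zero_motion_gives_24_zero_columns(self):
        out = build_motion_regressors(MotionParams(np.zeros((30, 6))))
        assert out.values.shape == (30, 24)
        assert np.all(out.values == 0)

    def test_ramp_derivative_constant(self):
        vals = np.zeros((20, 6))
        vals[:, 1] = np.arange(20) * 0.05
        out = build_motion_regressors(MotionParams(vals))
        deriv = out.values[:, 12 + 1]
        assert deriv[0] == 0.0
        assert np.allclose(deriv[1:], 0.05)
        # squared derivative likewise constant
        assert np.allclose(out.values[2:, 18 + 1], 0.05**2)


class TestTissueComponents:
    def test_rank1_pool_single_component(self, rng):
        sig = rng.standard_normal(80)
        wm = np.outer(sig, rng.standard_normal(5))
        csf = rng.standard_normal((80, 5))
        out = extract_tissue_components(wm, csf, k=3)
        # rank-1 WM pool -> its first PC explains all WM variance
        wm_cols = [i for i, lab in enumerate(out.labels) if lab.startswith("wm")]
        assert len(wm_cols) == 1  # rank deficiency flagged by fewer columns
        pc = out.values[:, wm_cols[0]]
        c = np.corrcoef(pc, sig - sig.mean())[0, 1]
        assert abs(c) == pytest.approx(1.0, abs=1e-10)

    def test_six_columns_for_k3(self, rng):
        wm = rng.standard_normal((60, 10))
        csf = rng.standard_normal((60, 8))
        out = extract_tissue_components(wm, csf, k=3)
        assert out.n_regressors == 6
        assert out.labels == ["wm_pc1", "wm_pc2", "wm_pc3",
                              "csf_pc1", "csf_pc2", "csf_pc3"]

    def test_orthogonal_equal_variance_signals_split_evenly(self):
        # eigen oracle: orthonormal columns -> equal singular values
        n = 64
        q, _ = np.linalg.qr(np.random.default_rng(3).standard_normal((n, 4)))
        pool = q * np.sqrt(n)
        out = extract_tissue_components(pool, pool.copy(), k=3)
        x = pool - pool.mean(axis=0)
        total = (x**2).sum()
        for j in range(3):
            pc = out.values[:, j]
            explained = ((x.T @ pc) ** 2).sum()
            assert explained / total == pytest.approx(0.25, abs=0.02)


class TestRegressNuisance:
    def test_voxel_equal_to_regressor_gives_zero(self, rng):
        reg = rng.standard_normal((50, 1))
        run = _run(np.hstack([reg, rng.standard_normal((50, 2))]))
        out = regress_nuisance(run, NuisanceMatrix(reg, ["r0"]))
        assert np.max(np.abs(out.data[:, 0])) < 1e-10

    def test_empty_nuisance_demeans(self, rng):
        x = rng.standard_normal((40, 3)) + 5.0
        out = regress_nuisance(_run(x), NuisanceMatrix(np.empty((0, 0)), []))
        assert np.allclose(out.data, x - x.mean(axis=0), atol=1e-12)

    def test_residuals_orthogonal_to_30_regressors(self, rng):
        n = 120
        nuis = NuisanceMatrix(rng.standard_normal((n, 30)))
        run = _run(rng.standard_normal((n, 8)))
        out = regress_nuisance(run, nuis)
        for j in range(30):
            c = np.corrcoef(out.data.T, nuis.values[:, j])[:-1, -1]
            assert np.max(np.abs(c)) < 1e-10

    def test_collinear_columns_dropped(self, rng):
        base = rng.standard_normal((60, 3))
        nuis = NuisanceMatrix(
            np.hstack([base, base[:, :1] * 2.0]), ["a", "b", "c", "dup"]
        )
        out = regress_nuisance(_run(rng.standard_normal((60, 4))), nuis)
        assert out.n_volumes == 60  # completes despite rank deficiency


class TestGmSelection:
    def test_strict_threshold(self):
        run = _run(np.zeros((10, 4)))
        out = select_voxels_gm(run, np.array([0.05, 0.10, 0.11, 0.9]))
        assert out.voxel_ids.tolist() == run.voxel_ids[[2, 3]].tolist()

    def test_all_pass_is_identity(self):
        run = _run(np.arange(20).reshape(5, 4))
        out = select_voxels_gm(run, np.ones(4))
        assert np.array_equal(out.data, run.data)

    def test_zero_threshold_keeps_positive(self):
        run = _run(np.zeros((5, 3)))
        out = select_voxels_gm(run, np.array([0.01, 0.5, 1.0]), threshold=0.0)
        assert out.n_voxels == 3

    def test_empty_selection_signals_roi_unusable(self):
        with pytest.raises(RoiUnusableError):
            select_voxels_gm(_run(np.zeros((5, 2))), np.array([0.0, 0.05]))


class TestMatchVolumes:
    def test_center_window(self):
        a = _run(np.arange(30).reshape(10, 3))
        b = _run(np.arange(18).reshape(6, 3))
        a2, b2 = match_volumes(a, b, min_volumes=2)
        assert a2.frame_index.tolist() == [2, 3, 4, 5, 6, 7]
        assert np.array_equal(b2.data, b.data)

    def test_equal_lengths_unchanged(self):
        a = _run(np.zeros((8, 3)))
        b = _run(np.ones((8, 3)))
        a2, b2 = match_volumes(a, b, min_volumes=2)
        assert np.array_equal(a2.data, a.data)
        assert np.array_equal(b2.data, b.data)

    def test_floor_rounding(self):
        a = _run(np.zeros((7, 3)))
        b = _run(np.zeros((6, 3)))
        a2, _ = match_volumes(a, b, min_volumes=2)
        assert a2.frame_index.tolist() == [0, 1, 2, 3, 4, 5]

    def test_too_short_pair_unusable(self):
        with pytest.raises(PairUnusableError):
            match_volumes(_run(np.zeros((10, 3))), _run(np.zeros((10, 3))),
                          min_volumes=30)

    def test_mixed_tr_rejected(self):
        with pytest.raises(ConfigError):
            match_volumes(_run(np.zeros((10, 3)), tr=1.0),
                          _run(np.zeros((10, 3)), tr=2.0), min_volumes=2)
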