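"""Time-averaged MSD estimation and weighted free-diffusion fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qdspt.core import MICROMETERS, AcquisitionMeta
from qdspt.msd import (MSDCurve, compute_msd, fit_contiguous_batch,
                       fit_diffusion, fit_trajectory)
from qdspt.simulate import SimulationConfig, simulate_brownian

from conftest import make_traj


def um_traj(xy, frames=None, id="t"):
    return make_traj(id, xy, frames=frames, unit=MICROMETERS)


class TestComputeMsd:
    def test_stationary_trajectory_has_zero_msd(self, unit_meta):
        curve = compute_msd(um_traj(np.tile([3.0, 4.0], (60, 1))), unit_meta)
        assert np.all(curve.msd == 0.0)

    def test_hand_enumerated_path(self, unit_meta):
        # (0,0),(1,0),(1,1),(2,1): all pairs enumerated by hand
        curve = compute_msd(
            um_traj([[0, 0], [1, 0], [1, 1], [2, 1]]), unit_meta)
        np.testing.assert_allclose(curve.msd, [1.0, 2.0, 5.0])
        np.testing.assert_array_equal(curve.n_pairs, [3, 2, 1])

    def test_pair_counts_for_contiguous_track(self, unit_meta):
        rng = np.random.default_rng(0)
        n_frames = 41      # 40 displacements
        curve = compute_msd(um_traj(rng.normal(size=(n_frames, 2))),
                            unit_meta)
        np.testing.assert_array_equal(curve.n_pairs, n_frames - curve.lags)

    def test_brownian_msd_matches_4dt(self, meta):
        config = SimulationConfig(D_simulation=0.5, t_lag=0.040, n_traj=1,
                                  steps_per_traj=10_000, seed=8)
        tracks, _ = simulate_brownian(config)
        curve = compute_msd(tracks.trajectories[0], meta, max_lag=1)
        assert curve.msd[0] == pytest.approx(4 * 0.5 * 0.040, rel=0.05)

    def test_gapped_track_pairs_by_frame_difference(self, unit_meta):
        # brute-force oracle: enumerate every (i, j) pair explicitly
        frames = np.array([0, 1, 2, 5, 6, 9])
        rng = np.random.default_rng(2)
        xy = rng.normal(size=(6, 2))
        curve = compute_msd(um_traj(xy, frames=frames), unit_meta, max_lag=9)
        for lag, m, n in zip(curve.lags, curve.msd, curve.n_pairs):
            sq = [np.sum((xy[j] - xy[i]) ** 2)
                  for i in range(6) for j in range(6)
                  if frames[j] - frames[i] == lag]
            assert n == len(sq)
            assert m == pytest.approx(np.mean(sq))

    def test_requires_micrometers(self, unit_meta):
        with pytest.raises(ValueError, match="convert"):
            compute_msd(make_traj("t", np.zeros((5, 2))), unit_meta)

    def test_too_short_trajectory_rejected(self, unit_meta):
        with pytest.raises(ValueError, match="fewer than 2"):
            compute_msd(um_traj(np.zeros((1, 2))), unit_meta)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(-50, 50), st.floats(-50, 50),
           st.floats(0, 2 * np.pi))
    def test_invariant_under_rigid_motion(self, dx, dy, angle):
        meta1 = AcquisitionMeta(frame_interval=0.04, pixel_size=1.0)
        rng = np.random.default_rng(13)
        xy = np.cumsum(rng.normal(size=(30, 2)), axis=0)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = xy @ rot.T + [dx, dy]
        a = compute_msd(um_traj(xy), meta1)
        b = compute_msd(um_traj(moved), meta1)
        np.testing.assert_allclose(b.msd, a.msd, rtol=1e-8, atol=1e-12)


def toy_curve(msd, variance, n_pairs=50, t_lag=0.040):
    msd = np.asarray(msd, dtype=float)
    variance = np.broadcast_to(np.asarray(variance, dtype=float), msd.shape)
    lags = np.arange(1, msd.size + 1)
    return MSDCurve(lags=lags, msd=msd,
                    variance=variance.copy(),
                    n_pairs=np.full(msd.size, n_pairs), t_lag=t_lag)


class TestFitDiffusion:
    def test_exact_line_recovers_d_and_zero_offset(self):
        curve = toy_curve(0.08 * np.arange(1, 6), 1e-4)
        fit = fit_diffusion(curve)
        assert fit.D5 == pytest.approx(0.5, abs=1e-12)
        assert fit.c == pytest.approx(0.0, abs=1e-12)

    def test_offset_from_30nm_precision(self):
        # c = 4 x (0.03 um)^2 = 0.0036 um^2
        curve = toy_curve(0.08 * np.arange(1, 6) + 0.0036, 1e-4)
        fit = fit_diffusion(curve)
        assert fit.D5 == pytest.approx(0.5, abs=1e-12)
        assert fit.c == pytest.approx(0.0036, abs=1e-12)

    def test_weighted_fit_matches_polyfit_oracle(self):
        # independent oracle: numpy.polyfit with w = 1/sigma
        msd = np.array([0.09, 0.15, 0.26])
        var = np.array([2e-4, 8e-4, 3e-3])
        n = 40
        curve = toy_curve(msd, var, n_pairs=n)
        fit = fit_diffusion(curve, fit_lags=(1, 2, 3))
        t = np.arange(1, 4) * 0.040
        slope, intercept = np.polyfit(t, msd, 1, w=1.0 / np.sqrt(var / n))
        assert fit.D5 == pytest.approx(slope / 4, rel=1e-10)
        assert fit.c == pytest.approx(intercept, rel=1e-10)

    def test_equal_weights_reduce_to_ols(self):
        msd = np.array([0.07, 0.17, 0.23, 0.33, 0.40])
        curve = toy_curve(msd, 5e-4)
        fit = fit_diffusion(curve)
        t = np.arange(1, 6) * 0.040
        slope, intercept = np.polyfit(t, msd, 1)
        assert fit.D5 == pytest.approx(slope / 4, rel=1e-10)
        assert fit.c == pytest.approx(intercept, rel=1e-10)

    def test_sample_variance_weighting_is_switchable(self):
        msd = np.array([0.09, 0.15, 0.26])
        var = np.array([2e-4, 8e-4, 3e-3])
        curve = toy_curve(msd, var, n_pairs=40)
        a = fit_diffusion(curve, fit_lags=(1, 2, 3))
        b = fit_diffusion(curve, fit_lags=(1, 2, 3),
                          weight_mode="sample_variance")
        # equal n_pairs at all lags: identical relative weights
        assert b.D5 == pytest.approx(a.D5, rel=1e-12)

    def test_zero_variance_falls_back_unweighted(self):
        curve = toy_curve(0.08 * np.arange(1, 6), 0.0)
        fit = fit_diffusion(curve)
        assert not fit.weighted
        assert "zero_variance_fallback_unweighted" in fit.flags
        assert fit.D5 == pytest.approx(0.5)

    def test_negative_d_is_reported_not_clipped(self):
        curve = toy_curve([0.5, 0.4, 0.3, 0.2, 0.1], 1e-3)
        assert fit_diffusion(curve).D5 < 0

    def test_missing_fit_lag_rejected(self):
        curve = toy_curve([0.1, 0.2, 0.3], 1e-3)
        with pytest.raises(ValueError, match="absent"):
            fit_diffusion(curve, fit_lags=range(1, 6))


class TestBatchFit:
    def test_batch_matches_per_trajectory_route(self, meta):
        rng = np.random.default_rng(21)
        n_traj, n_steps = 20, 60
        steps = rng.normal(0, 0.1, size=(n_traj, n_steps, 2))
        batch = fit_contiguous_batch(steps, meta.frame_interval)
        for i in range(n_traj):
            xy = np.vstack([np.zeros((1, 2)), np.cumsum(steps[i], axis=0)])
            fit = fit_trajectory(um_traj(xy, id=f"t{i}"), meta)
            assert batch[i] == pytest.approx(fit.D5, rel=1e-10)

    def test_ensemble_mean_d_is_unbiased(self, meta):
        """Mean fitted D over >=200 simulated trajectories of 50 steps lies
        within 2 standard errors of the simulated value."""
        rng = np.random.default_rng(17)
        from qdspt.simulate import brownian_steps_batch
        steps = brownian_steps_batch(250, 50, 0.5, 0.040, rng)
        Ds = fit_contiguous_batch(steps, 0.040)
        sem = Ds.std(ddof=1) / np.sqrt(Ds.size)
        assert abs(Ds.mean() - 0.5) < 2 * sem
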