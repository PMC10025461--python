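import numpy as np
import pytest

from gaitmesh import (FitConfig, fit_frame, fit_sequence, joint_centers,
                      make_foot_strap, objective, pose_model)
from gaitmesh.fitting import _rho

Z10 = np.zeros(10)


class TestObjective:
    def test_on_surface_terms_vanish(self, toy_model, static_recording):
        rec = static_recording
        energy, terms = objective(rec.frames[0].points, toy_model,
                                  rec.truth_shape, rec.truth_poses[0],
                                  rec.truth_translations[0])
        assert terms["data"] < 1e-12
        assert terms["aux_motion"] == 0
        assert terms["ankle"] == 0

    def test_single_point_quadratic_region(self, toy_model):
        """A 5 mm residual in the quadratic region of the Huber penalty
        contributes exactly lambda_data * (0.005)^2."""
        v = toy_model.template_vertices
        normal_dir = np.array([0.0, 0.0, -1.0])
        k = int(np.argmin(v[:, 2]))            # most anterior vertex
        point = v[k] + 0.005 * normal_dir
        cfg = FitConfig(robust="huber", lambda_pose_prior=0.0)
        energy, terms = objective(point[None], toy_model, Z10,
                                  np.zeros((24, 3)), np.zeros(3), config=cfg)
        assert abs(terms["data"] - 0.005 ** 2) < 1e-9

    def test_ankle_penalty_exactly_quadratic(self, toy_model,
                                             static_recording):
        cfg = FitConfig(ankle_limit=0.7, lambda_ankle=10.0)
        pose = static_recording.truth_poses[0].copy()
        pose[7, 0] = cfg.ankle_limit + 0.1    # left ankle dorsiflexion
        _, terms = objective(static_recording.frames[0].points, toy_model,
                             Z10, pose, static_recording.truth_translations[0],
                             config=cfg)
        assert abs(terms["ankle"] - 10.0 * 0.01) < 1e-12

    def test_all_zero_weights_rejected(self, toy_model, static_recording):
        cfg = FitConfig(lambda_data=0, lambda_aux_motion=0, lambda_ankle=0,
                        lambda_pose_prior=0, lambda_temporal=0)
        with pytest.raises(ValueError, match="zero"):
            objective(static_recording.frames[0].points, toy_model, Z10,
                      np.zeros((24, 3)), np.zeros(3), config=cfg)

    def test_empty_points_rejected(self, toy_model):
        with pytest.raises(ValueError, match="empty"):
            objective(np.empty((0, 3)), toy_model, Z10, np.zeros((24, 3)),
                      np.zeros(3))


def test_robust_penalties_closed_forms():
    d = np.array([0.001, 0.02, 0.05, 0.2])
    c = 0.05
    np.testing.assert_allclose(_rho(d, "quadratic", c), d * d)
    np.testing.assert_allclose(_rho(d, "gm", c),
                               c * c * d * d / (c * c + d * d))
    hub = _rho(d, "huber", c)
    assert hub[0] == d[0] ** 2                        # quadratic region
    assert abs(hub[3] - c * (2 * d[3] - c)) < 1e-15   # linear region


class TestFitFrame:
    def test_fixed_point_stays_at_truth(self, toy_model, static_recording):
        """Initialized at the generating parameters of noiseless data, the
        fit must not move: joint centers stay within 0.1 mm."""
        rec = static_recording
        cfg = FitConfig(n_sweeps=4, exact_corr=True)
        pose, trans, beta, _, diag = fit_frame(
            rec.frames[0].points, toy_model, rec.truth_shape,
            rec.truth_poses[0], rec.truth_translations[0], cfg)
        _, jt = pose_model(toy_model, rec.truth_shape, rec.truth_poses[0],
                           rec.truth_translations[0])
        _, jf = pose_model(toy_model, beta, pose, trans)
        assert np.linalg.norm(jf - jt, axis=1).max() < 1e-4

    def test_recovers_perturbed_leg_pose(self, toy_model, static_recording):
        """<= 5 degree perturbations of the gait joints (hips, knees,
        ankles) are pulled back to within 5 mm at the leg joints."""
        rec = static_recording
        rng = np.random.default_rng(1)
        pert = rec.truth_poses[0].copy()
        legs = [1, 2, 4, 5, 7, 8]
        pert[legs] += rng.uniform(-0.087, 0.087, (len(legs), 3))
        cfg = FitConfig(n_sweeps=24, exact_corr=True)
        pose, trans, beta, _, _ = fit_frame(
            rec.frames[0].points, toy_model, rec.truth_shape, pert,
            rec.truth_translations[0], cfg)
        _, jt = pose_model(toy_model, rec.truth_shape, rec.truth_poses[0],
                           rec.truth_translations[0])
        _, jf = pose_model(toy_model, beta, pose, trans)
        leg_joints = [1, 2, 4, 5, 7, 8, 10, 11]
        err = np.linalg.norm(jf[leg_joints] - jt[leg_joints], axis=1)
        assert err.max() < 5e-3

    def test_sweep_energy_monotone(self, toy_model, static_recording):
        """With a fixed robust scale and exact correspondences, the
        accepted objective can only decrease between ICP sweeps."""
        rec = static_recording
        rng = np.random.default_rng(2)
        pert = rec.truth_poses[0] + rng.uniform(-0.05, 0.05, (24, 3))
        cfg = FitConfig(n_sweeps=6, gnc_start=1.0, exact_corr=True,
                        corr_gate=0.0)
        *_, diag = fit_frame(rec.frames[0].points, toy_model,
                             rec.truth_shape, pert,
                             rec.truth_translations[0], cfg)
        e = diag["sweep_energies"]
        assert all(b <= a + 1e-12 for a, b in zip(e, e[1:]))

    def test_nonfinite_init_rejected(self, toy_model, static_recording):
        bad = np.zeros((24, 3))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_frame(static_recording.frames[0].points, toy_model, Z10,
                      bad, np.zeros(3))

    def test_deterministic(self, toy_model, static_recording):
        rec = static_recording
        cfg = FitConfig(n_sweeps=3, seed=42)
        out1 = fit_frame(rec.frames[0].points, toy_model, rec.truth_shape,
                         rec.truth_poses[0], rec.truth_translations[0], cfg)
        out2 = fit_frame(rec.frames[0].points, toy_model, rec.truth_shape,
                         rec.truth_poses[0], rec.truth_translations[0], cfg)
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1], out2[1])


class TestFitSequence:
    @pytest.fixture(scope="class")
    def static_fit(self, toy_model, static_recording):
        frames = [f.points for f in static_recording.frames[:8]]
        cfg = FitConfig(n_sweeps=5, cold_sweeps=12, max_points=800)
        return fit_sequence(frames, toy_model, height=1.70, config=cfg)

    def test_shape_frozen_bitwise_after_init(self, static_fit):
        frozen = static_fit.shapes[static_fit.config.n_init_frames:]
        assert all(np.array_equal(frozen[0], s) for s in frozen[1:])
        assert np.array_equal(frozen[0], static_fit.shape)

    def test_frozen_shape_is_mean_of_init_estimates(self, static_fit):
        """The frozen shape is the mean of the five initialization
        estimates, re-projected onto the hard height constraint."""
        mean = static_fit.init_shapes.mean(axis=0)
        np.testing.assert_allclose(
            static_fit.shape[1:], mean[1:], atol=1e-12)
        assert static_fit.init_shapes.shape == (5, 10)

    def test_warm_start_continuity(self, static_fit):
        dpose = np.abs(np.diff(static_fit.poses, axis=0))
        assert dpose.max() < 0.5

    def test_residuals_reported_in_mm(self, static_fit):
        assert static_fit.residual_mean_mm.shape == (8,)
        assert np.all(static_fit.residual_mean_mm >= 0)
        assert static_fit.residual_mean_mm.max() < 20.0

    def test_too_few_frames_rejected(self, toy_model, static_recording):
        with pytest.raises(ValueError, match="n_init_frames"):
            fit_sequence([static_recording.frames[0].points] * 3, toy_model,
                         height=1.70, config=FitConfig(n_init_frames=5))

    def test_strap_states_logged_when_enabled(self, toy_model,
                                              static_recording):
        frames = [f.points for f in static_recording.frames[:5]]
        cfg = FitConfig(n_sweeps=2, cold_sweeps=4, use_straps=True,
                        max_points=400, max_iter=8)
        fit = fit_sequence(frames, toy_model, height=1.70, config=cfg)
        assert set(fit.strap_states) == {"left", "right"}
        assert fit.strap_states["left"].shape == (5, 6)


def test_select_init_frame_ranks_by_residual(toy_model, static_recording):
    """The initialization-frame heuristic returns a candidate index and
    prefers frames whose single-sweep fit leaves small residuals."""
    from gaitmesh import select_init_frame
    frames = [f.points[:400] for f in static_recording.frames[:4]]
    # corrupt frame 2 with a dense far-away blob: it must not be chosen
    rng = np.random.default_rng(0)
    blob = rng.normal([0.5, 1.0, 1.9], 0.02, (200, 3))
    frames[2] = np.vstack([frames[2][:200], blob])
    cfg = FitConfig(n_sweeps=1, max_iter=10, max_points=400)
    choice = select_init_frame(frames, toy_model, height=1.70, config=cfg,
                               n_candidates=4)
    assert choice in range(4)
    assert choice != 2


def test_foot_strap_shape_contract(toy_model):
    strap = make_foot_strap(toy_model, "left")
    assert strap.local_vertices.shape == (8, 3)
    assert strap.state.shape == (6,)
    world = strap.world_vertices()
    assert world.shape == (8, 3)
    with pytest.raises(ValueError):
        strap.world_vertices(np.zeros(5))
    with pytest.raises(ValueError):
        make_foot_strap(toy_model, "middle")
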