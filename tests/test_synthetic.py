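import numpy as np
import pytest

from gaitmesh import (GaitProfile, add_robot_parts, add_stickers,
                      default_gait_profile, default_landmarks, generate_walk,
                      load_frame_ply, make_toy_model, pose_model,
                      write_recording, LANDMARK_NAMES)
from gaitmesh.geometry import MeshDistance


class TestGenerateWalk:
    def test_frame_count_30s_at_30fps(self):
        """30 s at 30 fps is a 900-frame recording window."""
        model = make_toy_model(500, seed=0)
        rec = generate_walk(model, GaitProfile(1.2), duration_s=30, fps=30,
                            noise_sd=0.0, seed=0, n_points=40,
                            include_floor=False)
        assert rec.n_frames == 900

    def test_noiseless_points_on_surface(self, toy_model, static_recording):
        md = MeshDistance(toy_model.faces, toy_model.n_vertices)
        rec = static_recording
        for t in (0, 5):
            verts, _ = pose_model(toy_model, rec.truth_shape,
                                  rec.truth_poses[t],
                                  rec.truth_translations[t])
            d = md.distances(rec.frames[t].points, verts, exact=True)
            assert d.max() < 1e-9

    def test_noise_magnitude_matches_half_normal(self, toy_model):
        """Mean point-to-surface distance under isotropic noise is close to
        the half-normal mean of the surface-normal component."""
        rec = generate_walk(toy_model, GaitProfile(1.2), 0.4, 30,
                            noise_sd=0.002, seed=5, n_points=2000,
                            include_floor=False)
        md = MeshDistance(toy_model.faces, toy_model.n_vertices)
        verts, _ = pose_model(toy_model, rec.truth_shape, rec.truth_poses[0],
                              rec.truth_translations[0])
        mean_d = md.distances(rec.frames[0].points, verts, exact=True).mean()
        half_normal = 0.002 * np.sqrt(2 / np.pi)
        assert abs(mean_d - half_normal) / half_normal < 0.20

    def test_determinism(self, toy_model):
        kw = dict(duration_s=0.4, fps=30, noise_sd=0.002, seed=9,
                  n_points=300)
        a = generate_walk(toy_model, default_gait_profile(), **kw)
        b = generate_walk(toy_model, default_gait_profile(), **kw)
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.points, fb.points)
            assert np.array_equal(fa.colors, fb.colors)

    def test_too_few_frames_rejected(self, toy_model):
        with pytest.raises(ValueError):
            generate_walk(toy_model, GaitProfile(1.2), 0.1, 30, 0.0, 0)

    def test_foot_trajectory_peaks_at_cadence(self, toy_model):
        """Spectral peak of the true foot height sits at the programmed
        cadence within one DFT bin."""
        prof = default_gait_profile(cadence_hz=1.2)
        rec = generate_walk(toy_model, prof, duration_s=5.0, fps=30,
                            noise_sd=0.0, seed=0, n_points=40,
                            include_floor=False)
        foot_y = rec.truth_joints(toy_model)[:, 10, 1]
        spec = np.abs(np.fft.rfft(foot_y - foot_y.mean()))
        freqs = np.fft.rfftfreq(len(foot_y), 1 / 30)
        peak = freqs[np.argmax(spec)]
        assert abs(peak - 1.2) <= freqs[1] + 1e-12


class TestStickers:
    def test_all_present_without_occlusion(self, walk_recording):
        assert set(walk_recording.sticker_truth) == set(LANDMARK_NAMES)
        for name in LANDMARK_NAMES:
            assert walk_recording.sticker_present[name].all()

    def test_eight_distinct_labels_per_frame(self, walk_recording):
        fr = walk_recording.frames[0]
        labels = {o for o in fr.origin if o.startswith("sticker:")}
        assert len(labels) == 8

    def test_centroid_matches_posed_landmark(self, toy_model):
        rec = generate_walk(toy_model, GaitProfile(1.2), 0.4, 30,
                            noise_sd=0.0, seed=2, n_points=200,
                            include_floor=False)
        rec = add_stickers(rec, toy_model, seed=1)
        fr = rec.frames[0]
        for name in LANDMARK_NAMES:
            pts = fr.points[fr.origin == f"sticker:{name}"]
            err = np.linalg.norm(pts.mean(axis=0)
                                 - rec.sticker_truth[name][0])
            assert err < 1e-3

    def test_sticker_truth_equals_posed_landmark(self, toy_model,
                                                 walk_recording):
        rec = walk_recording
        lm = rec.landmarks
        for t in (0, 10):
            verts, _ = pose_model(toy_model, rec.truth_shape,
                                  rec.truth_poses[t],
                                  rec.truth_translations[t])
            for name, vid in lm.items():
                np.testing.assert_allclose(rec.sticker_truth[name][t],
                                           verts[vid], atol=1e-12)

    def test_unknown_landmark_rejected(self, toy_model, static_recording):
        with pytest.raises(ValueError, match="unknown"):
            add_stickers(static_recording, toy_model,
                         landmarks={"left_elbow_sticker": 3})

    def test_occlusion_drops_requested_fraction(self, toy_model):
        rec = generate_walk(toy_model, default_gait_profile(), 1.0, 30,
                            noise_sd=0.0, seed=2, n_points=100,
                            include_floor=False)
        rec = add_stickers(rec, toy_model, occlusion_fraction=0.3, seed=7)
        present = np.concatenate([rec.sticker_present[n]
                                  for n in LANDMARK_NAMES])
        assert 0.15 < 1 - present.mean() < 0.45


class TestRobotParts:
    def test_zero_density_is_noop(self, toy_model, static_recording):
        rec = add_robot_parts(static_recording, toy_model, seed=0, density=0)
        assert rec is static_recording

    def test_contaminants_near_segment_axes_and_outside_mesh(self, toy_model):
        rec = generate_walk(toy_model, GaitProfile(1.2), 0.4, 30,
                            noise_sd=0.0, seed=2, n_points=100,
                            include_floor=False)
        rec = add_robot_parts(rec, toy_model, seed=3)
        fr = rec.frames[0]
        cont = fr.points[fr.contaminant_mask]
        joints = rec.truth_joints(toy_model)[0]
        ji = toy_model.tree.index
        segs = [("left_hip", "left_knee"), ("right_hip", "right_knee"),
                ("left_knee", "left_ankle"), ("right_knee", "right_ankle"),
                ("left_ankle", "left_foot"), ("right_ankle", "right_foot")]
        d_axis = np.full(len(cont), np.inf)
        for a, b in segs:
            pa, pb = joints[ji(a)], joints[ji(b)]
            ab = pb - pa
            t = np.clip((cont - pa) @ ab / (ab @ ab), 0, 1)
            proj = pa + t[:, None] * ab
            d_axis = np.minimum(d_axis, np.linalg.norm(cont - proj, axis=1))
        assert d_axis.max() < 0.12

        # outside test: for an outward-oriented watertight mesh, a point is
        # outside iff it lies on the positive-normal side of its closest face
        verts, _ = pose_model(toy_model, rec.truth_shape, rec.truth_poses[0],
                              rec.truth_translations[0])
        md = MeshDistance(toy_model.faces, toy_model.n_vertices)
        sub = cont[::5]
        dist, face, bary = md.query(sub, verts, exact=True)
        tri = verts[toy_model.faces[face]]
        normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        closest = np.einsum("nk,nki->ni", bary, tri)
        side = np.einsum("ni,ni->n", sub - closest, normals)
        assert np.all(side > 0)

    def test_strap_cluster_tracks_foot(self, toy_model):
        rec = generate_walk(toy_model, default_gait_profile(), 1.0, 30,
                            noise_sd=0.0, seed=2, n_points=100,
                            include_floor=False)
        rec = add_robot_parts(rec, toy_model, seed=3, parts=("straps",))
        joints = rec.truth_joints(toy_model)
        ji = toy_model.tree.index
        # the strap rides on the instep, between ankle and toe base
        instep = (0.55 * joints[:, ji("left_ankle")]
                  + 0.45 * joints[:, ji("left_foot")])
        cents = []
        for fr in rec.frames:
            pts = fr.points[fr.origin == "strap"]
            cents.append(pts[pts[:, 0] > 0].mean(axis=0))  # left side: +x
        cents = np.array(cents)
        for ax in (1, 2):  # vertical and fore-aft, where the foot moves
            r = np.corrcoef(cents[:, ax], instep[:, ax])[0, 1]
            assert r > 0.99


def test_recording_roundtrip_via_ply(toy_model, tmp_path):
    rec = generate_walk(toy_model, GaitProfile(1.2), 0.4, 30,
                        noise_sd=0.001, seed=6, n_points=150)
    write_recording(rec, tmp_path)
    frame = load_frame_ply(tmp_path / "frame_00000.ply")
    assert len(frame.points) == len(rec.frames[0].points)
    # ascii float precision: positions within 1e-6 m, colors within 1/255
    assert np.abs(frame.points - rec.frames[0].points).max() < 1e-5
    assert np.abs(frame.colors - rec.frames[0].colors).max() < 1 / 255 + 1e-9
    assert (tmp_path / "truth_poses.csv").exists()
    assert (tmp_path / "metadata.json").exists()
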