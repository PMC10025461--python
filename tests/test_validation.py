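import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gaitmesh import (ERROR_THRESHOLDS_MM, aggregate_across_subjects,
                      compare_shapes, decompose_error, error_cdf_table,
                      estimate_stride_frequency, select_reference_vertex,
                      steps_needed)
from gaitmesh.sticker_tracking import StickerTrack
from gaitmesh.validation import ShapeComparison


def _track(positions, valid=None, name="left_hallux"):
    positions = np.asarray(positions, dtype=float)
    if valid is None:
        valid = np.ones(len(positions), dtype=bool)
    pos = positions.copy()
    pos[~valid] = np.nan
    return StickerTrack(name, pos, np.asarray(valid, dtype=bool))


class TestCompareShapes:
    def test_identical_models_zero(self, toy_model):
        v = toy_model.template_vertices
        cmp = compare_shapes(v, v, toy_model.region_labels)
        assert cmp.total_mean_mm == 0
        assert all(x == 0 for x in cmp.per_region_mean_mm.values())

    def test_uniform_offset(self, toy_model):
        v = toy_model.template_vertices
        cmp = compare_shapes(v, v + [0.003, 0, 0], toy_model.region_labels)
        for x in cmp.per_region_mean_mm.values():
            assert abs(x - 3.0) < 1e-9
        assert abs(cmp.total_mean_mm - 3.0) < 1e-9

    def test_single_region_displacement_weighted_total(self, toy_model):
        v = toy_model.template_vertices.copy()
        b = v.copy()
        feet = toy_model.region_labels == "feet"
        b[feet] += [0.0, 0.008, 0.0]
        cmp = compare_shapes(v, b, toy_model.region_labels)
        assert abs(cmp.per_region_mean_mm["feet"] - 8.0) < 1e-9
        others = [x for r, x in cmp.per_region_mean_mm.items() if r != "feet"]
        assert all(x == 0 for x in others)
        expected_total = 8.0 * feet.sum() / len(v)
        assert abs(cmp.total_mean_mm - expected_total) < 1e-9

    def test_vertex_count_mismatch(self, toy_model):
        v = toy_model.template_vertices
        with pytest.raises(ValueError, match="mismatch"):
            compare_shapes(v, v[:-1], toy_model.region_labels)


class TestAggregate:
    def _cmp(self, val):
        return ShapeComparison({"head": val, "feet": 2 * val}, 1.5 * val)

    def test_single_subject(self):
        df = aggregate_across_subjects([self._cmp(3.0)])
        assert df.loc["head", "median_mm"] == 3.0
        assert df.loc["head", "iqr_mm"] == 0.0

    def test_known_quartiles(self):
        """{1..5}: median 3, IQR 2 under the linear (type-7) convention."""
        df = aggregate_across_subjects([self._cmp(v) for v in
                                        (1.0, 2.0, 3.0, 4.0, 5.0)])
        assert df.loc["head", "median_mm"] == 3.0
        assert df.loc["head", "iqr_mm"] == 2.0

    def test_identical_subjects_zero_iqr(self):
        df = aggregate_across_subjects([self._cmp(4.0)] * 7)
        assert (df["iqr_mm"] == 0).all()

    def test_quartiles_match_brute_force(self, rng):
        vals = rng.uniform(0, 10, 9)
        df = aggregate_across_subjects([self._cmp(v) for v in vals])
        s = np.sort(vals)

        def type7(q):
            h = (len(s) - 1) * q
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        assert abs(df.loc["head", "median_mm"] - type7(0.5)) < 1e-9
        assert abs(df.loc["head", "iqr_mm"]
                   - (type7(0.75) - type7(0.25))) < 1e-9


class TestSelectReferenceVertex:
    def test_recovers_glued_vertex(self, rng):
        T, V, k = 20, 50, 17
        verts = rng.normal(size=(T, V, 3))
        track = _track(verts[:, k] + rng.normal(0, 1e-4, (T, 3)))
        assert select_reference_vertex(track, verts) == k

    def test_tie_breaks_to_lowest_id(self):
        T = 12
        verts = np.zeros((T, 4, 3))
        verts[:, 2] = [1.0, 0, 0]
        verts[:, 3] = [1.0, 0, 0]   # vertices 2 and 3 coincide
        track = _track(np.tile([1.0, 0, 0.5], (T, 1)))
        assert select_reference_vertex(track, verts) == 2

    def test_equals_exhaustive_oracle(self, rng):
        T, V = 15, 120
        verts = rng.normal(size=(T, V, 3))
        valid = rng.random(T) > 0.2
        valid[:10] = True
        track = _track(rng.normal(size=(T, 3)), valid)
        got = select_reference_vertex(track, verts)
        means = [np.mean([np.linalg.norm(track.positions[t] - verts[t, v])
                          for t in range(T) if valid[t]])
                 for v in range(V)]
        assert got == int(np.argmin(means))

    def test_too_few_valid_frames(self, rng):
        verts = rng.normal(size=(5, 10, 3))
        track = _track(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="valid frames"):
            select_reference_vertex(track, verts)


class TestStrideFrequency:
    def _sine_track(self, f, fps=30.0, dur=30.0, noise=0.0, rng=None):
        t = np.arange(int(dur * fps)) / fps
        y = 0.02 * np.sin(2 * np.pi * f * t)
        pos = np.column_stack([np.zeros_like(t), y, np.zeros_like(t)])
        if noise:
            pos += (rng or np.random.default_rng(0)).normal(0, noise,
                                                            pos.shape)
        return _track(pos)

    def test_pure_sinusoid(self):
        f = estimate_stride_frequency(self._sine_track(1.2), fps=30)
        assert abs(f - 1.2) < 0.02

    def test_with_noise(self, rng):
        tr = self._sine_track(1.2, noise=0.002, rng=rng)
        assert abs(estimate_stride_frequency(tr, fps=30) - 1.2) < 0.05

    def test_constant_signal_raises(self):
        tr = _track(np.tile([0.1, 0.5, 1.5], (300, 1)))
        with pytest.raises(ValueError, match="cadence"):
            estimate_stride_frequency(tr, fps=30)


class TestDecomposeError:
    FPS = 30.0

    def _tracks_from_distance(self, d, valid=None):
        """Build sticker/vertex trajectories whose separation is d(t)."""
        T = len(d)
        vert = np.tile([0.0, 0.0, 1.5], (T, 1))
        stick = vert + np.column_stack([d, np.zeros(T), np.zeros(T)])
        return _track(stick, valid), vert

    def test_pure_harmonic(self):
        t = np.arange(300) / self.FPS
        A = 5.0  # mm
        d = 20.0 + A * np.sin(2 * np.pi * 1.2 * t)
        track, vert = self._tracks_from_distance(d / 1000.0)
        dec = decompose_error(track, vert, stride_hz=1.2, fps=self.FPS)
        assert abs(dec.offset_mm - 20.0) < 0.2
        assert abs(dec.systematic_rms_mm - A / np.sqrt(2)) < 0.02 * A
        assert dec.random_rms_mm < 0.05

    def test_white_noise_systematic_energy(self, rng):
        """With K harmonics fitted to N white-noise samples the projection
        captures E[sys^2] = (2K/N) sigma^2."""
        N, sigma, K = 3000, 3.0, 6
        d = 15.0 + rng.normal(0, sigma, N)
        track, vert = self._tracks_from_distance(d / 1000.0)
        dec = decompose_error(track, vert, stride_hz=1.2, fps=self.FPS,
                              n_harmonics=K)
        expected = (2 * K / N) * sigma ** 2
        # chi^2_{2K} spread: sd = sigma^2 * sqrt(4K)/N per unit
        se = sigma ** 2 * np.sqrt(4 * K) / N
        assert abs(dec.systematic_rms_mm ** 2 - expected) < 4 * se

    def test_perfect_tracking(self):
        T = 200
        vert = np.cumsum(np.full((T, 3), 0.001), axis=0) + [0, 1, 1.5]
        track = _track(vert.copy())
        dec = decompose_error(track, vert, stride_hz=1.2, fps=self.FPS)
        assert dec.sd_mm < 1e-9
        assert all(v == 1.0 for v in dec.cdf.values())

    def test_orthogonality_with_gaps(self, rng):
        T = 400
        t = np.arange(T) / self.FPS
        d = 10 + 3 * np.sin(2 * np.pi * 1.1 * t) + rng.normal(0, 2, T)
        valid = rng.random(T) > 0.15
        track, vert = self._tracks_from_distance(d / 1000.0, valid)
        dec = decompose_error(track, vert, stride_hz=1.1, fps=self.FPS)
        total_var = dec.sd_mm ** 2
        assert abs(dec.systematic_rms_mm ** 2 + dec.random_rms_mm ** 2
                   - total_var) < 1e-9 * max(total_var, 1.0)

    def test_rigid_translation_invariance(self, rng):
        T = 300
        t = np.arange(T) / self.FPS
        d = 12 + 4 * np.sin(2 * np.pi * 1.3 * t) + rng.normal(0, 1, T)
        track, vert = self._tracks_from_distance(d / 1000.0)
        shift = np.array([0.3, -0.2, 0.9])
        track2 = _track(track.positions + shift)
        dec1 = decompose_error(track, vert, 1.3, self.FPS)
        dec2 = decompose_error(track2, vert + shift, 1.3, self.FPS)
        assert abs(dec1.sd_mm - dec2.sd_mm) < 1e-9
        assert abs(dec1.systematic_rms_mm - dec2.systematic_rms_mm) < 1e-9

    def test_cdf_monotone(self, rng):
        d = 10 + rng.normal(0, 8, 500)
        track, vert = self._tracks_from_distance(d / 1000.0)
        dec = decompose_error(track, vert, 1.2, self.FPS)
        vals = [dec.cdf[thr] for thr in ERROR_THRESHOLDS_MM]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert dec.cdf[100.0] >= dec.cdf[5.0]

    def test_pearson_matches_brute_force(self, rng):
        T = 250
        vert = rng.normal(size=(T, 3)).cumsum(axis=0) * 0.001 + [0, 1, 1.5]
        track = _track(vert + rng.normal(0, 0.002, (T, 3)))
        dec = decompose_error(track, vert, 1.2, self.FPS)
        rs = []
        for ax in range(3):
            a, b = track.positions[:, ax], vert[:, ax]
            am, bm = a - a.mean(), b - b.mean()
            rs.append((am @ bm) / np.sqrt((am @ am) * (bm @ bm)))
        assert abs(dec.pearson_r - np.mean(rs)) < 1e-9

    def test_short_valid_data_raises(self):
        track, vert = self._tracks_from_distance(np.full(10, 0.01))
        with pytest.raises(ValueError, match="stride"):
            decompose_error(track, vert, stride_hz=1.2, fps=30.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6), st.floats(0.6, 1.9))
    def test_orthogonality_property(self, seed, stride_hz):
        rng = np.random.default_rng(seed)
        T = 240
        d = 10 + rng.normal(0, 4, T)
        valid = rng.random(T) > 0.1
        if valid.sum() < 60:
            return
        track, vert = self._tracks_from_distance(d / 1000.0, valid)
        dec = decompose_error(track, vert, stride_hz, 30.0)
        assert abs(dec.systematic_rms_mm ** 2 + dec.random_rms_mm ** 2
                   - dec.sd_mm ** 2) < 1e-9 * max(dec.sd_mm ** 2, 1.0)


class TestErrorTable:
    def _dec(self, mean):
        from gaitmesh.validation import ErrorDecomposition
        return ErrorDecomposition(
            offset_mm=mean, mean_error_mm=mean, sd_mm=mean / 2,
            systematic_rms_mm=mean / 3, random_rms_mm=mean / 4,
            pearson_r=0.99, cdf={t: 0.9 for t in ERROR_THRESHOLDS_MM},
            stride_hz=1.2, n_valid=100)

    def test_left_equals_right(self):
        decs = {}
        for site in ("hallux", "patella", "spina_iliaca",
                     "acromioclavicular"):
            decs[f"left_{site}"] = self._dec(10.0)
            decs[f"right_{site}"] = self._dec(10.0)
        table = error_cdf_table(decs)
        assert (table["offset_mm"] == 10.0).all()
        assert table["both_sides"].all()

    def test_left_right_average(self):
        decs = {"left_hallux": self._dec(10.0),
                "right_hallux": self._dec(20.0)}
        table = error_cdf_table(decs)
        assert table.loc["feet", "offset_mm"] == 15.0

    def test_segment_order_and_mapping(self):
        decs = {}
        for site, val in (("hallux", 14.0), ("patella", 6.8),
                          ("spina_iliaca", 6.2),
                          ("acromioclavicular", 4.6)):
            decs[f"left_{site}"] = self._dec(val)
            decs[f"right_{site}"] = self._dec(val)
        table = error_cdf_table(decs)
        assert list(table.index) == ["feet", "knees", "hips", "shoulders"]
        assert table.loc["feet", "offset_mm"] == 14.0
        assert table.loc["shoulders", "offset_mm"] == 4.6

    def test_missing_side_flagged(self):
        table = error_cdf_table({"left_hallux": self._dec(10.0)})
        assert not table.loc["feet", "both_sides"]


class TestStepsNeeded:
    def test_huge_effect_needs_minimum_two(self):
        assert steps_needed(sd_mm=1.0, delta_mm=1e9) == 2

    def test_monotone_in_sd(self):
        n = [steps_needed(sd, 10.0) for sd in (5.0, 10.0, 20.0, 40.0)]
        assert n == sorted(n)

    def test_matches_statsmodels_solver(self):
        """Cross-check against the independent statsmodels power solver."""
        from statsmodels.stats.power import TTestPower
        solver = TTestPower()
        for ratio in (0.5, 0.8, 1.0, 1.5, 2.0):
            ours = steps_needed(sd_mm=10.0 * ratio, delta_mm=10.0)
            nobs = solver.solve_power(effect_size=1.0 / ratio, alpha=0.05,
                                      power=0.8, alternative="two-sided")
            assert ours == int(np.ceil(nobs))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            steps_needed(-1.0, 1.0)
        with pytest.raises(ValueError):
            steps_needed(1.0, 1.0, alpha=1.5)
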