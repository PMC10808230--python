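"""Fusion tracking, motion anisotropy, and PIV on constructed movies."""

import numpy as np
import pytest

from nanocable.dynamics import (fusion_durations_by_bin, piv,
                                simulation_cluster_motion, track_fusion,
                                track_motion)
from nanocable.render import DensityImage
from nanocable.stats import kruskal_then_pairwise
from nanocable.synthetic import SceneSpec, generate_movie, render_ellipses

PITCH = 0.04325


def movie_from_script(script, n_frames=20, shape=(60, 60)):
    spec = SceneSpec(pattern="none", shape=shape, cluster_density=0.0,
                     n_frames=n_frames, fusion_script=script)
    frames, _ = generate_movie(spec)
    return frames


class TestFusion:
    def test_persistent_merge_capped_at_horizon(self):
        """Two disks merge at frame 5 and stay merged: one event, duration
        capped at the 11-frame tracking horizon."""
        frames = movie_from_script([(5, (1.3, 1.3), 60.0, 11)], n_frames=20)
        events = track_fusion(frames)
        assert len(events) == 1
        assert events[0].birth_frame == 5
        assert events[0].duration_frames == 11
        assert not events[0].censored

    def test_two_frame_merge_has_duration_two(self):
        frames = movie_from_script([(4, (1.3, 1.3), 0.0, 2)], n_frames=20)
        events = track_fusion(frames)
        assert len(events) == 1
        assert events[0].duration_frames == 2

    def test_static_disjoint_disks_no_events(self):
        img = render_ellipses([(0.7, 0.7), (1.8, 1.8)], [0.3, 0.3],
                              [0.3, 0.3], [0, 0], (60, 60), PITCH)
        frames = [DensityImage(img, PITCH, 0.32 * t) for t in range(6)]
        assert track_fusion(frames) == []

    def test_orientation_bins_follow_pair_axis(self):
        frames = movie_from_script([(3, (0.8, 0.8), 10.0, 5),
                                    (3, (1.8, 1.8), 80.0, 5)], n_frames=16)
        events = track_fusion(frames)
        bins = sorted(e.orientation_bin for e in events)
        # the boundary runs perpendicular to the approach axis
        assert bins == ["0-30", "60-90"]

    def test_event_near_movie_end_is_censored(self):
        frames = movie_from_script([(8, (1.3, 1.3), 0.0, 11)], n_frames=12)
        events = track_fusion(frames)
        assert len(events) == 1
        assert events[0].censored
        assert events[0].duration_frames < 11

    def test_x_flip_preserves_durations_and_bins(self):
        frames = movie_from_script([(3, (0.8, 0.8), 20.0, 4),
                                    (5, (1.8, 1.8), 75.0, 7)], n_frames=20)
        flipped = [DensityImage(f.pixels[:, ::-1].copy(), f.pixel_pitch,
                                f.frame_time) for f in frames]
        ev = track_fusion(frames)
        ev_f = track_fusion(flipped)
        assert sorted((e.duration_frames, e.orientation_bin) for e in ev) \
            == sorted((e.duration_frames, e.orientation_bin) for e in ev_f)

    def test_planted_bin_longevity_ordering_recovered(self):
        """Fig-2-style recovery: circumferential fusions scripted to outlive
        longitudinal ones are recovered with the planted ordering and the
        Kruskal-Wallis omnibus detects the effect."""
        rng = np.random.default_rng(0)
        script = []
        sites = [(0.6 + 1.0 * i, 0.6 + 1.0 * j) for i in range(4)
                 for j in range(4)]
        for k, site in enumerate(sites):
            if k % 2 == 0:
                ang, dur = 80.0, int(rng.integers(7, 11))   # circumferential
            else:
                ang, dur = 10.0, int(rng.integers(1, 4))    # longitudinal
            script.append((2 + (k % 3), site, ang, dur))
        frames = movie_from_script(script, n_frames=25, shape=(110, 110))
        by_bin = fusion_durations_by_bin(track_fusion(frames))
        assert len(by_bin["60-90"]) >= 5 and len(by_bin["0-30"]) >= 5
        assert np.median(by_bin["60-90"]) > np.median(by_bin["0-30"])
        out = kruskal_then_pairwise([by_bin["60-90"], by_bin["0-30"]])
        assert out["omnibus"].p_value < 0.01


class TestMotion:
    def test_static_clusters_ratio_undefined(self):
        frames, _ = generate_movie(SceneSpec(n_frames=5, motion="static",
                                             cluster_density=3.0))
        res = track_motion(frames)
        assert res["n"] > 0
        assert all(s.delta_x == 0 and s.delta_y == 0 for s in res["steps"])
        assert np.isnan(res["ratio"])

    def test_isotropic_walk_ratio_near_one(self):
        frames, _ = generate_movie(SceneSpec(n_frames=12, seed=5,
                                             motion="isotropic_walk"))
        res = track_motion(frames)
        assert res["n"] >= 300
        assert 0.85 < res["ratio"] < 1.18

    def test_constructed_double_bias_recovered(self):
        frames, _ = generate_movie(SceneSpec(n_frames=12, seed=6,
                                             motion="biased_walk",
                                             motion_ratio=2.0))
        res = track_motion(frames)
        assert res["ratio"] == pytest.approx(2.0, rel=0.15)

    def test_single_frame_movie_gives_empty_result(self):
        frames, _ = generate_movie(SceneSpec(n_frames=1))
        res = simulation_cluster_motion(frames)
        assert res["steps"] == [] and res["test"] is None


class TestPIV:
    def test_window_physical_width_is_0394_um(self):
        """91 px at the 10x-enlarged 0.04325 µm pitch span 0.394 µm."""
        frames = [DensityImage(np.random.default_rng(0).random((50, 50)),
                               0.04325, 0.32 * t) for t in range(2)]
        res = piv(frames)
        assert res["window_um"] == pytest.approx(0.394, abs=0.0005)

    def test_static_movie_gives_zero_vectors(self):
        rng = np.random.default_rng(1)
        img = rng.random((50, 50))
        frames = [DensityImage(img, 0.04325, 0.32 * t) for t in range(3)]
        res = piv(frames)
        assert res["mean_abs_vx"] < 1.0      # nm/s
        assert res["mean_abs_vy"] < 1.0

    def _disk_movie(self, shift_per_frame, n_frames=4, size=50):
        """Sharp-edged disks rigidly translating a fixed shift (native px)
        per frame, the feature class the correlator is built for."""
        rng = np.random.default_rng(2)
        n = 40
        centers = rng.uniform(0, size * PITCH, size=(n, 2))
        frames = []
        for t in range(n_frames):
            c = centers + np.array(shift_per_frame) * PITCH * t
            img = render_ellipses(c, [0.2] * n, [0.2] * n, [0] * n,
                                  (size, size), PITCH, amplitude=100.0)
            frames.append(DensityImage(img, PITCH, 0.32 * t))
        return frames

    def test_rigid_translation_velocity_arithmetic(self):
        """Arithmetic oracle: 2 native px/frame along y is 2 x 43.25 nm per
        0.32 s, about 270 nm/s, with |Vx| near zero.  The validity limit is
        widened because this speed exceeds the default 0.1-window cap."""
        res = piv(self._disk_movie((0.0, 2.0)), length_ratio_limit=0.3)
        assert res["mean_abs_vy"] == pytest.approx(270.0, rel=0.15)
        assert res["mean_abs_vx"] < 0.1 * res["mean_abs_vy"]

    def test_slow_drift_at_default_settings(self):
        """Half a native pixel per frame (~68 nm/s) measured with the default
        window, subdivision, and validity settings."""
        res = piv(self._disk_movie((0.0, 0.5)))
        assert res["mean_abs_vy"] == pytest.approx(67.6, rel=0.25)
        assert res["mean_abs_vx"] < 0.2 * res["mean_abs_vy"]

    def test_transpose_swaps_components(self):
        frames = self._disk_movie((1.5, 0.5))
        transposed = [DensityImage(f.pixels.T.copy(), f.pixel_pitch,
                                   f.frame_time) for f in frames]
        r1 = piv(frames)
        r2 = piv(transposed)
        assert r2.get("mean_abs_vx") == pytest.approx(r1["mean_abs_vy"],
                                                      rel=1e-6)
        assert r2.get("mean_abs_vy") == pytest.approx(r1["mean_abs_vx"],
                                                      rel=1e-6)

    def test_featureless_windows_are_invalid(self):
        frames = [DensityImage(np.zeros((50, 50)), 0.04325, 0.32 * t)
                  for t in range(2)]
        res = piv(frames)
        assert np.isnan(res["mean_abs_vx"])
        assert all(not f.valid.any() for f in res["fields"])
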