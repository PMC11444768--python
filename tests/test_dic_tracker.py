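"""Tracker correctness: grid construction, equivariance, accuracy, flags."""

import numpy as np
import pytest

from gelsense.dic_tracker import (
    FLAG_CLAMPED,
    FLAG_LOW_CORR,
    NodeGrid,
    TrackParams,
    build_grid,
    track_pair,
    track_sequence,
)
from gelsense.errors import ConfigError, DataError
from gelsense.synthgel import SceneConfig, generate_beads, render_frame


class TestBuildGrid:
    @pytest.mark.parametrize(
        "cols,rows,expected",
        [(10, 8, 99), (1, 1, 4), (3, 2, 12)],
    )
    def test_node_count_is_cells_plus_one_squared(self, cols, rows, expected):
        grid = build_grid(cols, rows, (512, 512))
        assert grid.n_nodes == expected

    def test_nodes_inset_by_margin(self):
        params = TrackParams()
        grid = build_grid(10, 8, (512, 512), params)
        m = params.margin_px
        assert grid.positions_px.min() >= m
        assert grid.positions_px.max() <= 511 - m

    def test_too_small_image_rejected_with_minimum_named(self):
        with pytest.raises(ConfigError, match="at least"):
            build_grid(10, 8, (40, 40))


class TestTrackPair:
    def test_identity_gives_zero_displacement_and_unit_correlation(self, shift_pair, grid_512):
        frame_a, _, _, _ = shift_pair
        fld = track_pair(frame_a, frame_a, grid_512)
        ok = fld.flags == "ok"
        assert np.sqrt((fld.disp_px[ok] ** 2).sum(axis=1).mean()) < 0.1
        assert fld.corr[ok].min() > 0.999

    def test_uniform_subpixel_shift_recovered(self, shift_pair, grid_512):
        frame_a, frame_b, shift, _ = shift_pair
        fld = track_pair(frame_a, frame_b, grid_512, pixel_size_um=0.65)
        err = fld.disp_px - shift
        assert np.sqrt((err**2).sum(axis=1).mean()) < 0.2
        # µm output is exactly px * pixel size
        assert np.allclose(fld.disp_um, fld.disp_px * 0.65)

    @pytest.mark.parametrize("shift", [(1.0, 0.0), (-2.4, 1.7), (4.6, -3.3)])
    def test_translation_equivariance(self, shift, grid_512):
        scene = SceneConfig(width_px=512, height_px=512, bead_count=800,
                            noise_sigma=100.0, seed=17)
        beads = generate_beads(scene)
        a = render_frame(beads, scene, np.random.default_rng(5))
        b = render_frame(beads + np.asarray(shift), scene, np.random.default_rng(6))
        fld = track_pair(a, b, grid_512)
        ok = fld.flags == "ok"
        assert ok.sum() > 50
        assert np.abs(fld.disp_px[ok] - np.asarray(shift)).max() < 0.35

    def test_antisymmetry_under_frame_exchange(self, grid_512):
        scene = SceneConfig(width_px=512, height_px=512, bead_count=800,
                            noise_sigma=100.0, seed=19)
        beads = generate_beads(scene)
        a = render_frame(beads, scene, np.random.default_rng(7))
        b = render_frame(beads + np.array([2.2, 1.4]), scene, np.random.default_rng(8))
        fab = track_pair(a, b, grid_512)
        fba = track_pair(b, a, grid_512)
        ok = (fab.flags == "ok") & (fba.flags == "ok")
        assert np.abs(fab.disp_px[ok] + fba.disp_px[ok]).max() < 0.4

    def test_smoothness_zero_disables_smoothing_exactly(self, shift_pair, grid_512):
        frame_a, frame_b, _, _ = shift_pair
        raw = track_pair(frame_a, frame_b, grid_512, TrackParams(smoothness=0.0))
        smoothed = track_pair(frame_a, frame_b, grid_512, TrackParams(smoothness=5.0))
        contributed = (raw.flags != FLAG_LOW_CORR) & (smoothed.flags != FLAG_LOW_CORR)
        assert not np.allclose(raw.disp_px[contributed], smoothed.disp_px[contributed])
        raw2 = track_pair(frame_a, frame_b, grid_512, TrackParams(smoothness=0.0))
        assert np.array_equal(raw.disp_px, raw2.disp_px)

    def test_shift_beyond_search_range_clamps_all_nodes(self, grid_512):
        # broad spots give a correlation surface that rises toward the true
        # (out-of-range) shift, so every node pins to the search border
        scene = SceneConfig(width_px=512, height_px=512, bead_count=2000,
                            psf_sigma_px=4.0, noise_sigma=0.0, seed=23)
        beads = generate_beads(scene)
        a = render_frame(beads, scene, None)
        b = render_frame(beads + np.array([10.0, 0.0]), scene, None)
        fld = track_pair(a, b, grid_512, TrackParams(outlier_r=np.inf))
        assert (fld.flags == FLAG_CLAMPED).all()

    def test_blank_template_flagged_low_corr(self, grid_512):
        a = np.full((512, 512), 100.0)
        b = np.full((512, 512), 100.0)
        fld = track_pair(a, b, grid_512)
        assert (fld.flags == FLAG_LOW_CORR).all()

    def test_monotone_degradation_with_snr(self, grid_512):
        shift = np.array([3.30, -2.10])
        rmses = []
        for snr in (3, 10, 30):
            scene = SceneConfig(width_px=512, height_px=512, bead_count=800,
                                noise_sigma=1000.0 / snr, seed=3)
            beads = generate_beads(scene)
            a = render_frame(beads, scene, np.random.default_rng(1))
            b = render_frame(beads + shift, scene, np.random.default_rng(2))
            fld = track_pair(a, b, grid_512)
            rmses.append(np.sqrt(((fld.disp_px - shift) ** 2).sum(axis=1).mean()))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_mismatched_shapes_rejected(self, grid_512):
        with pytest.raises(DataError):
            track_pair(np.zeros((512, 512)), np.zeros((256, 256)), grid_512)


class TestTrackSequence:
    def test_constant_velocity_accumulates_additively(self, grid_512):
        # three intervals of (1, 0) px -> advected nodes end +3 px from start
        scene = SceneConfig(width_px=512, height_px=512, bead_count=2000,
                            noise_sigma=20.0, seed=31)
        beads = generate_beads(scene)
        rngs = [np.random.default_rng(k) for k in range(4)]
        frames = np.stack(
            [render_frame(beads + np.array([k, 0.0]), scene, rngs[k]) for k in range(4)]
        )
        fields = track_sequence(frames, grid_512, lagrangian=True)
        total = sum(f.disp_px for f in fields)
        # nodes advected past the margin freeze and are flagged; the rest
        # accumulate the full +3 px
        free = fields[-1].flags != FLAG_CLAMPED
        assert free.sum() > 80
        err = total[free] - np.array([3.0, 0.0])
        assert np.sqrt((err**2).sum(axis=1).mean()) < 0.2  # within accumulated noise
        assert np.abs(err).max() < 0.6
        assert (fields[-1].flags[~free] == FLAG_CLAMPED).all()

    def test_zero_field_stack_stays_within_noise_floor(self, grid_512):
        scene = SceneConfig(width_px=512, height_px=512, bead_count=2000,
                            noise_sigma=100.0, seed=37)
        beads = generate_beads(scene)
        frames = np.stack(
            [render_frame(beads, scene, np.random.default_rng(50 + k)) for k in range(3)]
        )
        fields = track_sequence(frames, grid_512)
        for fld in fields:
            assert np.sqrt((fld.disp_px**2).sum(axis=1).mean()) < 0.1

    def test_contraction_matches_ground_truth_intervals(self, contraction_stack, grid_512):
        frames, truth, scene = contraction_stack
        du_true = np.diff(truth.displacements_um, axis=0)
        fields = track_sequence(
            frames, grid_512, pixel_size_um=scene.pixel_size_um, lagrangian=True
        )
        meas = np.stack([f.disp_um for f in fields])
        rmse = np.sqrt(((meas - du_true) ** 2).sum(axis=2).mean())
        assert rmse < 0.10 * np.linalg.norm(du_true, axis=2).max()

    def test_eulerian_mode_keeps_anchors_fixed(self, contraction_stack, grid_512):
        frames, _, scene = contraction_stack
        fields = track_sequence(frames[:3], grid_512, pixel_size_um=scene.pixel_size_um,
                                lagrangian=False)
        for fld in fields:
            assert np.array_equal(fld.positions_px, grid_512.positions_px)

    def test_requires_two_frames(self, grid_512):
        with pytest.raises(DataError):
            track_sequence(np.zeros((1, 512, 512)), grid_512)
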