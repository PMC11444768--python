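"""Generator correctness: determinism, field structure, ground-truth exactness."""

import numpy as np
import pandas as pd
import pytest
import tifffile

from gelsense.errors import ConfigError
from gelsense.layer_mechanics import LayerSpec
from gelsense.synthgel import (
    CellSpec,
    SceneConfig,
    Scenario,
    apply_attenuation,
    cell_field,
    generate_beads,
    place_cells_by_density,
    render_frame,
    render_stack,
    render_zprofile,
)


class TestGenerateBeads:
    def test_deterministic_for_fixed_seed(self):
        scene = SceneConfig(seed=7, bead_count=500)
        assert np.array_equal(generate_beads(scene), generate_beads(scene))

    def test_positions_within_bounds(self):
        scene = SceneConfig(bead_count=1000, seed=1)
        pos = generate_beads(scene)
        assert pos.shape == (1000, 2)
        assert (pos >= 0).all() and (pos[:, 0] < 512).all() and (pos[:, 1] < 512).all()

    def test_mean_nearest_neighbour_distance_matches_poisson_expectation(self):
        # uniform points at density rho have mean NN distance 0.5 / sqrt(rho)
        scene = SceneConfig(bead_count=5000, seed=42)
        pos = generate_beads(scene)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pos).query(pos, k=2)
        rho = 5000 / (512 * 512)
        expected = 0.5 / np.sqrt(rho)
        assert abs(d[:, 1].mean() - expected) / expected < 0.10

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            SceneConfig(bead_count=0)
        with pytest.raises(ConfigError):
            SceneConfig(width_px=0)


class TestCellField:
    def test_zero_at_time_zero(self):
        cells = (CellSpec(center_um=(50.0, 50.0)),)
        u = cell_field(cells, np.array([[10.0, 20.0], [80.0, 90.0]]), t_h=0.0)
        assert np.allclose(u, 0.0)

    def test_zero_at_cell_center(self):
        cells = (CellSpec(center_um=(50.0, 50.0)),)
        assert np.allclose(cell_field(cells, np.array([50.0, 50.0]), t_h=5.0), 0.0)

    def test_symmetric_pair_cancels_at_midpoint(self):
        # the tug-of-war mechanism: opposing pulls cancel between two cells
        cells = (
            CellSpec(center_um=(40.0, 50.0), strength_um=12.0),
            CellSpec(center_um=(160.0, 50.0), strength_um=12.0),
        )
        u = cell_field(cells, np.array([100.0, 50.0]), t_h=10.0)
        assert np.allclose(u, 0.0, atol=1e-12)

    def test_points_toward_cell_and_ramps_monotonically(self):
        cells = (CellSpec(center_um=(0.0, 0.0), strength_um=10.0, reach_um=40.0),)
        u1 = cell_field(cells, np.array([60.0, 0.0]), t_h=2.0)
        u2 = cell_field(cells, np.array([60.0, 0.0]), t_h=6.0)
        assert u1[0] < 0 and abs(u1[1]) < 1e-12  # pulled toward the origin
        assert np.linalg.norm(u2) > np.linalg.norm(u1)

    def test_magnitude_unimodal_with_peak_at_reach(self):
        cell = CellSpec(center_um=(0.0, 0.0), strength_um=10.0, reach_um=40.0)
        r = np.linspace(1.0, 300.0, 600)
        pts = np.column_stack([r, np.zeros_like(r)])
        mag = np.linalg.norm(cell_field((cell,), pts, t_h=50.0), axis=1)
        peak = r[np.argmax(mag)]
        assert abs(peak - 40.0) < 1.0
        assert np.all(np.diff(mag[r < 39]) > 0) and np.all(np.diff(mag[r > 41]) < 0)

    def test_dense_superposition_cancels_per_unit_total_strength(self):
        # N uniformly placed cells of total strength S produce a smaller p90
        # per unit strength than one cell carrying all of S
        rng = np.random.default_rng(5)
        fov = 400.0
        pts = rng.uniform(0, fov, size=(500, 2))
        single = (CellSpec(center_um=(200.0, 200.0), strength_um=30.0, reach_um=40.0),)
        many = tuple(
            CellSpec(center_um=tuple(c), strength_um=30.0 / 60, reach_um=40.0)
            for c in rng.uniform(0, fov, size=(60, 2))
        )
        p90_single = np.percentile(np.linalg.norm(cell_field(single, pts, 24.0), axis=1), 90)
        p90_many = np.percentile(np.linalg.norm(cell_field(many, pts, 24.0), axis=1), 90)
        assert p90_many < p90_single


class TestAttenuation:
    def test_mode_none_is_identity(self):
        u = np.array([[1.0, -2.0], [0.5, 0.25]])
        out = apply_attenuation(u, LayerSpec(E=5.5, h=50.0), mode="none")
        assert out is u

    def test_thin_gel_attenuates_more_than_thick(self):
        u = np.array([[1.0, 0.0]])
        thin = apply_attenuation(u, LayerSpec(E=5.5, h=50.0), mode="mechanics")
        thick = apply_attenuation(u, LayerSpec(E=5.5, h=200.0), mode="mechanics")
        assert np.linalg.norm(thin) < np.linalg.norm(thick) < 1.0


class TestRenderStack:
    def test_no_cells_frames_identical_up_to_noise(self, grid_512):
        scene = SceneConfig(width_px=256, height_px=256, bead_count=600,
                            cadence_min=60.0, duration_h=2.0, noise_sigma=50.0, seed=9)
        frames, truth = render_stack(
            Scenario(scene=scene), node_positions_px=np.array([[128.0, 128.0]])
        )
        assert np.allclose(truth.displacements_um, 0.0)
        diff = frames[0].astype(float) - frames[-1].astype(float)
        # difference of two iid N(0, sigma) noise fields has std sigma*sqrt(2)
        assert abs(np.std(diff) - 50.0 * np.sqrt(2)) < 5.0

    def test_fixed_seed_gives_bit_identical_tiff(self, tmp_path):
        scene = SceneConfig(width_px=128, height_px=128, bead_count=200,
                            cadence_min=60.0, duration_h=1.0, seed=4)
        scn = Scenario(scene=scene, cells=(CellSpec(center_um=(40.0, 40.0)),))
        nodes = np.array([[64.0, 64.0]])
        paths = []
        for tag in ("a", "b"):
            frames, _ = render_stack(scn, node_positions_px=nodes)
            p = tmp_path / f"{tag}.tif"
            tifffile.imwrite(p, frames, photometric="minisblack")
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_ground_truth_equals_cell_field_exactly(self):
        scene = SceneConfig(width_px=256, height_px=256, bead_count=300,
                            cadence_min=60.0, duration_h=3.0, seed=12)
        cells = (CellSpec(center_um=(80.0, 90.0), strength_um=8.0),)
        nodes = np.array([[50.0, 60.0], [180.0, 200.0]])
        _, truth = render_stack(Scenario(scene=scene, cells=cells), node_positions_px=nodes)
        for k, t in enumerate(truth.times_h):
            expected = cell_field(cells, nodes * scene.pixel_size_um, t)
            assert np.allclose(truth.displacements_um[k], expected, atol=1e-12)

    def test_rendered_spot_count_matches_bead_count(self):
        # local-maximum oracle at SNR 10 on a sparse field
        from scipy.ndimage import maximum_filter

        scene = SceneConfig(width_px=512, height_px=512, bead_count=300,
                            noise_sigma=100.0, seed=21)
        img = render_frame(generate_beads(scene), scene, np.random.default_rng(0)).astype(float)
        peaks = (img == maximum_filter(img, size=5)) & (img > scene.background_level + 500)
        n = int(peaks.sum())
        assert abs(n - 300) / 300 < 0.15  # few merged/clipped spots allowed


class TestDensityPlacement:
    def test_expected_count_scales_with_density_and_area(self):
        scene = SceneConfig(width_px=1024, height_px=1024, seed=8)
        counts = []
        for s in range(40):
            cells = place_cells_by_density(
                20000.0, SceneConfig(width_px=1024, height_px=1024, seed=s),
                CellSpec(center_um=(0, 0)),
            )
            counts.append(len(cells))
        w_um = 1024 * scene.pixel_size_um
        expected = 20000.0 * (w_um * 1e-4) ** 2
        assert abs(np.mean(counts) - expected) / expected < 0.15

    def test_at_least_one_cell_even_at_sparse_density(self):
        for s in range(10):
            cells = place_cells_by_density(
                100.0, SceneConfig(seed=s), CellSpec(center_um=(0, 0))
            )
            assert len(cells) >= 1


class TestZProfile:
    def test_exact_boxcar_has_100_interior_plateau_samples(self):
        df = render_zprofile(200.0, step_um=2.0, edge_sigma_um=0.0, noise_sigma=0.0)
        interior = df[(df.z_um > 5.0) & (df.z_um < 205.0)]
        assert int((interior.intensity == df.intensity.max()).sum()) == 100

    def test_deterministic_for_fixed_seed(self):
        a = render_zprofile(54.5, seed=3)
        b = render_zprofile(54.5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_step_must_resolve_slab(self):
        with pytest.raises(ConfigError):
            render_zprofile(8.0, step_um=10.0)
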