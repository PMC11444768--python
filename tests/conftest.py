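"""Shared fixtures: small rendered scenes reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from gelsense.dic_tracker import build_grid
from gelsense.synthgel import CellSpec, SceneConfig, Scenario, generate_beads, render_frame, render_stack


@pytest.fixture(scope="session")
def grid_512():
    return build_grid(10, 8, (512, 512))


@pytest.fixture(scope="session")
def shift_pair(grid_512):
    """Two SNR-10 frames of 800 beads, the second shifted by (3.30, -2.10) px."""
    scene = SceneConfig(width_px=512, height_px=512, bead_count=800, noise_sigma=100.0, seed=3)
    beads = generate_beads(scene)
    shift = np.array([3.30, -2.10])
    frame_a = render_frame(beads, scene, np.random.default_rng(1))
    frame_b = render_frame(beads + shift, scene, np.random.default_rng(2))
    return frame_a, frame_b, shift, scene


@pytest.fixture(scope="session")
def contraction_stack(grid_512):
    """Single contracting cell, hourly frames over 8 h, with ground truth."""
    scene = SceneConfig(
        width_px=512, height_px=512, cadence_min=60.0, duration_h=8.0, seed=11
    )
    cell = CellSpec(center_um=(166.0, 166.0), strength_um=16.0, reach_um=40.0, tau_h=8.0)
    frames, truth = render_stack(
        Scenario(scene=scene, cells=(cell,)), node_positions_px=grid_512.positions_px
    )
    return frames, truth, scene
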