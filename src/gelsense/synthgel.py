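"""Synthetic time-lapse bead imagery with exact ground-truth displacements.

No raw videos are deposited for the experiments this package re-analyses, so
every pipeline stage is exercised on synthetic data that emulates them:
0.5 µm fluorescent beads rendered as PSF-limited Gaussian spots on a hydrogel
surface, imaged on a fixed cadence while radially contracting "cells" deform
the gel.  The generator records the exact displacement field used for
rendering, which downstream tracking is judged against.

The cell traction surrogate is a radial contraction toward each cell centre

    u(x, t) = - s * (1 - exp(-t / tau)) * (r / sigma) * exp(-r^2 / (2 sigma^2)) * r_hat

with r = |x - c|: zero at the centre, maximal at r = sigma, integrable, and
ramping monotonically to a plateau amplitude ``s`` (µm).  Thickness-dependent
attenuation multiplies amplitudes by the finite-layer factor from
:mod:`gelsense.layer_mechanics`.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical configs give bit-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erf

from .errors import ConfigError
from .layer_mechanics import LayerSpec, PunchSpec, attenuation_factor

logger = logging.getLogger(__name__)

__all__ = [
    "SceneConfig",
    "CellSpec",
    "Scenario",
    "GroundTruth",
    "generate_beads",
    "place_cells_by_density",
    "cell_field",
    "apply_attenuation",
    "render_frame",
    "render_stack",
    "render_zprofile",
]


@dataclass(frozen=True)
class SceneConfig:
    """Imaging geometry, cadence and camera model for one synthetic movie.

    Defaults mirror the experimental conditions: one frame every 5 min for
    24 h at 10x magnification (0.65 µm/px), 16-bit single-channel frames.
    ``bead_count`` defaults to 10000 on a 512 px field: the 1% v/v bead
    loading puts roughly one bead per µm² inside a widefield depth of focus,
    i.e. fully developed speckle; 10k is a render-cost-thinned surrogate
    that keeps the speckle dense (~30 beads per correlation template).
    ``bead_peak`` sets spot amplitude above background, so the peak
    signal-to-noise ratio is ``bead_peak / noise_sigma``.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 0.65
    cadence_min: float = 5.0
    duration_h: float = 24.0
    bead_count: int = 10000
    psf_sigma_px: float = 1.2
    background_level: float = 200.0
    bead_peak: float = 1000.0
    noise_sigma: float = 100.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ConfigError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel size must be positive")
        if self.cadence_min <= 0 or self.duration_h <= 0:
            raise ConfigError("cadence and duration must be positive")
        if self.bead_count < 1:
            raise ConfigError("need at least one bead")
        if self.psf_sigma_px <= 0:
            raise ConfigError("PSF sigma must be positive")
        if self.background_level < 0 or self.noise_sigma < 0:
            raise ConfigError("background and noise levels must be nonnegative")
        if self.bit_depth not in (8, 16):
            raise ConfigError(f"bit depth must be 8 or 16, got {self.bit_depth}")

    @property
    def n_frames(self) -> int:
        """floor(duration * 60 / cadence) + 1, including the t=0 frame."""
        return int(math.floor(self.duration_h * 60.0 / self.cadence_min)) + 1

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.cadence_min / 60.0

    @property
    def fov_um(self) -> tuple[float, float]:
        return (self.width_px * self.pixel_size_um, self.height_px * self.pixel_size_um)


@dataclass(frozen=True)
class CellSpec:
    """One contracting cell: plateau amplitude ``strength_um`` (µm), radial
    scale ``reach_um`` (µm, the radius of maximal displacement) and ramp time
    constant ``tau_h`` (h)."""

    center_um: tuple[float, float]
    strength_um: float = 15.0
    reach_um: float = 100.0
    tau_h: float = 8.0

    def __post_init__(self) -> None:
        if self.strength_um < 0:
            raise ConfigError("cell strength must be nonnegative")
        if self.reach_um <= 0 or self.tau_h <= 0:
            raise ConfigError("reach and tau must be positive")


@dataclass(frozen=True)
class Scenario:
    """A full synthetic experiment: scene, cells, gel, attenuation mode.

    Cells are given either explicitly or as a seeding density (cells per cm²,
    Poisson-placed over the field of view).  ``attenuation_mode="mechanics"``
    scales all displacements by the finite-thickness factor of ``gel``.
    """

    scene: SceneConfig
    cells: tuple[CellSpec, ...] = ()
    density_cells_per_cm2: float | None = None
    cell_template: CellSpec = CellSpec(center_um=(0.0, 0.0))
    gel: LayerSpec = LayerSpec(E=5.5)
    punch: PunchSpec = PunchSpec()
    attenuation_mode: str = "none"
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.attenuation_mode not in ("none", "mechanics"):
            raise ConfigError(
                f"attenuation_mode must be 'none' or 'mechanics', got {self.attenuation_mode!r}"
            )
        if self.density_cells_per_cm2 is not None and self.density_cells_per_cm2 < 0:
            raise ConfigError("cell density must be nonnegative")

    def resolve_cells(self) -> tuple[CellSpec, ...]:
        """Explicit cells, or a seeded Poisson draw from the density."""
        if self.density_cells_per_cm2 is None:
            return self.cells
        return place_cells_by_density(
            self.density_cells_per_cm2, self.scene, self.cell_template
        )


@dataclass(frozen=True)
class GroundTruth:
    """Exact displacement field used for rendering, sampled at grid nodes.

    ``node_positions_px`` is (N, 2) in (x, y) pixels at t=0;
    ``displacements_um`` is (n_frames, N, 2) in µm, identically zero in
    frame 0; ``amplitudes`` holds the per-frame ramp factor.
    """

    node_positions_px: np.ndarray
    displacements_um: np.ndarray
    times_h: np.ndarray
    amplitudes: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        """Tidy table: frame, node_id, x_px, y_px, ux_um, uy_um."""
        n_frames, n_nodes, _ = self.displacements_um.shape
        frame = np.repeat(np.arange(n_frames), n_nodes)
        node = np.tile(np.arange(n_nodes), n_frames)
        return pd.DataFrame(
            {
                "frame": frame,
                "node_id": node,
                "x_px": np.tile(self.node_positions_px[:, 0], n_frames),
                "y_px": np.tile(self.node_positions_px[:, 1], n_frames),
                "ux_um": self.displacements_um[:, :, 0].ravel(),
                "uy_um": self.displacements_um[:, :, 1].ravel(),
            }
        )


def generate_beads(scene: SceneConfig) -> np.ndarray:
    """Uniform sub-pixel bead positions, (bead_count, 2) as (x, y) px.

    Reproducible for a fixed ``scene.seed``; bead placement uses a dedicated
    child of the scene seed so adding noise does not move beads.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scene.seed, 0]))
    pos = rng.uniform(
        low=[0.0, 0.0],
        high=[scene.width_px, scene.height_px],
        size=(scene.bead_count, 2),
    )
    return pos


def place_cells_by_density(
    density_cells_per_cm2: float, scene: SceneConfig, template: CellSpec
) -> tuple[CellSpec, ...]:
    """Poisson-place cells over the field of view at a seeding density.

    The expected count is density x FOV area; the draw is truncated below at
    one cell so a sparse scenario still contains a contracting cell.  Uses a
    placement-specific child seed, distinct from the bead stream.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scene.seed, 1]))
    w_um, h_um = scene.fov_um
    area_cm2 = (w_um * 1e-4) * (h_um * 1e-4)
    expected = density_cells_per_cm2 * area_cm2
    n = max(1, int(rng.poisson(expected)))
    centers = rng.uniform(low=[0.0, 0.0], high=[w_um, h_um], size=(n, 2))
    return tuple(
        replace(template, center_um=(float(cx), float(cy))) for cx, cy in centers
    )


def cell_field(
    cells: tuple[CellSpec, ...] | list[CellSpec],
    points_um: np.ndarray,
    t_h: float,
) -> np.ndarray:
    """Superposed displacement (µm) of all cells at ``points_um``, time ``t_h``.

    Each cell contributes an inward radial displacement
    ``s (1 - e^{-t/tau}) (r/sigma) e^{-r^2/(2 sigma^2)}`` toward its centre;
    the value at the centre itself is the zero vector.  ``points_um`` may be
    a single (2,) point or an (N, 2) array.
    """
    if t_h < 0:
        raise ConfigError("time must be nonnegative")
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    u = np.zeros_like(pts)
    for cell in cells:
        d = pts - np.asarray(cell.center_um)  # vector cell -> point
        r = np.hypot(d[:, 0], d[:, 1])
        ramp = 1.0 - math.exp(-t_h / cell.tau_h)
        g = (r / cell.reach_um) * np.exp(-(r**2) / (2.0 * cell.reach_um**2))
        mag = cell.strength_um * ramp * g
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r[:, None] > 0, d / np.maximum(r, 1e-300)[:, None], 0.0)
        u -= mag[:, None] * unit  # minus: displacement points toward the cell
    return u if np.asarray(points_um).ndim == 2 else u[0]


def apply_attenuation(
    u: np.ndarray, gel: LayerSpec, mode: str, punch: PunchSpec = PunchSpec()
) -> np.ndarray:
    """Scale a displacement field by the finite-thickness factor of ``gel``.

    ``mode="mechanics"`` multiplies by k_halfspace / k(h) from
    :func:`gelsense.layer_mechanics.attenuation_factor`; ``mode="none"``
    returns the field unchanged.
    """
    if mode == "none":
        return u
    if mode != "mechanics":
        raise ConfigError(f"unknown attenuation mode {mode!r}")
    return u * attenuation_factor(gel, punch)


def render_frame(
    positions_px: np.ndarray, scene: SceneConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """One quantized frame: background + Gaussian spots (+ noise if rng given)."""
    img = np.full((scene.height_px, scene.width_px), scene.background_level, dtype=float)
    halfw = max(2, int(math.ceil(4.0 * scene.psf_sigma_px)))
    two_s2 = 2.0 * scene.psf_sigma_px**2
    for x, y in positions_px:
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(0, cx - halfw), min(scene.width_px, cx + halfw + 1)
        y0, y1 = max(0, cy - halfw), min(scene.height_px, cy + halfw + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - x
        ys = np.arange(y0, y1) - y
        img[y0:y1, x0:x1] += scene.bead_peak * np.exp(
            -(xs[None, :] ** 2 + ys[:, None] ** 2) / two_s2
        )
    if rng is not None and scene.noise_sigma > 0:
        img += rng.normal(0.0, scene.noise_sigma, img.shape)
    vmax = 2**scene.bit_depth - 1
    img = np.clip(np.rint(img), 0, vmax)
    return img.astype(np.uint16 if scene.bit_depth == 16 else np.uint8)


def render_stack(
    scenario: Scenario, node_positions_px: np.ndarray | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Render the full time-lapse stack and its exact ground truth.

    Beads are displaced by the cell field evaluated at their t=0 positions
    (small-displacement Lagrangian approximation) and drawn as Gaussian spots
    with per-frame seeded noise.  Ground truth is sampled at
    ``node_positions_px`` (defaults to the standard tracking grid from
    :func:`gelsense.dic_tracker.build_grid`).
    """
    scene = scenario.scene
    cells = scenario.resolve_cells()
    factor = 1.0
    if scenario.attenuation_mode == "mechanics":
        factor = attenuation_factor(scenario.gel, scenario.punch)

    if node_positions_px is None:
        from .dic_tracker import TrackParams, build_grid

        node_positions_px = build_grid(
            10, 8, (scene.height_px, scene.width_px), TrackParams()
        ).positions_px

    beads_px = generate_beads(scene)
    beads_um = beads_px * scene.pixel_size_um
    nodes_um = np.asarray(node_positions_px, dtype=float) * scene.pixel_size_um
    times = scene.times_h

    noise_root = np.random.SeedSequence([scene.seed, 2])
    frame_rngs = [np.random.default_rng(s) for s in noise_root.spawn(len(times))]

    frames = np.empty((len(times), scene.height_px, scene.width_px),
                      dtype=np.uint16 if scene.bit_depth == 16 else np.uint8)
    node_disp = np.empty((len(times), nodes_um.shape[0], 2))
    amplitudes = np.empty(len(times))
    clipped_warned = False
    for k, t in enumerate(times):
        u_beads = cell_field(cells, beads_um, t) * factor
        node_disp[k] = cell_field(cells, nodes_um, t) * factor
        amplitudes[k] = max((1.0 - math.exp(-t / c.tau_h)) * c.strength_um for c in cells) if cells else 0.0
        disp_px = beads_px + u_beads / scene.pixel_size_um
        out = (
            (disp_px[:, 0] < 0) | (disp_px[:, 0] >= scene.width_px)
            | (disp_px[:, 1] < 0) | (disp_px[:, 1] >= scene.height_px)
        )
        if out.mean() > 0.01 and not clipped_warned:
            logger.warning(
                "%.1f%% of beads displaced out of bounds at t=%.2f h; clipped",
                100 * out.mean(), t,
            )
            clipped_warned = True
        frames[k] = render_frame(disp_px, scene, frame_rngs[k])
    truth = GroundTruth(
        node_positions_px=np.asarray(node_positions_px, dtype=float),
        displacements_um=node_disp,
        times_h=times,
        amplitudes=amplitudes,
    )
    return frames, truth


def render_zprofile(
    thickness_um: float,
    step_um: float = 2.0,
    edge_sigma_um: float = 2.0,
    noise_sigma: float = 0.02,
    seed: int = 0,
    z_start_um: float = 5.0,
    peak_intensity: float = 1.0,
) -> pd.DataFrame:
    """Confocal z-stack mean-intensity profile of a fluorescent slab.

    The slab occupies [z_start, z_start + thickness]; its profile is a boxcar
    with error-function edges of width ``edge_sigma_um``, sampled every
    ``step_um`` (the experiment used 2 or 10 µm steps) with additive Gaussian
    noise.  Returns a DataFrame with columns ``z_um, intensity`` plus the
    true thickness in ``df.attrs``.
    """
    if thickness_um <= 0:
        raise ConfigError("thickness must be positive")
    if step_um <= 0:
        raise ConfigError("z-step must be positive")
    if step_um >= thickness_um:
        raise ConfigError(
            f"z-step {step_um} must be smaller than the slab thickness {thickness_um}"
        )
    # scan well past the far edge so a lowest-decile baseline estimate always
    # sees enough gel-free samples, however thick the slab
    pad = 3.0 * edge_sigma_um + 4.0 * step_um + z_start_um + 0.15 * thickness_um
    z = np.arange(0.0, z_start_um + thickness_um + pad + step_um / 2, step_um)
    lo, hi = z_start_um, z_start_um + thickness_um
    if edge_sigma_um > 0:
        s = edge_sigma_um * math.sqrt(2.0)
        intensity = 0.5 * peak_intensity * (erf((z - lo) / s) - erf((z - hi) / s))
    else:
        intensity = np.where((z > lo) & (z < hi), peak_intensity, 0.0)
        intensity = np.where((z == lo) | (z == hi), 0.5 * peak_intensity, intensity)
    if noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
        intensity = intensity + rng.normal(0.0, noise_sigma * peak_intensity, z.shape)
    df = pd.DataFrame({"z_um": z, "intensity": intensity})
    df.attrs["true_thickness_um"] = thickness_um
    df.attrs["step_um"] = step_um
    return df
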