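"""End-to-end runs: simulate -> track -> summarize, with built-in scenarios.

The built-in scenarios mirror the experimental arms this package re-analyses
on synthetic ground truth:

``soft_thick`` / ``soft_thin``
    Identical three-cell traction fields on a soft gel (E = 5.5 kPa) of
    200 µm vs 50 µm thickness; displacement amplitudes are attenuated by the
    finite-thickness stiffness factor, so the thin gel deforms less.
``density_1k`` / ``density_5k`` / ``density_20k``
    Poisson-seeded cells at 1000-20 000 cells/cm² on a thick soft gel.  The
    monolayer's total traction budget is held fixed (per-cell strength scales
    as 1/density), a surrogate for the tug-of-war saturation between
    neighbouring cells, so deformations decline with density.
``timecourse_day1`` / ``timecourse_day10`` / ``timecourse_week7``
    Growing cell density (5000 -> 20 000 -> 60 000 cells/cm²) at fixed total
    budget, emulating proliferation during prolonged culture.
``static``
    No cells; used to measure the tracker noise floor.

Scenarios are rendered at one frame per hour: the hourly-pair analysis never
reads the intermediate 5-min frames, so generating them would only add I/O.
Every stage writes its outputs plus a config echo; ``run_all`` adds a
manifest with seeds and content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .cumdisp import StatsConfig, accumulate, group_summary, hourly_pairs, percentile_timecourse, window_average
from .dic_tracker import NodeGrid, TrackParams, build_grid, track_sequence
from .errors import ConfigError, DataError
from .layer_mechanics import LayerSpec, PunchSpec
from .synthgel import CellSpec, SceneConfig, Scenario, render_stack

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SCENARIO_NAMES",
    "make_scenario",
    "run_simulate",
    "run_track",
    "run_summarize",
    "run_all",
]

# per-cell plateau amplitude (µm) at the 1000 cells/cm² reference density;
# density scenarios scale it by 1000/density to keep the total budget fixed
_S_REF_UM = 30.0
_REF_DENSITY = 1000.0

_SOFT_GEL = dict(E=5.5, nu=0.48)
_THICK_CELLS = (
    CellSpec(center_um=(110.0, 120.0), strength_um=16.0, reach_um=100.0, tau_h=8.0),
    CellSpec(center_um=(230.0, 180.0), strength_um=16.0, reach_um=100.0, tau_h=8.0),
    CellSpec(center_um=(150.0, 255.0), strength_um=16.0, reach_um=100.0, tau_h=8.0),
)


def _scene(seed: int, width: int = 512) -> SceneConfig:
    return SceneConfig(
        width_px=width,
        height_px=width,
        cadence_min=60.0,
        duration_h=24.0,
        bead_count=10000 if width == 512 else 40000,
        seed=seed,
    )


def _density_scenario(name: str, density: float, h_um: float, seed: int) -> Scenario:
    return Scenario(
        scene=_scene(seed, width=1024),
        density_cells_per_cm2=density,
        cell_template=CellSpec(
            center_um=(0.0, 0.0),
            strength_um=_S_REF_UM * _REF_DENSITY / density,
            reach_um=100.0,
            tau_h=8.0,
        ),
        gel=LayerSpec(h=h_um, **_SOFT_GEL),
        attenuation_mode="mechanics",
        name=name,
    )


def make_scenario(name: str, seed: int) -> Scenario:
    """Instantiate a built-in scenario with all randomness derived from ``seed``."""
    gel_thick = LayerSpec(h=200.0, **_SOFT_GEL)
    if name == "soft_thick":
        return Scenario(scene=_scene(seed), cells=_THICK_CELLS, gel=gel_thick,
                        attenuation_mode="mechanics", name=name)
    if name == "soft_thin":
        return Scenario(scene=_scene(seed), cells=_THICK_CELLS,
                        gel=LayerSpec(h=50.0, **_SOFT_GEL),
                        attenuation_mode="mechanics", name=name)
    if name == "static":
        return Scenario(scene=_scene(seed), cells=(), gel=gel_thick, name=name)
    if name.startswith("density_"):
        density = {"density_1k": 1000.0, "density_5k": 5000.0, "density_20k": 20000.0}.get(name)
        if density is None:
            raise ConfigError(f"unknown density scenario {name!r}")
        # the density experiment used thick soft gels (~283 µm)
        return _density_scenario(name, density, 283.0, seed)
    if name.startswith("timecourse_"):
        density = {"timecourse_day1": 5000.0, "timecourse_day10": 20000.0,
                   "timecourse_week7": 60000.0}.get(name)
        if density is None:
            raise ConfigError(f"unknown timecourse scenario {name!r}")
        return _density_scenario(name, density, 200.0, seed)
    raise ConfigError(
        f"unknown scenario {name!r}; available: {', '.join(SCENARIO_NAMES)}"
    )


SCENARIO_NAMES = (
    "soft_thick",
    "soft_thin",
    "density_1k",
    "density_5k",
    "density_20k",
    "timecourse_day1",
    "timecourse_day10",
    "timecourse_week7",
    "static",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run needs; fully serialisable."""

    scenario: str = "soft_thick"
    out_dir: str = "gelsense_out"
    seed: int = 0
    n_replicates: int = 3
    grid_cols: int = 10
    grid_rows: int = 8
    lagrangian: bool = True
    track: TrackParams = field(default_factory=TrackParams)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def replicate_seed(self, replicate: int) -> int:
        return (self.seed * 8191 + replicate) % (2**31 - 1)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _echo_yaml(path: Path, payload: dict) -> None:
    path.write_text(yaml.safe_dump(payload, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_simulate(cfg: RunConfig) -> list[Path]:
    """Render every replicate of the scenario: TIFF stack + ground truth CSV."""
    out = Path(cfg.out_dir) / cfg.scenario
    rep_dirs = []
    for rep in range(cfg.n_replicates):
        scenario = make_scenario(cfg.scenario, cfg.replicate_seed(rep))
        scenario = replace(scenario)  # defensive copy
        rep_dir = out / f"rep{rep}"
        rep_dir.mkdir(parents=True, exist_ok=True)
        grid = build_grid(
            cfg.grid_cols, cfg.grid_rows,
            (scenario.scene.height_px, scenario.scene.width_px), cfg.track,
        )
        frames, truth = render_stack(scenario, node_positions_px=grid.positions_px)
        tifffile.imwrite(rep_dir / "stack.tif", frames, photometric="minisblack")
        truth.as_frame().to_csv(rep_dir / "ground_truth.csv", index=False)
        _echo_yaml(rep_dir / "scenario.yaml", {
            "scenario": cfg.scenario,
            "replicate": rep,
            "seed": scenario.scene.seed,
            "scene": dataclasses.asdict(scenario.scene),
            "n_cells": len(scenario.resolve_cells()),
            "gel": dataclasses.asdict(scenario.gel),
            "attenuation_mode": scenario.attenuation_mode,
        })
        rep_dirs.append(rep_dir)
        logger.info("simulated %s rep %d -> %s", cfg.scenario, rep, rep_dir)
    return rep_dirs


def run_track(cfg: RunConfig, stack_path: Path | str) -> Path:
    """Track one rendered stack; writes fields.csv + params.yaml beside it."""
    stack_path = Path(stack_path)
    if not stack_path.exists():
        raise DataError(f"stack not found: {stack_path}")
    frames = tifffile.imread(stack_path)
    scenario_meta = {}
    meta_path = stack_path.parent / "scenario.yaml"
    if meta_path.exists():
        scenario_meta = yaml.safe_load(meta_path.read_text())
    pixel_size = scenario_meta.get("scene", {}).get("pixel_size_um", 0.65)
    cadence = scenario_meta.get("scene", {}).get("cadence_min", cfg.stats.cadence_min)
    stats = replace(cfg.stats, cadence_min=cadence)
    grid = build_grid(cfg.grid_cols, cfg.grid_rows, frames.shape[1:], cfg.track)
    pairs = hourly_pairs(frames.shape[0], stats)
    fields = track_sequence(
        frames, grid, cfg.track, pixel_size_um=pixel_size,
        pairs=pairs, lagrangian=cfg.lagrangian,
    )
    table = pd.concat([f.as_frame() for f in fields], ignore_index=True)
    out_csv = stack_path.parent / "fields.csv"
    table.to_csv(out_csv, index=False)
    _echo_yaml(stack_path.parent / "track_params.yaml", {
        "track": dataclasses.asdict(cfg.track),
        "grid": {"cols": cfg.grid_cols, "rows": cfg.grid_rows, "n_nodes": grid.n_nodes},
        "lagrangian": cfg.lagrangian,
        "pixel_size_um": pixel_size,
        "coordinate_convention": "origin top-left, x=column rightward, y=row downward",
    })
    return out_csv


def _fields_from_csv(path: Path) -> list:
    from .dic_tracker import DisplacementField

    df = pd.read_csv(path)
    fields = []
    for (fa, fb), grp in df.groupby(["frame_a", "frame_b"], sort=True):
        grp = grp.sort_values("node_id")
        disp_um = grp[["ux_um", "uy_um"]].to_numpy()
        fields.append(
            DisplacementField(
                positions_px=grp[["x_px", "y_px"]].to_numpy(),
                disp_px=disp_um,  # px values not needed downstream
                disp_um=disp_um,
                corr=grp["corr"].to_numpy(),
                flags=grp["flag"].to_numpy(),
                frame_pair=(int(fa), int(fb)),
            )
        )
    if not fields:
        raise DataError(f"no intervals found in {path}")
    return fields


def run_summarize(cfg: RunConfig, field_csvs: list[Path | str]) -> dict:
    """Cumulative traces, pooled percentile time course and window mean.

    Writes per-replicate ``trace.csv``, a pooled ``summary.csv`` and returns
    the per-replicate window means with the pooled window mean.
    """
    stats = cfg.stats
    traces = []
    rep_means = []
    for path in field_csvs:
        path = Path(path)
        fields = _fields_from_csv(path)
        trace = accumulate(fields, stats)
        trace.to_csv(path.parent / "trace.csv", index=False)
        traces.append(trace)
        rep_means.append(window_average(percentile_timecourse([trace], stats), stats))
    summary = percentile_timecourse(traces, stats)
    first = Path(field_csvs[0]).parent.parent
    summary.to_csv(first / "summary.csv", index=False)
    _echo_yaml(first / "stats_config.yaml", dataclasses.asdict(stats))
    pooled_mean = window_average(summary, stats)
    return {
        "summary": summary,
        "window_mean_um": pooled_mean,
        "replicate_window_means_um": rep_means,
    }


def run_all(cfg: RunConfig) -> dict:
    """Full chain for one scenario; writes group.csv and a manifest."""
    rep_dirs = run_simulate(cfg)
    field_csvs = [run_track(cfg, d / "stack.tif") for d in rep_dirs]
    result = run_summarize(cfg, field_csvs)
    out = Path(cfg.out_dir) / cfg.scenario
    group = group_summary({cfg.scenario: result["replicate_window_means_um"]})
    group.to_csv(out / "group.csv", index=False)
    manifest = {
        "gelsense_version": __version__,
        "config": cfg.as_dict(),
        "seeds": [cfg.replicate_seed(r) for r in range(cfg.n_replicates)],
        "window_mean_um": result["window_mean_um"],
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {**result, "group": group, "manifest": manifest, "out_dir": out}
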