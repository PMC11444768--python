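"""Cumulative-displacement summary statistics.

The experimental read-out this package reproduces is not a traction map but a
simple, robust summary of how much the gel surface has moved: per grid node,
displacement increments between images one hour apart are accumulated from
the first frame; at each hourly time point the 90th percentile across all
nodes (pooled over replicate gels) summarises the deformation, with the
standard deviation across replicate-level percentiles as the error bar; and a
single window average (default 8-24 h, where the time course has plateaued)
condenses each condition to one number.

Accumulation modes
------------------
``path`` (default)
    C_k = sum over j <= k of |du_j| — the path length of the node's motion,
    nondecreasing in time even under oscillatory motion.
``net``
    C_k = |sum over j <= k of du_j| — magnitude of the net displacement.
Path dominates net pointwise (triangle inequality), with equality when the
interval vectors are nonnegatively collinear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dic_tracker import DisplacementField
from .errors import ConfigError, DataError

__all__ = [
    "StatsConfig",
    "hourly_pairs",
    "accumulate",
    "percentile_timecourse",
    "window_average",
    "group_summary",
]


@dataclass(frozen=True)
class StatsConfig:
    """Timing and summary parameters for the statistics stage."""

    cadence_min: float = 5.0
    pair_interval_h: float = 1.0
    window_start_h: float = 8.0
    window_end_h: float = 24.0
    accumulation_mode: str = "path"
    percentile: float = 90.0

    def __post_init__(self) -> None:
        if self.cadence_min <= 0 or self.pair_interval_h <= 0:
            raise ConfigError("cadence and pair interval must be positive")
        if not self.window_start_h < self.window_end_h:
            raise ConfigError(
                f"window start {self.window_start_h} must precede end {self.window_end_h}"
            )
        if self.accumulation_mode not in ("path", "net"):
            raise ConfigError(
                f"accumulation_mode must be 'path' or 'net', got {self.accumulation_mode!r}"
            )
        if not 0 < self.percentile <= 100:
            raise ConfigError("percentile must be in (0, 100]")

    @property
    def frames_per_pair(self) -> int:
        step = self.pair_interval_h * 60.0 / self.cadence_min
        if abs(step - round(step)) > 1e-9 or round(step) < 1:
            raise ConfigError(
                f"pair interval {self.pair_interval_h} h is not a whole number of "
                f"{self.cadence_min}-min frames"
            )
        return int(round(step))


def hourly_pairs(n_frames: int, cfg: StatsConfig) -> list[tuple[int, int]]:
    """Chained frame-index pairs one ``pair_interval_h`` apart.

    With the standard 5-min cadence over 24 h (289 frames) this yields the 24
    consecutive hourly intervals (0,12), (12,24), ..., (276,288).
    """
    step = cfg.frames_per_pair
    if n_frames < step + 1:
        raise ConfigError(
            f"{n_frames} frames cannot form a {cfg.pair_interval_h} h pair "
            f"at {cfg.cadence_min} min cadence"
        )
    return [(k * step, (k + 1) * step) for k in range((n_frames - 1) // step)]


def _interval_table(fields: list[DisplacementField]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-interval displacement vectors into (n_intervals, n_nodes, 2) µm."""
    if not fields:
        raise DataError("no displacement fields given")
    n_nodes = fields[0].disp_um.shape[0]
    out = np.empty((len(fields), n_nodes, 2))
    for k, fld in enumerate(fields):
        if fld.disp_um.shape[0] != n_nodes:
            raise DataError(
                f"interval {k} (frames {fld.frame_pair}) has {fld.disp_um.shape[0]} "
                f"nodes, expected {n_nodes}"
            )
        out[k] = fld.disp_um
    node_ids = np.arange(n_nodes)
    return out, node_ids


def accumulate(
    fields: list[DisplacementField], cfg: StatsConfig | None = None
) -> pd.DataFrame:
    """Cumulative displacement per node at each pair time point.

    Returns a tidy DataFrame (node_id, t_h, C_um); time of interval k is
    ``(k + 1) * pair_interval_h``.
    """
    cfg = cfg or StatsConfig()
    du, node_ids = _interval_table(fields)
    if cfg.accumulation_mode == "path":
        cum = np.cumsum(np.linalg.norm(du, axis=2), axis=0)
    else:
        cum = np.linalg.norm(np.cumsum(du, axis=0), axis=2)
    n_int, n_nodes = cum.shape
    t = (np.arange(n_int) + 1) * cfg.pair_interval_h
    return pd.DataFrame(
        {
            "node_id": np.tile(node_ids, n_int),
            "t_h": np.repeat(t, n_nodes),
            "C_um": cum.ravel(),
        }
    )


def percentile_timecourse(
    traces: list[pd.DataFrame], cfg: StatsConfig | None = None
) -> pd.DataFrame:
    """Percentile time course pooled over replicates.

    At each time point: the ``cfg.percentile``-th percentile (linear
    interpolation between order statistics) of all node values pooled across
    replicates, the sample SD (ddof=1) across per-replicate percentiles, and
    for reference the SD across pooled node values.  Columns:
    ``t_h, p90_um, sd_um, sd_nodes_um, n_replicates``.
    """
    cfg = cfg or StatsConfig()
    if not traces:
        raise DataError("need at least one replicate trace")
    times = np.asarray(sorted(traces[0]["t_h"].unique()))
    rows = []
    for t in times:
        per_rep = []
        pooled = []
        for rep in traces:
            vals = rep.loc[rep["t_h"] == t, "C_um"].to_numpy()
            if vals.size == 0:
                raise DataError(f"replicate missing time point {t} h")
            per_rep.append(np.percentile(vals, cfg.percentile))
            pooled.append(vals)
        pooled = np.concatenate(pooled)
        sd = float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else 0.0
        rows.append(
            {
                "t_h": t,
                "p90_um": float(np.percentile(pooled, cfg.percentile)),
                "sd_um": sd,
                "sd_nodes_um": float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0,
                "n_replicates": len(traces),
            }
        )
    return pd.DataFrame(rows)


def window_average(summary: pd.DataFrame, cfg: StatsConfig | None = None) -> float:
    """Unweighted mean of the percentile values with window_start <= t <= window_end."""
    cfg = cfg or StatsConfig()
    sel = summary[
        (summary["t_h"] >= cfg.window_start_h - 1e-9)
        & (summary["t_h"] <= cfg.window_end_h + 1e-9)
    ]
    if sel.empty:
        raise DataError(
            f"no time points inside window [{cfg.window_start_h}, {cfg.window_end_h}] h"
        )
    return float(sel["p90_um"].mean())


def group_summary(window_means: dict[str, list[float]]) -> pd.DataFrame:
    """Descriptive per-condition table: condition, mean_um, sd_um, n.

    ``window_means`` maps condition name to the per-replicate window means.
    Rows are ordered by condition name for stable output.
    """
    rows = []
    for cond in sorted(window_means):
        vals = np.asarray(window_means[cond], dtype=float)
        rows.append(
            {
                "condition": cond,
                "mean_um": float(vals.mean()),
                "sd_um": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows)
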