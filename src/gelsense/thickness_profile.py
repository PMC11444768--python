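"""Hydrogel thickness from a confocal z-stack intensity profile.

A fluorescently labelled gel slab imaged in z yields a boxcar-like intensity
profile; thickness is read off as the distance between the half-maximum
crossings (an FWHM-style slab measurement).  The baseline is the median of
the lowest decile of samples, so a constant autofluorescence offset does not
bias the estimate, and crossings are located by linear interpolation between
samples, so the estimate is not quantised to the z-step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = ["ZProfile", "ThicknessReport", "estimate_thickness"]


@dataclass(frozen=True)
class ZProfile:
    """A (z, intensity) table; z strictly increasing, at least 5 samples."""

    z_um: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_um, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if z.size != i.size:
            raise DataError("z and intensity must have equal length")
        if z.size < 5:
            raise DataError(f"need at least 5 samples, got {z.size}")
        if np.any(np.diff(z) <= 0):
            raise DataError("z must be strictly increasing")
        object.__setattr__(self, "z_um", z)
        object.__setattr__(self, "intensity", i)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ZProfile":
        return cls(df["z_um"].to_numpy(), df["intensity"].to_numpy())

    @property
    def step_um(self) -> float:
        return float(np.median(np.diff(self.z_um)))


@dataclass(frozen=True)
class ThicknessReport:
    """Thickness estimate with the crossing positions and plateau SNR."""

    thickness_um: float
    z_up_um: float
    z_down_um: float
    baseline: float
    peak: float
    plateau_snr: float
    threshold_frac: float

    def as_dict(self) -> dict:
        return {
            "thickness_um": self.thickness_um,
            "z_up_um": self.z_up_um,
            "z_down_um": self.z_down_um,
            "baseline": self.baseline,
            "peak": self.peak,
            "plateau_snr": self.plateau_snr,
            "threshold_frac": self.threshold_frac,
        }


def _crossing(z: np.ndarray, y: np.ndarray, i: int, level: float) -> float:
    """Linear interpolation of the crossing of ``level`` between samples i, i+1."""
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return float(z[i])
    return float(z[i] + (level - y0) / (y1 - y0) * (z[i + 1] - z[i]))


def estimate_thickness(profile: ZProfile, threshold_frac: float = 0.5) -> ThicknessReport:
    """Slab thickness as the width between threshold crossings.

    The intensity is normalised to [baseline, max] where the baseline is the
    median of the lowest 10% of samples; the first upward and last downward
    crossing of ``threshold_frac`` are interpolated linearly and their
    separation is the thickness.  Requires a clear plateau (max > 3x
    baseline scale); a profile with several separate plateaus is rejected
    with the candidate intervals named.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ConfigError("threshold_frac must be in (0, 1)")
    z, y = profile.z_um, profile.intensity
    n_low = max(1, y.size // 10)
    baseline = float(np.median(np.sort(y)[:n_low]))
    peak = float(y.max())
    noise = float(np.std(np.sort(y)[:n_low], ddof=0)) or 1e-12
    if peak <= 3.0 * abs(baseline) and peak - baseline <= 3.0 * noise:
        raise DataError(
            f"no slab detected: peak {peak:.3g} not above 3x baseline {baseline:.3g}"
        )
    norm = (y - baseline) / (peak - baseline)
    above = norm >= threshold_frac

    # contiguous above-threshold runs; single-sample noise spikes are ignored
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, above.size - 1))
    runs = [r for r in runs if r[1] > r[0]]
    if not runs:
        raise DataError("no slab detected: no two threshold crossings found")
    if len(runs) > 1:
        intervals = ", ".join(f"[{z[a]:.1f}, {z[b]:.1f}] um" for a, b in runs)
        raise DataError(f"multiple plateaus detected: {intervals}")

    a, b = runs[0]
    if a == 0 or b == above.size - 1:
        raise DataError("no slab detected: plateau touches the profile boundary")
    z_up = _crossing(z, norm, a - 1, threshold_frac)
    z_down = _crossing(z, norm, b, threshold_frac)
    return ThicknessReport(
        thickness_um=z_down - z_up,
        z_up_um=z_up,
        z_down_um=z_down,
        baseline=baseline,
        peak=peak,
        plateau_snr=(peak - baseline) / (3.0 * noise) if noise > 0 else float("inf"),
        threshold_frac=threshold_frac,
    )
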