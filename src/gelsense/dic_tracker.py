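"""Digital image correlation on a node lattice.

Displacements of the bead-speckled gel surface are tracked between frames by
zero-normalized cross-correlation of a square template around each grid node,
searched over integer offsets within ``max_move`` pixels, refined to sub-pixel
precision by a least-squares quadratic fit to the correlation peak, and
spatially regularised by blending each node with a Gaussian-weighted average
of its neighbours.

Default parameters are those used for the experimental analysis this package
reproduces: kernel size 31, sub-pixel window 9, smoothness 5, max move 6,
smoothing length 25 px, on a 10 x 8 grid of cells (99 nodes).  Exact
behavioural equivalence with the original MATLAB tracker is not claimed; the
parameter semantics follow standard DIC vocabulary and are documented on
:class:`TrackParams`.

Coordinates: origin at the top-left pixel centre, x = column index increasing
rightward, y = row index increasing downward; node positions are sub-pixel
floats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import match_template

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "TrackParams",
    "NodeGrid",
    "DisplacementField",
    "FLAG_OK",
    "FLAG_CLAMPED",
    "FLAG_LOW_CORR",
    "FLAG_FALLBACK",
    "build_grid",
    "track_pair",
    "track_sequence",
]

FLAG_OK = "ok"
FLAG_CLAMPED = "clamped"
FLAG_LOW_CORR = "low_corr"
FLAG_FALLBACK = "fallback"


@dataclass(frozen=True)
class TrackParams:
    """DIC tracking parameters.

    kernel_size
        Template width in px (odd).
    subpixel_window
        Width of the correlation neighbourhood used for the quadratic
        sub-pixel fit (odd; clipped at the search bounds).
    smoothness
        Blend weight of the neighbour-smoothed field:
        ``u = (u_raw + smoothness * u_neigh) / (1 + smoothness)``;
        0 disables smoothing exactly.
    max_move
        Half-width of the integer search range in px.
    smooth_grid
        Gaussian length scale (px) of the neighbour weighting.
    min_corr
        Peak-correlation floor: a node whose best match correlates below
        this is a speckle mismatch, not a measurement; it is flagged
        ``low_corr`` and takes the smoothed neighbour estimate.
    outlier_r
        Threshold of the normalized-median consistency test (the standard
        vector-field validation in particle-image velocimetry); nodes whose
        residual against the neighbourhood median exceeds it are likewise
        flagged ``low_corr`` and replaced.  Set to ``inf`` to disable.
    """

    kernel_size: int = 31
    subpixel_window: int = 9
    smoothness: float = 5.0
    max_move: int = 6
    smooth_grid: float = 25.0
    min_corr: float = 0.2
    outlier_r: float = 2.5

    def __post_init__(self) -> None:
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ConfigError(f"kernel_size must be an odd int >= 3, got {self.kernel_size}")
        if self.subpixel_window < 3 or self.subpixel_window % 2 == 0:
            raise ConfigError(f"subpixel_window must be an odd int >= 3, got {self.subpixel_window}")
        if self.smoothness < 0:
            raise ConfigError("smoothness must be nonnegative")
        if self.max_move < 1:
            raise ConfigError("max_move must be a positive integer")
        if self.smooth_grid <= 0:
            raise ConfigError("smooth_grid must be positive")
        if not 0.0 <= self.min_corr < 1.0:
            raise ConfigError("min_corr must be in [0, 1)")
        if self.outlier_r <= 0:
            raise ConfigError("outlier_r must be positive")

    @property
    def margin_px(self) -> int:
        """Inset needed so template + search window fit inside the image."""
        return self.kernel_size // 2 + self.max_move + 1


@dataclass(frozen=True)
class NodeGrid:
    """Evenly spaced tracking lattice: (n_cols_cells+1) x (n_rows_cells+1) nodes."""

    n_cols_cells: int
    n_rows_cells: int
    positions_px: np.ndarray  # (N, 2) float, (x, y)
    margin_px: int

    @property
    def n_nodes(self) -> int:
        return self.positions_px.shape[0]


@dataclass
class DisplacementField:
    """Per-node displacements for one frame interval.

    ``disp_px``/``disp_um`` are (N, 2) arrays (x, y); ``corr`` holds the peak
    correlation per node and ``flags`` the per-node quality flag.
    ``positions_px`` records where each template was anchored (the advected
    node position in Lagrangian tracking).
    """

    positions_px: np.ndarray
    disp_px: np.ndarray
    disp_um: np.ndarray
    corr: np.ndarray
    flags: np.ndarray
    frame_pair: tuple[int, int] = (0, 1)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_a": self.frame_pair[0],
                "frame_b": self.frame_pair[1],
                "node_id": np.arange(self.positions_px.shape[0]),
                "x_px": self.positions_px[:, 0],
                "y_px": self.positions_px[:, 1],
                "ux_um": self.disp_um[:, 0],
                "uy_um": self.disp_um[:, 1],
                "corr": self.corr,
                "flag": self.flags,
            }
        )


def build_grid(
    n_cols_cells: int,
    n_rows_cells: int,
    image_shape: tuple[int, int],
    params: TrackParams | None = None,
) -> NodeGrid:
    """Evenly spaced node lattice inset so every search window fits.

    A grid of ``n_cols_cells x n_rows_cells`` cells has
    ``(n_cols_cells + 1) * (n_rows_cells + 1)`` nodes — the standard 10 x 8
    grid yields 99.  ``image_shape`` is (rows, cols).
    """
    params = params or TrackParams()
    if n_cols_cells < 1 or n_rows_cells < 1:
        raise ConfigError("grid must have at least one cell in each direction")
    h, w = image_shape
    m = params.margin_px
    min_size = 2 * m + max(n_cols_cells, n_rows_cells) + 1
    if w - 1 - 2 * m < n_cols_cells or h - 1 - 2 * m < n_rows_cells:
        raise ConfigError(
            f"image {w}x{h} too small for a {n_cols_cells}x{n_rows_cells} grid "
            f"with margin {m} px; need at least {min_size}x{min_size}"
        )
    xs = np.linspace(m, w - 1 - m, n_cols_cells + 1)
    ys = np.linspace(m, h - 1 - m, n_rows_cells + 1)
    gx, gy = np.meshgrid(xs, ys)
    positions = np.column_stack([gx.ravel(), gy.ravel()])
    return NodeGrid(n_cols_cells, n_rows_cells, positions, m)


def _quadratic_subpixel(corr: np.ndarray, peak: tuple[int, int], window: int) -> tuple[float, float] | None:
    """Least-squares 2-D quadratic peak fit around the integer peak.

    The correlation peak of a Gaussian-spot speckle is itself near-Gaussian,
    so the quadratic is fitted to log-correlation (exact for a Gaussian peak;
    a fit to raw values systematically shrinks the sub-pixel fraction),
    weighted by correlation squared to concentrate on the peak.  Where too few
    strictly positive samples exist the fit falls back to raw values.
    Returns the sub-pixel offset, or None when the fitted surface is not
    concave (the caller then falls back to a centroid).
    """
    py, px = peak
    # symmetric clipping at the search bounds: an asymmetric sample of the
    # (non-quadratic) peak drags the fitted vertex toward the far side
    hwy = min(window // 2, py, corr.shape[0] - 1 - py)
    hwx = min(window // 2, px, corr.shape[1] - 1 - px)
    if hwy < 1 or hwx < 1:
        return None
    patch = corr[py - hwy : py + hwy + 1, px - hwx : px + hwx + 1]
    ys, xs = np.mgrid[-hwy : hwy + 1, -hwx : hwx + 1]
    dx = xs.ravel().astype(float)
    dy = ys.ravel().astype(float)
    v = patch.ravel()
    A = np.column_stack([np.ones_like(dx), dx, dy, dx**2, dx * dy, dy**2])

    pos = v > 1e-3 * v.max()
    if pos.sum() >= 6:
        w = np.sqrt(np.clip(v[pos], 0.0, None) ** 2)
        coef, *_ = np.linalg.lstsq(A[pos] * w[:, None], np.log(v[pos]) * w, rcond=None)
    else:
        coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    _, c1, c2, c3, c4, c5 = coef
    hess = np.array([[2 * c3, c4], [c4, 2 * c5]])
    if not (hess[0, 0] < 0 and np.linalg.det(hess) > 0):
        return None
    sub = np.linalg.solve(hess, -np.array([c1, c2]))
    if np.any(np.abs(sub) > 1.0):  # fit ran away from the peak; distrust it
        return None
    return float(sub[0]), float(sub[1])


def _centroid_subpixel(corr: np.ndarray, peak: tuple[int, int], window: int) -> tuple[float, float]:
    py, px = peak
    hwy = max(1, min(window // 2, py, corr.shape[0] - 1 - py))
    hwx = max(1, min(window // 2, px, corr.shape[1] - 1 - px))
    y0, y1 = max(0, py - hwy), min(corr.shape[0], py + hwy + 1)
    x0, x1 = max(0, px - hwx), min(corr.shape[1], px + hwx + 1)
    patch = corr[y0:y1, x0:x1] - corr[y0:y1, x0:x1].min()
    total = patch.sum()
    if total <= 0:
        return 0.0, 0.0
    ys, xs = np.mgrid[y0:y1, x0:x1]
    return (
        float(np.clip((patch * (xs - px)).sum() / total, -1, 1)),
        float(np.clip((patch * (ys - py)).sum() / total, -1, 1)),
    )


def _argmax_tiebreak(corr: np.ndarray) -> tuple[int, int]:
    """Integer peak; ties broken by smallest |offset|, then lexicographic (dx, dy)."""
    m = corr.shape[0] // 2
    best = corr.max()
    cand = np.argwhere(corr >= best - 1e-12)
    off = cand - m  # rows are (dy, dx)
    order = np.lexsort((off[:, 0], off[:, 1], np.abs(off).sum(axis=1)))
    py, px = cand[order[0]]
    return int(py), int(px)


def track_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    grid: NodeGrid,
    params: TrackParams | None = None,
    pixel_size_um: float = 1.0,
    positions_px: np.ndarray | None = None,
    frame_pair: tuple[int, int] = (0, 1),
) -> DisplacementField:
    """Track every grid node from ``frame_a`` to ``frame_b``.

    Per node: extract a ``kernel_size`` square template from ``frame_a``,
    zero-normalized cross-correlation against ``frame_b`` over integer offsets
    in [-max_move, max_move]^2, sub-pixel refinement by quadratic fit
    (centroid fallback, flag ``fallback``), then Gaussian neighbour smoothing
    blended with weight ``smoothness``.  Blank templates are flagged
    ``low_corr`` and take the smoothed neighbour estimate; peaks on the search
    border are flagged ``clamped``.
    """
    params = params or TrackParams()
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise DataError(f"frame shapes differ: {frame_a.shape} vs {frame_b.shape}")
    pos = np.asarray(positions_px if positions_px is not None else grid.positions_px, dtype=float)
    n = pos.shape[0]
    hk = params.kernel_size // 2
    mm = params.max_move
    h, w = frame_a.shape

    raw = np.zeros((n, 2))
    corr_peak = np.zeros(n)
    flags = np.array([FLAG_OK] * n, dtype=object)
    valid = np.ones(n, dtype=bool)

    for i, (x, y) in enumerate(pos):
        cx, cy = int(round(x)), int(round(y))
        if cx - hk - mm < 0 or cy - hk - mm < 0 or cx + hk + mm >= w or cy + hk + mm >= h:
            flags[i] = FLAG_CLAMPED
            valid[i] = False
            continue
        template = frame_a[cy - hk : cy + hk + 1, cx - hk : cx + hk + 1]
        if template.std() == 0:
            flags[i] = FLAG_LOW_CORR
            valid[i] = False
            continue
        search = frame_b[cy - hk - mm : cy + hk + mm + 1, cx - hk - mm : cx + hk + mm + 1]
        corr = match_template(search, template)  # (2mm+1, 2mm+1) ZNCC surface
        py, px = _argmax_tiebreak(corr)
        corr_peak[i] = corr[py, px]
        if corr_peak[i] < params.min_corr:
            flags[i] = FLAG_LOW_CORR
            valid[i] = False
            continue
        if py in (0, 2 * mm) or px in (0, 2 * mm):
            flags[i] = FLAG_CLAMPED
            raw[i] = (px - mm, py - mm)
            continue
        sub = _quadratic_subpixel(corr, (py, px), params.subpixel_window)
        if sub is None:
            sub = _centroid_subpixel(corr, (py, px), params.subpixel_window)
            flags[i] = FLAG_FALLBACK
        raw[i] = (px - mm + sub[0], py - mm + sub[1])

    # normalized-median consistency test: a node far from its neighbourhood
    # median (relative to the neighbourhood scatter) is a mismatch
    contribute = valid | (flags == FLAG_CLAMPED)
    if np.isfinite(params.outlier_r) and contribute.sum() >= 5:
        reject = _median_test(pos, raw, contribute, params)
        flags[reject] = FLAG_LOW_CORR
        valid[reject] = False
        contribute &= ~reject

    smoothed = _gaussian_neighbour_average(pos, raw, contribute, params.smooth_grid)
    s = params.smoothness
    disp = raw.copy()
    if s > 0:
        disp[contribute] = (raw[contribute] + s * smoothed[contribute]) / (1.0 + s)
    disp[~contribute] = smoothed[~contribute]

    return DisplacementField(
        positions_px=pos.copy(),
        disp_px=disp,
        disp_um=disp * pixel_size_um,
        corr=corr_peak,
        flags=flags,
        frame_pair=frame_pair,
    )


def _median_test(
    pos: np.ndarray, raw: np.ndarray, contribute: np.ndarray, params: TrackParams
) -> np.ndarray:
    """Normalized-median outlier detection on the raw displacement field.

    For each node, the residual of its raw vector against the median of the
    nearest contributing neighbours is normalized by the neighbourhood's
    median residual; values above ``params.outlier_r`` mark a mismatch.
    """
    eps = 0.1  # px; regularises the test where the neighbourhood is quiet
    n = pos.shape[0]
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    d2[:, ~contribute] = np.inf
    reject = np.zeros(n, dtype=bool)
    for i in range(n):
        if not contribute[i]:
            continue
        neigh = np.argsort(d2[i])[:8]
        neigh = neigh[np.isfinite(d2[i][neigh])]
        if neigh.size < 4:
            continue
        med = np.median(raw[neigh], axis=0)
        res_neigh = np.median(np.abs(raw[neigh] - med), axis=0)
        r = np.abs(raw[i] - med) / (res_neigh + eps)
        if r.max() > params.outlier_r:
            reject[i] = True
    return reject


def _gaussian_neighbour_average(
    pos: np.ndarray, raw: np.ndarray, contribute: np.ndarray, smooth_grid: float
) -> np.ndarray:
    """Leave-one-out Gaussian-weighted average of neighbouring raw displacements."""
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    wgt = np.exp(-d2 / (2.0 * smooth_grid**2))
    np.fill_diagonal(wgt, 0.0)
    wgt[:, ~contribute] = 0.0
    norm = wgt.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return (wgt @ raw) / norm


def track_sequence(
    frames: np.ndarray,
    grid: NodeGrid,
    params: TrackParams | None = None,
    pixel_size_um: float = 1.0,
    pairs: list[tuple[int, int]] | None = None,
    lagrangian: bool = True,
) -> list[DisplacementField]:
    """Track a chain of frame pairs, following material points.

    ``pairs`` defaults to consecutive frames; with ``lagrangian=True``
    (default) each node's template is re-anchored at its advected position so
    the same material point is followed across intervals.  A node advected
    too close to the border is frozen and flagged ``clamped``.
    """
    params = params or TrackParams()
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise DataError("need a stack of at least two frames")
    if pairs is None:
        pairs = [(k, k + 1) for k in range(frames.shape[0] - 1)]
    h, w = frames.shape[1:]
    m = params.margin_px
    current = grid.positions_px.copy()
    frozen = np.zeros(current.shape[0], dtype=bool)
    fields: list[DisplacementField] = []
    for a, b in pairs:
        fld = track_pair(
            frames[a], frames[b], grid, params,
            pixel_size_um=pixel_size_um, positions_px=current, frame_pair=(a, b),
        )
        fld.flags[frozen] = FLAG_CLAMPED
        fld.disp_px[frozen] = 0.0
        fld.disp_um[frozen] = 0.0
        fields.append(fld)
        if lagrangian:
            nxt = current + fld.disp_px
            # freeze only when the template+search window would actually leave
            # the frame (track_pair rounds the anchor, hence the 1.5 px slack)
            lo = m - 1.5
            out = (
                (nxt[:, 0] < lo) | (nxt[:, 0] > w - 1 - lo)
                | (nxt[:, 1] < lo) | (nxt[:, 1] > h - 1 - lo)
            )
            newly = out & ~frozen
            if newly.any():
                logger.warning("%d node(s) advected out of bounds; frozen", int(newly.sum()))
            frozen |= out
            current = np.where(frozen[:, None], current, nxt)
    return fields
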