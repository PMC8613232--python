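"""Fractal-dimension comparators for vessel skeletons.

Two standard estimators: grid box counting and a generalised sandbox
method producing the D_q spectrum.  These are comparators to the
alpha-shape descriptors, not replications of any particular published
multifractal pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateInputError
from .morphology import Skeleton

logger = logging.getLogger(__name__)

__all__ = ["FDResult", "box_counting_fd", "sandbox_fd", "default_scales", "default_radii"]

DEFAULT_Q = tuple(q for q in range(-5, 6) if q != 1)


@dataclass(frozen=True)
class FDResult:
    fd: float
    method: str
    scales: np.ndarray
    counts_or_masses: np.ndarray
    fit_r2: float
    q_values: tuple | None = None
    dq: dict | None = None  # q -> D_q (sandbox only)


def _as_grid(skel) -> np.ndarray:
    grid = skel.grid if isinstance(skel, Skeleton) else np.asarray(skel, bool)
    if not grid.any():
        raise DegenerateInputError("fractal dimension of an empty raster is undefined")
    return grid


def default_scales(grid: np.ndarray) -> np.ndarray:
    """Powers of 2 from 2 up to min(height, width) / 4."""
    top = min(grid.shape) // 4
    scales = []
    s = 2
    while s <= top:
        scales.append(s)
        s *= 2
    return np.array(scales, dtype=int)


def default_radii(grid: np.ndarray) -> np.ndarray:
    """Geometric radii from 4 to min(height, width) / 4."""
    top = min(grid.shape) / 4
    return np.unique(np.round(np.geomspace(4, top, 8)).astype(int))


def _loglog_slope(x, y):
    lx, ly = np.log(x), np.log(y)
    A = np.vstack([lx, np.ones_like(lx)]).T
    coef, res, *_ = np.linalg.lstsq(A, ly, rcond=None)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    ss_res = float(res[0]) if len(res) else float(((ly - A @ coef) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(coef[0]), r2


def box_counting_fd(skel, scales=None) -> FDResult:
    """Box-counting dimension: -slope of log(occupied boxes) vs log(box size).

    Box grids are anchored at the raster origin, so translating the pattern
    by whole box sizes leaves every count unchanged.
    """
    grid = _as_grid(skel)
    scales = default_scales(grid) if scales is None else np.asarray(scales, int)
    if len(scales) < 4:
        raise ValueError(f"need >= 4 scales for the log-log fit, got {len(scales)}")
    counts = np.empty(len(scales), dtype=float)
    for i, s in enumerate(scales):
        h = -(-grid.shape[0] // s) * s
        w = -(-grid.shape[1] // s) * s
        padded = np.zeros((h, w), dtype=bool)
        padded[: grid.shape[0], : grid.shape[1]] = grid
        boxes = padded.reshape(h // s, s, w // s, s).any(axis=(1, 3))
        counts[i] = boxes.sum()
    slope, r2 = _loglog_slope(scales, counts)
    return FDResult(
        fd=-slope, method="box_counting", scales=scales,
        counts_or_masses=counts, fit_r2=r2,
    )


def sandbox_fd(
    skel,
    radii=None,
    q_values: tuple = DEFAULT_Q,
    n_centers: int = 100,
    seed: int = 0,
) -> FDResult:
    """Generalised sandbox D_q spectrum from seeded random centres.

    For q != 1, D_q is the slope of ``log<(M(r)/N)^(q-1)>/(q-1)`` against
    ``log r``, where M(r) is the foreground mass within Euclidean radius r of
    a centre and the average runs over centres whose radius-r disc stays
    inside the raster (edge-crossing centres are excluded per radius).  The
    headline ``fd`` is D_0.
    """
    grid = _as_grid(skel)
    radii = default_radii(grid) if radii is None else np.asarray(radii, float)
    if 0 in q_values or any(q == 1 for q in q_values):
        q_values = tuple(q for q in q_values if q != 1)
    if 0 not in q_values:
        q_values = (0,) + tuple(q_values)
    coords = np.argwhere(grid)
    n_total = len(coords)
    if n_total < n_centers:
        raise DegenerateInputError(
            f"requested {n_centers} centres but only {n_total} foreground pixels"
        )
    rng = np.random.default_rng(seed)
    centers = coords[rng.choice(n_total, size=n_centers, replace=False)]
    tree = cKDTree(coords)
    h, w = grid.shape
    masses = np.full((n_centers, len(radii)), np.nan)
    for j, r in enumerate(radii):
        inside = (
            (centers[:, 0] >= r) & (centers[:, 0] <= h - 1 - r)
            & (centers[:, 1] >= r) & (centers[:, 1] <= w - 1 - r)
        )
        if inside.sum() < 3:
            logger.warning("radius %s exits the raster for most centres; skipped", r)
            continue
        counts = tree.query_ball_point(centers[inside], r, return_length=True)
        masses[inside, j] = counts
    usable = ~np.all(np.isnan(masses), axis=0)
    radii_u = radii[usable]
    dq = {}
    for q in q_values:
        y = np.empty(len(radii_u))
        for j, col in enumerate(np.flatnonzero(usable)):
            m = masses[:, col]
            m = m[~np.isnan(m)] / n_total
            y[j] = np.mean(m ** (q - 1))
        slope, _ = _loglog_slope(radii_u, y)
        dq[q] = slope / (q - 1)
    slope0, r2 = _loglog_slope(
        radii_u,
        [np.nanmean((masses[:, c] / n_total) ** (-1)) for c in np.flatnonzero(usable)],
    )
    return FDResult(
        fd=dq[0], method="sandbox", scales=radii_u,
        counts_or_masses=masses[:, usable], fit_r2=r2,
        q_values=tuple(sorted(dq)), dq=dq,
    )
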