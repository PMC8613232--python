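"""Per-image alpha-shape descriptors.

Four scalars summarise a vessel skeleton:

* ``op_alpha_min`` — minimum alpha giving a single all-covering region
  (complexity; smaller means a more complex vasculature),
* ``op_area`` — area of that optimum shape (spread),
* ``vs`` — vessel shape, the exact quotient ``op_area / op_alpha_min``,
* ``grad_alpha`` — slope of a robust line fitted to VS against the
  percentage of skeleton pixels remaining across spur-erosion iterations
  (lower values indicate many small terminal branches).

The robust line is an M-estimate with Tukey bisquare weights (tuning
constant 4.685), scale from the median absolute deviation, iterated to a
coefficient change below 1e-8 or 50 iterations, starting from ordinary
least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .geometry import PointSet
from .morphology import ErosionSeries, Mask, Skeleton, erosion_series, skeletonize
from .optimal_alpha import find_optimal_alpha

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorRecord",
    "RobustLine",
    "vessel_shape",
    "robust_line_fit",
    "vs_curve",
    "grad_alpha",
    "grad_alpha_from_curve",
    "compute_descriptors",
]

TUKEY_C = 4.685
_MAD_TO_SIGMA = 0.6744897501960817  # Phi^-1(0.75); MAD / this ~ sigma


@dataclass(frozen=True)
class RobustLine:
    slope: float
    intercept: float
    weights: np.ndarray
    converged: bool
    n_iterations: int


@dataclass(frozen=True)
class DescriptorRecord:
    """One image's descriptor row; ``vs == op_area / op_alpha_min`` exactly."""

    image_id: str
    op_alpha_min: float
    op_area: float
    vs: float
    grad_alpha: float
    fd: float | None = None
    group_label: str | None = None

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "op_alpha_min": self.op_alpha_min,
            "op_area": self.op_area,
            "vs": self.vs,
            "grad_alpha": self.grad_alpha,
            "fd": self.fd,
            "group_label": self.group_label,
        }


def vessel_shape(op_area: float, op_alpha_min: float) -> float:
    """VS = OpA / Op-alpha-min (area over refinement scale)."""
    if op_alpha_min <= 0:
        raise ValueError(f"op_alpha_min must be positive, got {op_alpha_min}")
    return op_area / op_alpha_min


def _wls_line(x, y, w):
    sw = w.sum()
    if sw <= 0:
        raise DegenerateInputError("all robust weights vanished")
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 0:
        raise DegenerateInputError("undefined slope: no spread in x")
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return slope, ym - slope * xm


def robust_line_fit(
    x, y, *, c: float = TUKEY_C, max_iter: int = 50, tol: float = 1e-8
) -> RobustLine:
    """Tukey-bisquare IRLS straight-line fit.

    Reduces to ordinary least squares on outlier-free data (all weights stay
    positive and near one).  Raises for fewer than 2 observations or all-equal
    x values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if len(x) < 2 or np.ptp(x) == 0:
        raise DegenerateInputError(
            "robust line fit needs >= 2 observations with distinct x"
        )
    w = np.ones_like(x)
    slope, intercept = _wls_line(x, y, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = y - slope * x - intercept
        scale = np.median(np.abs(r - np.median(r))) / _MAD_TO_SIGMA
        if scale <= 1e-12 * max(1.0, float(np.abs(y).max())):
            converged = True  # (near-)perfect fit
            w = np.ones_like(x)
            break
        u = r / (c * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        new_slope, new_intercept = _wls_line(x, y, w)
        delta = max(abs(new_slope - slope), abs(new_intercept - intercept))
        slope, intercept = new_slope, new_intercept
        if delta < tol * (1 + max(abs(slope), abs(intercept))):
            converged = True
            break
    return RobustLine(
        slope=float(slope),
        intercept=float(intercept),
        weights=w,
        converged=converged,
        n_iterations=it,
    )


def vs_curve(series: ErosionSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-iteration (percent_remaining, VS) arrays for an erosion series.

    The optimum alpha-shape is recomputed on each iteration's skeleton; the
    series is truncated at the first iteration whose point set is degenerate.
    """
    percents, vs_values = [], []
    for k, skel, pct in series.iterations:
        try:
            res = find_optimal_alpha(skel.points())
        except DegenerateInputError:
            logger.warning(
                "erosion iteration %d degenerate; VS curve truncated", k
            )
            break
        percents.append(pct)
        vs_values.append(vessel_shape(res.op_area, res.op_alpha_min))
    return np.array(percents), np.array(vs_values)


def grad_alpha_from_curve(percents, vs_values) -> float:
    """Robust-regression slope of VS against percent remaining."""
    percents = np.asarray(percents, dtype=float)
    if len(percents) < 3:
        raise DegenerateInputError(
            f"grad_alpha needs >= 3 usable erosion iterations, got {len(percents)}"
        )
    return robust_line_fit(percents, np.asarray(vs_values, float)).slope


def grad_alpha(series: ErosionSeries) -> float:
    """Grad_alpha of an erosion series (VS-units per percentage point)."""
    percents, vs_values = vs_curve(series)
    return grad_alpha_from_curve(percents, vs_values)


def compute_descriptors(
    raster,
    image_id: str = "image",
    *,
    n_iterations: int = 20,
    fd: bool = False,
    fd_kwargs: dict | None = None,
    group_label: str | None = None,
) -> DescriptorRecord:
    """Full descriptor pipeline for one mask or skeleton raster.

    A :class:`Mask` (or plain boolean array) is thinned first; a
    :class:`Skeleton` is re-thinned (a no-op on valid skeletons), so a mask
    and its own skeleton give identical records.  Deterministic for fixed
    input and configuration.
    """
    try:
        skel = skeletonize(raster)
        opt = find_optimal_alpha(skel.points())
        series = erosion_series(skel, n_iterations=n_iterations)
        ga = grad_alpha(series)
        fd_value = None
        if fd:
            from .fractal import box_counting_fd

            fd_value = box_counting_fd(skel, **(fd_kwargs or {})).fd
    except Exception as exc:
        exc.add_note(f"while computing descriptors for image {image_id!r}")
        raise
    return DescriptorRecord(
        image_id=image_id,
        op_alpha_min=opt.op_alpha_min,
        op_area=opt.op_area,
        vs=vessel_shape(opt.op_area, opt.op_alpha_min),
        grad_alpha=ga,
        fd=fd_value,
        group_label=group_label,
    )
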