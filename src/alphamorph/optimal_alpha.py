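"""Search for the optimum alpha-shape of a skeleton point set.

The optimum is the minimum spectrum alpha at which the shape is a single
edge-connected region covering every point.  Both criteria hold at the
largest spectrum value (the full triangulation of a non-degenerate set is
one covering region), so a binary search over the sorted spectrum finds the
threshold in O(log T) shape evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InternalConsistencyError
from .geometry import (
    AlphaShape,
    DelaunayTriangulation,
    alpha_spectrum,
    build_alpha_shape,
    count_regions,
    covers_all_points,
    triangulate,
)

__all__ = ["OptimalAlphaResult", "find_optimal_alpha"]


@dataclass(frozen=True)
class OptimalAlphaResult:
    """Optimum alpha-shape of a point set.

    Attributes
    ----------
    op_alpha_min : float
        Minimum alpha giving a single all-covering region (pixels).
    op_area : float
        Area of the shape at ``op_alpha_min`` (squared pixels).
    shape : AlphaShape
        The optimum shape itself.
    """

    op_alpha_min: float
    op_area: float
    shape: AlphaShape


def _acceptable(tri: DelaunayTriangulation, alpha: float) -> AlphaShape | None:
    shape = build_alpha_shape(tri, alpha)
    if count_regions(shape) == 1 and covers_all_points(shape):
        return shape
    return None


def find_optimal_alpha(points) -> OptimalAlphaResult:
    """Find the minimum alpha whose shape is one region covering all points.

    ``points`` may be a point array, :class:`~alphamorph.geometry.PointSet`
    or a prebuilt :class:`~alphamorph.geometry.DelaunayTriangulation` (the
    triangulation and circumradii are computed once and reused across the
    search).
    """
    tri = (
        points
        if isinstance(points, DelaunayTriangulation)
        else triangulate(points)
    )
    spectrum = alpha_spectrum(tri)
    lo, hi = 0, len(spectrum) - 1
    if _acceptable(tri, spectrum[hi]) is None:
        raise InternalConsistencyError(
            "full triangulation is not a single covering region; "
            "this cannot happen for a valid triangulation"
        )
    while lo < hi:
        mid = (lo + hi) // 2
        if _acceptable(tri, spectrum[mid]) is not None:
            hi = mid
        else:
            lo = mid + 1
    shape = _acceptable(tri, spectrum[hi])
    if shape is None:  # pragma: no cover - guarded by the loop invariant
        raise InternalConsistencyError("binary search converged on a bad alpha")
    return OptimalAlphaResult(
        op_alpha_min=float(spectrum[hi]), op_area=shape.area, shape=shape
    )
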