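"""Vessel skeleton production and degradation.

Thinning reduces a binary segmentation mask to 1-pixel-wide centrelines;
spur erosion then shortens free vessel ends by deleting, per iteration, every
pixel with exactly one foreground 8-neighbour.  Endpoint-free structures
(cycles) are fixed points of the erosion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "Mask",
    "Skeleton",
    "ErosionSeries",
    "skeletonize",
    "endpoints",
    "spur_erode",
    "erosion_series",
]

_NEIGHBOUR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


@dataclass(frozen=True)
class Mask:
    """Binary segmentation raster; any true cell is vessel foreground."""

    grid: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 2:
            raise DegenerateInputError(f"mask must be 2D, got {grid.ndim}D")
        object.__setattr__(self, "grid", grid)

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def pixel_count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class Skeleton:
    """1-pixel-wide centreline raster."""

    grid: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 2:
            raise DegenerateInputError(f"skeleton must be 2D, got {grid.ndim}D")
        object.__setattr__(self, "grid", grid)

    @property
    def pixel_count(self) -> int:
        return int(self.grid.sum())

    def points(self) -> np.ndarray:
        """(n, 2) float array of (row, col) foreground coordinates."""
        return np.argwhere(self.grid).astype(float)

    def is_thin(self) -> bool:
        """True iff no 2x2 block is fully foreground."""
        g = self.grid
        blocks = g[:-1, :-1] & g[1:, :-1] & g[:-1, 1:] & g[1:, 1:]
        return not blocks.any()


@dataclass(frozen=True)
class ErosionSeries:
    """Ordered spur-erosion states of a skeleton.

    ``iterations[k]`` is ``(k, skeleton_after_k_erosions, percent_remaining)``
    with iteration 0 the input at 100%.
    """

    iterations: tuple

    @property
    def n_iterations(self) -> int:
        return len(self.iterations) - 1

    @property
    def percents(self) -> np.ndarray:
        return np.array([p for _, _, p in self.iterations])

    @property
    def skeletons(self) -> list:
        return [s for _, s, _ in self.iterations]


_RING = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def _is_simple(grid: np.ndarray, r: int, c: int, *, require_open_side: bool = True) -> bool:
    """True iff deleting (r, c) preserves local 8-connectivity.

    The foreground 8-neighbours must form a single 8-connected component
    among themselves; with ``require_open_side`` at least one 4-neighbour
    must also be background (so deletion cannot create a pinhole).
    """
    h, w = grid.shape
    fg = [
        (dr, dc)
        for dr, dc in _RING
        if 0 <= r + dr < h and 0 <= c + dc < w and grid[r + dr, c + dc]
    ]
    if len(fg) < 2:
        return False
    if require_open_side:
        open_side = any(
            not (0 <= r + dr < h and 0 <= c + dc < w and grid[r + dr, c + dc])
            for dr, dc in ((-1, 0), (0, 1), (1, 0), (0, -1))
        )
        if not open_side:
            return False
    seen = {fg[0]}
    frontier = [fg[0]]
    while frontier:
        ar, ac = frontier.pop()
        for cand in fg:
            if cand not in seen and max(abs(cand[0] - ar), abs(cand[1] - ac)) <= 1:
                seen.add(cand)
                frontier.append(cand)
    return len(seen) == len(fg)


def _n_components(grid: np.ndarray) -> int:
    _, n = ndimage.label(grid, structure=np.ones((3, 3), dtype=int))
    return int(n)


def _has_block_near(grid: np.ndarray, r: int, c: int) -> bool:
    r0, c0 = max(0, r - 2), max(0, c - 2)
    win = grid[r0: r + 3, c0: c + 3]
    return bool((win[:-1, :-1] & win[1:, :-1] & win[:-1, 1:] & win[1:, 1:]).any())


def _rewire_block(grid: np.ndarray, corners) -> bool:
    """Resolve an irreducible 2x2 block (e.g. two diagonals crossing) by
    deleting one corner and adding one nearby reconnecting pixel; the move is
    committed only if the global component count is unchanged and no 2x2
    block remains in the neighbourhood."""
    h, w = grid.shape
    n_before = _n_components(grid)
    for r, c in corners:
        grid[r, c] = False
        for dr, dc in _RING:
            qr, qc = r + dr, c + dc
            if not (0 <= qr < h and 0 <= qc < w) or grid[qr, qc]:
                continue
            grid[qr, qc] = True
            if (
                not _has_block_near(grid, r, c)
                and not _has_block_near(grid, qr, qc)
                and _n_components(grid) == n_before
            ):
                return True
            grid[qr, qc] = False
        grid[r, c] = True
    return False


def _break_2x2_blocks(grid: np.ndarray) -> np.ndarray:
    """Remove every fully-foreground 2x2 block while keeping connectivity.

    Iterative thinning can leave 2x2 blocks where dense branches cross.
    Preferred fix is deleting a simple pixel; blocks locked inside a dense
    mesh fall back to a connectivity-preserving deletion (which may open a
    1-pixel hole), and irreducible crossings are locally rewired.
    """
    grid = grid.copy()
    for _ in range(16):  # blocks can cascade; a handful of sweeps suffices
        blocks = np.argwhere(
            grid[:-1, :-1] & grid[1:, :-1] & grid[:-1, 1:] & grid[1:, 1:]
        )
        if len(blocks) == 0:
            break
        changed = False
        for br, bc in blocks:
            if not (
                grid[br, bc] and grid[br + 1, bc]
                and grid[br, bc + 1] and grid[br + 1, bc + 1]
            ):
                continue  # already resolved by an earlier deletion
            corners = ((br, bc), (br, bc + 1), (br + 1, bc), (br + 1, bc + 1))
            hit = None
            for strict in (True, False):
                hit = next(
                    (
                        (r, c) for r, c in corners
                        if _is_simple(grid, r, c, require_open_side=strict)
                    ),
                    None,
                )
                if hit is not None:
                    break
            if hit is not None:
                grid[hit] = False
                changed = True
            elif _rewire_block(grid, corners):
                changed = True
            else:  # pragma: no cover - no known configuration reaches this
                logger.warning("unresolvable 2x2 block at (%d, %d)", br, bc)
        if not changed:
            break
    return grid


def skeletonize(mask: Mask | Skeleton | np.ndarray) -> Skeleton:
    """Topology-preserving iterative thinning to 1-pixel centrelines."""
    grid = mask.grid if isinstance(mask, (Mask, Skeleton)) else np.asarray(mask, bool)
    if not grid.any():
        raise DegenerateInputError("cannot skeletonize an empty mask")
    # iterate to a fixed point so skeletonize is exactly idempotent; block
    # rewiring may add the odd pixel back, so cap the loop defensively
    for _ in range(20):
        new = _break_2x2_blocks(_sk_skeletonize(grid))
        if np.array_equal(new, grid):
            break
        grid = new
    else:  # pragma: no cover
        logger.warning("skeletonize did not reach a fixed point in 20 rounds")
    return Skeleton(grid=grid)


def _neighbour_counts(grid: np.ndarray) -> np.ndarray:
    return ndimage.convolve(
        grid.astype(np.uint8), _NEIGHBOUR_KERNEL, mode="constant", cval=0
    )


def endpoints(skel: Skeleton) -> np.ndarray:
    """(k, 2) coordinates of foreground pixels with exactly one 8-neighbour."""
    counts = _neighbour_counts(skel.grid)
    return np.argwhere(skel.grid & (counts == 1))


def spur_erode(skel: Skeleton, iterations: int) -> Skeleton:
    """Delete all current endpoint pixels, simultaneously, ``iterations`` times.

    Endpoints are recomputed each iteration, so each free end loses one pixel
    per iteration; cycles are untouched.  Eroding to empty is allowed.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    grid = skel.grid.copy()
    for _ in range(iterations):
        ends = grid & (_neighbour_counts(grid) == 1)
        if not ends.any():
            break
        grid &= ~ends
    return Skeleton(grid=grid)


def erosion_series(skel: Skeleton, n_iterations: int = 20) -> ErosionSeries:
    """Incremental spur erosion, recording pixels remaining per iteration.

    Percentages are relative to the input skeleton (iteration 0).  If the
    skeleton empties before ``n_iterations``, the series is truncated at the
    last nonempty state with a logged warning.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    base = skel.pixel_count
    if base == 0:
        raise DegenerateInputError("cannot erode an empty skeleton")
    out = [(0, skel, 100.0)]
    current = skel
    for k in range(1, n_iterations + 1):
        current = spur_erode(current, 1)
        count = current.pixel_count
        if count == 0:
            logger.warning(
                "skeleton emptied at erosion iteration %d; series truncated", k
            )
            break
        out.append((k, current, 100.0 * count / base))
    return ErosionSeries(iterations=tuple(out))
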