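"""Seeded synthetic vessel skeletons.

Random-walk branching trees rasterised to thin skeletons stand in for
skeletonised fundus vasculature.  Two layouts are available:

* ``border`` — roots on the image border walking inward (generic trees for
  unit and property tests);
* ``radial`` — roots on a ring around a central avascular gap, walking
  outward inside a bounded disc, echoing the fovea-centred geometry of a
  fundus photograph.  This is the layout the matched-pair experiments use.

Controlled corruptions:

* *tufts* — clusters of short open arms grown into locally empty pockets of
  the network, emulating the many small vessels of neovascular fronds;
* *lesion blobs* — small disconnected rings away from the tree, emulating
  erroneously segmented lesions.

:func:`matched_tuft_pair` builds a (tufted, control) pair with exactly equal
pixel counts: the control receives the same pixel mass as webbed outward
"fans" (spread-carrying, steadily eroding) instead of tufts.  A detached
two-ring calibration marker at a fixed gap — akin to a peripheral lesion
fragment — pins the optimum alpha of both members to the same value so that
the pair differs in spread and erosion dynamics only.

All randomness flows from explicit seeds; identical parameters always yield
identical rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import circle_perimeter, line

from .errors import DegenerateInputError
from .morphology import Skeleton, endpoints, skeletonize

__all__ = [
    "TreeParams",
    "generate_vessel_tree",
    "add_neovascular_tufts",
    "add_lesion_noise",
    "add_calibration_marker",
    "matched_tuft_pair",
    "matched_pair_params",
]


@dataclass(frozen=True)
class TreeParams:
    image_size: int = 192
    layout: str = "border"  # "border" | "radial"
    n_roots: int = 2
    branch_probability: float = 0.18
    branch_angle_spread: float = 45.0
    segment_length_mean: float = 9.0
    segment_length_sd: float = 2.5
    heading_jitter_deg: float = 7.0
    max_depth: int = 5
    steps_per_branch: int = 0  # 0 -> derived from image_size
    central_gap_fraction: float = 0.12  # avascular central disc (fovea-like)
    outer_radius_fraction: float = 0.72  # radial layout: web confined to
    # this fraction of the half-width, leaving the corners empty
    radial_pull: float = 0.25  # radial layout: fraction of the deviation
    # from the outward direction corrected at each step
    tuft_count: int = 9           # tuft clusters
    tuft_vessel_count: int = 4    # open arms per cluster
    tuft_radius: int = 22         # maximum arm reach in pixels
    lesion_blob_count: int = 0
    lesion_blob_radius: int = 4
    marker_gap: float = 40.0      # calibration marker ring gap (pixels)
    marker_ring_radius: int = 5
    max_branches: int = 3000  # hard cap; supercritical branching would
    # otherwise grow exponentially
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.layout not in ("border", "radial"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability must lie in [0, 1]")
        if self.segment_length_mean <= 0 or self.segment_length_mean >= self.image_size:
            raise DegenerateInputError(
                "segment_length_mean must be positive and fit inside the image"
            )
        for name in (
            "n_roots", "max_depth", "tuft_count", "tuft_radius",
            "tuft_vessel_count", "lesion_blob_count", "lesion_blob_radius",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if 2 * self.lesion_blob_radius + 6 >= self.image_size:
            raise DegenerateInputError("lesion blobs cannot fit in the image")
        if not 0.0 <= self.central_gap_fraction < 0.5:
            raise ValueError("central_gap_fraction must lie in [0, 0.5)")
        if not 0.3 <= self.outer_radius_fraction <= 1.0:
            raise ValueError("outer_radius_fraction must lie in [0.3, 1]")

    @property
    def _half(self) -> float:
        return (self.image_size - 1) / 2.0

    @property
    def _gap_radius(self) -> float:
        return self.central_gap_fraction * self.image_size

    def _in_gap(self, r: float, c: float) -> bool:
        return math.hypot(r - self._half, c - self._half) < self._gap_radius

    @property
    def _steps(self) -> int:
        if self.steps_per_branch > 0:
            return self.steps_per_branch
        return max(4, int(0.6 * self.image_size / self.segment_length_mean))


def matched_pair_params(seed: int, image_size: int = 192) -> TreeParams:
    """Parameters tuned for the tufted-vs-control discrimination protocol."""
    return TreeParams(
        image_size=image_size,
        layout="radial",
        n_roots=14,
        branch_probability=0.3,
        max_depth=5,
        segment_length_mean=7.0,
        segment_length_sd=2.0,
        heading_jitter_deg=6.0,
        steps_per_branch=30,
        central_gap_fraction=0.15,
        max_branches=500,
        tuft_count=9,
        tuft_vessel_count=4,
        tuft_radius=22,
        seed=seed,
    )


def _draw_segment(canvas: np.ndarray, p0, p1) -> bool:
    """Draw the clipped line p0->p1; returns False if p1 was out of bounds."""
    h, w = canvas.shape
    r0, c0 = int(round(p0[0])), int(round(p0[1]))
    r1, c1 = int(round(p1[0])), int(round(p1[1]))
    rr, cc = line(r0, c0, r1, c1)
    inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    canvas[rr[inside], cc[inside]] = True
    return bool(inside.all())


def _border_roots(params: TreeParams, rng) -> list:
    size = params.image_size
    jitter = math.radians(params.heading_jitter_deg)
    roots = []
    for _ in range(params.n_roots):
        side = rng.integers(4)
        offset = rng.uniform(0.2, 0.8) * size
        if side == 0:
            pos, heading = (0.0, offset), math.pi / 2  # top edge, heading down
        elif side == 1:
            pos, heading = (size - 1.0, offset), -math.pi / 2
        elif side == 2:
            pos, heading = (offset, 0.0), 0.0
        else:
            pos, heading = (offset, size - 1.0), math.pi
        roots.append((pos, heading + rng.normal(0.0, jitter), 0))
    return roots


def _radial_roots(params: TreeParams, rng) -> list:
    half = params._half
    r0 = params._gap_radius
    roots = []
    for i in range(params.n_roots):
        ang = 2 * math.pi * (i + rng.uniform(-0.2, 0.2)) / params.n_roots
        pos = (half + r0 * math.sin(ang), half + r0 * math.cos(ang))
        roots.append((pos, ang, 0))
    return roots


def generate_vessel_tree(params: TreeParams):
    """Rasterise a random branching tree; returns (Skeleton, ground_truth).

    Each branch is a jittered random walk of normally distributed segment
    lengths that may spawn child branches (probability
    ``branch_probability`` per step, up to ``max_depth``).  The raster is
    thinned before return, so the output satisfies the skeleton invariants.
    ``ground_truth`` records the true number of branches spawned and the
    endpoint count of the final raster.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    half = params._half
    canvas = np.zeros((size, size), dtype=bool)
    jitter = math.radians(params.heading_jitter_deg)
    spread = math.radians(params.branch_angle_spread)
    radial = params.layout == "radial"
    rmax = params.outer_radius_fraction * half
    stack = _radial_roots(params, rng) if radial else _border_roots(params, rng)
    n_branches = len(stack)
    while stack:
        pos, heading, depth = stack.pop()
        for _ in range(params._steps):
            length = max(
                2.0, rng.normal(params.segment_length_mean, params.segment_length_sd)
            )
            heading += rng.normal(0.0, jitter)
            if radial:
                outward = math.atan2(pos[0] - half, pos[1] - half)
                diff = (heading - outward + math.pi) % (2 * math.pi) - math.pi
                heading -= params.radial_pull * diff
            nxt = (
                pos[0] + length * math.sin(heading),
                pos[1] + length * math.cos(heading),
            )
            if params._in_gap(*nxt):
                break  # branches stop at the avascular central zone
            if radial and math.hypot(nxt[0] - half, nxt[1] - half) > rmax:
                break
            fully_inside = _draw_segment(canvas, pos, nxt)
            pos = nxt
            if not fully_inside:
                break
            if (
                depth < params.max_depth
                and n_branches < params.max_branches
                and rng.random() < params.branch_probability
            ):
                sign = 1.0 if rng.random() < 0.5 else -1.0
                child = heading + sign * spread * rng.uniform(0.5, 1.0)
                stack.append((pos, child, depth + 1))
                n_branches += 1
    if not canvas.any():
        raise DegenerateInputError("generated tree is empty; adjust parameters")
    skel = skeletonize(canvas)
    ground_truth = {
        "n_branches": n_branches,
        "n_endpoints": int(len(endpoints(skel))),
    }
    return skel, ground_truth


# --------------------------------------------------------------------------
# corruptions
# --------------------------------------------------------------------------

def _emptiest_direction(grid: np.ndarray, a, probe: int):
    """Of 12 candidate directions, the one whose ray stays clear longest."""
    h, w = grid.shape
    best, best_len = None, -1
    for k in range(12):
        ang = 2 * math.pi * k / 12
        dr, dc = math.sin(ang), math.cos(ang)
        free = 0
        for t in range(3, probe):
            r, c = int(round(a[0] + t * dr)), int(round(a[1] + t * dc))
            if not (1 <= r < h - 1 and 1 <= c < w - 1) or grid[r, c]:
                break
            free += 1
        if free > best_len:
            best, best_len = ang, free
    return best, best_len


def add_neovascular_tufts(skel: Skeleton, params: TreeParams) -> Skeleton:
    """Attach ``tuft_count`` clusters of ``tuft_vessel_count`` short open arms.

    Arms sprout near existing vessel pixels into locally empty pockets (so
    they stay open and erode steadily) and reach at most ``tuft_radius``
    pixels; the result is re-thinned.  ``tuft_count == 0`` returns the input
    unchanged.
    """
    if params.tuft_count == 0:
        return skel
    rng = np.random.default_rng([params.seed, 1])
    canvas = skel.grid.copy()
    h, w = canvas.shape
    half = (h - 1) / 2.0
    coords = np.argwhere(skel.grid)
    rad = np.hypot(coords[:, 0] - half, coords[:, 1] - half)
    band = coords[(rad > 0.3 * half) & (rad < 0.6 * half)]
    if len(band) < params.tuft_count:
        band = coords
    k = min(params.tuft_count, len(band))
    anchors = band[rng.choice(len(band), size=k, replace=False)]
    for anchor in anchors:
        for _ in range(params.tuft_vessel_count):
            p = anchor + [int(rng.integers(-4, 5)), int(rng.integers(-4, 5))]
            p = np.clip(p, 1, h - 2)
            if not canvas[p[0], p[1]]:
                p = anchor
            ang, free = _emptiest_direction(canvas, p, probe=params.tuft_radius)
            if ang is None or free < 6:
                continue
            heading = ang + rng.normal(0.0, 0.1)
            pos = (float(p[0]), float(p[1]))
            for _ in range(max(2, int(params.tuft_radius // 2.5))):
                heading += rng.normal(0.0, 0.12)
                nxt = (pos[0] + 2.5 * math.sin(heading), pos[1] + 2.5 * math.cos(heading))
                if not (1 <= nxt[0] < h - 1 and 1 <= nxt[1] < w - 1):
                    break
                if canvas[int(round(nxt[0])), int(round(nxt[1]))]:
                    break  # stop before touching other structures
                _draw_segment(canvas, pos, nxt)
                pos = nxt
    return skeletonize(canvas)


def add_lesion_noise(skel: Skeleton, params: TreeParams) -> Skeleton:
    """Scatter ``lesion_blob_count`` small thin rings away from the tree.

    Blobs are placed pairwise disjoint and clear of the existing skeleton,
    so the connected-component count rises by exactly the blob count.
    ``lesion_blob_count == 0`` returns the input unchanged.
    """
    if params.lesion_blob_count == 0:
        return skel
    rng = np.random.default_rng([params.seed, 2])
    canvas = skel.grid.copy()
    h, w = canvas.shape
    r = max(2, params.lesion_blob_radius)
    margin = r + 3
    coords = np.argwhere(skel.grid)
    placed = []
    attempts = 0
    while len(placed) < params.lesion_blob_count:
        attempts += 1
        if attempts > 2000:
            raise DegenerateInputError(
                "could not place all lesion blobs clear of the vessel tree"
            )
        cr = int(rng.integers(margin, h - margin))
        cc = int(rng.integers(margin, w - margin))
        d_tree = np.min(np.hypot(coords[:, 0] - cr, coords[:, 1] - cc))
        if d_tree <= margin:
            continue
        if any(math.hypot(pr - cr, pc - cc) <= 2 * margin for pr, pc in placed):
            continue
        rr, cc_ = circle_perimeter(cr, cc, r, shape=canvas.shape)
        canvas[rr, cc_] = True
        placed.append((cr, cc))
    return Skeleton(grid=canvas)


def add_calibration_marker(skel: Skeleton, params: TreeParams) -> Skeleton:
    """Corner two-ring marker pinning the optimum alpha at ~``marker_gap``/2.

    One ring is attached to the nearest vessel pixel by a connector line;
    the second sits detached farther into the empty corner at a fixed
    perimeter gap.  Both rings and the connector are cycle/bridge structures
    immune to spur erosion, so the critical alpha they define survives the
    whole erosion series.
    """
    ring_r = params.marker_ring_radius
    canvas = skel.grid.copy()
    coords = np.argwhere(skel.grid)
    c2 = np.array([ring_r + 6.0, ring_r + 6.0])  # detached corner ring
    diag = np.array([1.0, 1.0]) / math.sqrt(2.0)
    c1 = c2 + diag * (params.marker_gap + 2 * ring_r)
    d = np.hypot(coords[:, 0] - c1[0], coords[:, 1] - c1[1])
    a = coords[np.argmin(d)]
    _draw_segment(canvas, a, c1)
    for c in (c1, c2):
        rr, cc = circle_perimeter(
            int(round(c[0])), int(round(c[1])), ring_r, shape=canvas.shape
        )
        canvas[rr, cc] = True
    return skeletonize(canvas)


# --------------------------------------------------------------------------
# matched-pair protocol
# --------------------------------------------------------------------------

def _add_fan(grid: np.ndarray, rng, half: float, n_arms: int, arm_len: int,
             avoid, avoid_r: float = 30.0):
    """Webbed cluster of outward arms from a rim anchor; carries filled area
    at the pinned alpha and erodes steadily from the tips."""
    h, w = grid.shape
    coords = np.argwhere(grid)
    rad = np.hypot(coords[:, 0] - half, coords[:, 1] - half)
    band = coords[(rad > 0.6 * half) & (rad < 0.74 * half)]
    if len(band):
        da = np.hypot(band[:, 0] - avoid[0], band[:, 1] - avoid[1])
        band = band[da > 2.5 * avoid_r]
    if len(band) == 0:
        return grid
    for _ in range(40):
        a = band[rng.integers(len(band))]
        out_dir = math.atan2(a[0] - half, a[1] - half)
        pts_all, ok = [], True
        for off in np.linspace(-0.42, 0.42, n_arms):
            heading = out_dir + off + rng.normal(0.0, 0.05)
            pos = (float(a[0]), float(a[1]))
            pts = [pos]
            for _ in range(arm_len // 3):
                heading += rng.normal(0.0, 0.06)
                nxt = (pos[0] + 3.0 * math.sin(heading), pos[1] + 3.0 * math.cos(heading))
                if not (1 <= nxt[0] < h - 1 and 1 <= nxt[1] < w - 1):
                    ok = False
                    break
                if math.hypot(nxt[0] - avoid[0], nxt[1] - avoid[1]) < avoid_r:
                    ok = False
                    break
                pts.append(nxt)
                pos = nxt
            if not ok or len(pts) < 4:
                ok = False
                break
            pts_all.append(pts)
        if not ok:
            continue
        canvas = grid.copy()
        for pts in pts_all:
            for p0, p1 in zip(pts[:-1], pts[1:]):
                _draw_segment(canvas, p0, p1)
        return canvas
    return grid


_STEPS8 = [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]


def _grow_exact(grid: np.ndarray, rng, n_px: int, half: float, seg_cap: int = 8) -> bool:
    """Add exactly ``n_px`` pixels as short thin twigs from random endpoints."""
    added, guard = 0, 0
    while added < n_px and guard < 400:
        guard += 1
        ends = endpoints(Skeleton(grid=grid))
        if len(ends) == 0:
            break
        p = ends[rng.integers(len(ends))]
        vr, vc = p[0] - half, p[1] - half
        nrm = math.hypot(vr, vc) or 1.0
        pos = p.copy()
        for _ in range(min(seg_cap, n_px - added)):
            best = None
            # prefer the most outward-pointing free neighbour that keeps
            # the raster strictly thin
            for dr, dc in sorted(
                _STEPS8, key=lambda s: -(s[0] * vr + s[1] * vc) / (math.hypot(*s) * nrm)
            ):
                q = (pos[0] + dr, pos[1] + dc)
                if not (1 <= q[0] < grid.shape[0] - 1 and 1 <= q[1] < grid.shape[1] - 1):
                    continue
                if grid[q]:
                    continue
                grid[q] = True
                win = grid[max(0, q[0] - 2): q[0] + 3, max(0, q[1] - 2): q[1] + 3]
                if Skeleton(grid=win).is_thin():
                    best = q
                    break
                grid[q] = False
            if best is None:
                break
            pos = np.array(best)
            added += 1
    return added == n_px


def matched_tuft_pair(params: TreeParams):
    """(tufted, control) skeletons with exactly equal pixel counts.

    Both share a radial base tree carrying the calibration marker; the
    tufted member gains tuft clusters while the control receives the same
    pixel mass as outward fans (plus, for the last few pixels, short rim
    twigs).  Returns ``(tufted, control)``.
    """
    if params.tuft_count <= 0:
        raise ValueError("matched_tuft_pair requires tuft_count > 0")
    base_params = replace(params, tuft_count=0)
    base, _ = generate_vessel_tree(base_params)
    base = add_calibration_marker(base, params)
    tufted = add_neovascular_tufts(base, params)
    target = tufted.pixel_count
    half = params._half
    corner = np.array([params.marker_ring_radius + 6.0] * 2)
    rng = np.random.default_rng([params.seed, 3])
    grid = base.grid.copy()
    for _ in range(60):
        deficit = target - int(grid.sum())
        if deficit < 40:
            break
        n_arms = 5 if deficit > 160 else 3
        arm_len = 34 if deficit > 160 else max(10, deficit // n_arms)
        candidate = skeletonize(
            _add_fan(grid, rng, half, n_arms=n_arms, arm_len=arm_len, avoid=corner)
        ).grid
        if int(candidate.sum()) <= target:
            grid = candidate
        else:
            break
    deficit = target - int(grid.sum())
    if deficit > 0 and not _grow_exact(grid, rng, deficit, half):
        raise DegenerateInputError("could not match control pixel count exactly")
    control = Skeleton(grid=grid)
    if control.pixel_count != target:  # pragma: no cover
        raise DegenerateInputError("matched pair bookkeeping failed")
    return tufted, control
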