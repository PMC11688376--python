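"""Gestational-sac biometry from binary segmentation masks.

Pipeline: largest connected component -> Moore-neighbor boundary tracing ->
convex hull -> minimum-area enclosing rectangle (rotating calipers) ->
pixel-spacing-scaled side lengths (DM, Dm, in cm) -> Hellman gestational-age
estimate::

    GW = (0.5 * (DM + Dm) + 2.543) / 0.7       [weeks]

Conventions
-----------
* Pixels are points at integer ``(row, col)`` centers, 0-based.
* Rectangle corners are real-valued ``(row, col)`` points.
* ``c1`` is the reference corner, ``c2`` its neighbor along the *longer*
  physical side, ``c3`` its neighbor along the *shorter* side, ``c4`` the
  opposite corner, so ``DM >= Dm`` always holds.
* Spacing is carried in cm/pixel (DICOM PixelSpacing, in mm, is divided by
  10 at ingestion; see :mod:`sacmetry.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "GW_FLOOR_WEEKS",
    "PixelSpacing",
    "MinAreaRect",
    "BiometryResult",
    "extract_largest_component",
    "trace_boundary",
    "convex_hull",
    "min_area_rect",
    "measure_diameters",
    "estimate_gw",
    "run_biometry",
]

#: Gestational weeks implied by a zero-size sac (DM = Dm = 0): 2.543 / 0.7.
GW_FLOOR_WEEKS = 2.543 / 0.7


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PixelSpacing:
    """Physical length per pixel step, in cm/pixel.

    Attributes
    ----------
    row_spacing : float
        cm per step along rows (``PSrow``).
    col_spacing : float
        cm per step along columns (``PScol``).
    """

    row_spacing: float
    col_spacing: float

    def __post_init__(self) -> None:
        for name in ("row_spacing", "col_spacing"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @classmethod
    def isotropic(cls, spacing_cm: float) -> "PixelSpacing":
        return cls(spacing_cm, spacing_cm)

    @classmethod
    def from_mm(cls, row_spacing_mm: float, col_spacing_mm: float) -> "PixelSpacing":
        """Build from millimetre spacings (DICOM stores mm; DM/Dm need cm)."""
        return cls(row_spacing_mm / 10.0, col_spacing_mm / 10.0)


@dataclass(frozen=True)
class MinAreaRect:
    """Smallest-area enclosing rectangle of a planar point set.

    Corners are real-valued ``(row, col)`` points: ``c1`` reference,
    ``c2`` adjacent along the longer side, ``c3`` adjacent along the
    shorter side, ``c4 = c2 + c3 - c1`` opposite.  ``angle`` is the
    orientation of the long side against the column axis, degrees in
    ``[0, 180)``.  ``area_px`` is in squared pixels.
    """

    c1: tuple[float, float]
    c2: tuple[float, float]
    c3: tuple[float, float]
    c4: tuple[float, float]
    angle: float
    area_px: float

    @property
    def corners(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3, self.c4], dtype=float)

    @property
    def side_long_px(self) -> float:
        return float(np.hypot(*(np.subtract(self.c2, self.c1))))

    @property
    def side_short_px(self) -> float:
        return float(np.hypot(*(np.subtract(self.c3, self.c1))))


@dataclass(frozen=True)
class BiometryResult:
    """Sac diameters and gestational age for one mask.

    ``DM_cm`` is the maximum length, ``Dm_cm`` the short diameter (long and
    short sides of the minimum-area rectangle after per-axis spacing), and
    ``GW_weeks = (0.5 * (DM_cm + Dm_cm) + 2.543) / 0.7``.
    """

    DM_cm: float
    Dm_cm: float
    GW_weeks: float
    rect: MinAreaRect
    spacing: PixelSpacing

    def to_dict(self) -> dict:
        return {
            "DM_cm": self.DM_cm,
            "Dm_cm": self.Dm_cm,
            "GW_weeks": self.GW_weeks,
            "corners": self.rect.corners.tolist(),
            "angle_deg": self.rect.angle,
            "spacing_cm": [self.spacing.row_spacing, self.spacing.col_spacing],
        }


# ---------------------------------------------------------------------------
# mask plumbing
# ---------------------------------------------------------------------------

def _validate_mask(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"mask must be a non-empty 2D grid, got shape {arr.shape}")
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    return arr.astype(np.uint8)


_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


def extract_largest_component(mask) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Raises
    ------
    ValueError
        If the mask has no foreground pixel.
    """
    arr = _validate_mask(mask)
    labels, n = ndimage.label(arr, structure=_EIGHT)
    if n == 0:
        raise ValueError("no foreground: mask contains no foreground pixels")
    if n == 1:
        return arr
    sizes = ndimage.sum_labels(arr, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return (labels == keep).astype(np.uint8)


# ---------------------------------------------------------------------------
# Moore-neighbor boundary tracing
# ---------------------------------------------------------------------------

# Moore 8-neighborhood in clockwise order (image coords, row axis downward),
# starting at West.
_MOORE = (
    (0, -1), (-1, -1), (-1, 0), (-1, 1),
    (0, 1), (1, 1), (1, 0), (1, -1),
)
_MOORE_INDEX = {off: k for k, off in enumerate(_MOORE)}


def trace_boundary(mask) -> np.ndarray:
    """Trace the outer boundary of a single connected object.

    Moore-neighbor tracing with Jacob's stopping criterion: starting from the
    first foreground pixel in row-major scan order, the 8-neighborhood of the
    current boundary pixel is scanned clockwise from the backtrack pixel; the
    walk stops when the start pixel is re-entered from the starting backtrack
    direction.  The mask is implicitly padded by one background pixel on each
    side so objects touching the border have a well-defined outer boundary.

    Parameters
    ----------
    mask : 2D {0,1} array
        Expected to hold exactly one 8-connected component (pass through
        :func:`extract_largest_component` first).

    Returns
    -------
    (n, 2) int ndarray
        Ordered boundary pixels ``(row, col)`` in the original frame;
        consecutive entries are 8-neighbors and the path is closed.
    """
    arr = _validate_mask(mask)
    padded = np.pad(arr, 1)

    flat = np.flatnonzero(padded)
    if flat.size == 0:
        raise ValueError("no foreground: cannot trace an empty mask")
    p0 = tuple(int(v) for v in np.unravel_index(flat[0], padded.shape))
    # Row-major scan guarantees the West neighbor of p0 is background.
    b0 = (p0[0], p0[1] - 1)

    contour = [p0]
    p, b = p0, b0
    max_steps = 4 * int(padded.sum()) + 8
    for _ in range(max_steps):
        start = _MOORE_INDEX[(b[0] - p[0], b[1] - p[1])]
        nxt = None
        for k in range(1, 9):
            dr, dc = _MOORE[(start + k) % 8]
            cand = (p[0] + dr, p[1] + dc)
            if padded[cand]:
                nxt = cand
                break
            b = cand  # last background examined becomes the new backtrack
        if nxt is None:
            break  # isolated single pixel
        if nxt[0] != p[0] and nxt[1] != p[1]:
            # Diagonal step: the walk cuts a staircase corner.  The two
            # 4-common neighbors of p and nxt are the backtrack b (background)
            # and its mirror; when the mirror is foreground it is a boundary
            # pixel (b is its diagonal background neighbor) that the plain
            # walk would silently bypass -- emit it to keep the contour's
            # pixel set equal to the full background-adjacent boundary.
            corner = (p[0] + nxt[0] - b[0], p[1] + nxt[1] - b[1])
            if padded[corner]:
                contour.append(corner)
        if nxt == p0 and b == b0:
            break  # Jacob's criterion: re-entered the start the same way
        contour.append(nxt)
        p = nxt
    return np.array(contour, dtype=int) - 1  # back to unpadded frame


# ---------------------------------------------------------------------------
# convex hull and minimum-area rectangle
# ---------------------------------------------------------------------------

def convex_hull(points: Sequence) -> np.ndarray:
    """Convex-hull vertices in counterclockwise order.

    Collinear interior points are excluded.  One or two distinct points are
    returned as-is; a fully collinear set returns its two extreme endpoints.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("points must be a non-empty (n, 2) sequence")
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] <= 2:
        return uniq
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # Degenerate (collinear) input: endpoints along the spread direction.
        centered = uniq - uniq.mean(axis=0)
        direction = np.linalg.svd(centered, full_matrices=False)[2][0]
        proj = centered @ direction
        return uniq[[int(np.argmin(proj)), int(np.argmax(proj))]]
    return pts[hull.vertices]  # scipy orders 2D hull vertices CCW


def min_area_rect(points: Sequence) -> MinAreaRect:
    """Minimum-area enclosing rectangle via rotating calipers.

    Some edge of the convex hull is flush with the optimal rectangle, so only
    hull-edge orientations are examined.  Collinear input degenerates to a
    zero-width rectangle (short side 0); a single point to a zero-size one.
    """
    hull = convex_hull(points)
    n = hull.shape[0]
    if n == 1:
        c = (float(hull[0, 0]), float(hull[0, 1]))
        return MinAreaRect(c, c, c, c, angle=0.0, area_px=0.0)
    if n == 2:
        a, b = hull
        return _labeled_rect(u=_unit(b - a), v=_normal(_unit(b - a)),
                             lo_u=0.0, hi_u=float(np.linalg.norm(b - a)),
                             lo_v=0.0, hi_v=0.0, origin=a)

    edges = np.roll(hull, -1, axis=0) - hull
    best = None
    for edge in edges:
        u = _unit(edge)
        v = _normal(u)
        pu = hull @ u
        pv = hull @ v
        lo_u, hi_u = pu.min(), pu.max()
        lo_v, hi_v = pv.min(), pv.max()
        area = (hi_u - lo_u) * (hi_v - lo_v)
        if best is None or area < best[0] - 1e-12:
            best = (area, u, v, lo_u, hi_u, lo_v, hi_v)
    area, u, v, lo_u, hi_u, lo_v, hi_v = best
    return _labeled_rect(u=u, v=v, lo_u=float(lo_u), hi_u=float(hi_u),
                         lo_v=float(lo_v), hi_v=float(hi_v),
                         origin=np.zeros(2))


def _unit(vec: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else np.array([1.0, 0.0])


def _normal(u: np.ndarray) -> np.ndarray:
    return np.array([-u[1], u[0]])


def _labeled_rect(u, v, lo_u, hi_u, lo_v, hi_v, origin) -> MinAreaRect:
    """Assemble a :class:`MinAreaRect` with the c1..c4 labeling convention."""
    len_u = hi_u - lo_u
    len_v = hi_v - lo_v
    if len_u >= len_v:
        long_axis, short_axis = u, v
        lo_l, hi_l, lo_s, hi_s = lo_u, hi_u, lo_v, hi_v
    else:
        long_axis, short_axis = v, u
        lo_l, hi_l, lo_s, hi_s = lo_v, hi_v, lo_u, hi_u

    def corner(cl, cs):
        p = origin + cl * long_axis + cs * short_axis
        return (float(p[0]), float(p[1]))

    quad = [corner(lo_l, lo_s), corner(hi_l, lo_s), corner(lo_l, hi_s),
            corner(hi_l, hi_s)]
    # c1 = lexicographically smallest corner (stable reference choice).
    ref = min(range(4), key=lambda i: (round(quad[i][0], 9), round(quad[i][1], 9)))
    c1 = quad[ref]
    c2 = quad[ref ^ 1]  # flip along the long axis
    c3 = quad[ref ^ 2]  # flip along the short axis
    c4 = quad[ref ^ 3]
    ang = math.degrees(math.atan2(c2[0] - c1[0], c2[1] - c1[1])) % 180.0
    return MinAreaRect(c1, c2, c3, c4, angle=ang,
                       area_px=float(max(len_u, 0.0) * max(len_v, 0.0)))


# ---------------------------------------------------------------------------
# diameters and gestational age
# ---------------------------------------------------------------------------

def _scaled_distance(a, b, spacing: PixelSpacing) -> float:
    # Each coordinate is scaled by its axis spacing before the Euclidean
    # distance: d = sqrt((dcol * PScol)^2 + (drow * PSrow)^2).
    drow = (b[0] - a[0]) * spacing.row_spacing
    dcol = (b[1] - a[1]) * spacing.col_spacing
    return math.hypot(drow, dcol)


def measure_diameters(rect: MinAreaRect, spacing: PixelSpacing) -> tuple[float, float]:
    """Physical side lengths (DM, Dm) of the rectangle, in cm.

    DM is measured across the corner pair (c1, c2) and Dm across (c1, c3),
    with each coordinate scaled by its axis spacing before the Euclidean
    distance.  Returned as ``(max, min)`` so ``DM >= Dm`` even when
    anisotropic spacing flips the pixel-space ordering.
    """
    if not isinstance(spacing, PixelSpacing):
        spacing = PixelSpacing(*spacing)
    d12 = _scaled_distance(rect.c1, rect.c2, spacing)
    d13 = _scaled_distance(rect.c1, rect.c3, spacing)
    return (max(d12, d13), min(d12, d13))


def estimate_gw(DM_cm: float, Dm_cm: float) -> float:
    """Gestational age in weeks from the two sac diameters (Hellman method).

    ``GW = (0.5 * (DM + Dm) + 2.543) / 0.7``; depends on the diameters only
    through their sum (i.e. the mean sac diameter), and is strictly
    increasing in each argument.
    """
    if DM_cm < 0 or Dm_cm < 0:
        raise ValueError(f"diameters must be non-negative, got ({DM_cm}, {Dm_cm})")
    return (0.5 * (DM_cm + Dm_cm) + 2.543) / 0.7


def _relabel_physical(rect: MinAreaRect, spacing: PixelSpacing) -> MinAreaRect:
    """Swap c2/c3 if anisotropic spacing makes the c1-c3 side physically longer."""
    if _scaled_distance(rect.c1, rect.c3, spacing) <= _scaled_distance(
            rect.c1, rect.c2, spacing):
        return rect
    ang = math.degrees(math.atan2(rect.c3[0] - rect.c1[0],
                                  rect.c3[1] - rect.c1[1])) % 180.0
    return MinAreaRect(rect.c1, rect.c3, rect.c2, rect.c4,
                       angle=ang, area_px=rect.area_px)


def run_biometry(mask, spacing: PixelSpacing) -> BiometryResult:
    """Full Algorithm-1 pipeline: mask -> (DM, Dm, GW).

    Composition of :func:`extract_largest_component`,
    :func:`trace_boundary`, :func:`min_area_rect` on the contour points,
    :func:`measure_diameters`, and :func:`estimate_gw`.
    """
    if not isinstance(spacing, PixelSpacing):
        spacing = PixelSpacing(*spacing)
    component = extract_largest_component(mask)
    contour = trace_boundary(component)
    rect = _relabel_physical(min_area_rect(contour), spacing)
    DM, Dm = measure_diameters(rect, spacing)
    return BiometryResult(DM_cm=DM, Dm_cm=Dm, GW_weeks=estimate_gw(DM, Dm),
                          rect=rect, spacing=spacing)
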