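"""2D shape descriptors of projected nuclear (or cytoplasmic) masks.

The central quantity is the Shape Factor (SF), an elongation measure built
from the semi-axes of the mask's equivalent ellipse: the central second
moments of the uniform mask form the 2x2 covariance (inertia) tensor, whose
eigenvalues ``lam1 >= lam2`` give semi-axes ``a = 2*sqrt(lam1)``,
``b = 2*sqrt(lam2)``.  For a uniform ellipse with semi-axes (A, B) this
recovers exactly a = A, b = B.  Under the default formula

    SF = (a - b) / (a + b)

SF is 0 for an isotropic (round) mask and approaches 1 for a needle-like
one.  An alternative formula ``1 - b/a`` with the same limits is available
via ``sf_formula="one_minus_ratio"``.

Feret (caliper) diameters are computed by rotating calipers over the convex
hull of the pixel *corner* points, so a w x h axis-aligned rectangle of
pixels has min Feret exactly w and max Feret exactly sqrt(w^2 + h^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage.measure import perimeter_crofton

__all__ = [
    "ShapeMeasures",
    "measure_shape",
    "min_diameter",
    "central_moments",
    "equivalent_ellipse_axes",
    "shape_factor",
    "feret_diameters",
    "mask_corner_hull",
]

SF_FORMULAS = ("axis_diff", "one_minus_ratio")


@dataclass(frozen=True)
class ShapeMeasures:
    """Per-mask shape descriptors, all lengths in micrometres."""

    area_um2: float
    centroid_um: tuple[float, float]  # (x, y)
    long_axis_um: float  # semi-axis a of the equivalent ellipse
    short_axis_um: float  # semi-axis b
    orientation_rad: float  # major-axis angle from +x, in (-pi/2, pi/2]
    shape_factor: float
    circularity: float
    min_feret_um: float
    max_feret_um: float


def _as_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2D; got shape {mask.shape}")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    return mask


def central_moments(mask: np.ndarray) -> tuple[float, float, float]:
    """Normalized central second moments (mu20, mu11, mu02) of a binary mask.

    Moments are taken over pixel-centre coordinates with x = column,
    y = row, each divided by the pixel count (so they are variances, in
    px^2).  This is the raw double-sum definition with no pixel-extent
    correction.
    """
    mask = _as_mask(mask)
    ys, xs = np.nonzero(mask)
    x = xs.astype(np.float64)
    y = ys.astype(np.float64)
    dx = x - x.mean()
    dy = y - y.mean()
    n = x.size
    return (
        float(np.dot(dx, dx) / n),
        float(np.dot(dx, dy) / n),
        float(np.dot(dy, dy) / n),
    )


def equivalent_ellipse_axes(
    mask: np.ndarray, *, pixel_correction: bool = True
) -> tuple[float, float, float]:
    """Semi-axes (a, b) in px and orientation of the equivalent ellipse.

    With ``pixel_correction`` each pixel contributes the second moment of a
    unit square about its own centre (1/12 on each diagonal term), which
    keeps the minor axis strictly positive for any mask of >= 2 pixels and
    removes most of the small-mask digitization bias.
    """
    mu20, mu11, mu02 = central_moments(mask)
    if pixel_correction:
        mu20 += 1.0 / 12.0
        mu02 += 1.0 / 12.0
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    lam, vec = np.linalg.eigh(cov)  # ascending
    lam = np.clip(lam, 0.0, None)
    a = 2.0 * math.sqrt(float(lam[1]))
    b = 2.0 * math.sqrt(float(lam[0]))
    vx, vy = float(vec[0, 1]), float(vec[1, 1])  # major-axis eigenvector
    theta = math.atan2(vy, vx)
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    return a, b, theta


def shape_factor(a: float, b: float, formula: str = "axis_diff") -> float:
    """Elongation from semi-axes a >= b; 0 = round, -> 1 = elongated."""
    if formula not in SF_FORMULAS:
        raise ValueError(f"unknown SF formula {formula!r}; one of {SF_FORMULAS}")
    if a <= 0:
        return 0.0
    if formula == "axis_diff":
        return (a - b) / (a + b)
    return 1.0 - b / a


def mask_corner_hull(mask: np.ndarray) -> np.ndarray:
    """Convex-hull vertices (x, y), CCW, of the mask's pixel corner points."""
    mask = _as_mask(mask)
    ys, xs = np.nonzero(mask)
    # 4 corners of every foreground pixel
    corners = np.empty((xs.size * 4, 2), dtype=np.float64)
    for i, (ox, oy) in enumerate(((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))):
        corners[i * xs.size : (i + 1) * xs.size, 0] = xs + ox
        corners[i * xs.size : (i + 1) * xs.size, 1] = ys + oy
    corners = np.unique(corners, axis=0)
    if corners.shape[0] < 3:
        return corners
    hull = ConvexHull(corners)
    return corners[hull.vertices]  # CCW for 2D qhull


def _hull_max_feret(pts: np.ndarray) -> float:
    """Rotating-calipers (antipodal pairs) diameter of a CCW convex polygon."""
    n = pts.shape[0]
    if n == 1:
        return 0.0
    if n == 2:
        return float(np.hypot(*(pts[1] - pts[0])))

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    best = 0.0
    k = 1
    for i in range(n):
        j = (i + 1) % n
        # advance the antipodal point while the triangle area keeps growing
        while True:
            k_next = (k + 1) % n
            diff = cross(pts[i], pts[j], pts[k_next]) - cross(pts[i], pts[j], pts[k])
            if diff > 0:
                k = k_next
            else:
                break
        for p in (pts[i], pts[j]):
            d = math.hypot(pts[k][0] - p[0], pts[k][1] - p[1])
            if d > best:
                best = d
    return best


def _hull_min_feret(pts: np.ndarray) -> float:
    """Minimum caliper width: min over hull edges of the farthest-vertex distance."""
    n = pts.shape[0]
    if n == 1:
        return 0.0
    if n == 2:
        return 0.0
    best = math.inf
    for i in range(n):
        p = pts[i]
        q = pts[(i + 1) % n]
        ex, ey = q[0] - p[0], q[1] - p[1]
        norm = math.hypot(ex, ey)
        if norm == 0:
            continue
        # distance of every vertex from the edge's supporting line
        d = np.abs((pts[:, 0] - p[0]) * ey - (pts[:, 1] - p[1]) * ex) / norm
        w = float(d.max())
        if w < best:
            best = w
    return best if math.isfinite(best) else 0.0


def feret_diameters(mask: np.ndarray) -> tuple[float, float]:
    """(min_feret, max_feret) in pixels, over the pixel-corner convex hull."""
    pts = mask_corner_hull(mask)
    return _hull_min_feret(pts), _hull_max_feret(pts)


def measure_shape(
    mask: np.ndarray,
    pixel_size_um: float,
    *,
    sf_formula: str = "axis_diff",
) -> ShapeMeasures:
    """All 2D shape descriptors of one projected binary mask.

    Raises ``ValueError`` on an empty mask.
    """
    mask = _as_mask(mask)
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    ys, xs = np.nonzero(mask)
    n_px = xs.size
    area = n_px * pixel_size_um**2
    cx = float(xs.mean()) * pixel_size_um
    cy = float(ys.mean()) * pixel_size_um
    a_px, b_px, theta = equivalent_ellipse_axes(mask)
    sf = shape_factor(a_px, b_px, sf_formula)
    perim = perimeter_crofton(mask, directions=4) * pixel_size_um
    circ = 4.0 * math.pi * area / perim**2 if perim > 0 else math.nan
    fmin, fmax = feret_diameters(mask)
    return ShapeMeasures(
        area_um2=float(area),
        centroid_um=(cx, cy),
        long_axis_um=a_px * pixel_size_um,
        short_axis_um=b_px * pixel_size_um,
        orientation_rad=theta,
        shape_factor=float(sf),
        circularity=float(circ),
        min_feret_um=fmin * pixel_size_um,
        max_feret_um=fmax * pixel_size_um,
    )


def min_diameter(mask: np.ndarray, pixel_size_um: float) -> float:
    """Minimum nuclear diameter: the min Feret (smallest caliper width).

    Automated analogue of measuring the narrowest span of a nucleus by hand.
    """
    mask = _as_mask(mask)
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    fmin, _ = feret_diameters(mask)
    return fmin * pixel_size_um
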