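"""Probability-aware geometric primitives on keypoint triples.

Occluded keypoints are never dropped upstream (no outlier-correction pass);
instead every primitive here either weights by the detection likelihood or
excludes points below a minimum likelihood ``p_min``.  Degenerate geometry
never produces NaN: areas fall back to 0, angles to 0, undefined centroids
are propagated as the last valid value (see the per-series helpers).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

#: default minimum likelihood for threshold-excluded point families
DEFAULT_P_MIN = 0.5


def weighted_centroid(points: np.ndarray) -> tuple[float, float]:
    """Likelihood-weighted centroid of ``(x, y, p)`` points.

    Returns ``(sum p_i x_i / sum p_i, sum p_i y_i / sum p_i)``; if every
    likelihood is zero the location is undefined and ``(nan, nan)`` is
    returned (callers working on frame series propagate the last valid
    value instead, see :func:`weighted_centroid_series`).
    """
    pts = np.asarray(points, dtype=float)
    w = pts[:, 2]
    total = w.sum()
    if total <= 0:
        return (float("nan"), float("nan"))
    return (float((w * pts[:, 0]).sum() / total), float((w * pts[:, 1]).sum() / total))


def _fill_undefined(xy: np.ndarray, defined: np.ndarray, fallback: tuple[float, float]) -> np.ndarray:
    """Forward-fill undefined rows; leading undefined rows take the first
    defined value; an all-undefined series takes ``fallback``."""
    out = xy.copy()
    if not defined.any():
        out[:] = fallback
        return out
    idx = np.where(defined, np.arange(len(defined)), -1)
    idx = np.maximum.accumulate(idx)
    first = int(np.argmax(defined))
    idx[idx < 0] = first
    return out[idx]


def weighted_centroid_series(
    coords: np.ndarray, fallback: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame weighted centroid of a ``(n, k, 3)`` block.

    Returns ``(xy, defined)`` where ``xy`` has shape ``(n, 2)`` and frames
    with no positively-weighted point inherit the nearest preceding defined
    centroid (else the first defined one, else ``fallback``).
    """
    coords = np.asarray(coords, dtype=float)
    w = coords[..., 2]
    total = w.sum(axis=1)
    defined = total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        x = (w * coords[..., 0]).sum(axis=1) / total
        y = (w * coords[..., 1]).sum(axis=1) / total
    xy = np.column_stack([x, y])
    return _fill_undefined(xy, defined, fallback), defined


def convex_hull_area(points: np.ndarray, p_min: float = DEFAULT_P_MIN, px_per_mm: float = 1.0) -> float:
    """Convex hull area (mm^2) over points with likelihood >= ``p_min``.

    Fewer than 3 admissible points, or a degenerate (collinear) hull,
    yields 0.
    """
    pts = np.asarray(points, dtype=float)
    ok = pts[:, 2] >= p_min
    xy = pts[ok, :2]
    if xy.shape[0] < 3:
        return 0.0
    try:
        hull = ConvexHull(xy)
    except QhullError:
        return 0.0
    return float(hull.volume) / (px_per_mm**2)


def back_arch_angle(
    back_points: np.ndarray,
    p_min: float = DEFAULT_P_MIN,
) -> tuple[float, bool]:
    """Central angle (degrees) of a circle fitted through the back points.

    An algebraic least-squares (Kasa) circle is fitted through the
    admissible back points (likelihood >= ``p_min``); the returned value is
    the unsigned angle at the fitted centre between the first and last
    admissible points, in [0, 180].  Collinear points and frames with fewer
    than 3 admissible points return 0.0; the second element of the result
    flags whether the estimate is trustworthy (False for the <3-point
    fallback).
    """
    pts = np.asarray(back_points, dtype=float)[None, :, :]
    ang, ok = back_arch_angle_series(pts, p_min)
    return float(ang[0]), bool(ok[0])


def back_arch_angle_series(
    back: np.ndarray, p_min: float = DEFAULT_P_MIN
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`back_arch_angle` over a ``(n, k, 3)`` block."""
    back = np.asarray(back, dtype=float)
    n, k, _ = back.shape
    w = (back[..., 2] >= p_min).astype(float)
    m = w.sum(axis=1)
    enough = m >= 3

    # weighted centring improves conditioning of the normal equations
    safe_m = np.where(m > 0, m, 1.0)
    mx = (w * back[..., 0]).sum(axis=1) / safe_m
    my = (w * back[..., 1]).sum(axis=1) / safe_m
    u = back[..., 0] - mx[:, None]
    v = back[..., 1] - my[:, None]

    suu = (w * u * u).sum(axis=1)
    svv = (w * v * v).sum(axis=1)
    suv = (w * u * v).sum(axis=1)
    suuu = (w * u**3).sum(axis=1)
    svvv = (w * v**3).sum(axis=1)
    suvv = (w * u * v * v).sum(axis=1)
    svuu = (w * v * u * u).sum(axis=1)

    det = suu * svv - suv**2
    scale = (suu + svv) ** 2
    nondeg = enough & (det > 1e-12 * np.where(scale > 0, scale, 1.0))

    b1 = 0.5 * (suuu + suvv)
    b2 = 0.5 * (svvv + svuu)
    safe_det = np.where(nondeg, det, 1.0)
    uc = (b1 * svv - b2 * suv) / safe_det
    vc = (b2 * suu - b1 * suv) / safe_det
    cx = mx + uc
    cy = my + vc

    # endpoints: first and last admissible back points
    has = w > 0
    first = np.argmax(has, axis=1)
    last = k - 1 - np.argmax(has[:, ::-1], axis=1)
    rows = np.arange(n)
    p1 = back[rows, first, :2]
    p2 = back[rows, last, :2]
    v1 = p1 - np.column_stack([cx, cy])
    v2 = p2 - np.column_stack([cx, cy])
    dot = (v1 * v2).sum(axis=1)
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    ang = np.degrees(np.arctan2(np.abs(cross), dot))
    ang = np.where(nondeg, ang, 0.0)
    return ang, enough


def point_movement(coords: np.ndarray, px_per_mm: float = 1.0) -> np.ndarray:
    """Per-frame likelihood-weighted displacement (mm) of one keypoint.

    ``coords`` is ``(n, 3)``; the displacement between consecutive frames is
    scaled by ``min(p_t, p_{t-1})`` so that occluded frames do not register
    spurious motion; frame 0 reports 0.
    """
    c = np.asarray(coords, dtype=float)
    out = np.zeros(c.shape[0])
    if c.shape[0] < 2:
        return out
    d = np.linalg.norm(np.diff(c[:, :2], axis=0), axis=1) / px_per_mm
    wmin = np.minimum(c[1:, 2], c[:-1, 2])
    out[1:] = d * wmin
    return out


def movement_block(coords: np.ndarray, px_per_mm: float = 1.0) -> np.ndarray:
    """Vectorized :func:`point_movement` over a ``(n, k, 3)`` block -> (n, k)."""
    c = np.asarray(coords, dtype=float)
    n, k, _ = c.shape
    out = np.zeros((n, k))
    if n < 2:
        return out
    d = np.linalg.norm(np.diff(c[..., :2], axis=0), axis=2) / px_per_mm
    wmin = np.minimum(c[1:, :, 2], c[:-1, :, 2])
    out[1:] = d * wmin
    return out


def bearing_deg(vec: np.ndarray) -> np.ndarray:
    """Orientation of 2-D vectors in degrees, mapped to [0, 360)."""
    ang = np.degrees(np.arctan2(vec[..., 1], vec[..., 0]))
    return np.mod(ang, 360.0)


def angle_between_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Unsigned angle between paired 2-D vectors, degrees in [0, 180].

    Zero-length vectors yield 0 (degenerate-input sentinel).
    """
    dot = (a * b).sum(axis=-1)
    cross = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    ang = np.degrees(np.arctan2(np.abs(cross), dot))
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    return np.where((na > 0) & (nb > 0), ang, 0.0)
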