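"""Small shared geometry helpers (polylines in pixel coordinates)."""

from __future__ import annotations

import numpy as np


def polyline_arclength(poly: np.ndarray) -> np.ndarray:
    """Cumulative arc length (same units as coordinates) along an (M,2) polyline."""
    poly = np.asarray(poly, dtype=float)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def polyline_project(points: np.ndarray, poly: np.ndarray):
    """Project points onto a polyline.

    Parameters
    ----------
    points : (N, 2) array of (x, y)
    poly : (M, 2) polyline, M ≥ 2

    Returns
    -------
    dist : (N,) distance from each point to its nearest polyline location
    s : (N,) arc-length coordinate of the projection
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(poly, dtype=float)
    p0 = poly[:-1]  # (M-1, 2)
    d = poly[1:] - p0  # (M-1, 2)
    seglen2 = np.maximum(np.sum(d * d, axis=1), 1e-30)
    s0 = polyline_arclength(poly)[:-1]

    rel = points[:, None, :] - p0[None, :, :]  # (N, M-1, 2)
    t = np.clip(np.einsum("nmk,mk->nm", rel, d) / seglen2, 0.0, 1.0)
    proj = p0[None, :, :] + t[:, :, None] * d[None, :, :]
    dist2 = np.sum((points[:, None, :] - proj) ** 2, axis=2)
    idx = np.argmin(dist2, axis=1)
    n = np.arange(len(points))
    dist = np.sqrt(dist2[n, idx])
    s = s0[idx] + t[n, idx] * np.sqrt(seglen2[idx])
    return dist, s


def point_at_arclength(poly: np.ndarray, s) -> np.ndarray:
    """Interpolate (x, y) positions at arc-length coordinates ``s``."""
    poly = np.asarray(poly, dtype=float)
    cum = polyline_arclength(poly)
    s = np.atleast_1d(np.asarray(s, dtype=float))
    x = np.interp(s, cum, poly[:, 0])
    y = np.interp(s, cum, poly[:, 1])
    return np.stack([x, y], axis=1)


def tangent_at_arclength(poly: np.ndarray, s) -> np.ndarray:
    """Unit tangent vectors at arc-length coordinates ``s`` (finite difference)."""
    cum = polyline_arclength(poly)
    total = cum[-1]
    h = max(total * 1e-3, 1e-6)
    s = np.atleast_1d(np.asarray(s, dtype=float))
    a = point_at_arclength(poly, np.clip(s - h, 0, total))
    b = point_at_arclength(poly, np.clip(s + h, 0, total))
    t = b - a
    norm = np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-12)
    return t / norm
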