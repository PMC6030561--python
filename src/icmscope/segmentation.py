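"""Cell detection and per-cell geometry from the phase-contrast channel.

Cells appear darker than the background in phase contrast, so detection
thresholds the inverted, Gaussian-smoothed phase channel (Otsu by default).
Touching cells are separated by marker-based watershed where the distance
transform shows two well-separated ridge plateaus (an automated stand-in for
manual splitting of touching cells).

Per-cell geometry follows the standard rod-cell convention: the medial axis
is the pruned skeleton of the mask, extended along its end tangents to the
boundary to define the two poles; cell length is the arc length of that
polyline, width the mean transverse extent at interior axis points.  All
lengths are reported in µm; pixel centers sit at integer coordinates with a
0-based, top-left origin, and points are (x, y) = (column, row).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation as sks

from .errors import ConfigError, DegenerateGeometryError, RegistrationRequiredError
from .geometry import polyline_arclength


@dataclass(frozen=True)
class SegmentationConfig:
    """Detection and shape-filter settings (areas in µm², distances in px)."""

    min_area: float = 0.5
    max_area: float = 8.0
    min_aspect: float = 1.5
    smoothing_sigma: float = 1.0
    split_min_distance: float = 7.0
    split_h_rel: float = 0.4  # relative ridge-dip depth that triggers a split
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None

    def validate(self) -> None:
        if not self.min_area < self.max_area:
            raise ConfigError("min_area must be < max_area")
        if self.min_aspect < 1:
            raise ConfigError("min_aspect must be >= 1")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ConfigError("fixed threshold_method requires fixed_threshold")


@dataclass
class CellRecord:
    """One segmented cell with its geometry.

    ``mask`` is a boolean array local to ``bbox = (min_row, min_col)``;
    ``medial_axis_px`` runs pole_a → pole_b in full-image (x, y) pixel
    coordinates with ``s = 0`` at pole_a.
    """

    id: int
    bbox: tuple  # (min_row, min_col)
    mask: np.ndarray
    outline_xy: np.ndarray
    medial_axis_px: np.ndarray | None
    length_um: float
    width_um: float
    pole_a: tuple
    pole_b: tuple
    area_um2: float
    centroid_xy: tuple
    pixel_size: float
    qc_flags: list = field(default_factory=list)
    _edt: np.ndarray = field(default=None, repr=False)

    @property
    def edt(self) -> np.ndarray:
        """Euclidean distance transform of the mask (lazy, cached)."""
        if self._edt is None:
            self._edt = ndimage.distance_transform_edt(self.mask)
        return self._edt

    def flip(self) -> None:
        """Reverse axis orientation in place (pole_a ↔ pole_b)."""
        if self.medial_axis_px is not None:
            self.medial_axis_px = self.medial_axis_px[::-1].copy()
        self.pole_a, self.pole_b = self.pole_b, self.pole_a


# ---------------------------------------------------------------------------
# medial axis
# ---------------------------------------------------------------------------

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray):
    nodes = set(map(tuple, np.argwhere(skel)))
    adj = {}
    for r, c in nodes:
        nb = []
        for dr, dc in _NBRS:
            if (r + dr, c + dc) in nodes:
                nb.append(((r + dr, c + dc), math.hypot(dr, dc)))
        adj[(r, c)] = nb
    return adj


def _prune_branches(adj: dict, prune_len: float) -> dict:
    """Iteratively delete side branches shorter than prune_len."""
    adj = {k: list(v) for k, v in adj.items()}
    changed = True
    while changed:
        changed = False
        endpoints = [n for n, nb in adj.items() if len(nb) == 1]
        for ep in endpoints:
            if ep not in adj or len(adj[ep]) != 1:
                continue
            path, dist = [ep], 0.0
            cur, prev = ep, None
            while True:
                nbrs = [(n, w) for n, w in adj[cur] if n != prev]
                if len(adj[cur]) >= 3 or (cur != ep and len(adj[cur]) != 2):
                    break
                if not nbrs:
                    break
                nxt, w = nbrs[0]
                dist += w
                prev, cur = cur, nxt
                if len(adj[cur]) >= 3:
                    break
                path.append(cur)
                if dist > prune_len:
                    break
            # cur is a junction (deg >= 3) reached from a short dangling branch
            if len(adj.get(cur, [])) >= 3 and dist <= prune_len:
                for n in path:
                    for m, _ in adj.pop(n, []):
                        if m in adj:
                            adj[m] = [(q, w) for q, w in adj[m] if q != n]
                changed = True
    return adj


def _farthest(adj: dict, start):
    dist = {start: 0.0}
    prev = {start: None}
    pq = [(0.0, start)]
    while pq:
        d, u = heapq.heappop(pq)
        if d > dist.get(u, math.inf):
            continue
        for v, w in adj[u]:
            nd = d + w
            if nd < dist.get(v, math.inf):
                dist[v] = nd
                prev[v] = u
                heapq.heappush(pq, (nd, v))
    far = max(dist, key=dist.get)
    return far, dist, prev


def _longest_path(adj: dict):
    start = next(iter(adj))
    u, _, _ = _farthest(adj, start)
    v, _, prev = _farthest(adj, u)
    path = []
    cur = v
    while cur is not None:
        path.append(cur)
        cur = prev[cur]
    return path[::-1]


def _smooth_polyline(pts: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing of interior points (endpoints fixed).

    Removes the diagonal-step zigzag of discrete skeletons so that arc length
    is not systematically inflated at oblique cell orientations.
    """
    n = len(pts)
    if n < 3:
        return pts
    out = pts.astype(float).copy()
    half = window // 2
    for i in range(1, n - 1):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = pts[lo:hi].mean(axis=0)
    return out


def medial_axis_of(mask: np.ndarray, pixel_size: float):
    """Medial axis polyline, length and width of a single-component mask.

    Returns ``(polyline_xy, length_um, width_um)`` with the polyline in
    local (x, y) pixel coordinates spanning pole to pole.  Raises
    :class:`DegenerateGeometryError` for masks with no elongation.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 4:
        raise DegenerateGeometryError("mask too small for a medial axis")
    skel = morphology.skeletonize(mask)
    if skel.sum() == 0:
        raise DegenerateGeometryError("empty skeleton")
    edt = ndimage.distance_transform_edt(mask)
    width_px_est = 2.0 * float(np.median(edt[skel]))

    adj = _skeleton_graph(skel)
    if len(adj) == 1:
        raise DegenerateGeometryError("skeleton is a single point")
    pruned = _prune_branches(adj, prune_len=max(width_px_est, 2.0))
    if len(pruned) < 2:
        pruned = adj  # pruning collapsed everything; fall back to raw skeleton
    path = _longest_path(pruned)
    if len(path) < 2:
        raise DegenerateGeometryError("skeleton has no extent")

    pts = np.array([(c, r) for r, c in path], dtype=float)  # (x, y)
    pts = _smooth_polyline(pts)

    # extend each end along its tangent to the sub-pixel mask boundary (the
    # poles); the boundary is the 0.5 level of the bilinearly interpolated
    # mask, which is symmetric under translation, rotation and reflection
    maskf = mask.astype(float)

    def occupancy(p: np.ndarray) -> float:
        return float(ndimage.map_coordinates(maskf, [[p[1]], [p[0]]], order=1)[0])

    def extend(end: np.ndarray, inner: np.ndarray) -> np.ndarray:
        d = end - inner
        nrm = np.linalg.norm(d)
        if nrm < 1e-9:
            return end
        d = d / nrm
        lo, step = 0.0, 0.5
        hi = None
        for k in range(1, int(2 * (width_px_est + 3)) + 1):
            if occupancy(end + k * step * d) < 0.5:
                hi = k * step
                break
            lo = k * step
        if hi is None:
            return end + lo * d
        for _ in range(20):
            mid = 0.5 * (lo + hi)
            if occupancy(end + mid * d) >= 0.5:
                lo = mid
            else:
                hi = mid
        return end + lo * d

    k = min(4, len(pts) - 1)
    start = extend(pts[0], pts[k])
    stop = extend(pts[-1], pts[-1 - k])
    poly = np.vstack([start, pts, stop])
    # drop duplicate points
    keep = np.concatenate([[True], np.linalg.norm(np.diff(poly, axis=0), axis=1) > 1e-6])
    poly = poly[keep]

    cum = polyline_arclength(poly)
    length_um = float(cum[-1] * pixel_size)

    # width: mean transverse extent at interior axis points
    interior = (cum >= width_px_est / 2) & (cum <= cum[-1] - width_px_est / 2)
    ref = poly[interior] if interior.sum() >= 2 else poly
    vals = ndimage.map_coordinates(edt, [ref[:, 1], ref[:, 0]], order=1)
    width_um = float(2.0 * vals.mean() * pixel_size)
    return poly, length_um, width_um


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def split_touching(labels: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Divide components whose distance transform shows multiple ridge plateaus.

    A component is split when the high band of its distance transform
    (pixels above ``(1 − split_h_rel)`` × the ridge maximum, i.e. the medial
    ridge) falls apart into ≥ 2 connected markers separated by at least
    ``split_min_distance`` pixels — the signature of two rods joined by a
    neck.  Marker-based watershed then divides the component.  Single cells
    have one connected ridge band and are left unchanged.
    """
    eight = np.ones((3, 3), dtype=int)
    out = np.zeros_like(labels)
    next_id = 1
    for region in measure.regionprops(labels):
        sub = region.image
        minr, minc, _, _ = region.bbox
        edt = ndimage.distance_transform_edt(np.pad(sub, 1))[1:-1, 1:-1]
        ridge = edt > (1.0 - cfg.split_h_rel) * edt.max()
        markers, n_mark = ndimage.label(ridge, structure=eight)
        if n_mark >= 2:
            cents = ndimage.center_of_mass(np.ones_like(markers), markers,
                                           range(1, n_mark + 1))
            cents = np.asarray(cents)
            keep = []
            for i, c in enumerate(cents):
                if all(np.linalg.norm(c - cents[j]) >= cfg.split_min_distance
                       for j in keep):
                    keep.append(i)
            if len(keep) >= 2:
                sel = np.isin(markers, [i + 1 for i in keep]) * markers
                sel_lab, _ = ndimage.label(sel > 0, structure=eight)
                ws = sks.watershed(-edt, markers=sel_lab, mask=sub)
                for v in np.unique(ws):
                    if v == 0:
                        continue
                    out[minr:minr + sub.shape[0], minc:minc + sub.shape[1]][
                        ws == v] = next_id
                    next_id += 1
                continue
        out[minr:minr + sub.shape[0], minc:minc + sub.shape[1]][sub] = next_id
        next_id += 1
    return out


def segment_cells(
    phase: np.ndarray,
    pixel_size: float,
    cfg: SegmentationConfig | None = None,
    *,
    correction_applied: bool = False,
    waive_correction: bool = False,
):
    """Detect cells in a phase channel and compute per-cell geometry.

    The channel must have been registered (``correction_applied``) or the
    requirement explicitly waived.  Returns ``(label_image, records)`` where
    labels are positive integers matching ``CellRecord.id`` (background 0).
    A blank image yields an empty result, not an error.
    """
    cfg = cfg or SegmentationConfig()
    cfg.validate()
    if not (correction_applied or waive_correction):
        raise RegistrationRequiredError(
            "channels not registered; run distortion correction first or "
            "pass waive_correction=True"
        )
    phase = np.asarray(phase, dtype=float)
    sm = ndimage.gaussian_filter(phase, cfg.smoothing_sigma)
    inv = sm.max() - sm
    if cfg.threshold_method == "fixed":
        thr = cfg.fixed_threshold
    else:
        thr = filters.threshold_otsu(inv) if np.ptp(inv) > 0 else np.inf
    fg = inv > thr
    # a blank (noise-only) field is unimodal: Otsu lands mid-noise and marks
    # about half the pixels — treat that as "no detections", not as cells
    if fg.mean() > 0.45:
        return np.zeros_like(fg, dtype=int), []
    # drop speckles well below the area filter before the (per-component) split
    min_px = max(4, int(0.25 * cfg.min_area / pixel_size**2))
    lab, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(lab.ravel())
    fg = sizes[lab] >= min_px
    fg &= lab > 0
    fg = ndimage.binary_fill_holes(fg)
    raw = measure.label(fg)
    raw = split_touching(raw, cfg)

    records = []
    labels_out = np.zeros_like(raw)
    next_id = 1
    for region in measure.regionprops(raw):
        area_um2 = region.area * pixel_size**2
        if not (cfg.min_area <= area_um2 <= cfg.max_area):
            continue
        minor = max(region.axis_minor_length, 1e-9)
        if region.axis_major_length / minor < cfg.min_aspect:
            continue
        sub = region.image
        minr, minc, _, _ = region.bbox
        try:
            poly, length_um, width_um = medial_axis_of(sub, pixel_size)
        except DegenerateGeometryError:
            continue  # no elongation: excluded from axial analyses
        poly_global = poly + np.array([minc, minr], dtype=float)
        contours = measure.find_contours(np.pad(sub.astype(float), 1), 0.5)
        outline = max(contours, key=len) if contours else np.zeros((0, 2))
        outline_xy = outline[:, ::-1] + np.array([minc - 1, minr - 1])
        rec = CellRecord(
            id=next_id,
            bbox=(minr, minc),
            mask=sub.copy(),
            outline_xy=outline_xy,
            medial_axis_px=poly_global,
            length_um=length_um,
            width_um=width_um,
            pole_a=tuple(poly_global[0]),
            pole_b=tuple(poly_global[-1]),
            area_um2=area_um2,
            centroid_xy=(region.centroid[1], region.centroid[0]),
            pixel_size=pixel_size,
        )
        records.append(rec)
        labels_out[minr:minr + sub.shape[0], minc:minc + sub.shape[1]][sub] = next_id
        next_id += 1
    return labels_out, records


def segment_field(field_img, cfg: SegmentationConfig | None = None,
                  waive_correction: bool = False):
    """Segment the phase channel of a :class:`FieldImage` (registration-aware)."""
    return segment_cells(
        field_img.channel("phase"),
        field_img.pixel_size,
        cfg,
        correction_applied=field_img.provenance.registration_applied,
        waive_correction=waive_correction,
    )


def cells_frame(records) -> "object":
    """Tabulate cell records as a DataFrame (CSV-ready)."""
    import pandas as pd

    rows = []
    for c in records:
        rows.append(
            dict(
                cell_id=c.id,
                centroid_x=c.centroid_xy[0],
                centroid_y=c.centroid_xy[1],
                length_um=c.length_um,
                width_um=c.width_um,
                area_um2=c.area_um2,
                pole_a_x=c.pole_a[0],
                pole_a_y=c.pole_a[1],
                pole_b_x=c.pole_b[0],
                pole_b_y=c.pole_b[1],
                qc_flags=";".join(c.qc_flags),
            )
        )
    return pd.DataFrame(rows)
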