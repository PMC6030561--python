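"""Population-level statistics of ICM localization.

Implements the standard population readouts for single-cell fluorescence
surveys of membrane-compartment placement:

* demographs — per-cell axial intensity profiles stacked as a heatmap with
  cells sorted shortest to longest;
* centroid maps — focus positions in a pole-aligned, size-normalized cell
  frame, with the population-average outline;
* focus-count vs length tables with Tukey outlier flags;
* focus-spacing vs cell-length regression (in cells with two foci the
  inter-focus distance grows linearly with length when each focus keeps a
  fixed distance from its pole);
* pole-distance conservation statistics (median/IQR/CV of the old-pole and
  new-pole focus distances);
* paired old/new focus intensity comparison (Wilcoxon signed-rank);
* correlation of bulk BChl content (A770/OD660) with mean cellular
  fluorescence;
* classification of a population as longitudinally restricted vs
  nonrestricted from per-cell axial occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, InsufficientDataError, PairingError


# ---------------------------------------------------------------------------
# demograph
# ---------------------------------------------------------------------------


@dataclass
class Demograph:
    """Cells × axial-bin intensity matrix, rows sorted by cell length."""

    matrix: np.ndarray
    row_order: list  # cell ids, length-ascending
    lengths: np.ndarray  # µm, same order as rows
    alignment: str
    bin_step: float
    per_cell_norm: str


def build_demograph(
    profiles,
    alignment: str = "old_pole_left",
    per_cell_norm: str = "none",
    bin_step: float | None = None,
) -> Demograph:
    """Stack oriented axial profiles into a length-sorted intensity matrix.

    Rows are resampled to a common ``bin_step`` (default: the profiles' own
    sampling step), left-aligned at s = 0 (``old_pole_left``) or centered at
    L/2 (``centered``); entries beyond a cell's length are NaN.
    ``per_cell_norm='max1'`` scales each row to unit maximum.
    """
    if alignment not in ("old_pole_left", "centered"):
        raise ConfigError(f"unknown alignment {alignment!r}")
    if per_cell_norm not in ("none", "max1"):
        raise ConfigError(f"unknown per_cell_norm {per_cell_norm!r}")
    profiles = list(profiles)
    if not profiles:
        return Demograph(np.zeros((0, 0)), [], np.zeros(0), alignment,
                         bin_step or 0.0, per_cell_norm)
    step = bin_step or profiles[0].sampling_step
    order = np.argsort([p.length_um for p in profiles], kind="stable")
    lengths = np.array([profiles[i].length_um for i in order])
    L_max = lengths.max()
    n_bins = int(np.floor(L_max / step)) + 1
    mat = np.full((len(profiles), n_bins), np.nan)
    centers = np.arange(n_bins) * step
    for row, i in enumerate(order):
        p = profiles[i]
        L = p.length_um
        offset = (L_max - L) / 2 if alignment == "centered" else 0.0
        s_target = centers - offset
        inside = (s_target >= 0) & (s_target <= L)
        vals = np.interp(s_target[inside], p.s, p.I)
        if per_cell_norm == "max1":
            m = np.nanmax(vals) if len(vals) else np.nan
            if m and m > 0:
                vals = vals / m
        mat[row, inside] = vals
    return Demograph(
        matrix=mat,
        row_order=[profiles[i].cell_id for i in order],
        lengths=lengths,
        alignment=alignment,
        bin_step=step,
        per_cell_norm=per_cell_norm,
    )


# ---------------------------------------------------------------------------
# centroid map
# ---------------------------------------------------------------------------


def centroid_map(cells, foci, profiles=None, n_outline: int = 25):
    """Focus positions in a pole-aligned unit-cell frame + mean outline.

    For each focus: ``x_norm = s_pos / L`` (0 = old pole when profiles were
    oriented) and ``y_norm`` = transverse offset / local half-width.  The
    population mean outline is the average of the per-cell half-width
    profiles on a normalized axial grid (x in [0, 1], half-width in µm).

    Returns ``(points_df, outline)`` where outline is an (n, 2) array of
    (x_norm, mean half-width µm).
    """
    by_id = {c.id: c for c in cells}
    prof_by_id = {p.cell_id: p for p in profiles} if profiles else {}
    rows = []
    for f in foci:
        c = by_id.get(f.cell_id)
        if c is None or c.length_um <= 0:
            continue
        x_norm = f.s_pos / c.length_um
        hw_px = None
        p = prof_by_id.get(f.cell_id)
        if p is not None and p.halfwidth_px is not None:
            hw_px = float(np.interp(f.s_pos, p.s, p.halfwidth_px))
        if not hw_px or hw_px <= 0:
            hw_px = c.width_um / 2 / c.pixel_size
        y_norm = f.t_offset_px / hw_px
        rows.append(dict(cell_id=f.cell_id, x_norm=x_norm, y_norm=y_norm,
                         mean_intensity=f.mean_intensity))
    points = pd.DataFrame(rows)

    grid = np.linspace(0, 1, n_outline)
    hw_sum = np.zeros(n_outline)
    n = 0
    for p in prof_by_id.values():
        if p.halfwidth_px is None or p.length_um <= 0:
            continue
        c = by_id.get(p.cell_id)
        px = c.pixel_size if c else 1.0
        hw_sum += np.interp(grid * p.length_um, p.s, p.halfwidth_px) * px
        n += 1
    outline = np.stack([grid, hw_sum / n if n else hw_sum], axis=1)
    return points, outline


# ---------------------------------------------------------------------------
# focus count / length classes
# ---------------------------------------------------------------------------


def tukey_outliers(values, k: float = 1.5):
    """Indices of values outside [Q1 − k·IQR, Q3 + k·IQR] (linear-interpolation quartiles)."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        return np.array([], dtype=int)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return np.nonzero((v < q1 - k * iqr) | (v > q3 + k * iqr))[0]


def foci_count_length_table(cells, foci):
    """Per focus-count class {0, 1, 2, 3+}: n, length quartiles, Tukey outliers.

    Returns ``(summary_df, per_cell_df)``; per-cell rows carry the class and
    an outlier flag (outliers computed within each class).
    """
    counts = {}
    for f in foci:
        counts[f.cell_id] = counts.get(f.cell_id, 0) + 1
    rows = []
    for c in cells:
        n = counts.get(c.id, 0)
        cls = "3+" if n >= 3 else str(n)
        rows.append(dict(cell_id=c.id, n_foci=n, focus_class=cls,
                         length_um=c.length_um, outlier=False))
    per_cell = pd.DataFrame(rows)
    summary_rows = []
    for cls, grp in per_cell.groupby("focus_class"):
        lens = grp["length_um"].to_numpy()
        out_idx = tukey_outliers(lens)
        per_cell.loc[grp.index[out_idx], "outlier"] = True
        q1, med, q3 = np.percentile(lens, [25, 50, 75])
        summary_rows.append(dict(focus_class=cls, n=len(lens), median_um=med,
                                 q1_um=q1, q3_um=q3, n_outliers=len(out_idx)))
    summary = pd.DataFrame(summary_rows)
    return summary, per_cell


# ---------------------------------------------------------------------------
# spacing regression
# ---------------------------------------------------------------------------


@dataclass
class SpacingPair:
    cell_id: int
    spacing: float  # µm between the two focus positions
    length: float  # µm


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    n: int
    zero_variance: bool = False


def spacing_pairs(cells, foci):
    """Inter-focus spacing vs length for every two-focus cell."""
    by_cell = {}
    for f in foci:
        by_cell.setdefault(f.cell_id, []).append(f)
    lengths = {c.id: c.length_um for c in cells}
    pairs = []
    for cid, fl in by_cell.items():
        if len(fl) != 2 or cid not in lengths:
            continue
        s = sorted(f.s_pos for f in fl)
        pairs.append(SpacingPair(cell_id=cid, spacing=s[1] - s[0],
                                 length=lengths[cid]))
    return pairs


def spacing_regression(pairs) -> RegressionResult:
    """Ordinary least squares of inter-focus spacing on cell length."""
    pairs = list(pairs)
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"spacing regression needs >= 3 pairs, got {len(pairs)}"
        )
    x = np.array([p.length for p in pairs])
    y = np.array([p.spacing for p in pairs])
    if np.allclose(y, y[0]):
        return RegressionResult(slope=0.0, intercept=float(y[0]), r=0.0,
                                n=len(pairs), zero_variance=True)
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r=float(res.rvalue), n=len(pairs))


# ---------------------------------------------------------------------------
# pole distances, intensity comparison
# ---------------------------------------------------------------------------


def _oriented_cell_ids(calls):
    return {c.cell_id for c in calls if c.old_pole in ("A", "B")} if calls else None


def pole_distance_stats(foci, cells, calls=None, include_unassigned=False):
    """Dispersion of focus distances from the poles on oriented cells.

    In two-focus cells the smaller-s focus is old-pole-proximal (distance =
    s) and the larger-s focus new-pole-proximal (distance = L − s); a single
    focus counts toward the old pole.  Returns a dict with median, IQR and
    coefficient of variation for both pole distances.
    """
    keep = _oriented_cell_ids(calls)
    lengths = {c.id: c.length_um for c in cells}
    by_cell = {}
    for f in foci:
        if f.cell_id not in lengths:
            continue
        if keep is not None and not include_unassigned and f.cell_id not in keep:
            continue
        by_cell.setdefault(f.cell_id, []).append(f)
    old_d, new_d = [], []
    for cid, fl in by_cell.items():
        s = sorted(f.s_pos for f in fl)
        if len(fl) == 1:
            old_d.append(s[0])
        elif len(fl) == 2:
            old_d.append(s[0])
            new_d.append(lengths[cid] - s[1])

    def summarize(v):
        v = np.asarray(v, dtype=float)
        if len(v) == 0:
            return dict(n=0, median=np.nan, iqr=np.nan, cv=np.nan)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        cv = float(v.std(ddof=1) / v.mean()) if len(v) > 1 and v.mean() != 0 else np.nan
        return dict(n=len(v), median=float(med), iqr=float(q3 - q1), cv=cv)

    return {"old": summarize(old_d), "new": summarize(new_d)}


def old_new_intensity_compare(cells, foci, calls=None):
    """Paired comparison of old- vs new-pole focus intensity in 2-focus cells.

    Returns a dict with the per-cell new/old mean-intensity ratios, their
    median, and a Wilcoxon signed-rank statistic on the paired differences.
    """
    keep = _oriented_cell_ids(calls)
    lengths = {c.id: c.length_um for c in cells}
    by_cell = {}
    for f in foci:
        if f.cell_id not in lengths:
            continue
        if keep is not None and f.cell_id not in keep:
            continue
        by_cell.setdefault(f.cell_id, []).append(f)
    old_i, new_i, ratios = [], [], []
    for fl in by_cell.values():
        if len(fl) != 2:
            continue
        a, b = sorted(fl, key=lambda f: f.s_pos)
        old_i.append(a.mean_intensity)
        new_i.append(b.mean_intensity)
        if a.mean_intensity > 0:
            ratios.append(b.mean_intensity / a.mean_intensity)
    result = dict(
        n_pairs=len(old_i),
        median_ratio=float(np.median(ratios)) if ratios else np.nan,
        ratios=np.asarray(ratios),
        median_old=float(np.median(old_i)) if old_i else np.nan,
        median_new=float(np.median(new_i)) if new_i else np.nan,
        wilcoxon_stat=np.nan,
        wilcoxon_p=np.nan,
    )
    diffs = np.asarray(new_i) - np.asarray(old_i)
    if len(diffs) >= 5 and np.any(diffs != 0):
        w = sps.wilcoxon(diffs)
        result["wilcoxon_stat"] = float(w.statistic)
        result["wilcoxon_p"] = float(w.pvalue)
    return result


# ---------------------------------------------------------------------------
# BChl content correlation
# ---------------------------------------------------------------------------


@dataclass
class BChlMeasurement:
    """Bulk spectrophotometry of one culture; content is always recomputed."""

    culture_id: str
    A770: float
    OD660: float
    light_intensity: float = float("nan")  # µmol s⁻¹ m⁻², metadata only

    @property
    def content(self) -> float:
        return bchl_content(self.A770, self.OD660)


def bchl_content(a770: float, od660: float) -> float:
    """BChl-a content normalized to culture density: A770 / OD660."""
    if od660 <= 0:
        raise ConfigError("OD660 must be > 0")
    if a770 < 0:
        raise ConfigError("A770 must be >= 0")
    return a770 / od660


def intensity_content_correlation(measurements, mean_intensities: dict):
    """Pearson r between bulk BChl content and mean cellular fluorescence.

    ``mean_intensities`` maps culture_id → population mean background-
    corrected cellular intensity.  Keys must pair exactly with the
    measurements; unmatched ids raise :class:`PairingError`.
    Returns ``(r, table_df)``.
    """
    meas = {m.culture_id: m for m in measurements}
    unmatched = set(meas) ^ set(mean_intensities)
    if unmatched:
        raise PairingError(unmatched)
    if len(meas) < 3:
        raise InsufficientDataError("need >= 3 paired cultures")
    ids = sorted(meas)
    content = np.array([meas[i].content for i in ids])
    intensity = np.array([mean_intensities[i] for i in ids])
    r = float(sps.pearsonr(content, intensity).statistic)
    table = pd.DataFrame(
        dict(culture_id=ids, content=content, mean_intensity=intensity)
    )
    return r, table


# ---------------------------------------------------------------------------
# localization classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassificationConfig:
    occupancy_threshold: float = 0.5  # cell is 'focal' if occupancy <= this
    focal_fraction_threshold: float = 0.8  # population restricted if >= this
    nonrestricted_fraction: float = 0.2  # population nonrestricted if <= this
    min_cells: int = 30


@dataclass
class ClassificationResult:
    label: str  # 'restricted' | 'nonrestricted' | 'indeterminate'
    focal_fraction: float
    occupancy: np.ndarray = field(repr=False, default=None)
    n_cells: int = 0
    insufficient_data: bool = False


def classify_localization(profiles, cfg: ClassificationConfig | None = None
                          ) -> ClassificationResult:
    """Label a population restricted vs nonrestricted from axial occupancy.

    Per-cell occupancy is the fraction of axial samples whose intensity
    reaches half that cell's profile maximum; a cell is focal when occupancy
    ≤ ``occupancy_threshold``.  The population is restricted when the focal
    fraction ≥ ``focal_fraction_threshold``, nonrestricted when ≤
    ``nonrestricted_fraction``, else indeterminate.  Fewer than ``min_cells``
    analyzable cells yields an indeterminate result with the
    insufficient-data flag set.
    """
    cfg = cfg or ClassificationConfig()
    occ = []
    for p in profiles:
        I = np.asarray(p.I, dtype=float)
        m = I.max()
        if m <= 0 or len(I) < 3:
            continue
        occ.append(float(np.mean(I >= 0.5 * m)))
    occ = np.asarray(occ)
    if len(occ) < cfg.min_cells:
        return ClassificationResult(
            label="indeterminate", focal_fraction=np.nan, occupancy=occ,
            n_cells=len(occ), insufficient_data=True,
        )
    focal = float(np.mean(occ <= cfg.occupancy_threshold))
    if focal >= cfg.focal_fraction_threshold:
        label = "restricted"
    elif focal <= cfg.nonrestricted_fraction:
        label = "nonrestricted"
    else:
        label = "indeterminate"
    return ClassificationResult(label=label, focal_fraction=focal,
                                occupancy=occ, n_cells=len(occ))


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def plot_demograph(dg: Demograph, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    extent = [0, dg.matrix.shape[1] * dg.bin_step, 0, dg.matrix.shape[0]]
    im = ax.imshow(dg.matrix, aspect="auto", origin="lower", extent=extent,
                   cmap="viridis", interpolation="nearest")
    ax.set_xlabel("distance along medial axis (µm)")
    ax.set_ylabel("cells (sorted by length)")
    fig.colorbar(im, ax=ax, label="BChl fluorescence (a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_centroid_map(points: pd.DataFrame, outline: np.ndarray, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    if len(outline):
        ax.plot(outline[:, 0], outline[:, 1], "k-", lw=1)
        ax.plot(outline[:, 0], -outline[:, 1], "k-", lw=1)
    if len(points):
        ax.scatter(points["x_norm"], points["y_norm"] * (
            outline[:, 1].mean() if len(outline) else 1.0), s=6, alpha=0.5)
    ax.set_xlabel("normalized position from old pole")
    ax.set_ylabel("transverse (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
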