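"""Synthetic micrograph generator with exact ground truth.

Emulates epifluorescence fields of rod-shaped purple nonsulfur bacteria in
which the bacteriochlorophyll (BChl) autofluorescence is either

* **restricted** — confined to one or two discrete foci (intracytoplasmic
  membrane sites) at conserved distances from the cell poles: a single focus
  ``d_old`` µm from the old pole in short cells, plus a second, weaker focus
  ``d_new`` µm from the new pole once the cell length exceeds ``L_star``; or
* **nonrestricted** — uniform over the whole cell.

Cells are spherocylinders (optionally slightly curved, with a mild width
taper beyond ``L_star`` approximating budding morphology) placed without
overlap by rejection sampling.  Three channels are rendered: a phase-contrast
proxy (dark cells on a bright background), the BChl fluorescence channel, and
an adhesin-stain channel with a diffraction-limited spot at the old pole of a
random subset of cells (only part of a population carries the polar
adhesin).  Optics are modelled as a Gaussian PSF; noise as Poisson shot noise
followed by additive Gaussian read noise.

Everything is deterministic given ``SceneConfig.seed``, and the returned
:class:`SceneTruth` carries exact per-cell geometry and per-focus positions
and integrated intensities, so recovery by the analysis pipeline can be
scored without real data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, DataError, PlacementError
from .geometry import point_at_arclength, polyline_project, tangent_at_arclength
from .imgio import FieldImage, Provenance, write_field


@dataclass(frozen=True)
class LocalizationModel:
    """Phenomenological model of longitudinal BChl localization.

    Parameters (µm unless noted): ``d_old`` — distance of the first focus
    from the old pole; ``d_new`` — distance of the second focus from the new
    pole; ``L_star`` — length above which a second focus exists; ``rho`` —
    new/old peak intensity ratio (the second focus is consistently weaker);
    ``sigma_focus`` — Gaussian axial extent of a focus; ``amp`` — peak signal
    in photons/pixel.
    """

    pattern: str = "restricted"
    d_old: float = 0.6
    d_new: float = 0.5
    L_star: float = 2.5
    rho: float = 0.6
    sigma_focus: float = 0.25
    amp: float = 300.0

    def validate(self) -> None:
        if self.pattern not in ("restricted", "nonrestricted"):
            raise ConfigError(f"unknown pattern {self.pattern!r}")
        if self.pattern == "restricted" and not (self.d_old + self.d_new < self.L_star):
            raise ConfigError("model requires d_old + d_new < L_star")
        if not (0 < self.rho <= 1):
            raise ConfigError("rho must be in (0, 1]")
        if self.sigma_focus <= 0:
            raise ConfigError("sigma_focus must be > 0")
        if self.amp <= 0:
            raise ConfigError("amp must be > 0")


@dataclass(frozen=True)
class SceneConfig:
    """Imaging and population parameters of one synthetic field.

    ``length_dist`` is (mean, sd, min, max) of a truncated normal in µm.
    Intensities are in photons/pixel so that Poisson noise is meaningful.
    """

    n_cells: int = 100
    field_shape: tuple = (1024, 1024)
    pixel_size: float = 0.065
    length_dist: tuple = (2.2, 0.6, 1.5, 4.2)
    width: float = 0.8
    curvature: float = 0.0  # 1/µm; 0 = straight rods
    adhesin_fraction: float = 0.6
    psf_sigma: float = 0.1  # µm
    background: float = 100.0
    read_noise_sd: float = 2.0
    poisson_noise: bool = True
    seed: int = 0
    # rendering constants
    phase_background: float = 200.0
    phase_cell_level: float = 60.0
    adhesin_amp: float = 400.0
    adhesin_sigma: float = 0.15  # µm
    taper_fraction: float = 0.8  # relative tip width for cells longer than L_star
    include_adhesin: bool = True
    max_place_attempts: int = 100

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be > 0")
        mean, sd, lo, hi = self.length_dist
        if not (0 < lo <= hi):
            raise ConfigError("length bounds must satisfy 0 < min <= max")
        if self.width <= 0:
            raise ConfigError("width must be > 0")
        if not (0 <= self.adhesin_fraction <= 1):
            raise ConfigError("adhesin_fraction must be in [0, 1]")
        if self.background < 0 or self.read_noise_sd < 0 or self.psf_sigma < 0:
            raise ConfigError("background, read_noise_sd, psf_sigma must be >= 0")
        if self.n_cells < 0:
            raise ConfigError("n_cells must be >= 0")


@dataclass
class TruthFocus:
    s_um: float  # longitudinal position from the old pole
    peak_amp: float  # photons/pixel at the focus center
    integrated: float = 0.0  # summed noise-free signal of this focus


@dataclass
class TruthCell:
    id: int
    axis_px: np.ndarray  # polyline old pole -> new pole, pixel coords (x, y)
    length_um: float
    width_um: float
    old_pole_xy: tuple
    new_pole_xy: tuple
    centroid_xy: tuple
    area_px: int
    outline_xy: np.ndarray  # closed polygon, pixel coords
    foci: list
    adhesin: bool
    pattern: str
    integrated_fluor: float = 0.0
    # rasterization cache (pixel indices), used internally for rendering
    _pix_xy: np.ndarray = field(default=None, repr=False)
    _pix_s_um: np.ndarray = field(default=None, repr=False)


@dataclass
class SceneTruth:
    cells: list
    config: SceneConfig
    model: LocalizationModel

    def cells_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                dict(
                    cell_id=c.id,
                    length_um=c.length_um,
                    width_um=c.width_um,
                    centroid_x=c.centroid_xy[0],
                    centroid_y=c.centroid_xy[1],
                    old_pole_x=c.old_pole_xy[0],
                    old_pole_y=c.old_pole_xy[1],
                    new_pole_x=c.new_pole_xy[0],
                    new_pole_y=c.new_pole_xy[1],
                    area_px=c.area_px,
                    n_foci=len(c.foci),
                    adhesin=c.adhesin,
                    pattern=c.pattern,
                    integrated_fluor=c.integrated_fluor,
                )
            )
        return pd.DataFrame(rows)

    def foci_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            for k, f in enumerate(c.foci):
                xy = point_at_arclength(c.axis_px, f.s_um / self.config.pixel_size)[0]
                rows.append(
                    dict(
                        cell_id=c.id,
                        focus_index=k,
                        s_um=f.s_um,
                        x=xy[0],
                        y=xy[1],
                        peak_amp=f.peak_amp,
                        integrated=f.integrated,
                    )
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geometry of a single cell
# ---------------------------------------------------------------------------


def _cell_axis(center, angle, length_um, curvature, pixel_size) -> np.ndarray:
    """Axis polyline (old pole -> new pole) in pixel coordinates."""
    L_px = length_um / pixel_size
    if abs(curvature) <= 1e-9:
        t = np.array([-0.5, 0.5]) * L_px
        d = np.array([math.cos(angle), math.sin(angle)])
        return center + t[:, None] * d[None, :]
    # circular arc of signed curvature kappa (1/µm), centred on `center`
    R_px = 1.0 / (abs(curvature) * pixel_size)
    half = L_px / (2 * R_px)
    phis = np.linspace(-half, half, 17)
    # arc in local frame, tangent along +x at the midpoint
    pts = np.stack(
        [R_px * np.sin(phis), math.copysign(1.0, curvature) * R_px * (1 - np.cos(phis))],
        axis=1,
    )
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return center + pts @ rot.T


def _halfwidth_um(s_um, length_um, cfg: SceneConfig, model: LocalizationModel):
    """Local half-width profile; tapers toward the new pole beyond L_star."""
    h = np.full_like(np.asarray(s_um, dtype=float), cfg.width / 2.0)
    if length_um > model.L_star and cfg.taper_fraction < 1.0:
        span = length_um - model.L_star
        frac = np.clip((np.asarray(s_um) - model.L_star) / max(span, 1e-9), 0, 1)
        h = h * (1 - (1 - cfg.taper_fraction) * frac)
    return h


def _rasterize(axis_px, length_um, cfg, model, pad_px):
    """Pixels belonging to a spherocylindrical cell.

    Returns (xs, ys, s_um, claim_xs, claim_ys): member pixels with their
    axial coordinate, plus a dilated "claimed" footprint used for
    overlap-free placement.
    """
    px = cfg.pixel_size
    L_px = length_um / px
    w2_px = cfg.width / 2.0 / px
    lo = np.floor(axis_px.min(axis=0) - w2_px - pad_px - 1).astype(int)
    hi = np.ceil(axis_px.max(axis=0) + w2_px + pad_px + 1).astype(int)
    xs, ys = np.meshgrid(np.arange(lo[0], hi[0] + 1), np.arange(lo[1], hi[1] + 1))
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)

    # spine: axis clipped inward by the cap radii so tip-to-tip length == L
    h_old = cfg.width / 2.0
    h_new = float(_halfwidth_um(length_um - cfg.width / 4.0, length_um, cfg, model))
    s_lo, s_hi = h_old / px, L_px - h_new / px
    cum = np.linspace(0, L_px, 33)
    spine_s = cum[(cum >= s_lo) & (cum <= s_hi)]
    spine_s = np.concatenate([[s_lo], spine_s, [s_hi]])
    spine = point_at_arclength(axis_px, spine_s)

    dist_spine, s_spine = polyline_project(pts, spine)
    s_spine_um = (s_spine + s_lo) * px  # arc length along full axis
    h_px = _halfwidth_um(s_spine_um, length_um, cfg, model) / px
    inside = dist_spine <= h_px
    claimed = dist_spine <= h_px + pad_px

    _, s_axis = polyline_project(pts[inside], axis_px)
    return (
        pts[inside, 0].astype(int),
        pts[inside, 1].astype(int),
        s_axis * px,
        pts[claimed, 0].astype(int),
        pts[claimed, 1].astype(int),
    )


def _outline(axis_px, length_um, cfg, model, n=24) -> np.ndarray:
    """Closed outline polygon of the spherocylinder (pixel coords)."""
    px = cfg.pixel_size
    L_px = length_um / px
    h_old_px = cfg.width / 2.0 / px
    s_grid = np.linspace(h_old_px, L_px - h_old_px, n)
    pos = point_at_arclength(axis_px, s_grid)
    tan = tangent_at_arclength(axis_px, s_grid)
    nor = np.stack([-tan[:, 1], tan[:, 0]], axis=1)
    h_px = _halfwidth_um(s_grid * px, length_um, cfg, model) / px
    left = pos + nor * h_px[:, None]
    right = pos - nor * h_px[:, None]
    # semicircular caps
    def cap(center, tangent_out, radius):
        base = math.atan2(tangent_out[1], tangent_out[0])
        angs = base + np.linspace(-math.pi / 2, math.pi / 2, 9)
        return center + radius * np.stack([np.cos(angs), np.sin(angs)], axis=1)

    old_cap = cap(pos[0], -tan[0], h_px[0])
    new_cap = cap(pos[-1], tan[-1], h_px[-1])
    poly = np.vstack([left, new_cap[::-1], right[::-1], old_cap[::-1]])
    return np.vstack([poly, poly[:1]])


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def _truth_foci(length_um: float, model: LocalizationModel) -> list:
    if model.pattern != "restricted":
        return []
    if length_um < model.L_star:
        return [TruthFocus(s_um=model.d_old, peak_amp=model.amp)]
    return [
        TruthFocus(s_um=model.d_old, peak_amp=model.amp),
        TruthFocus(s_um=length_um - model.d_new, peak_amp=model.rho * model.amp),
    ]


def generate_scene(cfg: SceneConfig, model: LocalizationModel):
    """Generate one synthetic field.

    Returns ``(FieldImage, SceneTruth)``.  The field carries phase, fluor and
    (optionally) adhesin channels, already mutually aligned (the provenance
    registration flag is set).  Raises :class:`PlacementError` if the field
    is too crowded to place all cells without overlap within the attempt cap.
    """
    cfg.validate()
    model.validate()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.field_shape
    px = cfg.pixel_size
    psf_px = cfg.psf_sigma / px
    border = int(max(3, math.ceil(4 * psf_px)))
    gap_px = 2.0

    mean, sd, lo, hi = cfg.length_dist
    lengths = []
    while len(lengths) < cfg.n_cells:
        draw = rng.normal(mean, sd, size=cfg.n_cells)
        lengths.extend(draw[(draw >= lo) & (draw <= hi)].tolist())
    lengths = lengths[: cfg.n_cells]

    occupied = np.zeros((h, w), dtype=bool)
    cells = []
    for i, L in enumerate(lengths):
        placed = False
        for _ in range(cfg.max_place_attempts):
            extent = L / px / 2 + cfg.width / px + gap_px + border + 2
            if 2 * extent >= min(h, w):
                break
            cx = rng.uniform(extent, w - 1 - extent)
            cy = rng.uniform(extent, h - 1 - extent)
            angle = rng.uniform(0, 2 * math.pi)
            curv = cfg.curvature * rng.choice([-1.0, 1.0]) if cfg.curvature else 0.0
            axis = _cell_axis(np.array([cx, cy]), angle, L, curv, px)
            xs, ys, s_um, cxs, cys = _rasterize(axis, L, cfg, model, gap_px)
            if (
                xs.min() < border
                or ys.min() < border
                or xs.max() >= w - border
                or ys.max() >= h - border
            ):
                continue
            if occupied[cys, cxs].any():
                continue
            occupied[cys, cxs] = True
            if rng.random() < 0.5:
                axis = axis[::-1].copy()
                s_um = L - s_um
            cell = TruthCell(
                id=i + 1,
                axis_px=axis,
                length_um=L,
                width_um=cfg.width,
                old_pole_xy=tuple(axis[0]),
                new_pole_xy=tuple(axis[-1]),
                centroid_xy=(float(xs.mean()), float(ys.mean())),
                area_px=len(xs),
                outline_xy=_outline(axis, L, cfg, model),
                foci=_truth_foci(L, model),
                adhesin=bool(rng.random() < cfg.adhesin_fraction),
                pattern=model.pattern,
            )
            cell._pix_xy = np.stack([xs, ys], axis=1)
            cell._pix_s_um = s_um
            cells.append(cell)
            placed = True
            break
        if not placed:
            raise PlacementError(placed=len(cells), requested=cfg.n_cells)

    truth = SceneTruth(cells=cells, config=cfg, model=model)

    fluor = render_fluorescence(truth, model, cfg)
    phase = _render_phase(truth, cfg)
    channels = {"phase": phase, "fluor": fluor}
    if cfg.include_adhesin:
        channels["adhesin"] = _render_adhesin(truth, cfg)

    noisy = {}
    for k, (name, img) in enumerate(channels.items()):
        noise_rng = np.random.default_rng([int(cfg.seed) % (2**31), 101 + k])
        noisy[name] = apply_noise(img, cfg, rng=noise_rng)

    field_img = FieldImage(
        channels=noisy,
        pixel_size=px,
        provenance=Provenance(
            source="synthetic", transforms=["aligned-by-construction"],
            registration_applied=True,
        ),
    )
    return field_img, truth


def render_fluorescence(
    truth: SceneTruth, model: LocalizationModel, cfg: SceneConfig
) -> np.ndarray:
    """Noise-free fluorescence channel (PSF-blurred, background added).

    Restricted cells render axial Gaussians of extent ``sigma_focus``
    centered on the truth focus positions, masked to the cell; nonrestricted
    cells render uniform in-cell intensity ``amp``.  Per-focus and per-cell
    integrated intensities are recorded on the truth (the PSF preserves
    integrals).
    """
    h, w = cfg.field_shape
    img = np.zeros((h, w), dtype=float)
    for cell in truth.cells:
        if cell._pix_xy is None:
            raise DataError("truth cells not rasterized; use generate_scene")
        xs, ys = cell._pix_xy[:, 0], cell._pix_xy[:, 1]
        s = cell._pix_s_um
        if model.pattern == "restricted":
            total = np.zeros(len(xs))
            for f in cell.foci:
                contrib = f.peak_amp * np.exp(
                    -((s - f.s_um) ** 2) / (2 * model.sigma_focus**2)
                )
                f.integrated = float(contrib.sum())
                total += contrib
            img[ys, xs] += total
            cell.integrated_fluor = float(total.sum())
        else:
            img[ys, xs] += model.amp
            cell.integrated_fluor = float(model.amp * len(xs))
    if cfg.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, cfg.psf_sigma / cfg.pixel_size,
                                      mode="constant")
    return img + cfg.background


def _render_phase(truth: SceneTruth, cfg: SceneConfig) -> np.ndarray:
    """Phase-contrast proxy: dark cells on a bright background, PSF-blurred."""
    h, w = cfg.field_shape
    mask = np.zeros((h, w), dtype=float)
    for cell in truth.cells:
        mask[cell._pix_xy[:, 1], cell._pix_xy[:, 0]] = 1.0
    if cfg.psf_sigma > 0:
        mask = ndimage.gaussian_filter(mask, cfg.psf_sigma / cfg.pixel_size)
    return cfg.phase_background - (cfg.phase_background - cfg.phase_cell_level) * mask


def _render_adhesin(truth: SceneTruth, cfg: SceneConfig) -> np.ndarray:
    """Adhesin-stain channel: a Gaussian spot at the old pole of marked cells."""
    h, w = cfg.field_shape
    img = np.zeros((h, w), dtype=float)
    sig_px = cfg.adhesin_sigma / cfg.pixel_size
    r = int(math.ceil(4 * sig_px))
    for cell in truth.cells:
        if not cell.adhesin:
            continue
        x0, y0 = cell.old_pole_xy
        xs = np.arange(max(0, int(x0) - r), min(w, int(x0) + r + 1))
        ys = np.arange(max(0, int(y0) - r), min(h, int(y0) + r + 1))
        gx, gy = np.meshgrid(xs, ys)
        img[gy, gx] += cfg.adhesin_amp * np.exp(
            -((gx - x0) ** 2 + (gy - y0) ** 2) / (2 * sig_px**2)
        )
    if cfg.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, cfg.psf_sigma / cfg.pixel_size,
                                      mode="constant")
    return img + cfg.background


def apply_noise(image: np.ndarray, cfg: SceneConfig, rng=None) -> np.ndarray:
    """Poisson shot noise (if enabled) followed by Gaussian read noise.

    The input must be non-negative (photon expectation values).  With both
    noise sources disabled this is the identity.
    """
    image = np.asarray(image, dtype=float)
    if (image < 0).any():
        raise DataError("apply_noise requires a non-negative image")
    if not cfg.poisson_noise and cfg.read_noise_sd == 0:
        return image.copy()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out = rng.poisson(image).astype(float) if cfg.poisson_noise else image.copy()
    if cfg.read_noise_sd > 0:
        out = out + rng.normal(0.0, cfg.read_noise_sd, size=image.shape)
    return out


def write_scene(field_img: FieldImage, truth: SceneTruth, outdir) -> None:
    """Write the scene as TIFF + truth CSVs + a machine-readable config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_field(field_img, outdir / "scene.tif")
    truth.cells_frame().to_csv(outdir / "truth_cells.csv", index=False)
    truth.foci_frame().to_csv(outdir / "truth_foci.csv", index=False)
    echo = {"config": asdict(truth.config), "model": asdict(truth.model)}
    echo["config"]["field_shape"] = list(truth.config.field_shape)
    echo["config"]["length_dist"] = list(truth.config.length_dist)
    (outdir / "scene_config.json").write_text(json.dumps(echo, indent=2))
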