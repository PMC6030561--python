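"""Calibrated multi-channel image I/O and inter-channel distortion correction.

A :class:`FieldImage` holds the channels of one microscope field (phase
contrast, fluorescence, optionally an adhesin stain) together with the pixel
size in µm and a provenance record.  Fluorescence optics can be spatially
offset from the phase-contrast path; before any per-cell measurement the
fluorescence channels are resampled into phase coordinates with a low-order
polynomial map fitted to landmark pairs (:func:`estimate_distortion` /
:func:`apply_correction`).

Coordinate convention: points are ``(x, y)`` with ``x`` the column index and
``y`` the row index, 0-based, pixel centers at integer coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import (
    CalibrationError,
    ConfigError,
    DataError,
    DegenerateGeometryError,
    FormatError,
)

DEFAULT_CHANNEL_NAMES = ("phase", "fluor", "adhesin")


@dataclass
class Provenance:
    source: str | None = None
    transforms: list = field(default_factory=list)
    registration_applied: bool = False


@dataclass
class FieldImage:
    """One multi-channel field with pixel calibration."""

    channels: dict
    pixel_size: float
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ConfigError(f"pixel_size must be > 0, got {self.pixel_size}")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise FormatError(f"channel shapes differ: {shapes}")

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise FormatError(
                f"channel {name!r} absent; present: {sorted(self.channels)}"
            )
        return self.channels[name]

    def has_channel(self, name: str) -> bool:
        return name in self.channels


def read_field(path, pixel_size_override=None, channel_names=None) -> FieldImage:
    """Read a single- or multi-page TIFF as a :class:`FieldImage`.

    Pages are mapped to channel names by order.  ``channel_names=None`` uses
    the default ``(phase, fluor, adhesin)`` truncated to the page count; an
    explicit tuple must match the page count exactly.  Pixel size is taken
    from the image description metadata (written by :func:`write_field`),
    else from ``pixel_size_override``; if neither is available a
    :class:`CalibrationError` is raised.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    if arr.ndim == 2:
        pages = [arr]
    elif arr.ndim == 3:
        # channel axis: the small axis (pages or interleaved samples)
        ax = int(np.argmin(arr.shape))
        if arr.shape[ax] > 8:
            raise FormatError(f"cannot infer channel axis of shape {arr.shape}")
        pages = [np.take(arr, i, axis=ax) for i in range(arr.shape[ax])]
    else:
        raise FormatError(f"unsupported TIFF dimensionality {arr.shape}")
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}

    if channel_names is None:
        if len(pages) > len(DEFAULT_CHANNEL_NAMES):
            raise FormatError(
                f"{len(pages)} pages but no channel-name config supplied"
            )
        names = list(meta.get("channel_names", DEFAULT_CHANNEL_NAMES[: len(pages)]))
        names = names[: len(pages)]
    else:
        names = list(channel_names)
    if len(names) != len(pages):
        raise FormatError(
            f"channel config names {len(names)} channels but file has "
            f"{len(pages)} pages"
        )

    pixel_size = meta.get("pixel_size_um")
    if pixel_size_override is not None:
        pixel_size = pixel_size_override
    if pixel_size is None:
        raise CalibrationError(
            f"{path}: no pixel size in metadata and no override given"
        )
    return FieldImage(
        channels=dict(zip(names, pages)),
        pixel_size=float(pixel_size),
        provenance=Provenance(source=str(path)),
    )


def write_field(field_img: FieldImage, path) -> None:
    """Write a FieldImage as a multi-page TIFF with JSON calibration metadata."""
    path = Path(path)
    names = list(field_img.channels)
    meta = {"pixel_size_um": field_img.pixel_size, "channel_names": names}
    data = np.stack([np.asarray(field_img.channels[n]) for n in names])
    tifffile.imwrite(path, data, photometric="minisblack",
                     description=json.dumps(meta))


# ---------------------------------------------------------------------------
# Distortion correction
# ---------------------------------------------------------------------------

_MODEL_TERMS = {"identity": 3, "affine": 3, "quadratic": 6}


def _basis(points: np.ndarray, model: str) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    cols = [x, y, np.ones_like(x)]
    if model == "quadratic":
        cols += [x * x, x * y, y * y]
    return np.stack(cols, axis=1)


@dataclass
class DistortionMap:
    """Polynomial map from fluorescence-channel to phase-channel coordinates.

    ``coefficients`` is a (2, k) matrix: ``(x', y') = C @ basis(x, y)`` with
    basis ``(x, y, 1)`` for affine and ``(x, y, 1, x², xy, y²)`` for
    quadratic.
    """

    model: str
    coefficients: np.ndarray
    residual_rms: float = 0.0

    @classmethod
    def identity(cls) -> "DistortionMap":
        c = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        return cls(model="identity", coefficients=c, residual_rms=0.0)

    def is_identity(self) -> bool:
        return self.model == "identity"

    def transform(self, points) -> np.ndarray:
        """Map fluorescence coordinates to phase coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        model = "quadratic" if self.coefficients.shape[1] == 6 else "affine"
        return _basis(pts, model) @ self.coefficients.T

    def inverse_transform(self, points) -> np.ndarray:
        """Map phase coordinates back to fluorescence coordinates.

        Affine maps are inverted exactly; a quadratic map is inverted by
        Newton iteration from the affine part (the quadratic terms are a
        small perturbation within the field of view).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        A = self.coefficients[:, :2]
        b = self.coefficients[:, 2]
        Ainv = np.linalg.inv(A)
        guess = (pts - b) @ Ainv.T
        if self.coefficients.shape[1] == 3:
            return guess
        for _ in range(25):
            err = self.transform(guess) - pts
            if np.max(np.abs(err)) < 1e-9:
                break
            guess = guess - err @ Ainv.T
        return guess

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "coefficients": self.coefficients.tolist(),
                "residual_rms": self.residual_rms,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DistortionMap":
        d = json.loads(text)
        return cls(
            model=d["model"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            residual_rms=float(d["residual_rms"]),
        )


def estimate_distortion(point_pairs, model: str = "affine") -> DistortionMap:
    """Least-squares fit of the fluor→phase coordinate map from landmarks.

    ``point_pairs`` is an iterable of ``((x_fluor, y_fluor), (x_phase,
    y_phase))`` tuples or an (N, 4) array with those columns.  Affine needs
    ≥3 non-collinear pairs, quadratic ≥6; degenerate geometry raises
    :class:`DegenerateGeometryError`.  Exactly aligned pairs return the
    identity map.
    """
    if model not in ("affine", "quadratic"):
        raise ConfigError(f"unknown distortion model {model!r}")
    arr = np.asarray(
        [(p[0][0], p[0][1], p[1][0], p[1][1]) if len(p) == 2 else tuple(p)
         for p in point_pairs],
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise DataError("point pairs must have 4 coordinates each")
    src, dst = arr[:, :2], arr[:, 2:]
    k = _MODEL_TERMS[model]
    if len(arr) < k:
        raise DataError(f"{model} fit needs ≥{k} pairs, got {len(arr)}")
    if np.array_equal(src, dst):
        return DistortionMap.identity()
    B = _basis(src, model)
    coef, _, rank, _ = np.linalg.lstsq(B, dst, rcond=None)
    if rank < k:
        raise DegenerateGeometryError(
            f"landmark geometry is rank-deficient (rank {rank} < {k}); "
            "points may be collinear"
        )
    resid = B @ coef - dst
    rms = float(np.sqrt(np.mean(resid**2)))  # per-coordinate RMS
    return DistortionMap(model=model, coefficients=coef.T, residual_rms=rms)


def apply_correction(channel: np.ndarray, dmap: DistortionMap, background=None):
    """Resample a fluorescence channel into phase coordinates.

    Bilinear interpolation; output pixels that map outside the input field
    are set to ``background`` (default: channel median) and flagged in the
    returned boolean out-of-field mask.

    Returns ``(corrected, oob_mask)``.
    """
    channel = np.asarray(channel)
    if dmap.is_identity():
        return channel.copy(), np.zeros(channel.shape, dtype=bool)
    h, w = channel.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    src = dmap.inverse_transform(pts)
    sx = src[:, 0].reshape(h, w)
    sy = src[:, 1].reshape(h, w)
    oob = (sx < 0) | (sx > w - 1) | (sy < 0) | (sy > h - 1)
    out = ndimage.map_coordinates(
        channel.astype(float), [sy, sx], order=1, mode="nearest"
    )
    if background is None:
        background = float(np.median(channel))
    out[oob] = background
    return out.astype(channel.dtype) if channel.dtype.kind in "iu" else out, oob


def correct_field(
    field_img: FieldImage, dmap: DistortionMap, channels=("fluor", "adhesin")
) -> FieldImage:
    """Apply a distortion correction to the listed channels of a field.

    Returns a new :class:`FieldImage` whose provenance records the applied
    transform and sets the registration flag required by segmentation.
    """
    new = {}
    for name, ch in field_img.channels.items():
        if name in channels:
            corrected, _ = apply_correction(ch, dmap)
            new[name] = corrected
        else:
            new[name] = ch.copy()
    prov = Provenance(
        source=field_img.provenance.source,
        transforms=field_img.provenance.transforms
        + [f"distortion:{dmap.model}"],
        registration_applied=True,
    )
    return FieldImage(channels=new, pixel_size=field_img.pixel_size, provenance=prov)


def read_landmarks(path) -> np.ndarray:
    """Read landmark pairs from a 4-column CSV (x_fluor, y_fluor, x_phase, y_phase)."""
    df = pd.read_csv(path)
    cols = ["x_fluor", "y_fluor", "x_phase", "y_phase"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"landmark CSV missing columns {missing}")
    return df[cols].to_numpy(dtype=float)


def match_spot_landmarks(
    moving: np.ndarray, reference: np.ndarray, max_shift: float = 10.0,
    min_distance: int = 5,
):
    """Auto-derive landmark pairs from bright spots present in both channels.

    Detects local maxima in each image and pairs each moving-channel spot
    with the nearest reference spot within ``max_shift`` pixels.  Returns an
    (N, 4) array (x_moving, y_moving, x_ref, y_ref).
    """
    from skimage.feature import peak_local_max

    def spots(img):
        img = np.asarray(img, dtype=float)
        thr = img.mean() + 3 * img.std()
        pk = peak_local_max(img, min_distance=min_distance, threshold_abs=thr)
        return pk[:, ::-1].astype(float)  # (row,col) -> (x,y)

    a, b = spots(moving), spots(reference)
    pairs = []
    if len(a) and len(b):
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        for i in range(len(a)):
            j = int(np.argmin(d[i]))
            if d[i, j] <= max_shift:
                pairs.append((*a[i], *b[j]))
    return np.asarray(pairs, dtype=float).reshape(-1, 4)
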