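"""End-to-end analysis pipeline and truth-based evaluation.

:func:`analyze_field` runs the full single-field chain — segmentation of the
phase channel, background estimation, medial-axis profiling, adhesin-based
pole orientation, focus detection — and returns everything downstream
statistics need.  :func:`run` drives the same chain from a config file and
writes the standard output set (cells/foci/polarity/profiles CSVs, demograph
and centroid-map CSV+PNG, a population summary and a reproducibility
manifest).  Evaluation helpers score detections against the synthetic
ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from .imgio import (
    DistortionMap,
    FieldImage,
    correct_field,
    estimate_distortion,
    read_field,
    read_landmarks,
)
from .polarity import PolarityConfig, call_polarity, orient_profiles, polarity_frame
from .popstats import (
    ClassificationConfig,
    build_demograph,
    centroid_map,
    classify_localization,
    foci_count_length_table,
    old_new_intensity_compare,
    plot_centroid_map,
    plot_demograph,
    pole_distance_stats,
    spacing_pairs,
    spacing_regression,
)
from .quantify import (
    FocusConfig,
    background_level,
    detect_foci,
    foci_frame,
    mean_cell_intensity,
    medial_profile,
    profiles_frame,
)
from .segmentation import SegmentationConfig, cells_frame, segment_field
from .synthetic import LocalizationModel, SceneConfig, generate_scene, write_scene

log = logging.getLogger("icmscope")


@dataclass
class AnalysisResult:
    labels: np.ndarray
    cells: list
    background: float
    profiles: list  # oriented MedialProfiles
    calls: list
    foci: list
    adhesin_available: bool
    mean_intensities: dict = field(default_factory=dict)  # cell_id -> corrected mean


def analyze_field(
    field_img: FieldImage,
    seg_cfg: SegmentationConfig | None = None,
    focus_cfg: FocusConfig | None = None,
    pol_cfg: PolarityConfig | None = None,
    fallback: str = "none",
    sampling_step: float | None = None,
    waive_correction: bool = False,
) -> AnalysisResult:
    """Segment, profile, orient and detect foci on one field."""
    labels, cells = segment_field(field_img, seg_cfg,
                                  waive_correction=waive_correction)
    fluor = field_img.channel("fluor")
    bg = background_level(fluor, labels) if cells else float(np.median(fluor))
    profiles, kept = [], []
    for c in cells:
        try:
            profiles.append(medial_profile(c, fluor, bg, sampling_step))
            kept.append(c)
        except DataError:
            c.qc_flags.append("degenerate_axis")
    adhesin = field_img.channels.get("adhesin")
    calls = call_polarity(kept, adhesin, labels, pol_cfg)
    oriented = orient_profiles(profiles, kept, calls, fallback=fallback)
    foci = []
    for p in oriented:
        foci.extend(detect_foci(p, focus_cfg))
    means = {c.id: mean_cell_intensity(c, fluor, bg) for c in kept}
    return AnalysisResult(
        labels=labels,
        cells=kept,
        background=bg,
        profiles=oriented,
        calls=calls,
        foci=foci,
        adhesin_available=adhesin is not None,
        mean_intensities=means,
    )


# ---------------------------------------------------------------------------
# evaluation against synthetic truth
# ---------------------------------------------------------------------------


def match_cells(truth, cells, max_dist_px: float = 2.0):
    """Greedy nearest-centroid matching of detected cells to truth cells.

    Returns a dict with matched (truth_cell, record) pairs, recall,
    precision and per-match relative length errors.
    """
    t_cent = np.array([c.centroid_xy for c in truth.cells], dtype=float)
    d_cent = np.array([c.centroid_xy for c in cells], dtype=float)
    matches = []
    if len(t_cent) and len(d_cent):
        dist = np.linalg.norm(t_cent[:, None, :] - d_cent[None, :, :], axis=2)
        used_t, used_d = set(), set()
        for k in np.argsort(dist, axis=None):
            i, j = np.unravel_index(k, dist.shape)
            if dist[i, j] > max_dist_px:
                break
            if i in used_t or j in used_d:
                continue
            used_t.add(i)
            used_d.add(j)
            matches.append((truth.cells[i], cells[j]))
    recall = len(matches) / len(truth.cells) if truth.cells else np.nan
    precision = len(matches) / len(cells) if cells else np.nan
    len_err = np.array(
        [(rec.length_um - tc.length_um) / tc.length_um for tc, rec in matches]
    )
    return dict(matches=matches, recall=recall, precision=precision,
                length_rel_errors=len_err)


def focus_position_errors(truth, cells, foci):
    """Axial focus-position errors (µm) for truth-matched cells.

    Detected positions are compared under both axis orientations (the truth
    knows the old pole; an unoriented detection may run either way) and the
    better-matching orientation is scored, pairing sorted positions.
    """
    m = match_cells(truth, cells)
    by_cell = {}
    for f in foci:
        by_cell.setdefault(f.cell_id, []).append(f.s_pos)
    errors = []
    for tc, rec in m["matches"]:
        truth_pos = sorted(f.s_um for f in tc.foci)
        det = sorted(by_cell.get(rec.id, []))
        if not truth_pos or len(det) != len(truth_pos):
            continue
        fwd = [abs(a - b) for a, b in zip(det, truth_pos)]
        rev = [abs(a - b) for a, b in
               zip(sorted(rec.length_um - np.array(det)), truth_pos)]
        errors.extend(fwd if np.mean(fwd) <= np.mean(rev) else rev)
    return np.asarray(errors)


# ---------------------------------------------------------------------------
# config-driven run
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    output_dir: str
    input_path: str | None = None
    pixel_size: float | None = None
    channel_names: tuple | None = None
    landmarks_path: str | None = None
    registration_model: str = "affine"
    waive_correction: bool = False
    fallback: str = "none"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    focus: FocusConfig = field(default_factory=FocusConfig)
    polarity: PolarityConfig = field(default_factory=PolarityConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "output_dir" not in raw:
            raise ConfigError("config requires output_dir")
        kw = {}
        for key in ("output_dir", "input_path", "pixel_size", "channel_names",
                    "landmarks_path", "registration_model", "waive_correction",
                    "fallback", "seed", "log_level", "simulate"):
            if key in raw:
                kw[key] = raw.pop(key)
        for key, cfg_cls in (
            ("segmentation", SegmentationConfig),
            ("focus", FocusConfig),
            ("polarity", PolarityConfig),
            ("classification", ClassificationConfig),
        ):
            if key in raw:
                kw[key] = cfg_cls(**raw.pop(key))
        if raw:
            raise ConfigError(f"unknown config keys: {sorted(raw)}")
        cfg = cls(**kw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.segmentation.validate()
        self.focus.validate()
        self.polarity.validate()
        if self.input_path is None and self.simulate is None:
            raise ConfigError("config needs input_path or a simulate block")


def _simulate_from_config(sim: dict):
    sim = dict(sim)
    pattern = sim.pop("pattern", "restricted")
    model_keys = {"d_old", "d_new", "L_star", "rho", "sigma_focus", "amp"}
    model_kw = {k: sim.pop(k) for k in list(sim) if k in model_keys}
    if "field_shape" in sim:
        sim["field_shape"] = tuple(sim["field_shape"])
    if "length_dist" in sim:
        sim["length_dist"] = tuple(sim["length_dist"])
    cfg = SceneConfig(**sim)
    model = LocalizationModel(pattern=pattern, **model_kw)
    return generate_scene(cfg, model)


def run(config: PipelineConfig) -> Path:
    """Execute the pipeline and write the standard output set.

    Deterministic for fixed inputs, config and seed; the manifest records
    the config hash, package version and per-stage counts.
    """
    t0 = time.time()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        field_img, truth = _simulate_from_config(sim)
        write_scene(field_img, truth, outdir / "scene")
        log.info("simulated %d cells", len(truth.cells))
    else:
        field_img = read_field(config.input_path, config.pixel_size,
                               config.channel_names)

    if config.landmarks_path:
        pairs = read_landmarks(config.landmarks_path)
        dmap = estimate_distortion(pairs, model=config.registration_model)
        field_img = correct_field(field_img, dmap)
        (outdir / "distortion_map.json").write_text(dmap.to_json())
        log.info("registration: %s, residual_rms=%.3f px", dmap.model,
                 dmap.residual_rms)

    res = analyze_field(
        field_img,
        seg_cfg=config.segmentation,
        focus_cfg=config.focus,
        pol_cfg=config.polarity,
        fallback=config.fallback,
        waive_correction=config.waive_correction,
    )
    log.info("segmented %d cells, %d foci", len(res.cells), len(res.foci))

    cells_frame(res.cells).to_csv(outdir / "cells.csv", index=False)
    foci_frame(res.foci).to_csv(outdir / "foci.csv", index=False)
    polarity_frame(res.calls, res.profiles).to_csv(outdir / "polarity.csv",
                                                   index=False)
    profiles_frame(res.profiles).to_csv(outdir / "profiles.csv")

    dg = build_demograph(res.profiles)
    pd.DataFrame(dg.matrix).to_csv(outdir / "demograph.csv", index=False)
    plot_demograph(dg, outdir / "demograph.png")
    points, outline = centroid_map(res.cells, res.foci, res.profiles)
    points.to_csv(outdir / "centroid_map.csv", index=False)
    plot_centroid_map(points, outline, outdir / "centroid_map.png")

    summary = _summarize(res, config)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))

    manifest = {
        "config_hash": _config_hash(config),
        "version": __version__,
        "counts": {
            "cells": len(res.cells),
            "foci": len(res.foci),
            "oriented": sum(1 for c in res.calls if c.old_pole != "unassigned"),
        },
        "elapsed_s": round(time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    if truth is not None:
        ev = evaluate_against_truth(truth, res)
        (outdir / "evaluation.json").write_text(json.dumps(ev, indent=2))
    return outdir


def _summarize(res: AnalysisResult, config: PipelineConfig) -> dict:
    summary_df, _ = foci_count_length_table(res.cells, res.foci)
    out = {
        "n_cells": len(res.cells),
        "background": res.background,
        "focus_classes": summary_df.to_dict(orient="records"),
        "adhesin_channel": res.adhesin_available,
    }
    if not res.adhesin_available:
        out["pole_referenced_stats"] = "absent (no adhesin channel)"
    else:
        oriented = [c for c in res.calls if c.old_pole != "unassigned"]
        out["n_oriented"] = len(oriented)
        out["pole_distances"] = pole_distance_stats(res.foci, res.cells, res.calls)
        cmp_ = old_new_intensity_compare(res.cells, res.foci, res.calls)
        out["old_new_intensity"] = {
            k: v for k, v in cmp_.items() if k != "ratios"
        }
    pairs = spacing_pairs(res.cells, res.foci)
    if len(pairs) >= 3:
        reg = spacing_regression(pairs)
        out["spacing_regression"] = dict(slope=reg.slope, intercept=reg.intercept,
                                         r=reg.r, n=reg.n)
    cls = classify_localization(res.profiles, config.classification)
    out["classification"] = dict(label=cls.label, focal_fraction=cls.focal_fraction,
                                 n_cells=cls.n_cells,
                                 insufficient_data=cls.insufficient_data)
    return _jsonify(out)


def evaluate_against_truth(truth, res: AnalysisResult) -> dict:
    m = match_cells(truth, res.cells)
    errs = focus_position_errors(truth, res.cells, res.foci)
    return _jsonify(
        {
            "recall": m["recall"],
            "precision": m["precision"],
            "median_abs_length_rel_error": (
                float(np.median(np.abs(m["length_rel_errors"])))
                if len(m["length_rel_errors"]) else None
            ),
            "n_focus_errors": int(len(errs)),
            "median_focus_error_um": float(np.median(errs)) if len(errs) else None,
        }
    )


def _config_hash(config: PipelineConfig) -> str:
    def enc(o):
        if isinstance(o, (SegmentationConfig, FocusConfig, PolarityConfig,
                          ClassificationConfig)):
            return o.__dict__
        return str(o)

    text = json.dumps(config.__dict__, default=enc, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
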