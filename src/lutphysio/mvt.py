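"""Micturition video thermography: spot segmentation, calibration, and
scent-marking metrics.

Thermal screenshots are thresholded (Otsu by default, fixed level for
manual-threshold fidelity) and connected components become candidate
spots.  A 10 cm2 reflecting template in each frame calibrates the
pixel-to-cm2 conversion, absorbing camera height/angle variation; spot
volumes come from a linear calibration curve.  Voids vs leaks are a
geometric proxy for the behavioral classification: large spots near a
corner are voids, everything else is a leak (or a mark in marking-session
mode).  The dominance screen follows the marking rules: initiation within
the first 5 minutes and at least 10 marks.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .config import DEFAULTS

logger = logging.getLogger("lutphysio")


class CalibrationError(ValueError):
    """Template region missing or degenerate."""


@dataclasses.dataclass
class SpotRecord:
    """One segmented urine spot (or the calibration template)."""

    spot_id: str
    centroid: tuple           # (row, col), 0-based pixel coordinates
    area_px: int
    area_cm2: float = float("nan")
    volume_ul: float = float("nan")
    klass: str = ""           # void | leak | mark | template
    t_appear_s: float = float("nan")
    corner_distance_cm: float = float("nan")
    mean_intensity: float = float("nan")


@dataclasses.dataclass
class CalibrationModel:
    """Pixel density and volume curve tied to one recording."""

    px_per_cm2: float
    volume_slope_ul_per_cm2: float = 50.0
    volume_intercept_ul: float = 0.0
    area_max_cm2: float = 20.0    # validity range of the curve

    def __post_init__(self) -> None:
        if self.px_per_cm2 <= 0:
            raise CalibrationError("px_per_cm2 must be positive")


def segment_spots(
    image: np.ndarray,
    threshold_mode: str = "otsu",
    fixed_threshold: float = 128,
    min_spot_px: int = 20,
) -> list[SpotRecord]:
    """Threshold + 8-connected components; tiny components are noise.

    Touching spots merge into one region — a documented limitation of
    connectivity-based segmentation.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a grayscale image")
    if img.size == 0 or img.max() == img.min():
        return []
    thr = threshold_otsu(img) if threshold_mode == "otsu" else fixed_threshold
    mask = img > thr
    labels = cc_label(mask, connectivity=2)
    spots = []
    for k, region in enumerate(regionprops(labels, intensity_image=img)):
        if region.area < min_spot_px:
            continue
        spots.append(
            SpotRecord(
                spot_id=f"s{k:03d}",
                centroid=tuple(region.centroid),
                area_px=int(region.area),
                mean_intensity=float(region.intensity_mean),
            )
        )
    logger.info("segment_spots: %d regions (threshold=%.1f)", len(spots), thr)
    return spots


def find_template(spots: Sequence[SpotRecord]) -> SpotRecord:
    """The calibration template is the brightest segmented region."""
    if not spots:
        raise CalibrationError("no regions; template not found")
    return max(spots, key=lambda s: s.mean_intensity)


def calibrate(
    template: SpotRecord,
    known_area_cm2: float = 10.0,
    volume_slope_ul_per_cm2: float | None = None,
    volume_intercept_ul: float | None = None,
) -> CalibrationModel:
    """px_per_cm2 = template pixel count / its known area (10 cm2)."""
    if template.area_px <= 0:
        raise CalibrationError("template region has no pixels")
    return CalibrationModel(
        px_per_cm2=template.area_px / known_area_cm2,
        volume_slope_ul_per_cm2=(
            float(DEFAULTS["volume_slope_ul_per_cm2"])
            if volume_slope_ul_per_cm2 is None
            else volume_slope_ul_per_cm2
        ),
        volume_intercept_ul=(
            float(DEFAULTS["volume_intercept_ul"])
            if volume_intercept_ul is None
            else volume_intercept_ul
        ),
        area_max_cm2=float(DEFAULTS["volume_area_max_cm2"]),
    )


def estimate_volume(area_cm2: float, model: CalibrationModel) -> float:
    """Linear calibration curve, clipped at zero."""
    if area_cm2 < 0 or area_cm2 > model.area_max_cm2:
        raise ValueError(
            f"area {area_cm2:.2f} cm2 outside calibration validity "
            f"[0, {model.area_max_cm2}]"
        )
    return max(model.volume_slope_ul_per_cm2 * area_cm2 + model.volume_intercept_ul, 0.0)


def apply_calibration(
    spots: Sequence[SpotRecord], model: CalibrationModel, template_id: str | None = None
) -> list[SpotRecord]:
    """Fill area_cm2 and volume_ul on every non-template spot."""
    out = []
    for s in spots:
        s = dataclasses.replace(s)
        s.area_cm2 = s.area_px / model.px_per_cm2
        if template_id is not None and s.spot_id == template_id:
            s.klass = "template"
            s.volume_ul = float("nan")
        else:
            s.volume_ul = estimate_volume(s.area_cm2, model)
        out.append(s)
    return out


def classify_spots(
    spots: Sequence[SpotRecord],
    image_shape: tuple,
    model: CalibrationModel,
    mode: str = "voiding",
    void_area_min_cm2: float | None = None,
    corner_radius_cm: float | None = None,
) -> list[SpotRecord]:
    """Geometric void/leak/mark proxy.

    void: area >= threshold AND within the corner radius of an arena
    corner; otherwise leak (voiding mode) or mark (marking mode, small
    non-corner spots).  Template spots pass through unchanged.
    """
    amin = (
        float(DEFAULTS["void_area_min_cm2"])
        if void_area_min_cm2 is None
        else void_area_min_cm2
    )
    rmax = (
        float(DEFAULTS["corner_radius_cm"])
        if corner_radius_cm is None
        else corner_radius_cm
    )
    h, w = image_shape
    corners = np.array([(0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1)], float)
    px_per_cm = np.sqrt(model.px_per_cm2)
    out = []
    for s in spots:
        s = dataclasses.replace(s)
        if s.klass == "template":
            out.append(s)
            continue
        c = np.asarray(s.centroid, float)
        dist_px = np.min(np.linalg.norm(corners - c, axis=1))
        s.corner_distance_cm = float(dist_px / px_per_cm)
        if s.area_cm2 >= amin and s.corner_distance_cm <= rmax:
            s.klass = "void"
        else:
            s.klass = "mark" if mode == "marking" else "leak"
        out.append(s)
    return out


def marking_metrics(
    events: pd.DataFrame,
    stimulus_time_s: float,
    session_end_s: float,
    mark_min_count: int | None = None,
    latency_max_s: float | None = None,
) -> dict:
    """Mark count (corner voids excluded), latency, and the dominance flag.

    Dominance requires initiation within ``latency_max_s`` (5 minutes) of
    the stimulus AND at least ``mark_min_count`` (10) marks.  With no
    marks the latency is censored at session end.
    """
    kmin = int(DEFAULTS["mark_min_count"]) if mark_min_count is None else mark_min_count
    lmax = (
        float(DEFAULTS["mark_latency_max_s"]) if latency_max_s is None else latency_max_s
    )
    marks = events[(events["kind"] == "mark")]
    marks = marks[marks["t_align_s"] >= stimulus_time_s]
    count = int(len(marks))
    if count:
        latency = float(marks["t_align_s"].min() - stimulus_time_s)
        censored = False
    else:
        latency = float(session_end_s - stimulus_time_s)
        censored = True
    dominant = (not censored) and latency <= lmax and count >= kmin
    return {
        "mark_count": count,
        "latency_s": latency,
        "latency_censored": censored,
        "dominance_flag": bool(dominant),
    }


def session_summary(
    spots: Sequence[SpotRecord], mode: str = "voiding"
) -> dict:
    """Per-animal counts and volumes; marking mode adds mark counts."""
    voids = [s for s in spots if s.klass == "void"]
    leaks = [s for s in spots if s.klass == "leak"]
    marks = [s for s in spots if s.klass == "mark"]
    vols = [s.volume_ul for s in voids if np.isfinite(s.volume_ul)]
    rec = {
        "n_voids": len(voids),
        "n_leaks": len(leaks),
        "mean_void_volume_ul": float(np.mean(vols)) if vols else 0.0,
        "total_void_volume_ul": float(np.sum(vols)) if vols else 0.0,
    }
    if mode == "marking":
        rec["n_marks"] = len(marks)
    return rec


def average_runs(run_a: dict, run_b: dict) -> dict:
    """Average the numeric fields of two session summaries (two-run design)."""
    keys = set(run_a) & set(run_b)
    return {k: (run_a[k] + run_b[k]) / 2.0 for k in sorted(keys)}


def analyze_frame(
    image: np.ndarray,
    mode: str = "voiding",
    config: dict | None = None,
) -> tuple[list[SpotRecord], CalibrationModel]:
    """Segment, calibrate against the template, size, and classify."""
    cfg = dict(DEFAULTS) if config is None else {**DEFAULTS, **config}
    spots = segment_spots(
        image,
        threshold_mode=str(cfg["mvt_threshold_mode"]),
        fixed_threshold=float(cfg["mvt_fixed_threshold"]),
        min_spot_px=int(cfg["mvt_min_spot_px"]),
    )
    template = find_template(spots)
    model = calibrate(
        template,
        known_area_cm2=float(cfg["template_area_cm2"]),
        volume_slope_ul_per_cm2=float(cfg["volume_slope_ul_per_cm2"]),
        volume_intercept_ul=float(cfg["volume_intercept_ul"]),
    )
    spots = apply_calibration(spots, model, template_id=template.spot_id)
    spots = classify_spots(
        spots, image.shape, model, mode,
        void_area_min_cm2=float(cfg["void_area_min_cm2"]),
        corner_radius_cm=float(cfg["corner_radius_cm"]),
    )
    return spots, model


def spots_to_frame(spots: Sequence[SpotRecord]) -> pd.DataFrame:
    rows = []
    for s in spots:
        d = dataclasses.asdict(s)
        d["centroid_row"], d["centroid_col"] = d.pop("centroid")
        rows.append(d)
    return pd.DataFrame(rows)
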