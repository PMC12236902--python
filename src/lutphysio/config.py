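"""Flat key-value analysis configuration (TOML), with field-standard defaults.

Every tunable threshold used anywhere in the pipeline is a named key here,
so a single TOML file pins an entire analysis.  Unknown keys are rejected to
catch typos.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

DEFAULTS: dict[str, object] = {
    # photometry
    "downsample_target_dt_s": 0.1,     # post-demodulation resolution
    "dff_baseline_cascade": "double_exp,single_exp_const,poly2",
    "isosbestic_fit_gain": True,       # least-squares gain+offset before subtraction
    "baseline_guard_eps": 0.005,       # |baseline dF/F0| below this -> subtractive only
    "perievent_window_s": 60.0,        # half-width of the peri-event window
    # cystometry
    "contraction_prominence_cmh2o": 5.0,
    "contraction_min_interval_s": 10.0,
    "detrend_span_s": 90.0,            # rolling-median span removing the filling ramp
    "peak_prominence_frac": 0.2,       # sub-peak counts if prominence >= frac * rise
    "nvc_min_rise_cmh2o": 5.0,
    "dpdt_smooth_s": 3.0,
    "dpdt_refine_half_s": 3.0,         # parabolic vertex refinement of max dP/dt
    "dpdt_search_back_s": 15.0,
    "pre_episode_baseline_s": 30.0,
    # emg / optogenetics
    "emg_drop_threshold_frac": 0.05,   # >=5% TTP decrease counts as a response
    "cmg_rise_threshold_cmh2o": 3.0,
    "emg_artifact_mad_mult": 8.0,
    "emg_artifact_min_ms": 2.0,
    "ttp_remove_dc": True,
    # mvt
    "mvt_threshold_mode": "otsu",      # or "fixed"
    "mvt_fixed_threshold": 128,
    "mvt_min_spot_px": 12,
    "template_area_cm2": 10.0,
    "volume_slope_ul_per_cm2": 50.0,
    "volume_intercept_ul": 0.0,
    "volume_area_max_cm2": 20.0,       # calibration-curve validity range
    "void_area_min_cm2": 0.8,
    "corner_radius_cm": 8.0,
    "mark_min_count": 10,
    "mark_latency_max_s": 300.0,
    # perievent
    "shuffle_exclusion_zones": False,
    "padj_method": "holm",
}


def load_config(path: str | Path | None = None) -> dict[str, object]:
    """Defaults overlaid with a flat TOML file; unknown keys are an error."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    unknown = set(user) - set(DEFAULTS)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    return cfg
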