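"""Synthetic session generator with known ground truth.

Emulates the statistical structure the analysis stages assume, at desk
scale: cystometry traces with a linear filling ramp (infusion rate x
bladder compliance), voiding contractions and single-peaked non-voiding
contractions (NVCs); two-channel photometry with double-exponential
photobleaching, void-locked calcium transients and motion artifacts shared
across the 465/405 nm channels; tonic sphincter EMG with programmed
relaxation epochs during a fraction of optogenetic stimulations; and
thermal frames of warm elliptical urine spots with a 10 cm2 calibration
template.

Every generator is deterministic given (params, seed): one explicitly
seeded RNG stream per call, no hidden global state.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from skimage.draw import ellipse as draw_ellipse

from .io_formats import (
    SessionBundle,
    StimTrain,
    TimeSeries,
    ValidationError,
    events_from_records,
)


class GenerationError(RuntimeError):
    """Programmed events cannot be realized (overlap, out of frame, ...)."""


# RNG stream tags so each generator draws from an independent stream even
# when called with the same base seed
_TAG_CMG, _TAG_PHOT, _TAG_EMG, _TAG_THERM, _TAG_MARK, _TAG_STIM = range(6)


@dataclasses.dataclass
class SimParams:
    """All generator knobs, defaulting to the emulated study conditions."""

    # session geometry
    duration_s: float = 7200.0
    fs: float = 50.0                      # pressure / photometry raw rate, Hz
    seed: int = 0
    animal_id: str = "sim01"

    # cystometry: linear fill + contractions
    infusion_rate_ul_min: float = 25.0    # saline infusion, 15-30 uL/min range
    bladder_compliance_cmh2o_per_ul: float = 0.01
    pressure_baseline_cmh2o: float = 5.0
    n_voids: int = 6
    n_nvcs: int = 4
    void_pressure_peak_cmh2o: float = 30.0
    void_width_s: float = 5.0             # Gaussian sigma of the contraction
    nvc_amplitude_cmh2o: float = 7.0
    nvc_amplitudes: tuple | None = None   # per-NVC override, cycled
    nvc_width_s: float = 3.0
    double_peak_fraction: float = 0.0     # fraction of voids given a 2nd peak
    pressure_noise_sd: float = 0.5
    min_event_gap_s: float = 65.0
    event_jitter_frac: float = 0.15

    # photometry
    f_base_465: float = 2.0               # a.u. pre-bleach fluorescence
    f_base_405: float = 1.5
    bleach_frac_fast: float = 0.3
    bleach_tau_fast_s: float = 300.0
    bleach_tau_slow_s: float = 20000.0
    transient_amp: float = 0.06           # peak dF/F0 of the void transient
    transient_rise_s: float = 0.5
    transient_decay_s: float = 4.0
    transient_amp_jitter: float = 0.2     # lognormal sigma of per-event amp
    nvc_attenuation: float = 0.3          # NVC transient = atten x void amp
    motion_artifact_rate_per_min: float = 0.2
    motion_artifact_amp: float = 0.1      # a.u., added to both channels
    motion_405_gain: float = 1.0
    motion_width_s: float = 0.3
    photometry_noise_sd: float = 0.01     # a.u. per raw sample

    # optogenetics / EMG
    emg_fs: float = 1000.0
    emg_band_low_hz: float = 8.0
    emg_band_high_hz: float = 400.0
    emg_tonic_mv: float = 0.05            # RMS of tonic sphincter activity
    emg_relaxation_depth: float = 0.5     # fractional RMS drop when flagged
    relaxation_prob: float = 0.75         # programmed response probability
    n_stim_trials: int = 20
    stim_duration_s: float = 10.0         # light delivery; 5 s also used
    stim_interval_s: float = 40.0
    stim_pressure_rise_cmh2o: float = 0.0
    artifact_baseline_frac: float = 0.0   # trials with a baseline-phase artifact
    artifact_stim_frac: float = 0.0       # trials with a stim-phase artifact
    emg_artifact_amp_mult: float = 20.0

    # thermography
    frame_shape: tuple = (480, 640)
    px_per_cm2: float = 144.0
    background_level: float = 60.0
    spot_level: float = 180.0
    template_level: float = 250.0
    image_noise_sd: float = 2.0
    n_void_spots: int = 3
    n_leak_spots: int = 4
    void_spot_area_cm2: tuple = (1.2, 3.0)
    leak_spot_area_cm2: tuple = (0.15, 0.4)
    void_area_min_cm2: float = 0.8        # classification margin anchors
    corner_radius_cm: float = 8.0

    # scent-marking sessions
    marking_session_s: float = 3600.0
    stimulus_time_s: float = 300.0
    mark_rate_per_min: float = 0.3
    mark_latency_s: float = 60.0
    n_corner_voids: int = 1

    def __post_init__(self) -> None:
        for name in (
            "pressure_noise_sd", "photometry_noise_sd", "motion_artifact_rate_per_min",
            "transient_amp", "emg_tonic_mv", "image_noise_sd", "mark_rate_per_min",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.emg_relaxation_depth <= 1:
            raise ValidationError("emg_relaxation_depth must be in [0, 1]")
        if self.emg_band_high_hz > self.emg_fs / 2:
            raise ValidationError("emg_fs must be >= 2x the EMG band upper edge")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValidationError("fs and duration_s must be positive")


@dataclasses.dataclass
class GroundTruth:
    """Everything a recovery test needs to score a pipeline stage."""

    void_times: list = dataclasses.field(default_factory=list)       # peak s
    void_align_times: list = dataclasses.field(default_factory=list)  # steepest rise s
    void_n_peaks: list = dataclasses.field(default_factory=list)
    nvc_times: list = dataclasses.field(default_factory=list)         # peak s
    nvc_amplitudes: list = dataclasses.field(default_factory=list)    # cmH2O
    transient_amplitudes: dict = dataclasses.field(default_factory=dict)  # time -> dF/F0
    stim_trials: list = dataclasses.field(default_factory=list)
    # stim_trials entries: (onset_s, duration_s, relaxation_flag, artifact_phase)
    spot_truth: list = dataclasses.field(default_factory=list)
    artifact_times: list = dataclasses.field(default_factory=list)    # photometry motion


def _schedule_events(params: SimParams, rng: np.random.Generator):
    """Jittered, non-overlapping void and NVC times inside the safe margin."""
    n = params.n_voids + params.n_nvcs
    if n == 0:
        return [], []
    lo, hi = 60.0 + params.min_event_gap_s, params.duration_s - 60.0
    if hi <= lo:
        raise GenerationError("session too short for the requested events")
    slots = np.linspace(lo, hi, n + 1)
    centers = 0.5 * (slots[:-1] + slots[1:])
    gap = slots[1] - slots[0]
    jitter = rng.uniform(-params.event_jitter_frac, params.event_jitter_frac, n) * gap
    times = centers + jitter
    if np.any(np.diff(times) < params.min_event_gap_s):
        raise GenerationError("events would overlap within one analysis window")
    idx = rng.permutation(n)
    void_times = sorted(times[idx[: params.n_voids]])
    nvc_times = sorted(times[idx[params.n_voids:]])
    return list(void_times), list(nvc_times)


def simulate_cmg(params: SimParams) -> tuple[TimeSeries, GroundTruth]:
    """Bladder-pressure trace: baseline + fill ramp + contractions + noise.

    The fill ramp slope is infusion rate x compliance and resets at each
    void peak (the bladder empties).  Voiding contractions are Gaussian
    pulses of peak ``void_pressure_peak_cmh2o``; the ground-truth alignment
    time of a void is its steepest rise, one Gaussian sigma before the peak.
    """
    rng = np.random.default_rng([params.seed, _TAG_CMG])
    t = np.arange(int(round(params.duration_s * params.fs))) / params.fs
    truth = GroundTruth()
    truth.void_times, truth.nvc_times = _schedule_events(params, rng)

    slope = params.infusion_rate_ul_min / 60.0 * params.bladder_compliance_cmh2o_per_ul
    n_double = int(round(params.double_peak_fraction * params.n_voids))
    double_idx = set(rng.choice(params.n_voids, n_double, replace=False)) if n_double else set()
    w = params.void_width_s

    # sawtooth ramp: the bladder empties as the voiding contraction wanes,
    # so the accumulated fill resets at the end of the contraction complex
    reset_times = [
        tv + (5.0 * w if i in double_idx else 2.0 * w)
        for i, tv in enumerate(truth.void_times)
    ]
    last_reset = np.zeros_like(t)
    for tr in reset_times:
        last_reset = np.where(t >= tr, tr, last_reset)
    p = params.pressure_baseline_cmh2o + slope * (t - last_reset)

    for i, tv in enumerate(truth.void_times):
        p += params.void_pressure_peak_cmh2o * np.exp(-0.5 * ((t - tv) / w) ** 2)
        n_peaks = 1
        if i in double_idx:
            # a second, narrower sub-peak within the same contraction episode
            p += 0.6 * params.void_pressure_peak_cmh2o * np.exp(
                -0.5 * ((t - (tv + 3.0 * w)) / (0.5 * w)) ** 2
            )
            n_peaks = 2
        truth.void_align_times.append(tv - w)  # inflection of the Gaussian rise
        truth.void_n_peaks.append(n_peaks)
    for j, tn in enumerate(truth.nvc_times):
        amp = (
            params.nvc_amplitudes[j % len(params.nvc_amplitudes)]
            if params.nvc_amplitudes
            else params.nvc_amplitude_cmh2o
        )
        p += amp * np.exp(-0.5 * ((t - tn) / params.nvc_width_s) ** 2)
        truth.nvc_amplitudes.append(amp)

    if params.pressure_noise_sd > 0:
        p = p + rng.normal(0.0, params.pressure_noise_sd, t.size)
    return TimeSeries("pressure", 0.0, params.fs, p, "cmH2O"), truth


def transient_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials calcium transient, zero for t<0."""
    if decay_s <= rise_s:
        raise ValidationError("decay must exceed rise")
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_s) - np.exp(-np.maximum(t, 0) / rise_s), 0.0)
    t_pk = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    peak = np.exp(-t_pk / decay_s) - np.exp(-t_pk / rise_s)
    return k / peak


def kernel_unit_peak_scale(rise_s: float, decay_s: float) -> float:
    """Peak value of exp(-t/decay) - exp(-t/rise); divides the raw kernel."""
    t_pk = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    return np.exp(-t_pk / decay_s) - np.exp(-t_pk / rise_s)


def simulate_photometry(
    truth: GroundTruth, params: SimParams
) -> tuple[TimeSeries, TimeSeries]:
    """Two-channel fluorescence locked to the cystometry ground truth.

    ch465 carries bleach x (1 + calcium transients); ch405 carries bleach
    only.  Motion artifacts are additive deflections shared by both
    channels (405 scaled by ``motion_405_gain``); noise is independent.
    """
    rng = np.random.default_rng([params.seed, _TAG_PHOT])
    t = np.arange(int(round(params.duration_s * params.fs))) / params.fs

    bleach = params.bleach_frac_fast * np.exp(-t / params.bleach_tau_fast_s) + (
        1.0 - params.bleach_frac_fast
    ) * np.exp(-t / params.bleach_tau_slow_s)

    activity = np.zeros_like(t)
    events = [(tv, 1.0) for tv in truth.void_align_times] + [
        (tn, params.nvc_attenuation) for tn in truth.nvc_times
    ]
    for te, scale in events:
        amp = params.transient_amp * scale
        if params.transient_amp_jitter > 0:
            amp *= rng.lognormal(0.0, params.transient_amp_jitter)
        truth.transient_amplitudes[te] = amp
        activity += amp * transient_kernel(
            t - te, params.transient_rise_s, params.transient_decay_s
        )

    n_art = rng.poisson(params.motion_artifact_rate_per_min * params.duration_s / 60.0)
    motion = np.zeros_like(t)
    for ta in np.sort(rng.uniform(60.0, params.duration_s - 60.0, n_art)):
        amp = params.motion_artifact_amp * rng.choice([-1.0, 1.0])
        motion += amp * np.exp(-0.5 * ((t - ta) / params.motion_width_s) ** 2)
        truth.artifact_times.append(float(ta))

    f465 = params.f_base_465 * bleach * (1.0 + activity) + motion
    f405 = params.f_base_405 * bleach + params.motion_405_gain * motion
    if params.photometry_noise_sd > 0:
        f465 = f465 + rng.normal(0.0, params.photometry_noise_sd, t.size)
        f405 = f405 + rng.normal(0.0, params.photometry_noise_sd, t.size)
    return (
        TimeSeries("photometry465", 0.0, params.fs, f465, "a.u."),
        TimeSeries("photometry405", 0.0, params.fs, f405, "a.u."),
    )


def make_stim_trials(params: SimParams) -> tuple[StimTrain, GroundTruth]:
    """Programmed stimulation schedule with per-trial relaxation/artifact flags."""
    rng = np.random.default_rng([params.seed, _TAG_STIM])
    d = params.stim_duration_s
    onsets = (
        2.0 * d
        + params.stim_interval_s * np.arange(params.n_stim_trials)
    )
    needed = onsets[-1] + 2.0 * d + 1.0 if params.n_stim_trials else 0.0
    truth = GroundTruth()
    flags = rng.random(params.n_stim_trials) < params.relaxation_prob
    u = rng.random(params.n_stim_trials)
    for i in range(params.n_stim_trials):
        if u[i] < params.artifact_baseline_frac:
            phase = "baseline"
        elif u[i] < params.artifact_baseline_frac + params.artifact_stim_frac:
            phase = "stim"
        else:
            phase = "none"
        truth.stim_trials.append((float(onsets[i]), float(d), bool(flags[i]), phase))
    train = StimTrain(onsets=onsets, durations=np.full(params.n_stim_trials, d))
    if needed > params.duration_s:
        raise GenerationError(
            f"duration_s={params.duration_s} too short for {params.n_stim_trials} "
            f"trials at {params.stim_interval_s} s spacing (need {needed:.0f} s)"
        )
    return train, truth


def simulate_emg(truth: GroundTruth, params: SimParams) -> TimeSeries:
    """Band-limited tonic EMG with programmed relaxation during flagged stims.

    The relaxation is a multiplicative envelope of (1 - depth) over the
    stimulation epoch, so epoch power scales exactly with (1 - depth)^2.
    Artifact-flagged trials receive a large-amplitude spike inside the
    flagged phase for exclusion-rule testing.
    """
    if not truth.stim_trials:
        raise ValidationError("stim_trials must be populated (see make_stim_trials)")
    rng = np.random.default_rng([params.seed, _TAG_EMG])
    fs = params.emg_fs
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs

    white = rng.standard_normal(n)
    sos = sps.butter(
        4, [params.emg_band_low_hz, params.emg_band_high_hz], btype="band", fs=fs,
        output="sos",
    )
    tonic = sps.sosfiltfilt(sos, white)
    tonic *= params.emg_tonic_mv / np.sqrt(np.mean(tonic**2))

    envelope = np.ones(n)
    for onset, dur, relax, _phase in truth.stim_trials:
        if relax:
            i0, i1 = int(round(onset * fs)), int(round((onset + dur) * fs))
            envelope[i0:i1] = 1.0 - params.emg_relaxation_depth
    emg = tonic * envelope

    spike_len = max(int(round(0.005 * fs)), 3)
    for onset, dur, _relax, phase in truth.stim_trials:
        if phase == "none":
            continue
        lo = onset - dur if phase == "baseline" else onset
        ta = lo + rng.uniform(0.2, 0.8) * dur
        i0 = int(round(ta * fs))
        emg[i0 : i0 + spike_len] += (
            params.emg_artifact_amp_mult * params.emg_tonic_mv
        ) * rng.choice([-1.0, 1.0])
    return TimeSeries("emg", 0.0, fs, emg, "mV")


def simulate_stim_pressure(truth: GroundTruth, params: SimParams) -> TimeSeries:
    """Filling-ramp pressure for an optogenetic session (no voids).

    ``stim_pressure_rise_cmh2o`` > 0 adds a plateau rise during flagged
    trials on top of the natural filling trend.
    """
    rng = np.random.default_rng([params.seed, _TAG_CMG])
    fs = params.emg_fs
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs
    slope = params.infusion_rate_ul_min / 60.0 * params.bladder_compliance_cmh2o_per_ul
    p = params.pressure_baseline_cmh2o + slope * t
    if params.stim_pressure_rise_cmh2o > 0:
        for onset, dur, relax, _phase in truth.stim_trials:
            if relax:
                ramp_up = np.clip((t - onset) / 1.0, 0.0, 1.0)
                ramp_dn = np.clip(((onset + dur + 2.0) - t) / 2.0, 0.0, 1.0)
                p += params.stim_pressure_rise_cmh2o * np.minimum(ramp_up, ramp_dn)
    if params.pressure_noise_sd > 0:
        p = p + rng.normal(0.0, params.pressure_noise_sd, n)
    return TimeSeries("pressure", 0.0, fs, p, "cmH2O")


def simulate_session(params: SimParams) -> tuple[SessionBundle, GroundTruth]:
    """Full photometry/cystometry session bundle with shared ground truth."""
    pressure, truth = simulate_cmg(params)
    ch465, ch405 = simulate_photometry(truth, params)
    bundle = SessionBundle(
        animal_id=params.animal_id,
        photometry465=ch465,
        photometry405=ch405,
        pressure=pressure,
        metadata={"infusion_rate_ul_min": str(params.infusion_rate_ul_min)},
    )
    return bundle, truth


def simulate_opto_session(params: SimParams) -> tuple[SessionBundle, GroundTruth]:
    """EMG + pressure session around a programmed stimulation train."""
    train, truth = make_stim_trials(params)
    emg = simulate_emg(truth, params)
    pressure = simulate_stim_pressure(truth, params)
    bundle = SessionBundle(
        animal_id=params.animal_id,
        emg=emg,
        pressure=pressure,
        stim_train=train,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# thermography


@dataclasses.dataclass
class SpotSpec:
    """One programmed urine spot: an ellipse in pixel coordinates."""

    center: tuple         # (row, col) px
    axes: tuple           # (semi_r, semi_c) px
    klass: str            # void | leak | mark
    t_appear_s: float = 0.0


def _template_geometry(params: SimParams) -> tuple[int, int, int, int]:
    """Template rectangle (top, left, height, width) with exact pixel count."""
    target_px = int(round(params.px_per_cm2 * 10.0))
    h = int(np.floor(np.sqrt(target_px)))
    while target_px % h:
        h -= 1
    w = target_px // h
    return 10, 10, h, w


def simulate_thermal_frame(
    spot_specs: Sequence[SpotSpec],
    params: SimParams,
    template_area_cm2: float = 10.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize warm spots + the calibration template on a cool background.

    Ground truth records exact pixel areas (rasterization counts), the
    implied cm2 areas at the programmed pixel density, and volumes from the
    shared linear calibration curve.
    """
    rng = np.random.default_rng([params.seed, _TAG_THERM])
    h, w = params.frame_shape
    img = np.full((h, w), params.background_level, dtype=float)

    top, left, th, tw = _template_geometry(params)
    template_px = th * tw
    img[top : top + th, left : left + tw] = params.template_level
    occupied = np.zeros((h, w), dtype=bool)
    occupied[top : top + th, left : left + tw] = True

    truth = GroundTruth()
    px_per_cm2 = template_px / template_area_cm2
    from .config import DEFAULTS

    slope = float(DEFAULTS["volume_slope_ul_per_cm2"])
    for spec in spot_specs:
        rr, cc = draw_ellipse(*spec.center, *spec.axes)
        if rr.min() < 0 or cc.min() < 0 or rr.max() >= h or cc.max() >= w:
            raise GenerationError(f"spot at {spec.center} out of frame")
        # a 2 px clearance keeps regions 8-disconnected after thresholding
        rr2, cc2 = draw_ellipse(*spec.center, spec.axes[0] + 2, spec.axes[1] + 2,
                                shape=(h, w))
        if occupied[rr2, cc2].any():
            raise GenerationError(f"spot at {spec.center} touches another region")
        occupied[rr, cc] = True
        img[rr, cc] = params.spot_level
        area_px = int(rr.size)
        area_cm2 = area_px / px_per_cm2
        vol = slope * area_cm2 if spec.klass != "template" else 0.0
        truth.spot_truth.append(
            {
                "centroid": (float(rr.mean()), float(cc.mean())),
                "area_px": area_px,
                "area_cm2": area_cm2,
                "volume_ul": vol,
                "klass": spec.klass,
                "t_appear_s": spec.t_appear_s,
            }
        )
    truth.spot_truth.append(
        {
            "centroid": (top + (th - 1) / 2.0, left + (tw - 1) / 2.0),
            "area_px": template_px,
            "area_cm2": template_area_cm2,
            "volume_ul": 0.0,
            "klass": "template",
            "t_appear_s": 0.0,
        }
    )
    if params.image_noise_sd > 0:
        img = img + rng.normal(0.0, params.image_noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, truth


def make_spot_specs(params: SimParams) -> list[SpotSpec]:
    """Sample void (large, corner) and leak (small, central) spot layouts.

    Placement respects the classification margins: void spots sit well
    inside ``corner_radius_cm`` of a corner with area comfortably above
    ``void_area_min_cm2``; leaks sit mid-arena and well below it.
    """
    rng = np.random.default_rng([params.seed, _TAG_THERM, 1])
    h, w = params.frame_shape
    px_per_cm = np.sqrt(params.px_per_cm2)
    specs: list[SpotSpec] = []
    corners = [(0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1)]

    def axes_for(area_cm2: float) -> tuple:
        area_px = area_cm2 * params.px_per_cm2
        ecc = rng.uniform(0.7, 1.0)
        a = np.sqrt(area_px / (np.pi * ecc))
        return (a, a * ecc)

    t_appear = 60.0
    # corner (0, 0) hosts the calibration template; voids use the others
    void_corners = corners[1:] + corners[:1]
    for i in range(params.n_void_spots):
        cr, cc_ = void_corners[i % 3]
        r_off = rng.uniform(0.25, 0.5) * params.corner_radius_cm * px_per_cm
        ang = rng.uniform(0.3, 1.2)
        center = (
            int(np.clip(cr + np.sign(h / 2 - cr) * r_off * np.sin(ang), 40, h - 40)),
            int(np.clip(cc_ + np.sign(w / 2 - cc_) * r_off * np.cos(ang), 60, w - 60)),
        )
        area = rng.uniform(*params.void_spot_area_cm2)
        specs.append(SpotSpec(center, axes_for(area), "void", t_appear))
        t_appear += 300.0

    def collides(center, axes) -> bool:
        r = max(axes) + 6.0
        return any(
            np.hypot(center[0] - s.center[0], center[1] - s.center[1])
            < r + max(s.axes)
            for s in specs
        )

    for _ in range(params.n_leak_spots):
        area = rng.uniform(*params.leak_spot_area_cm2)
        axes = axes_for(area)
        for _try in range(100):
            center = (
                int(rng.uniform(0.3, 0.7) * h),
                int(rng.uniform(0.3, 0.7) * w),
            )
            if not collides(center, axes):
                break
        else:
            raise GenerationError("could not place a leak spot without overlap")
        specs.append(SpotSpec(center, axes, "leak", t_appear))
        t_appear += 120.0
    return specs


def simulate_marking_session(params: SimParams) -> pd.DataFrame:
    """Mark events after a urine-stimulus presentation, plus corner voids.

    Marks follow a homogeneous Poisson process at ``mark_rate_per_min``
    starting ``mark_latency_s`` after the stimulus; dominant vs subordinate
    archetypes are encoded purely through latency and rate.  Returns an
    ordered event table.
    """
    rng = np.random.default_rng([params.seed, _TAG_MARK])
    t_stim = params.stimulus_time_s
    t_end = params.marking_session_s
    start = t_stim + params.mark_latency_s
    records = []
    if params.mark_rate_per_min > 0 and start < t_end:
        n = rng.poisson(params.mark_rate_per_min * (t_end - start) / 60.0)
        times = np.sort(rng.uniform(start, t_end, n))
        for i, tm in enumerate(times):
            records.append(
                {
                    "event_id": f"mark{i:03d}",
                    "animal_id": params.animal_id,
                    "kind": "mark",
                    "t_align_s": tm,
                    "t_start_s": tm,
                    "t_end_s": tm,
                }
            )
    for j in range(params.n_corner_voids):
        tv = rng.uniform(t_stim, t_end)
        records.append(
            {
                "event_id": f"void{j:03d}",
                "animal_id": params.animal_id,
                "kind": "void",
                "t_align_s": tv,
                "t_start_s": tv,
                "t_end_s": tv,
            }
        )
    records.sort(key=lambda r: r["t_align_s"])
    return events_from_records(records)
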