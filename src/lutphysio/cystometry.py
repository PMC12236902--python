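"""Cystometry event detection, gating, and alignment.

Contraction candidates are found on a detrended 10 Hz pressure trace
(rolling-median detrending absorbs the slow filling ramp); candidates are
classified as voids (externally confirmed) or non-voiding contractions
(NVCs) and gated by the inclusion rules: single contraction peak for both
kinds, and a >= 5 cmH2O pressure rise for NVCs.  Voids are aligned to the
maximum of dP/dt preceding the contraction (steepest pre-void rise); NVCs
are aligned to peak bladder pressure.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .config import DEFAULTS
from .io_formats import TimeSeries, ValidationError, events_from_records
from .photometry import downsample

logger = logging.getLogger("lutphysio")


@dataclasses.dataclass
class Event:
    """A detected or programmed episode on the session time axis."""

    event_id: str
    kind: str | None          # void | nvc | stim | mark | leak; None = unclassified
    t_align: float
    t_start: float
    t_end: float
    included: bool = True
    exclusion_reason: str = ""
    animal_id: str = ""
    qc: dict = dataclasses.field(default_factory=dict)

    def exclude(self, reason: str) -> None:
        self.included = False
        self.exclusion_reason = reason


@dataclasses.dataclass
class PressureDerivative:
    """dP/dt (cmH2O/s) of the smoothed, downsampled pressure trace."""

    values: np.ndarray
    fs: float
    t0: float
    smooth_s: float

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


def _to_analysis_rate(pressure: TimeSeries, target_dt: float = 0.1) -> TimeSeries:
    if pressure.fs > 1.0 / target_dt:
        return downsample(pressure, target_dt)
    return pressure


def compute_dpdt(
    pressure: TimeSeries, smooth_s: float = 1.0, target_dt: float = 0.1
) -> PressureDerivative:
    """Centered finite difference of the moving-average-smoothed pressure."""
    ts = _to_analysis_rate(pressure, target_dt)
    k = int(round(smooth_s * ts.fs))
    if smooth_s < 2.0 / ts.fs:
        raise ValidationError("smooth_s must span at least two samples")
    if ts.n <= k:
        raise ValidationError("trace shorter than the smoothing window")
    smoothed = uniform_filter1d(ts.values, size=max(k, 1), mode="nearest")
    dpdt = np.gradient(smoothed) * ts.fs
    return PressureDerivative(dpdt, ts.fs, ts.t0, smooth_s)


def detect_contractions(
    pressure: TimeSeries, config: dict | None = None
) -> list[Event]:
    """Candidate contraction episodes (kind unset) from the pressure trace.

    Episodes are peaks of the rolling-median-detrended trace with
    prominence above ``contraction_prominence_cmh2o``.  Each candidate
    carries QC fields: peak count within the episode (sub-peaks with
    prominence >= ``peak_prominence_frac`` x rise) and the pressure rise
    over the median of the 30 s pre-episode segment.
    """
    cfg = dict(DEFAULTS) if config is None else {**DEFAULTS, **config}
    ts = _to_analysis_rate(pressure)
    fs = ts.fs
    p = ts.values

    span = max(int(round(float(cfg["detrend_span_s"]) * fs)) | 1, 3)
    trend = (
        pd.Series(p).rolling(span, center=True, min_periods=1).median().to_numpy()
    )
    detr = uniform_filter1d(p - trend, size=max(int(round(0.5 * fs)), 1), mode="nearest")

    prom = float(cfg["contraction_prominence_cmh2o"])
    peaks, props = find_peaks(
        detr,
        prominence=prom,
        distance=max(int(round(float(cfg["contraction_min_interval_s"]) * fs)), 1),
    )
    events: list[Event] = []
    pre_n = int(round(float(cfg["pre_episode_baseline_s"]) * fs))
    for j, pk in enumerate(peaks):
        height = detr[pk]
        # episode bounds: where the detrended trace falls below 5% of the
        # peak height (well above the smoothed noise floor); a generous
        # bound keeps nearby sub-peaks of one contraction in one episode
        thresh = 0.05 * height
        lo = pk
        while lo > 0 and detr[lo - 1] > thresh:
            lo -= 1
        hi = pk
        while hi < detr.size - 1 and detr[hi + 1] > thresh:
            hi += 1
        baseline = float(np.median(p[max(lo - pre_n, 0) : lo])) if lo > 0 else float(p[0])
        rise = float(p[lo : hi + 1].max() - baseline)
        seg = detr[lo : hi + 1]
        sub_peaks, _ = find_peaks(
            seg, prominence=max(float(cfg["peak_prominence_frac"]) * rise, 1e-9)
        )
        n_peaks = max(int(sub_peaks.size), 1)
        t_peak = ts.t0 + pk / fs
        events.append(
            Event(
                event_id=f"c{j:03d}",
                kind=None,
                t_align=t_peak,          # provisional; see alignment_point
                t_start=ts.t0 + lo / fs,
                t_end=ts.t0 + hi / fs,
                qc={
                    "n_peaks": n_peaks,
                    "pressure_rise": rise,
                    "t_peak": t_peak,
                    "prominence": float(props["prominences"][j]),
                },
            )
        )
    logger.info("detect_contractions: %d candidates", len(events))
    return events


def classify_and_gate(
    candidates: Sequence[Event],
    confirmed_void_times: Sequence[float],
    config: dict | None = None,
    match_tol_s: float = 5.0,
) -> list[Event]:
    """Assign void/nvc kinds and apply the inclusion rules.

    A candidate whose peak falls within ``match_tol_s`` of a confirmed void
    time (urine-spot confirmation, or the synthetic ground-truth flag) is a
    void; all others are NVCs.  Exclusions: ``multi_peak`` when the episode
    shows more than one contraction peak (either kind), ``sub_threshold``
    for NVCs rising less than ``nvc_min_rise_cmh2o``.
    """
    cfg = dict(DEFAULTS) if config is None else {**DEFAULTS, **config}
    nvc_min = float(cfg["nvc_min_rise_cmh2o"])
    confirmed = np.asarray(sorted(confirmed_void_times), dtype=float)
    out: list[Event] = []
    for ev in sorted(candidates, key=lambda e: e.qc.get("t_peak", e.t_align)):
        ev = dataclasses.replace(ev, qc=dict(ev.qc))
        t_peak = ev.qc.get("t_peak", ev.t_align)
        is_void = confirmed.size > 0 and np.min(np.abs(confirmed - t_peak)) <= match_tol_s
        ev.kind = "void" if is_void else "nvc"
        if ev.qc.get("n_peaks", 1) > 1:
            ev.exclude("multi_peak")
        elif ev.kind == "nvc" and ev.qc.get("pressure_rise", 0.0) < nvc_min:
            ev.exclude("sub_threshold")
        out.append(ev)
    n_exc = sum(not e.included for e in out)
    logger.info(
        "classify_and_gate: %d events (%d excluded: %s)",
        len(out), n_exc,
        {e.event_id: e.exclusion_reason for e in out if not e.included},
    )
    return out


def alignment_point(
    pressure: TimeSeries, event: Event, config: dict | None = None
) -> Event:
    """Set the alignment time: max dP/dt before the peak (void) or the peak
    pressure time (NVC); ties break to the earliest sample."""
    cfg = dict(DEFAULTS) if config is None else {**DEFAULTS, **config}
    if not event.included:
        return event
    event = dataclasses.replace(event, qc=dict(event.qc))
    ts = _to_analysis_rate(pressure)
    t_peak = event.qc.get("t_peak", event.t_align)
    if event.kind == "void":
        dpdt = compute_dpdt(pressure, smooth_s=float(cfg["dpdt_smooth_s"]))
        back = float(cfg["dpdt_search_back_s"])
        i_hi = int(round((t_peak - dpdt.t0) * dpdt.fs))
        i_lo = int(round((t_peak - back - dpdt.t0) * dpdt.fs))
        if i_lo < 0:
            event.exclude("search_window_truncated")
            return event
        i_hi = min(i_hi + 1, dpdt.values.size)
        seg = dpdt.values[i_lo:i_hi]
        i_max = i_lo + int(np.argmax(seg))  # earliest sample on exact ties
        t_align = dpdt.t0 + i_max / dpdt.fs
        # parabolic vertex refinement: the smoothed derivative is flat-topped,
        # so a local quadratic fit beats the raw argmax under noise
        half = int(round(float(cfg["dpdt_refine_half_s"]) * dpdt.fs))
        a, b = max(i_max - half, i_lo), min(i_max + half, i_hi)
        if b - a >= 5:
            tt = (np.arange(a, b) - i_max) / dpdt.fs
            c2, c1, _c0 = np.polyfit(tt, dpdt.values[a:b], 2)
            if c2 < 0:
                vertex = float(np.clip(-c1 / (2.0 * c2),
                                       (a - i_max) / dpdt.fs,
                                       (b - 1 - i_max) / dpdt.fs))
                t_align = dpdt.t0 + i_max / dpdt.fs + vertex
        event.t_align = t_align
    else:
        i_lo = max(int(round((event.t_start - ts.t0) * ts.fs)), 0)
        i_hi = min(int(round((event.t_end - ts.t0) * ts.fs)) + 1, ts.n)
        smoothed = uniform_filter1d(ts.values, size=max(int(round(0.5 * ts.fs)), 1),
                                    mode="nearest")
        event.t_align = ts.t0 + (i_lo + int(np.argmax(smoothed[i_lo:i_hi]))) / ts.fs
    return event


def detect_events(
    pressure: TimeSeries,
    confirmed_void_times: Sequence[float],
    config: dict | None = None,
    animal_id: str = "",
) -> pd.DataFrame:
    """Full detection chain returning the canonical event table."""
    candidates = detect_contractions(pressure, config)
    gated = classify_and_gate(candidates, confirmed_void_times, config)
    aligned = [alignment_point(pressure, ev, config) for ev in gated]
    records = []
    for ev in aligned:
        records.append(
            {
                "event_id": ev.event_id,
                "animal_id": animal_id,
                "kind": ev.kind,
                "t_align_s": ev.t_align,
                "t_start_s": ev.t_start,
                "t_end_s": ev.t_end,
                "included": int(ev.included),
                "exclusion_reason": ev.exclusion_reason,
            }
        )
    return events_from_records(records)
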