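"""EUS-EMG epoch statistics around optogenetic stimulations.

Each stimulation trial is split into three equal-length epochs — before
(baseline, same duration as the stimulation), during (light delivery), and
after (recovery) — and each epoch is reduced to its Total Power (TTP),
the summed signal power across all frequencies.  By Parseval's theorem the
canonical time-domain form (sum of squared mean-removed samples) equals
the periodogram-bin sum; both are provided and must agree.  Normalized
epoch powers are each epoch's percent share of the trial total.  Response
rates follow the per-animal rules: a >= 5% TTP decrease during stimulation
(EMG), and a >= 3 cmH2O pressure rise over the extrapolated filling trend
(CMG).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULTS
from .io_formats import StimTrain, TimeSeries

logger = logging.getLogger("lutphysio")


@dataclasses.dataclass
class EpochPower:
    """Raw and normalized total power for one stimulation trial."""

    trial_id: str
    animal_id: str
    ttp_before: float
    ttp_stim: float
    ttp_after: float
    norm_before: float = float("nan")   # % of trial total
    norm_stim: float = float("nan")
    norm_after: float = float("nan")
    cmg_before: float = float("nan")    # mean pressure, cmH2O
    cmg_stim: float = float("nan")
    cmg_trend_slope: float = 0.0        # baseline-epoch fill trend, cmH2O/s
    duration_s: float = float("nan")    # stimulation (and epoch) duration
    baseline_artifact: bool = False
    included: bool = True
    exclusion_reason: str = ""


class EpochError(ValueError):
    """Trial epochs do not fit inside the recording."""


def epoch_trial(
    emg: TimeSeries, stim_onset: float, stim_duration: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split [t-d, t+2d) into before/during/after with equal sample counts."""
    fs = emg.fs
    n = int(round(stim_duration * fs))
    i0 = int(round((stim_onset - emg.t0) * fs))
    if i0 - n < 0 or i0 + 2 * n > emg.n:
        raise EpochError(
            f"trial at t={stim_onset} s (d={stim_duration} s) is out of bounds"
        )
    x = emg.values
    return x[i0 - n : i0], x[i0 : i0 + n], x[i0 + n : i0 + 2 * n]


def total_power(epoch: np.ndarray, remove_dc: bool = True) -> float:
    """Sum of squared (mean-removed) samples: the summed power across all
    frequencies of the epoch, in the time-domain convention."""
    x = np.asarray(epoch, dtype=float)
    if x.size == 0:
        raise ValueError("empty epoch")
    if remove_dc:
        x = x - x.mean()
    return float(np.sum(x * x))


def total_power_freq(epoch: np.ndarray, remove_dc: bool = True) -> float:
    """Frequency-domain total power: periodogram-bin sum, normalized so
    that Parseval makes it equal :func:`total_power`."""
    x = np.asarray(epoch, dtype=float)
    if remove_dc:
        x = x - x.mean()
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2
    # double the interior bins of the one-sided spectrum
    power[1:] *= 2.0
    if x.size % 2 == 0 and x.size > 1:
        power[-1] /= 2.0
    return float(power.sum() / x.size)


def normalize_epochs(
    ttp_before: float, ttp_stim: float, ttp_after: float
) -> tuple[float, float, float]:
    """Each epoch's percent share of the trial total: TTP_p / sum x 100."""
    total = ttp_before + ttp_stim + ttp_after
    if total <= 0:
        raise ValueError("all-zero trial has no defined normalization")
    return (
        ttp_before / total * 100.0,
        ttp_stim / total * 100.0,
        ttp_after / total * 100.0,
    )


def detect_baseline_artifact(
    baseline: np.ndarray,
    fs: float,
    scale: float,
    mad_mult: float = 8.0,
    min_ms: float = 2.0,
) -> bool:
    """Threshold-crossing rule: any run of samples exceeding ``mad_mult`` x
    the session's robust amplitude scale for at least ``min_ms``."""
    thresh = mad_mult * scale
    over = np.abs(baseline) > thresh
    min_run = max(int(round(min_ms / 1000.0 * fs)), 1)
    if not over.any():
        return False
    # longest run of consecutive True
    padded = np.concatenate([[0], over.astype(int), [0]])
    edges = np.flatnonzero(np.diff(padded))
    runs = edges[1::2] - edges[::2]
    return bool(runs.max() >= min_run)


def robust_amplitude_scale(emg: TimeSeries) -> float:
    """Session-wide MAD-based amplitude scale (Gaussian-consistent)."""
    x = emg.values
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def analyze_trials(
    emg: TimeSeries,
    pressure: TimeSeries | None,
    stim: StimTrain,
    animal_id: str = "",
    config: dict | None = None,
    artifact_flags: Sequence[str] | None = None,
) -> list[EpochPower]:
    """Epoch, power, and normalize every stimulation trial.

    ``artifact_flags`` may carry ground-truth per-trial phases
    ("none" | "baseline" | "stim" | "after"); otherwise baseline artifacts
    are detected with the threshold-crossing rule.  Out-of-bounds trials
    are excluded with a reason, artifact exclusion is applied by
    :func:`exclude_artifact_trials`.
    """
    cfg = dict(DEFAULTS) if config is None else {**DEFAULTS, **config}
    scale = robust_amplitude_scale(emg)
    remove_dc = bool(cfg["ttp_remove_dc"])
    trials: list[EpochPower] = []
    for k in range(stim.n_trials):
        onset, dur = float(stim.onsets[k]), float(stim.durations[k])
        trial_id = f"stim{k:03d}"
        try:
            before, during, after = epoch_trial(emg, onset, dur)
        except EpochError as exc:
            trials.append(
                EpochPower(trial_id, animal_id, np.nan, np.nan, np.nan,
                           included=False, exclusion_reason=str(exc))
            )
            continue
        tb = total_power(before, remove_dc)
        ts_ = total_power(during, remove_dc)
        ta = total_power(after, remove_dc)
        nb, ns, na = normalize_epochs(tb, ts_, ta)
        if artifact_flags is not None:
            artifact = artifact_flags[k] == "baseline"
        else:
            artifact = detect_baseline_artifact(
                before, emg.fs, scale,
                float(cfg["emg_artifact_mad_mult"]), float(cfg["emg_artifact_min_ms"]),
            )
        ep = EpochPower(
            trial_id, animal_id, tb, ts_, ta, nb, ns, na,
            duration_s=dur, baseline_artifact=artifact,
        )
        if pressure is not None:
            pb, ps, _pa = epoch_trial(pressure, onset, dur)
            ep.cmg_before = float(pb.mean())
            ep.cmg_stim = float(ps.mean())
            t_rel = np.arange(pb.size) / pressure.fs
            ep.cmg_trend_slope = float(np.polyfit(t_rel, pb, 1)[0])
        trials.append(ep)
    logger.info("analyze_trials: %d trials (%d in bounds)",
                stim.n_trials, sum(t.included for t in trials))
    return trials


def exclude_artifact_trials(trials: Sequence[EpochPower]) -> list[EpochPower]:
    """Drop trials with baseline-phase artifacts; stimulation- or
    recovery-phase artifacts never cause removal."""
    kept = []
    for t in trials:
        t = dataclasses.replace(t)
        if t.included and t.baseline_artifact:
            t.included = False
            t.exclusion_reason = "baseline_artifact"
        kept.append(t)
    n_exc = sum(not t.included for t in kept)
    logger.info("exclude_artifact_trials: %d/%d excluded", n_exc, len(kept))
    return kept


def subsample_trials(
    trials: Sequence[EpochPower], n_per_animal: int, seed: int
) -> list[EpochPower]:
    """Equal representation across animals: n randomly selected included
    trials per animal (seeded, without replacement)."""
    rng = np.random.default_rng(seed)
    by_animal: dict[str, list[EpochPower]] = {}
    for t in trials:
        if t.included:
            by_animal.setdefault(t.animal_id, []).append(t)
    out: list[EpochPower] = []
    for animal in sorted(by_animal):
        pool = by_animal[animal]
        if len(pool) < n_per_animal:
            raise ValueError(
                f"animal {animal!r} has {len(pool)} included trials, "
                f"needs >= {n_per_animal}"
            )
        idx = np.sort(rng.choice(len(pool), n_per_animal, replace=False))
        out.extend(pool[i] for i in idx)
    return out


def response_rates(
    trials: Sequence[EpochPower],
    emg_drop_threshold: float = 0.05,
    cmg_rise_threshold: float = 3.0,
    stim_duration: float | None = None,
) -> pd.DataFrame:
    """Per-animal response percentages.

    EMG: percent of trials with TTP_stim <= (1 - threshold) x TTP_before.
    CMG: percent of trials where mean stimulation pressure exceeds the
    baseline mean by >= threshold after subtracting the predicted
    filling-related rise (linear extrapolation of the baseline-epoch
    trend across the stimulation epoch).
    """
    rows = []
    by_animal: dict[str, list[EpochPower]] = {}
    for t in trials:
        if t.included:
            by_animal.setdefault(t.animal_id, []).append(t)
    for animal in sorted(by_animal):
        pool = by_animal[animal]
        emg_hits = sum(
            t.ttp_stim <= (1.0 - emg_drop_threshold) * t.ttp_before for t in pool
        )
        cmg_hits = 0
        cmg_n = 0
        for t in pool:
            if np.isnan(t.cmg_before) or np.isnan(t.cmg_stim):
                continue
            cmg_n += 1
            d = t.duration_s if np.isfinite(t.duration_s) else (stim_duration or 0.0)
            # baseline mean sits at epoch center -d/2; stim mean at +d/2
            predicted_fill = t.cmg_trend_slope * d
            rise = t.cmg_stim - t.cmg_before - predicted_fill
            if rise >= cmg_rise_threshold:
                cmg_hits += 1
        rows.append(
            {
                "animal_id": animal,
                "n_trials": len(pool),
                "emg_response_rate_pct": 100.0 * emg_hits / len(pool),
                "cmg_response_rate_pct": (
                    100.0 * cmg_hits / cmg_n if cmg_n else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def trials_to_frame(trials: Sequence[EpochPower]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in trials])
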