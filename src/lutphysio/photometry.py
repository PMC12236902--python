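"""Two-channel fiber-photometry processing.

Pipeline: block-mean downsampling to 0.1 s resolution, baseline (F0)
fitting over the entire trace and conversion to dF/F0 = (F - F0)/F0,
motion correction by subtracting the calcium-independent 405 nm
(isosbestic) dF/F0 from the 465 nm signal, then the per-event percent
normalization (baseline = mean dF/F0 of the 60 s preceding the event) and
Z-scoring used for averaged traces and heatmaps.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import TimeSeries, ValidationError

logger = logging.getLogger("lutphysio")


class FitError(RuntimeError):
    """No family in the baseline cascade converged."""


class WindowError(ValueError):
    """Peri-event window extends outside the trace."""


@dataclasses.dataclass
class DffTrace:
    """dF/F0 trace with its baseline-fit provenance."""

    values: np.ndarray       # dimensionless dF/F0
    fs: float
    t0: float = 0.0
    corrected: bool = False  # isosbestic subtraction applied
    baseline_model: dict = dataclasses.field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def index_at(self, t: float) -> int:
        return int(round((t - self.t0) * self.fs))


def downsample(ts: TimeSeries, target_dt: float = 0.1) -> TimeSeries:
    """Non-overlapping block means at the target resolution.

    The target interval must be an integer multiple of the source sample
    interval; the trailing partial block is dropped.
    """
    factor_f = ts.fs * target_dt
    factor = int(round(factor_f))
    if factor < 1:
        raise ValidationError(
            f"target_dt={target_dt} is finer than the source interval 1/{ts.fs}"
        )
    if abs(factor_f - factor) > 1e-6:
        raise ValidationError(
            f"target_dt={target_dt} is not an integer multiple of 1/fs"
        )
    n_blocks = ts.n // factor
    blocks = ts.values[: n_blocks * factor].reshape(n_blocks, factor)
    return TimeSeries(ts.label, ts.t0, ts.fs / factor, blocks.mean(axis=1), ts.units)


# ---------------------------------------------------------------------------
# baseline fitting


def _fit_double_exp(t, y):
    span = max(t[-1] - t[0], 1.0)
    y0 = max(y[0], 1e-12)

    def f(t, a1, tau1, a2, tau2):
        return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)

    p0 = (0.3 * y0, span / 10.0, 0.7 * y0, 5.0 * span)
    bounds = ([0.0, 1e-3, 0.0, 1e-3], [10.0 * y0, 1e7, 10.0 * y0, 1e8])
    popt, _ = curve_fit(f, t, y, p0=p0, bounds=bounds, maxfev=20000)
    return f(t, *popt), {"family": "double_exp", "coefficients": list(popt)}


def _fit_single_exp_const(t, y):
    span = max(t[-1] - t[0], 1.0)
    y0 = max(y[0], 1e-12)

    def f(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    p0 = (0.5 * y0, span / 3.0, 0.5 * y0)
    bounds = ([0.0, 1e-3, 0.0], [10.0 * y0, 1e8, 10.0 * y0])
    popt, _ = curve_fit(f, t, y, p0=p0, bounds=bounds, maxfev=20000)
    return f(t, *popt), {"family": "single_exp_const", "coefficients": list(popt)}


def _fit_poly2(t, y):
    coeffs = np.polyfit(t, y, 2)
    return np.polyval(coeffs, t), {"family": "poly2", "coefficients": list(coeffs)}


_FAMILIES = {
    "double_exp": _fit_double_exp,
    "single_exp_const": _fit_single_exp_const,
    "poly2": _fit_poly2,
}


def compute_dff(
    ts: TimeSeries,
    cascade: str = "double_exp,single_exp_const,poly2",
) -> DffTrace:
    """Fit F0 over the entire trace and return (F - F0) / F0.

    Families are tried in cascade order; a family that fails to converge or
    yields a non-positive baseline falls through to the next, logged.
    """
    y = ts.values
    if np.any(y <= 0):
        raise ValidationError("fluorescence must be strictly positive")
    t = np.arange(y.size) / ts.fs
    last_exc: Exception | None = None
    for name in (s.strip() for s in cascade.split(",")):
        try:
            f0, model = _FAMILIES[name](t, y)
        except KeyError:
            raise ValidationError(f"unknown baseline family {name!r}") from None
        except Exception as exc:  # non-convergence
            logger.warning("compute_dff: family %s failed (%s), falling back", name, exc)
            last_exc = exc
            continue
        if np.any(f0 <= 0) or not np.all(np.isfinite(f0)):
            logger.warning("compute_dff: family %s gave invalid F0, falling back", name)
            continue
        dff = (y - f0) / f0
        model["residual_rms"] = float(np.sqrt(np.mean((y - f0) ** 2)))
        return DffTrace(dff, ts.fs, ts.t0, corrected=False, baseline_model=model)
    raise FitError(f"no baseline family converged (last error: {last_exc})")


def isosbestic_correct(
    dff465: DffTrace, dff405: DffTrace, fit_gain: bool = True
) -> DffTrace:
    """Subtract the motion-bearing 405 nm dF/F0 from the 465 nm dF/F0.

    With ``fit_gain`` the 405 trace is first rescaled by least-squares
    gain + offset onto the 465 trace; with ``fit_gain=False`` the raw
    difference is taken.

    The gain fit uses only samples where the 405 trace deflects clearly
    from its baseline (beyond 3 robust SDs).  A whole-trace fit is
    dominated by artifact-free noise, which shrinks the gain toward zero
    and leaves most of each shared artifact in the corrected trace;
    restricting to deflection samples estimates the shared-motion gain
    itself.  When the 405 trace has no such deflections the fit falls back
    to all samples.
    """
    if dff465.n != dff405.n or dff465.fs != dff405.fs:
        raise ValidationError("channels must share length and sampling rate")
    x, y = dff405.values, dff465.values
    if fit_gain:
        med = np.median(x)
        mad = 1.4826 * np.median(np.abs(x - med))
        mask = np.abs(x - med) > 3.0 * mad if mad > 0 else np.zeros_like(x, bool)
        if mask.sum() < 10:
            mask = np.ones_like(x, bool)
        A = np.column_stack([x[mask], np.ones(int(mask.sum()))])
        (gain, offset), *_ = np.linalg.lstsq(A, y[mask], rcond=None)
    else:
        gain, offset = 1.0, 0.0
    corrected = y - (gain * x + offset)
    model = dict(dff465.baseline_model)
    model["isosbestic_gain"] = float(gain)
    model["isosbestic_offset"] = float(offset)
    return DffTrace(corrected, dff465.fs, dff465.t0, corrected=True, baseline_model=model)


# ---------------------------------------------------------------------------
# per-event normalization and z-scoring


@dataclasses.dataclass
class EventWindow:
    """One peri-event window after normalization."""

    values: np.ndarray     # % units (or z / raw depending on mode)
    lags: np.ndarray       # seconds relative to the alignment point
    baseline: float        # mean dF/F0 of the 60 s preceding the event
    divisive: bool         # False when the small-baseline guard fired
    flagged: bool = False


def normalize_per_event(
    dff: DffTrace,
    t_align: float,
    window_s: float = 60.0,
    guard_eps: float = 0.005,
) -> EventWindow:
    """Percent change relative to the pre-event baseline.

    Implements (dF/F0 - baseline) / baseline x 100 with baseline = mean
    dF/F0 over the ``window_s`` seconds preceding the alignment point.
    When |baseline| < ``guard_eps`` the division is unstable and the window
    falls back to subtractive-only normalization, flagged.
    """
    w = int(round(window_s * dff.fs))
    i = dff.index_at(t_align)
    if i - w < 0 or i + w >= dff.n:
        raise WindowError(
            f"window +/-{window_s} s around t={t_align} s is out of bounds"
        )
    window = dff.values[i - w : i + w + 1]
    baseline = float(np.mean(dff.values[i - w : i]))
    lags = (np.arange(2 * w + 1) - w) / dff.fs
    if abs(baseline) < guard_eps:
        return EventWindow((window - baseline) * 100.0, lags, baseline,
                           divisive=False, flagged=True)
    return EventWindow((window - baseline) / baseline * 100.0, lags, baseline,
                       divisive=True)


def zscore(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Z = (x - mean(x)) / std(x); zero-variance input yields zeros, flagged."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0.0:
        return np.zeros_like(x), True
    return (x - np.mean(x)) / sd, False
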