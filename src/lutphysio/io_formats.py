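"""Reading and writing of session, event, stimulation, and image artifacts.

The session container format is a self-describing UTF-8 text file: header
lines ``#key=value`` (required keys: ``fs_hz``, ``t0_s``, ``channels``,
``units``, ``animal_id``), then a tab-separated body with one row per sample
and one column per declared channel.  Values round-trip losslessly (written
with 17 significant digits).  All times are seconds from session start.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lutphysio")

VALID_UNITS = {"cmH2O", "mV", "a.u.", "dimensionless"}

#: expected units per channel role; channels not listed accept any valid unit
CHANNEL_UNITS = {
    "pressure": "cmH2O",
    "emg": "mV",
    "photometry465": "a.u.",
    "photometry405": "a.u.",
}

EVENT_KINDS = ("void", "nvc", "stim", "mark", "leak")

EVENT_COLUMNS = [
    "event_id",
    "animal_id",
    "kind",
    "t_align_s",
    "t_start_s",
    "t_end_s",
    "included",
    "exclusion_reason",
]

FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """Malformed file structure (bad header, missing rows)."""


class SamplingError(ValueError):
    """Time column inconsistent with uniform sampling at the declared rate."""


class ValidationError(ValueError):
    """Semantically invalid content (bad units, NaN values, unknown kinds)."""


@dataclasses.dataclass
class TimeSeries:
    """Uniformly sampled channel.

    Sample ``i`` occurs at exactly ``t0 + i / fs``; gaps are not
    representable.
    """

    label: str
    t0: float
    fs: float
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError("values must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"channel {self.label!r} contains non-finite values")
        if self.units not in VALID_UNITS:
            raise ValidationError(f"unknown units {self.units!r}")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def index_at(self, t: float) -> int:
        """Index of the sample at/just after session time ``t``."""
        return int(round((t - self.t0) * self.fs))


@dataclasses.dataclass
class StimTrain:
    """Programmed optogenetic pulse-train log: one row per stimulation trial."""

    onsets: np.ndarray          # s, trial onset times
    durations: np.ndarray       # s, light-delivery duration per trial
    pulse_hz: float = 20.0      # pulse rate within a trial
    pulse_ms: float = 10.0      # single pulse width

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.onsets.shape != self.durations.shape:
            raise ValidationError("onsets and durations must have equal length")

    @property
    def n_trials(self) -> int:
        return int(self.onsets.size)


@dataclasses.dataclass
class SessionBundle:
    """All simultaneously recorded channels of one session."""

    animal_id: str
    photometry465: TimeSeries | None = None
    photometry405: TimeSeries | None = None
    pressure: TimeSeries | None = None
    emg: TimeSeries | None = None
    stim_train: StimTrain | None = None
    metadata: dict = dataclasses.field(default_factory=dict)

    CHANNEL_FIELDS = ("photometry465", "photometry405", "pressure", "emg")

    def __post_init__(self) -> None:
        if all(getattr(self, f) is None for f in self.CHANNEL_FIELDS):
            raise ValidationError("a session needs at least one channel")
        p465, p405 = self.photometry465, self.photometry405
        if p465 is not None and p405 is not None:
            if (p465.fs, p465.t0, p465.n) != (p405.fs, p405.t0, p405.n):
                raise ValidationError(
                    "photometry channels must share fs, t0 and length"
                )

    def channels(self) -> dict[str, TimeSeries]:
        return {
            f: getattr(self, f)
            for f in self.CHANNEL_FIELDS
            if getattr(self, f) is not None
        }


# ---------------------------------------------------------------------------
# session files


def write_session(bundle: SessionBundle, path: str | Path) -> None:
    """Write a session file readable by :func:`read_session`.

    Channels with different sampling rates are not representable in one
    file; all present channels must share fs, t0, and length.
    """
    chans = bundle.channels()
    rates = {(ts.fs, ts.t0, ts.n) for ts in chans.values()}
    if len(rates) != 1:
        raise ValidationError(
            "all channels in one session file must share fs, t0 and length"
        )
    fs, t0, n = rates.pop()
    names = [name for name in bundle.CHANNEL_FIELDS if name in chans]
    units = [chans[name].units for name in names]

    lines = [
        f"#fs_hz={FLOAT_FMT % fs}",
        f"#t0_s={FLOAT_FMT % t0}",
        f"#channels={','.join(names)}",
        f"#units={','.join(units)}",
        f"#animal_id={bundle.animal_id}",
    ]
    for key in sorted(bundle.metadata):
        lines.append(f"#{key}={bundle.metadata[key]}")
    cols = np.column_stack([chans[name].values for name in names])
    body = "\n".join("\t".join(FLOAT_FMT % v for v in row) for row in cols)
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n", encoding="utf-8")
    logger.info("write_session: %s (%d channels, %d samples)", path, len(names), n)


_REQUIRED_KEYS = ("fs_hz", "t0_s", "channels", "units", "animal_id")


def read_session(path: str | Path) -> SessionBundle:
    """Parse a session file into a :class:`SessionBundle`."""
    path = Path(path)
    header: dict[str, str] = {}
    body_start = 0
    with open(path, encoding="utf-8") as fh:
        raw = fh.read().splitlines()
    for lineno, line in enumerate(raw, start=1):
        if not line.startswith("#"):
            body_start = lineno - 1
            break
        if "=" not in line:
            raise FormatError(f"{path}: malformed header at line {lineno}: {line!r}")
        key, _, value = line[1:].partition("=")
        header[key.strip()] = value.strip()
    else:
        raise FormatError(f"{path}: no data rows found")

    missing = [k for k in _REQUIRED_KEYS if k not in header]
    if missing:
        raise FormatError(f"{path}: header missing required keys {missing}")
    fs = float(header["fs_hz"])
    t0 = float(header["t0_s"])
    names = header["channels"].split(",")
    units = header["units"].split(",")
    if len(names) != len(units):
        raise FormatError(f"{path}: channels/units count mismatch")

    try:
        data = np.loadtxt(raw[body_start:], delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed data row ({exc})") from exc
    if data.shape[1] != len(names):
        raise FormatError(
            f"{path}: {len(names)} channels declared but rows have "
            f"{data.shape[1]} columns"
        )

    kwargs: dict = {}
    has_time = "t_s" in names
    for j, (name, unit) in enumerate(zip(names, units)):
        if name == "t_s":
            t = data[:, j]
            expected = t0 + np.arange(len(t)) / fs
            if not np.allclose(t, expected, atol=0.25 / fs):
                raise SamplingError(
                    f"{path}: time column is not uniform at fs={fs} Hz "
                    "(gap or non-monotone step)"
                )
            continue
        expected_unit = CHANNEL_UNITS.get(name)
        if expected_unit is not None and unit != expected_unit:
            raise ValidationError(
                f"{path}: channel {name!r} declares units {unit!r}, "
                f"expected {expected_unit!r}"
            )
        if name not in SessionBundle.CHANNEL_FIELDS:
            raise FormatError(f"{path}: unknown channel {name!r}")
        kwargs[name] = TimeSeries(name, t0, fs, data[:, j], unit)

    metadata = {
        k: v for k, v in header.items() if k not in _REQUIRED_KEYS
    }
    bundle = SessionBundle(animal_id=header["animal_id"], metadata=metadata, **kwargs)
    logger.info(
        "read_session: %s (%d channels, %d samples%s)",
        path, len(kwargs), data.shape[0], ", time column" if has_time else "",
    )
    return bundle


# ---------------------------------------------------------------------------
# event tables


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write an ordered event table as CSV with the canonical column order."""
    df = _validate_events(events)
    df.to_csv(path, index=False, float_format="%.12g")
    logger.info("write_events: %s (%d events)", path, len(df))


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event table CSV, validating kinds and duplicate ids."""
    df = pd.read_csv(
        path, dtype={"event_id": str, "animal_id": str, "exclusion_reason": str},
        keep_default_na=False,
    )
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: event table missing columns {missing}")
    for col in ("t_align_s", "t_start_s", "t_end_s"):
        df[col] = pd.to_numeric(df[col])
    df["included"] = pd.to_numeric(df["included"]).astype(int)
    return _validate_events(df)


def _validate_events(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, EVENT_COLUMNS].copy()
    bad = set(df["kind"]) - set(EVENT_KINDS)
    if bad:
        raise ValidationError(f"unknown event kinds: {sorted(bad)}")
    dup = df["event_id"][df["event_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate event ids: {sorted(set(dup))}")
    excluded = df[df["included"] == 0]
    if (excluded["exclusion_reason"].astype(str).str.len() == 0).any():
        raise ValidationError("excluded events must carry an exclusion_reason")
    return df


def empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": pd.Series(dtype=str),
            "animal_id": pd.Series(dtype=str),
            "kind": pd.Series(dtype=str),
            "t_align_s": pd.Series(dtype=float),
            "t_start_s": pd.Series(dtype=float),
            "t_end_s": pd.Series(dtype=float),
            "included": pd.Series(dtype=int),
            "exclusion_reason": pd.Series(dtype=str),
        }
    )


def events_from_records(records: Sequence[Mapping]) -> pd.DataFrame:
    """Build a validated event table from a list of dicts."""
    if not records:
        return empty_events()
    df = pd.DataFrame.from_records(records)
    for col, default in (("included", 1), ("exclusion_reason", "")):
        if col not in df.columns:
            df[col] = default
    return _validate_events(df)


# ---------------------------------------------------------------------------
# stimulation logs


def write_stim_log(stim: StimTrain, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "trial_id": [f"stim{i:03d}" for i in range(stim.n_trials)],
            "t_on_s": stim.onsets,
            "duration_s": stim.durations,
            "pulse_hz": stim.pulse_hz,
            "pulse_ms": stim.pulse_ms,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_stim_log(path: str | Path) -> StimTrain:
    df = pd.read_csv(path)
    for col in ("t_on_s", "duration_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: stim log missing column {col!r}")
    return StimTrain(
        onsets=df["t_on_s"].to_numpy(float),
        durations=df["duration_s"].to_numpy(float),
        pulse_hz=float(df["pulse_hz"].iloc[0]) if "pulse_hz" in df else 20.0,
        pulse_ms=float(df["pulse_ms"].iloc[0]) if "pulse_ms" in df else 10.0,
    )
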