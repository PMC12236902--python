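"""Peri-event matrices, averaged traces, shuffle nulls, and group summaries.

A peri-event matrix holds one row per included event, spanning -60..+60 s
around the alignment point at the dF/F0 resolution.  Rows are ordered by
animal then event time.  The shuffle null rebuilds the same matrix at
randomly selected time points on the same traces, giving the chance-level
signal; group comparisons use the Kruskal-Wallis omnibus followed by
Dunn's pairwise test with Holm adjustment.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .photometry import DffTrace, EventWindow, WindowError, normalize_per_event, zscore

logger = logging.getLogger("lutphysio")


@dataclasses.dataclass
class PeriEventMatrix:
    """events x lag grid of normalized dF/F0 (or z / raw) values."""

    values: np.ndarray        # shape (n_events, n_lags)
    lags: np.ndarray          # seconds, symmetric around 0
    rows: pd.DataFrame        # event_id, animal_id, kind, t_align_s, flagged
    normalization: str        # percent | zscore | raw
    alignment: str = ""       # what lag 0 means (e.g. "max_dpdt", "peak_pressure")

    @property
    def n_events(self) -> int:
        return int(self.values.shape[0])

    def to_frame(self) -> pd.DataFrame:
        lag_cols = [f"lag_{l:+.1f}s" for l in self.lags]
        return pd.concat(
            [self.rows.reset_index(drop=True),
             pd.DataFrame(self.values, columns=lag_cols)],
            axis=1,
        )


def _empty_matrix(lags: np.ndarray, normalization: str, alignment: str) -> PeriEventMatrix:
    rows = pd.DataFrame(
        columns=["event_id", "animal_id", "kind", "t_align_s", "flagged"]
    )
    return PeriEventMatrix(
        np.empty((0, lags.size)), lags, rows, normalization, alignment
    )


def _one_row(
    dff: DffTrace, t_align: float, normalization: str, window_s: float,
    guard_eps: float,
) -> EventWindow:
    win = normalize_per_event(dff, t_align, window_s, guard_eps)
    if normalization == "percent":
        return win
    w = int(round(window_s * dff.fs))
    i = dff.index_at(t_align)
    raw = dff.values[i - w : i + w + 1]
    if normalization == "raw":
        return EventWindow(raw, win.lags, win.baseline, divisive=False)
    if normalization == "zscore":
        z, flat = zscore(raw)
        return EventWindow(z, win.lags, win.baseline, divisive=False, flagged=flat)
    raise ValueError(f"unknown normalization {normalization!r}")


def build_matrix(
    dff: DffTrace,
    events: pd.DataFrame,
    normalization: str = "percent",
    window_s: float = 60.0,
    guard_eps: float = 0.005,
    alignment: str = "",
) -> PeriEventMatrix:
    """One matrix row per included event; out-of-bounds events are dropped.

    ``events`` is the canonical event table; only rows with included == 1
    are used.  Rows are ordered by (animal_id, t_align_s).
    """
    use = events[events["included"] == 1].sort_values(
        ["animal_id", "t_align_s"], kind="mergesort"
    )
    w = int(round(window_s * dff.fs))
    lags = (np.arange(2 * w + 1) - w) / dff.fs
    rows, data = [], []
    n_dropped = 0
    for _, ev in use.iterrows():
        try:
            win = _one_row(dff, float(ev["t_align_s"]), normalization, window_s,
                           guard_eps)
        except WindowError as exc:
            n_dropped += 1
            logger.info("build_matrix: dropped %s (%s)", ev["event_id"], exc)
            continue
        data.append(win.values)
        rows.append(
            {
                "event_id": ev["event_id"],
                "animal_id": ev["animal_id"],
                "kind": ev["kind"],
                "t_align_s": float(ev["t_align_s"]),
                "flagged": win.flagged,
            }
        )
    if not data:
        return _empty_matrix(lags, normalization, alignment)
    return PeriEventMatrix(
        np.vstack(data), lags, pd.DataFrame(rows), normalization, alignment
    )


def shuffle_null(
    dff: DffTrace,
    n_events: int,
    seed: int,
    exclusion_zones: Sequence[tuple] = (),
    normalization: str = "percent",
    window_s: float = 60.0,
    guard_eps: float = 0.005,
    animal_id: str = "",
    max_tries: int = 10000,
) -> PeriEventMatrix:
    """Peri-event matrix at randomly selected time points (chance level).

    Pseudo-event times are uniform over the span where the +/-window fits
    inside the trace; optional exclusion zones (e.g. around true voids) are
    respected by rejection sampling.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    w = int(round(window_s * dff.fs))
    lags = (np.arange(2 * w + 1) - w) / dff.fs
    if n_events == 0:
        return _empty_matrix(lags, normalization, "shuffle")
    lo = dff.t0 + (w + 1) / dff.fs
    hi = dff.t0 + (dff.n - w - 2) / dff.fs
    if hi <= lo:
        raise ValueError("trace too short to host a single +/-window")
    times: list[float] = []
    tries = 0
    while len(times) < n_events:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n_events} pseudo-events outside "
                f"{len(exclusion_zones)} exclusion zones in {max_tries} draws"
            )
        t = rng.uniform(lo, hi)
        tries += 1
        if any(a <= t <= b for a, b in exclusion_zones):
            continue
        times.append(t)
    records = [
        {
            "event_id": f"null{i:03d}",
            "animal_id": animal_id,
            "kind": "null",
            "t_align_s": t,
            "t_start_s": t,
            "t_end_s": t,
            "included": 1,
            "exclusion_reason": "",
        }
        for i, t in enumerate(times)
    ]
    events = pd.DataFrame.from_records(records)
    mat = build_matrix(dff, events, normalization, window_s, guard_eps, "shuffle")
    return mat


def average_trace(matrix: PeriEventMatrix) -> tuple[np.ndarray, np.ndarray, int]:
    """Column-wise mean and SEM across events; SEM is zero for n = 1."""
    n = matrix.n_events
    if n == 0:
        raise ValueError("empty matrix has no average")
    mean = matrix.values.mean(axis=0)
    sem = (
        matrix.values.std(axis=0, ddof=1) / np.sqrt(n)
        if n > 1
        else np.zeros(matrix.values.shape[1])
    )
    return mean, sem, n


def per_animal_summary(
    matrix: PeriEventMatrix,
    stat_window: tuple,
    n_per_animal: int,
    seed: int,
) -> pd.DataFrame:
    """Equally weighted per-event summary values.

    For each animal, ``n_per_animal`` rows are sampled without replacement
    (seeded), and each sampled row is reduced to its mean over the
    ``stat_window`` lag range (seconds).  The pooled output keeps animal
    labels so downstream tests can stay per-animal aware.
    """
    rng = np.random.default_rng(seed)
    lo, hi = stat_window
    cols = (matrix.lags >= lo) & (matrix.lags <= hi)
    if not cols.any():
        raise ValueError("stat_window selects no lags")
    out = []
    for animal, grp in matrix.rows.groupby("animal_id", sort=True):
        idx = grp.index.to_numpy()
        if idx.size < n_per_animal:
            raise ValueError(
                f"animal {animal!r} has {idx.size} events, "
                f"needs >= {n_per_animal}"
            )
        take = (
            idx
            if idx.size == n_per_animal
            else np.sort(rng.choice(idx, n_per_animal, replace=False))
        )
        for i in take:
            out.append(
                {
                    "animal_id": animal,
                    "event_id": matrix.rows.loc[i, "event_id"],
                    "value": float(matrix.values[i, cols].mean()),
                }
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# group comparison


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment."""
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj


def dunn_test(groups: Mapping[str, np.ndarray]) -> list[dict]:
    """Dunn's pairwise rank test with tie correction and Holm adjustment."""
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], float) for k in names])
    sizes = [len(groups[k]) for k in names]
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks = {}
    start = 0
    for k, sz in zip(names, sizes):
        mean_ranks[k] = ranks[start : start + sz].mean()
        start += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs, zs, ps = [], [], []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ka, kb = names[a], names[b]
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[ka] - mean_ranks[kb]) / se if se > 0 else 0.0
            pairs.append((ka, kb))
            zs.append(z)
            ps.append(2.0 * stats.norm.sf(abs(z)))
    adj = _holm(np.asarray(ps))
    return [
        {"pair": pair, "z": z, "p": p, "p_adj": pa}
        for pair, z, p, pa in zip(pairs, zs, ps, adj)
    ]


def compare_groups(
    void_values: np.ndarray,
    nvc_values: np.ndarray,
    null_values: np.ndarray,
) -> dict:
    """Omnibus + pairwise nonparametric comparison of the three groups.

    Returns contract-level report fields: group medians, Kruskal-Wallis
    H and p, and Dunn pairwise z / p / Holm-adjusted p.
    """
    groups = {"void": np.asarray(void_values, float),
              "nvc": np.asarray(nvc_values, float),
              "null": np.asarray(null_values, float)}
    for name, vals in groups.items():
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
        pairwise = [
            {"pair": pair, "z": 0.0, "p": 1.0, "p_adj": 1.0}
            for pair in (("void", "nvc"), ("void", "null"), ("nvc", "null"))
        ]
    else:
        h, p = stats.kruskal(*groups.values())
        pairwise = dunn_test(groups)
    return {
        "medians": {k: float(np.median(v)) for k, v in groups.items()},
        "n": {k: int(v.size) for k, v in groups.items()},
        "kruskal_h": float(h),
        "kruskal_p": float(p),
        "pairwise": pairwise,
    }
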