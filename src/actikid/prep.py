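"""Epoch-series I/O, non-wear detection, and day/recording inclusion rules.

The study protocol this implements: the device records movement counts in
fixed epochs; non-wear time is any continuous period of minimal movement
strictly longer than one hour; a recording day is included if it contains at
least five hours of wear; a recording is eligible if the best window of at
most seven consecutive calendar days contains at least three such days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("actikid")

#: default movement threshold below which an epoch counts as "minimal
#: movement", in counts per second of epoch (so 5 counts at 1-s epochs).
MINIMAL_MOVEMENT_COUNTS_PER_SEC = 5.0


class PrepError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class EpochSeries:
    """One child's contiguous epoch-level count-magnitude series."""

    child_id: str
    start_time: np.datetime64
    epoch_seconds: float
    magnitudes: np.ndarray

    def __post_init__(self):
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.start_time = np.datetime64(self.start_time, "s")
        if len(self.magnitudes) < 1:
            raise PrepError("series must contain at least one epoch")
        if np.any(self.magnitudes < 0):
            raise PrepError("magnitudes must be non-negative")

    def __len__(self) -> int:
        return len(self.magnitudes)

    @property
    def timestamps(self) -> np.ndarray:
        offs = (np.arange(len(self)) * self.epoch_seconds).astype("timedelta64[s]")
        return self.start_time + offs

    @property
    def dates(self) -> np.ndarray:
        """Calendar date of each epoch's start (local clock time)."""
        return self.timestamps.astype("datetime64[D]")


@dataclass
class WearMask:
    """Per-epoch wear/non-wear labels plus maximal segments."""

    wear: np.ndarray  # bool, True = wear
    segments: list = field(default_factory=list)  # (start_idx, end_idx, label)

    def __post_init__(self):
        self.wear = np.asarray(self.wear, dtype=bool)

    @property
    def n_wear(self) -> int:
        return int(self.wear.sum())


@dataclass
class DayRecord:
    date: np.datetime64
    wear_hours: float
    valid: bool


@dataclass
class RecordingSelection:
    window_start: np.datetime64
    window_days: int
    included_days: list  # valid DayRecords inside the window
    eligible: bool
    total_wear_hours: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_epoch_series(path, epoch_seconds: float, child_id: str | None = None) -> EpochSeries:
    """Read a delimited epoch-count trace.

    Accepts either ``timestamp,magnitude`` or ``timestamp,axis1,axis2,axis3``
    columns (header required, ISO-8601 timestamps). Triaxial counts are
    collapsed to the Euclidean vector magnitude. Gaps in the timestamp grid
    are filled with zero-count epochs (logged); non-monotone timestamps are
    an error.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise PrepError(f"cannot parse {path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "timestamp" not in cols:
        raise PrepError(f"{path}: missing 'timestamp' column")
    if "magnitude" in cols:
        mags = pd.to_numeric(df["magnitude"], errors="coerce").to_numpy(dtype=float)
    elif {"axis1", "axis2", "axis3"}.issubset(cols):
        axes = df[["axis1", "axis2", "axis3"]].apply(pd.to_numeric, errors="coerce")
        mags = np.sqrt((axes.to_numpy(dtype=float) ** 2).sum(axis=1))
    else:
        raise PrepError(f"{path}: need 'magnitude' or 'axis1..axis3' columns")
    if np.any(~np.isfinite(mags)):
        line = int(np.flatnonzero(~np.isfinite(mags))[0]) + 2  # 1-based + header
        raise PrepError(f"{path}: unparsable count value at line {line}")
    try:
        ts = pd.to_datetime(df["timestamp"]).to_numpy().astype("datetime64[s]")
    except Exception as exc:  # noqa: BLE001
        raise PrepError(f"{path}: unparsable timestamp: {exc}") from exc
    if len(ts) == 0:
        raise PrepError(f"{path}: empty trace")
    step = np.timedelta64(int(round(epoch_seconds)), "s")
    offsets = (ts - ts[0]) / step
    idx = np.round(offsets.astype(float)).astype(np.int64)
    if np.any(np.diff(idx) <= 0):
        line = int(np.flatnonzero(np.diff(idx) <= 0)[0]) + 3
        raise PrepError(f"{path}: non-monotone timestamps at line {line}")
    n = idx[-1] + 1
    if n > len(ts):
        logger.warning(
            "%s: %d missing epochs filled with zero counts", path, n - len(ts)
        )
    mags_full = np.zeros(n, dtype=float)
    mags_full[idx] = mags
    cid = child_id if child_id is not None else _stem(path)
    return EpochSeries(child_id=cid, start_time=ts[0], epoch_seconds=epoch_seconds, magnitudes=mags_full)


def write_epoch_series(series: EpochSeries, path) -> None:
    """Write a trace as ``child_id,timestamp,magnitude`` CSV."""
    df = pd.DataFrame(
        {
            "child_id": series.child_id,
            "timestamp": np.datetime_as_string(series.timestamps, unit="s"),
            "magnitude": series.magnitudes,
        }
    )
    df.to_csv(path, index=False)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


# ---------------------------------------------------------------------------
# Non-wear detection
# ---------------------------------------------------------------------------


def detect_non_wear(
    series: EpochSeries,
    min_duration_minutes: float = 60.0,
    movement_threshold: float | None = None,
) -> WearMask:
    """Label maximal minimal-movement runs strictly longer than the minimum
    duration (default 60 min) as non-wear.

    ``movement_threshold`` is in counts per epoch; when omitted it defaults
    to ``MINIMAL_MOVEMENT_COUNTS_PER_SEC`` scaled by the epoch length. A run
    of epochs qualifies only if every magnitude is strictly below the
    threshold and the run duration strictly exceeds ``min_duration_minutes``
    ("longer than" is read as a strict inequality).
    """
    if min_duration_minutes <= 0:
        raise PrepError("min_duration_minutes must be positive")
    if movement_threshold is None:
        movement_threshold = MINIMAL_MOVEMENT_COUNTS_PER_SEC * series.epoch_seconds
    below = series.magnitudes < movement_threshold
    wear = np.ones(len(series), dtype=bool)
    min_epochs = min_duration_minutes * 60.0 / series.epoch_seconds
    # maximal runs of sub-threshold epochs
    padded = np.concatenate([[False], below, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for a, b in zip(starts, ends):
        if (b - a) > min_epochs:  # strictly longer than the minimum
            wear[a:b] = False
    segments = _segments_from_mask(wear)
    return WearMask(wear=wear, segments=segments)


def _segments_from_mask(wear: np.ndarray) -> list:
    if len(wear) == 0:
        return []
    boundaries = np.flatnonzero(np.diff(wear.astype(np.int8)) != 0) + 1
    edges = np.concatenate([[0], boundaries, [len(wear)]])
    return [
        (int(a), int(b), "wear" if wear[a] else "non_wear")
        for a, b in zip(edges[:-1], edges[1:])
    ]


def wear_segments(series: EpochSeries, mask: WearMask) -> list[np.ndarray]:
    """Magnitude arrays of the maximal wear runs, in order."""
    return [series.magnitudes[a:b] for a, b, lab in mask.segments if lab == "wear"]


# ---------------------------------------------------------------------------
# Day and recording inclusion
# ---------------------------------------------------------------------------


def summarize_days(
    series: EpochSeries, mask: WearMask, min_wear_hours: float = 5.0
) -> list[DayRecord]:
    """One record per calendar day the series overlaps; a day is valid if it
    holds at least ``min_wear_hours`` of wear (inclusive)."""
    if len(mask.wear) != len(series):
        raise PrepError("wear mask not aligned with series")
    dates = series.dates
    out = []
    day0, day1 = dates[0], dates[-1]
    n_days = int((day1 - day0) / np.timedelta64(1, "D")) + 1
    epoch_hours = series.epoch_seconds / 3600.0
    for i in range(n_days):
        day = day0 + np.timedelta64(i, "D")
        sel = dates == day
        wear_hours = float(mask.wear[sel].sum() * epoch_hours)
        out.append(DayRecord(date=day, wear_hours=wear_hours, valid=wear_hours >= min_wear_hours))
    return out


def select_recording(
    days: list[DayRecord], max_window: int = 7, min_valid_days: int = 3
) -> RecordingSelection:
    """Best window of at most ``max_window`` consecutive calendar days.

    The window maximizing total wear hours is chosen (ties broken by the
    earliest start, then the shortest window); the recording is eligible iff
    the window contains at least ``min_valid_days`` valid days. Calendar days
    inside the span but absent from ``days`` contribute zero wear.
    """
    if not days:
        raise PrepError("empty day list")
    d0 = min(d.date for d in days)
    d1 = max(d.date for d in days)
    span = int((d1 - d0) / np.timedelta64(1, "D")) + 1
    wear = np.zeros(span)
    valid = np.zeros(span, dtype=bool)
    recs: dict[int, DayRecord] = {}
    for d in days:
        i = int((d.date - d0) / np.timedelta64(1, "D"))
        wear[i] = d.wear_hours
        valid[i] = d.valid
        recs[i] = d
    best = None  # (total, start, length)
    for start in range(span):
        for length in range(1, min(max_window, span - start) + 1):
            total = float(wear[start : start + length].sum())
            key = (-total, start, length)
            if best is None or key < best[0]:
                best = (key, start, length, total)
    _, start, length, total = best
    included = [recs[i] for i in range(start, start + length) if i in recs and valid[i]]
    return RecordingSelection(
        window_start=d0 + np.timedelta64(start, "D"),
        window_days=length,
        included_days=included,
        eligible=len(included) >= min_valid_days,
        total_wear_hours=total,
    )
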