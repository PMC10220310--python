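"""Per-child activity outcomes from decoded state sequences.

Outcome definitions: time in states 2-5 is total active time, states 4-5 is
intense activity, states 0-1 inactivity; the headline outcomes are expressed
as proportions of total wear time over the included valid days, to control
for wear-time differences between children. A conventional cut-point
estimate (counts re-aggregated to 5-s epochs, threshold 40) and compliance
with the 180 min/day physical-activity guideline are also computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hsmm import ACTIVE, CATEGORY_NAMES, INACTIVE, INTENSE, NON_WEAR_CAT
from .prep import DayRecord, EpochSeries, RecordingSelection, WearMask


class MetricsError(ValueError):
    pass


@dataclass
class IntensitySequence:
    """Per-epoch intensity categories aligned to an epoch series."""

    child_id: str
    start_time: np.datetime64
    epoch_seconds: float
    labels: np.ndarray  # codes: INACTIVE, ACTIVE, INTENSE, NON_WEAR_CAT

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.start_time = np.datetime64(self.start_time, "s")

    def __len__(self):
        return len(self.labels)

    @property
    def timestamps(self) -> np.ndarray:
        offs = (np.arange(len(self)) * self.epoch_seconds).astype("timedelta64[s]")
        return self.start_time + offs


@dataclass
class ActivitySummary:
    child_id: str
    n_days: int
    wear_hours_per_day: float
    active_hours_per_day: float
    intense_hours_per_day: float
    prop_active: float
    prop_intense: float
    cutpoint_active_mins_per_day: float = np.nan
    meets_guideline: bool | None = None


def _included_dates(selection: RecordingSelection) -> list:
    return [d.date for d in selection.included_days]


def summarize_activity(
    seq: IntensitySequence, selection: RecordingSelection
) -> ActivitySummary:
    """Average daily hours and pooled wear-time proportions over the included
    valid days of an eligible recording.

    Proportions use total wear epochs across included days as the
    denominator; hours-per-day figures weight included days equally.
    """
    if not selection.eligible:
        raise MetricsError(
            f"recording for {seq.child_id} is ineligible "
            "(fewer than the minimum number of valid days); exclude this child"
        )
    dates = seq.timestamps.astype("datetime64[D]")
    included = _included_dates(selection)
    epoch_hours = seq.epoch_seconds / 3600.0
    wear_h, act_h, int_h = [], [], []
    n_wear = n_active = n_intense = 0
    for day in included:
        lab = seq.labels[dates == day]
        w = lab != NON_WEAR_CAT
        a = (lab == ACTIVE) | (lab == INTENSE)
        i = lab == INTENSE
        n_wear += int(w.sum())
        n_active += int(a.sum())
        n_intense += int(i.sum())
        wear_h.append(w.sum() * epoch_hours)
        act_h.append(a.sum() * epoch_hours)
        int_h.append(i.sum() * epoch_hours)
    if n_wear == 0:
        raise MetricsError(f"no wear epochs on included days for {seq.child_id}")
    return ActivitySummary(
        child_id=seq.child_id,
        n_days=len(included),
        wear_hours_per_day=float(np.mean(wear_h)),
        active_hours_per_day=float(np.mean(act_h)),
        intense_hours_per_day=float(np.mean(int_h)),
        prop_active=n_active / n_wear,
        prop_intense=n_intense / n_wear,
    )


def cutpoint_active_minutes(
    series: EpochSeries,
    mask: WearMask,
    selection: RecordingSelection,
    cutpoint: float = 40.0,
    agg_seconds: float = 5.0,
) -> tuple[float, list[float]]:
    """Daily active minutes by the cut-point method.

    Counts are re-aggregated to ``agg_seconds`` windows by summation
    (windows aligned to the series start); a window is active if its summed
    counts reach the cut-point (default 40 counts per 5 s) and every source
    epoch is wear time. Returns (mean over included valid days, per-day
    list).
    """
    if cutpoint <= 0:
        raise MetricsError("cutpoint must be positive")
    factor = agg_seconds / series.epoch_seconds
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise MetricsError(
            f"epoch length {series.epoch_seconds}s does not divide the "
            f"{agg_seconds}s aggregation window evenly"
        )
    factor = int(round(factor))
    dates = series.dates
    included = _included_dates(selection)
    if not included:
        raise MetricsError("no included valid days")
    per_day = []
    for day in included:
        sel = dates == day
        mags = series.magnitudes[sel]
        wear = mask.wear[sel]
        n = (len(mags) // factor) * factor
        if n == 0:
            per_day.append(0.0)
            continue
        sums = mags[:n].reshape(-1, factor).sum(axis=1)
        allwear = wear[:n].reshape(-1, factor).all(axis=1)
        active = (sums >= cutpoint) & allwear
        per_day.append(float(active.sum() * agg_seconds / 60.0))
    return float(np.mean(per_day)), per_day


def meets_who_guideline(
    daily_active_minutes, threshold: float = 180.0, rule: str = "mean"
) -> bool:
    """Guideline compliance: by default, mean daily active minutes over the
    included days must reach the threshold (180 min); ``rule='all_days'``
    requires every included day to comply."""
    mins = np.asarray(list(daily_active_minutes), dtype=float)
    if mins.size == 0:
        raise MetricsError("need at least one included day")
    if rule == "mean":
        return bool(mins.mean() >= threshold)
    if rule == "all_days":
        return bool((mins >= threshold).all())
    raise MetricsError(f"unknown compliance rule {rule!r}")


@dataclass
class DiurnalProfile:
    bin_minutes: float
    bin_starts: np.ndarray  # seconds since midnight
    fractions: pd.DataFrame  # index bin, columns category names

    def to_long(self) -> pd.DataFrame:
        df = self.fractions.copy()
        df.insert(0, "bin_start_seconds", self.bin_starts)
        return df.melt(
            id_vars="bin_start_seconds", var_name="category", value_name="fraction"
        )


def diurnal_profile(
    sequences: list[IntensitySequence], bin_minutes: float = 10.0
) -> DiurnalProfile:
    """Time-of-day occupancy fractions across child-days.

    For each clock-time bin the fraction of child-day epochs in each of the
    four categories is computed; clock time a child-day's series does not
    cover counts as non-wear (the device was off). Per-bin fractions sum
    to 1.
    """
    if not sequences:
        raise MetricsError("need at least one sequence")
    bin_sec = bin_minutes * 60.0
    n_bins = 24 * 3600 / bin_sec
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise MetricsError(f"{bin_minutes}-minute bins do not divide 24 h evenly")
    n_bins = int(round(n_bins))
    counts = np.zeros((4, n_bins))
    total_child_days = 0
    for seq in sequences:
        ts = seq.timestamps
        days = ts.astype("datetime64[D]")
        total_child_days += len(np.unique(days))
        secs = (ts - days).astype("timedelta64[s]").astype(float)
        bins = np.minimum((secs / bin_sec).astype(np.int64), n_bins - 1)
        np.add.at(counts, (seq.labels, bins), 1.0)
    epochs_per_bin = bin_sec / sequences[0].epoch_seconds
    expected = total_child_days * epochs_per_bin
    observed = counts.sum(axis=0)
    counts[NON_WEAR_CAT] += np.maximum(expected - observed, 0.0)
    frac = counts / counts.sum(axis=0, keepdims=True)
    fractions = pd.DataFrame(
        {CATEGORY_NAMES[c]: frac[c] for c in (NON_WEAR_CAT, INACTIVE, ACTIVE, INTENSE)}
    )
    return DiurnalProfile(
        bin_minutes=bin_minutes,
        bin_starts=np.arange(n_bins) * bin_sec,
        fractions=fractions,
    )


def plot_diurnal_profile(profile: DiurnalProfile, path=None):
    """Stacked area plot of the diurnal occupancy profile (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hours = profile.bin_starts / 3600.0
    cats = list(profile.fractions.columns)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.stackplot(hours, *[profile.fractions[c] for c in cats], labels=cats)
    ax.set_xlabel("time of day (h)")
    ax.set_ylabel("fraction of child-days")
    ax.set_xlim(0, 24)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
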