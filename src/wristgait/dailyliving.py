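"""Free-living post-processing: non-wear detection, day selection, walking time.

The chain is: per-minute non-wear detection (sustained low per-axis SD for
at least 30 min), selection of the first four full calendar days with
enough wear time, and the daily walking duration as the median of the four
per-day gait-window minute sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np

from .io_preprocess import AccelRecording

SD_THRESHOLD_G = 0.013       # 13 mg, the common actigraphy stillness bound
MIN_NONWEAR_MINUTES = 30
MIN_WEAR_HOURS = 20.0
N_DAYS_REQUIRED = 4
SECONDS_PER_DAY = 86400


@dataclass
class WearMask:
    """Per-epoch (1-minute) wear flags; True means the device was worn."""

    wear: np.ndarray                 # (n_epochs,) bool
    epoch_s: float = 60.0
    sd_threshold: float = SD_THRESHOLD_G
    min_nonwear_minutes: int = MIN_NONWEAR_MINUTES

    @property
    def n_epochs(self) -> int:
        return self.wear.size

    def wear_hours(self) -> float:
        return float(self.wear.sum()) * self.epoch_s / 3600.0


@dataclass
class DaySelection:
    """Qualifying full calendar days and the exclusion status."""

    day_dates: list[date]
    wear_hours: list[float]
    qualifies: list[bool]
    selected: list[int]              # indices into day_dates, first 4 qualifying
    excluded: bool
    min_wear_hours: float = MIN_WEAR_HOURS


@dataclass
class DailySummary:
    """Per-day gait minutes over the four selected days and their median."""

    day_dates: list[date]
    gait_minutes: list[float]
    daily_walking_time: float
    included: bool = True
    subject_id: str = ""


def detect_nonwear(rec: AccelRecording, sd_threshold: float = SD_THRESHOLD_G,
                   min_minutes: int = MIN_NONWEAR_MINUTES,
                   epoch_s: float = 60.0) -> WearMask:
    """Flag non-wear: runs of epochs in which every axis's SD stays below
    ``sd_threshold`` for at least ``min_minutes``.

    Epochs are counted from the recording start with a stride equal to the
    epoch, so shifting the recording by whole epochs shifts the mask
    identically.  A recording shorter than ``min_minutes`` is all-wear.
    """
    epoch_len = int(round(epoch_s * rec.fs))
    n_epochs = rec.n_samples // epoch_len
    if n_epochs == 0:
        return WearMask(wear=np.ones(0, dtype=bool), epoch_s=epoch_s,
                        sd_threshold=sd_threshold, min_nonwear_minutes=min_minutes)
    x = rec.samples[: n_epochs * epoch_len].reshape(n_epochs, epoch_len, 3)
    # single-pass per-epoch SD (E[x^2] - E[x]^2 in float64 accumulators)
    s1 = np.einsum("ijk->ik", x, dtype=np.float64)
    s2 = np.einsum("ijk,ijk->ik", x, x, dtype=np.float64)
    var = s2 / epoch_len - (s1 / epoch_len) ** 2
    sd = np.sqrt(np.maximum(var, 0.0))          # (n_epochs, 3)
    low = (sd < sd_threshold).all(axis=1)
    wear = np.ones(n_epochs, dtype=bool)
    min_epochs = int(np.ceil(min_minutes * 60.0 / epoch_s))
    # flag every low-SD run of at least min_epochs
    if low.any():
        padded = np.concatenate([[False], low, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for lo, hi in zip(edges[::2], edges[1::2]):
            if hi - lo >= min_epochs:
                wear[lo:hi] = False
    return WearMask(wear=wear, epoch_s=epoch_s, sd_threshold=sd_threshold,
                    min_nonwear_minutes=min_minutes)


def _anchor(rec: AccelRecording) -> datetime:
    return rec.t0 if rec.t0 is not None else datetime(2000, 1, 1)


def select_days(rec: AccelRecording, mask: WearMask,
                min_wear_hours: float = MIN_WEAR_HOURS,
                n_days: int = N_DAYS_REQUIRED) -> DaySelection:
    """Select the first ``n_days`` full (midnight-to-midnight) calendar days
    with wear time of at least ``min_wear_hours``.

    A subject with fewer qualifying days than ``n_days`` (i.e. under
    ``n_days``×24 h of usable data) is flagged excluded; exclusion is a
    status, not an exception.
    """
    t0 = _anchor(rec)
    total_s = rec.duration_s
    # first midnight at or after t0
    first_midnight = datetime.combine(t0.date(), datetime.min.time())
    if first_midnight < t0:
        first_midnight += timedelta(days=1)
    offset_s = (first_midnight - t0).total_seconds()
    day_dates: list[date] = []
    wear_hours: list[float] = []
    qualifies: list[bool] = []
    day_start = offset_s
    while day_start + SECONDS_PER_DAY <= total_s + 1e-9:
        e0 = int(day_start // mask.epoch_s)
        e1 = int((day_start + SECONDS_PER_DAY) // mask.epoch_s)
        wh = float(mask.wear[e0:e1].sum()) * mask.epoch_s / 3600.0
        day_dates.append((first_midnight + timedelta(seconds=day_start - offset_s)).date())
        wear_hours.append(wh)
        qualifies.append(wh >= min_wear_hours)
        day_start += SECONDS_PER_DAY
    selected = [i for i, q in enumerate(qualifies) if q][:n_days]
    return DaySelection(
        day_dates=day_dates, wear_hours=wear_hours, qualifies=qualifies,
        selected=selected, excluded=len(selected) < n_days,
        min_wear_hours=min_wear_hours,
    )


def daily_walking_time(gait_windows_per_day, window_s: float = 10.0,
                       subject_id: str = "", day_dates=None) -> DailySummary:
    """Median daily gait minutes over exactly four selected days.

    Per-day minutes = gait-window count × window_s / 60; with four days the
    median is the mean of the middle two values.
    """
    counts = np.asarray(gait_windows_per_day, dtype=np.float64)
    if counts.size != N_DAYS_REQUIRED:
        raise ValueError(f"need exactly {N_DAYS_REQUIRED} selected days, got {counts.size}")
    minutes = counts * window_s / 60.0
    return DailySummary(
        day_dates=list(day_dates) if day_dates is not None else [],
        gait_minutes=[float(m) for m in minutes],
        daily_walking_time=float(np.median(minutes)),
        subject_id=subject_id,
    )


def window_wear_flags(window_start_s: np.ndarray, window_s: float,
                      mask: WearMask) -> np.ndarray:
    """True where a prediction window lies fully inside wear time."""
    starts = np.asarray(window_start_s, dtype=np.float64)
    w0 = (starts // mask.epoch_s).astype(int)
    w1 = ((starts + window_s - 1e-9) // mask.epoch_s).astype(int)
    # windows fully inside one epoch or straddling two: check both endpoints
    # against the cumulative count of non-wear epochs (all-wear iff no
    # non-wear epoch falls in [w0, w1])
    nonwear_cum = np.concatenate([[0], np.cumsum(~mask.wear)])
    a = np.clip(w0, 0, mask.n_epochs)
    b = np.clip(w1 + 1, 0, mask.n_epochs)
    covered = nonwear_cum[b] - nonwear_cum[a]
    return covered == 0


def summarize_subject(rec: AccelRecording, window_start_s, window_pred,
                      window_s: float = 10.0,
                      sd_threshold: float = SD_THRESHOLD_G,
                      min_wear_hours: float = MIN_WEAR_HOURS) -> DailySummary | None:
    """Full daily-living chain for one subject.

    Predictions over non-wear spans are zeroed before summation; returns
    None (exclusion) when fewer than four qualifying days exist.
    """
    mask = detect_nonwear(rec, sd_threshold=sd_threshold)
    days = select_days(rec, mask, min_wear_hours=min_wear_hours)
    if days.excluded:
        return None
    starts = np.asarray(window_start_s, dtype=np.float64)
    pred = np.asarray(window_pred).astype(np.int8).copy()
    pred[~window_wear_flags(starts, window_s, mask)] = 0
    t0 = _anchor(rec)
    first_midnight = datetime.combine(t0.date(), datetime.min.time())
    if first_midnight < t0:
        first_midnight += timedelta(days=1)
    offset_s = (first_midnight - t0).total_seconds()
    day_idx = np.floor((starts - offset_s) / SECONDS_PER_DAY).astype(int)
    counts = []
    for sel in days.selected:
        in_day = day_idx == sel
        counts.append(int(pred[in_day].sum()))
    summary = daily_walking_time(
        counts, window_s=window_s, subject_id=rec.subject_id,
        day_dates=[days.day_dates[i] for i in days.selected],
    )
    return summary
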