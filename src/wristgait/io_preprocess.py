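"""Reading, resampling, windowing and standardizing wrist accelerometer data.

The canonical representation downstream of this module is a
:class:`WindowSet`: non-overlapping fixed-length tri-axial windows (by
default 10 s at 30 Hz, i.e. 300 samples) with optional binary gait labels
assigned by the half-or-more overlap rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.signal import resample_poly
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

FS_TARGET = 30.0
WINDOW_S = 10.0

AXES = ("x", "y", "z")


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular layout."""


@dataclass
class AccelRecording:
    """Uniformly sampled tri-axial acceleration in g, with a wall-clock anchor."""

    samples: np.ndarray            # (n, 3) float
    fs: float                      # Hz
    t0: datetime | None = None
    subject_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if not np.issubdtype(self.samples.dtype, np.floating):
            self.samples = self.samples.astype(np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if not self.fs > 0:
            raise ValueError("sampling frequency must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class AnnotationTrack:
    """Half-open labeled intervals in seconds from the recording start."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self):
        for start, end, label in self.intervals:
            if not start < end:
                raise ValueError(f"empty or inverted interval ({start}, {end})")
            if label not in ("gait", "non_gait"):
                raise ValueError(f"unknown interval label {label!r}")
        self.intervals = sorted(self.intervals, key=lambda iv: iv[0])
        for (s0, e0, _), (s1, _, _) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0:
                raise ValueError("annotation intervals overlap after sorting")

    def gait_intervals(self) -> np.ndarray:
        """(m, 2) array of gait interval bounds in seconds."""
        ivs = [(s, e) for s, e, lab in self.intervals if lab == "gait"]
        return np.asarray(ivs, dtype=np.float64).reshape(-1, 2)


@dataclass
class WindowSet:
    """Batch of fixed-length standardized windows with per-window metadata."""

    windows: np.ndarray                    # (n, 3, L)
    fs: float
    window_s: float
    labels: np.ndarray | None = None       # (n,) in {0, 1}
    subject_ids: np.ndarray | None = None  # (n,) str
    window_start_s: np.ndarray | None = None

    def __post_init__(self):
        self.windows = np.asarray(self.windows)
        if not np.issubdtype(self.windows.dtype, np.floating):
            self.windows = self.windows.astype(np.float64)
        if self.windows.ndim != 3 or self.windows.shape[1] != 3:
            raise ValueError("windows must have shape (n, 3, L)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary")
        if self.subject_ids is not None:
            self.subject_ids = np.asarray(self.subject_ids)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def window_length(self) -> int:
        return self.windows.shape[2]

    @staticmethod
    def concatenate(sets: "list[WindowSet]") -> "WindowSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        fs, ws = sets[0].fs, sets[0].window_s
        if any(s.fs != fs or s.window_s != ws for s in sets):
            raise ValueError("incompatible window geometry")
        cat = lambda parts: None if any(p is None for p in parts) else np.concatenate(parts)
        return WindowSet(
            windows=np.concatenate([s.windows for s in sets]),
            fs=fs, window_s=ws,
            labels=cat([s.labels for s in sets]),
            subject_ids=cat([s.subject_ids for s in sets]),
            window_start_s=cat([s.window_start_s for s in sets]),
        )

    # -- persistence ---------------------------------------------------------
    def save_h5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("windows", data=self.windows)
            f.attrs["fs"] = self.fs
            f.attrs["window_s"] = self.window_s
            if self.labels is not None:
                f.create_dataset("labels", data=self.labels.astype(np.int8))
            if self.subject_ids is not None:
                f.create_dataset(
                    "subject_ids", data=np.asarray(self.subject_ids, dtype="S64")
                )
            if self.window_start_s is not None:
                f.create_dataset("window_start_s", data=self.window_start_s)

    @staticmethod
    def load_h5(path: str | Path) -> "WindowSet":
        with h5py.File(path, "r") as f:
            return WindowSet(
                windows=f["windows"][...],
                fs=float(f.attrs["fs"]),
                window_s=float(f.attrs["window_s"]),
                labels=f["labels"][...] if "labels" in f else None,
                subject_ids=(
                    f["subject_ids"][...].astype("U64") if "subject_ids" in f else None
                ),
                window_start_s=(
                    f["window_start_s"][...] if "window_start_s" in f else None
                ),
            )


def read_accelerometer(path: str | Path, subject_id: str = "") -> AccelRecording:
    """Read a time/x/y/z CSV (time in ISO-8601 or seconds; axes in g).

    The sampling frequency is inferred from the median timestamp spacing.
    Rows containing non-finite values are dropped with a logged count.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("time",) + tuple(AXES) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t_raw = df["time"]
    if pd.api.types.is_numeric_dtype(t_raw):
        t_s = t_raw.to_numpy(dtype=np.float64)
        t0 = None
    else:
        stamps = pd.to_datetime(t_raw, format="ISO8601")
        t0 = stamps.iloc[0].to_pydatetime()
        t_s = (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy()
    if len(t_s) > 1 and (np.diff(t_s) <= 0).any():
        raise FormatError(f"{path}: timestamps are not strictly increasing")
    xyz = df[list(AXES)].to_numpy(dtype=np.float64)
    finite = np.isfinite(xyz).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("%s: dropped %d non-finite sample row(s)", path, n_dropped)
        xyz = xyz[finite]
        t_s = t_s[finite]
    if len(t_s) > 1:
        fs = 1.0 / float(np.median(np.diff(t_s)))
    else:
        fs = FS_TARGET
    if not 10.0 <= fs <= 500.0:
        raise ValueError(f"{path}: inferred sampling rate {fs:.2f} Hz outside [10, 500]")
    return AccelRecording(samples=xyz, fs=fs, t0=t0, subject_id=subject_id)


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read a start_s/end_s/label CSV into an annotation track."""
    df = pd.read_csv(path)
    missing = [c for c in ("start_s", "end_s") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    labels = df["label"] if "label" in df.columns else ["gait"] * len(df)
    return AnnotationTrack(
        intervals=[
            (float(s), float(e), str(lab))
            for s, e, lab in zip(df["start_s"], df["end_s"], labels)
        ]
    )


def resample_to_target(rec: AccelRecording, fs_target: float = FS_TARGET) -> AccelRecording:
    """Polyphase anti-aliased resampling to the canonical rate.

    A recording already at the target rate is returned unchanged; an empty
    recording stays empty.  Content below the gait band (< 10 Hz) is
    preserved by the FIR anti-aliasing filter.
    """
    if rec.fs == fs_target:
        return rec
    if rec.fs < fs_target / 3.0:
        raise ValueError(
            f"native rate {rec.fs} Hz too far below target {fs_target} Hz"
        )
    if rec.n_samples == 0:
        return replace(rec, samples=rec.samples.copy(), fs=fs_target)
    ratio = Fraction(fs_target / rec.fs).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    out = resample_poly(rec.samples, up, down, axis=0)
    n_target = int(round(rec.n_samples * fs_target / rec.fs))
    out = out[:n_target]
    return replace(rec, samples=out, fs=fs_target)


def segment_windows(rec: AccelRecording, window_s: float = WINDOW_S) -> WindowSet:
    """Cut a recording into non-overlapping windows; a trailing partial window
    is dropped so every window has identical length."""
    L = int(round(window_s * rec.fs))
    n_win = rec.n_samples // L
    data = rec.samples[: n_win * L].reshape(n_win, L, 3).transpose(0, 2, 1)
    starts = np.arange(n_win, dtype=np.float64) * window_s
    subjects = np.full(n_win, rec.subject_id, dtype="U64")
    return WindowSet(
        windows=data.copy(), fs=rec.fs, window_s=window_s,
        subject_ids=subjects, window_start_s=starts,
    )


def label_windows(ws: WindowSet, ann: AnnotationTrack,
                  duration_s: float | None = None) -> WindowSet:
    """Assign the binary gait label: 1 iff gait intervals cover at least half
    of the window (a tie at exactly half counts as gait)."""
    if ws.window_start_s is None:
        raise ValueError("window set lacks start offsets")
    end_of_data = (
        duration_s if duration_s is not None
        else float(ws.window_start_s[-1] + ws.window_s) if ws.n_windows else 0.0
    )
    gait = ann.gait_intervals()
    if gait.size and gait[:, 1].max() > end_of_data + 1e-9:
        logger.warning(
            "annotation extends past recording end (%.1f s); clipping", end_of_data
        )
        gait = gait.copy()
        gait[:, 1] = np.minimum(gait[:, 1], end_of_data)
        gait = gait[gait[:, 0] < gait[:, 1]]
    w0 = ws.window_start_s[:, None]
    w1 = w0 + ws.window_s
    if gait.size:
        overlap = np.clip(
            np.minimum(w1, gait[None, :, 1]) - np.maximum(w0, gait[None, :, 0]),
            0.0, None,
        ).sum(axis=1)
    else:
        overlap = np.zeros(ws.n_windows)
    labels = (overlap >= ws.window_s / 2.0 - 1e-12).astype(np.int8)
    return replace(ws, labels=labels)


class WindowStandardizer(TransformerMixin, BaseEstimator):
    """Per-axis zero-mean unit-variance whitening over a window set.

    ``scope="dataset"`` learns one mean/std per axis from the fitting windows;
    ``scope="identity"`` is a no-op pass-through (whitening is configurable
    per dataset because it does not always help the labeled data).
    """

    def __init__(self, scope: str = "dataset"):
        self.scope = scope

    def fit(self, X, y=None):
        X = self._as_array(X)
        if self.scope == "identity":
            self.mean_ = np.zeros(3)
            self.std_ = np.ones(3)
            return self
        if X.shape[0] == 0:
            raise ValueError("cannot fit standardization on an empty window set")
        self.mean_ = X.mean(axis=(0, 2))
        self.std_ = X.std(axis=(0, 2))
        for i, s in enumerate(self.std_):
            if s <= 0:
                raise ValueError(f"zero-variance axis {AXES[i]!r}")
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        ws = X if isinstance(X, WindowSet) else None
        arr = self._as_array(X)
        out = (arr - self.mean_[None, :, None]) / self.std_[None, :, None]
        if ws is not None:
            return replace(ws, windows=out)
        return out

    def inverse_transform(self, X):
        check_is_fitted(self, "mean_")
        ws = X if isinstance(X, WindowSet) else None
        arr = self._as_array(X)
        out = arr * self.std_[None, :, None] + self.mean_[None, :, None]
        if ws is not None:
            return replace(ws, windows=out)
        return out

    @staticmethod
    def _as_array(X) -> np.ndarray:
        arr = X.windows if isinstance(X, WindowSet) else np.asarray(X, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[1] != 3:
            raise ValueError("expected windows of shape (n, 3, L)")
        return arr


def compute_standardization(ws: WindowSet, scope: str = "dataset") -> WindowStandardizer:
    """Fit whitening statistics on the given (training) windows only."""
    return WindowStandardizer(scope=scope).fit(ws)


def apply_standardization(ws: WindowSet, stats: WindowStandardizer) -> WindowSet:
    return stats.transform(ws)


def preprocess_recording(rec: AccelRecording, ann: AnnotationTrack | None = None,
                         fs_target: float = FS_TARGET,
                         window_s: float = WINDOW_S) -> WindowSet:
    """Resample -> segment -> (optionally) label, in the canonical order."""
    rec30 = resample_to_target(rec, fs_target)
    ws = segment_windows(rec30, window_s)
    if ann is not None:
        ws = label_windows(ws, ann, duration_s=rec30.duration_s)
    return ws
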