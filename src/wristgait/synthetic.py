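"""Synthetic free-living wrist-accelerometer recordings with ground truth.

The generator emulates the statistical structure a wrist-worn gait detector
exploits: quasi-periodic gait bouts (step frequency with harmonics, mixed
across axes by a random sensor orientation and attenuated by arm swing),
broadband non-gait arm activity, optional 4-6 Hz tremor, a slowly drifting
gravity component, stillness, and non-wear spans of near-constant signal.
Bout intervals are recorded exactly, so every downstream stage can be
tested against programmed ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt

from .io_preprocess import AccelRecording, AnnotationTrack, WindowSet, preprocess_recording

SECONDS_PER_DAY = 86400


@dataclass
class SyntheticSubjectConfig:
    """Signal-model parameters for one simulated subject.

    Amplitudes are in g.  ``step_frequency=None`` draws the subject's cadence
    uniformly from ``step_frequency_range``.  ``daily_walking_minutes``
    overrides ``gait_fraction`` for day-scale recordings.
    """

    fs: float = 60.0
    step_frequency: float | None = None
    step_frequency_range: tuple[float, float] = (1.5, 2.2)
    arm_swing_amplitude: float = 0.25
    tremor_amplitude: float = 0.0
    tremor_band: tuple[float, float] = (4.0, 6.0)
    bout_mean_s: float = 30.0
    bout_sigma: float = 0.6
    min_bout_s: float = 5.0
    gait_fraction: float = 0.15
    daily_walking_minutes: float | None = None
    active_hours: tuple[float, float] = (7.0, 23.0)
    daily_nonwear_minutes: float = 60.0
    activity_fraction: float = 0.3
    activity_amplitude: float = 0.12
    gravity_drift_period_s: float = 300.0
    noise_sd: float = 0.02
    nonwear_noise_sd: float = 0.003
    day_jitter: float = 0.04          # relative day-to-day walking variation
    seed: int = 0

    def __post_init__(self):
        if self.arm_swing_amplitude < 0 or self.tremor_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0.0 <= self.gait_fraction <= 1.0:
            raise ValueError("gait fraction must lie in [0, 1]")
        f = self.step_frequency
        if f is not None and not 0.5 < f < 4.0:
            raise ValueError("step frequency must lie in (0.5, 4) Hz")


@dataclass
class CohortGroup:
    name: str
    mean_daily_walking_min: float
    n_subjects: int
    mobility_score: int = 0
    parkinsonian_signs: int = 0
    arm_swing_amplitude: float = 0.25
    tremor_amplitude: float = 0.0

    def __post_init__(self):
        if self.mean_daily_walking_min < 0:
            raise ValueError("group mean walking minutes must be non-negative")
        if self.n_subjects < 2:
            raise ValueError("each group needs at least 2 subjects")


@dataclass
class SyntheticCohortConfig:
    """Groups with programmed daily-walking means plus covariate model."""

    groups: list[CohortGroup] = field(default_factory=list)
    between_subject_sd_min: float = 10.0
    day_jitter: float = 0.04          # relative day-to-day variation
    days: int = 4
    fs: float = 30.0
    age_mean: float = 80.0
    age_sd: float = 7.0
    age_group_effect: float = 2.0     # years of extra age per group index
    bmi_mean: float = 27.0
    bmi_sd: float = 4.0
    female_fraction: float = 0.76


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

def _drifting_gravity(n: int, fs: float, period_s: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit gravity vector drifting as a smooth random walk on the sphere.

    The orientation is interpolated on a coarse (5-second) grid and repeated
    to the sample rate; the drift is far slower than that, so the staircase
    is well below the sensor noise floor.
    """
    grid_s = 5.0
    n_coarse = int(np.ceil(n / (fs * grid_s))) + 1
    n_knots = max(2, int(n / (fs * period_s)) + 2)
    knots = np.empty((n_knots, 3))
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    knots[0] = v
    for k in range(1, n_knots):
        v = v + 0.4 * rng.normal(size=3)
        v /= np.linalg.norm(v)
        knots[k] = v
    t_knots = np.linspace(0, n_coarse, n_knots)
    t = np.arange(n_coarse)
    g = np.empty((n_coarse, 3), dtype=np.float32)
    for a in range(3):
        g[:, a] = np.interp(t, t_knots, knots[:, a])
    g /= np.maximum(np.linalg.norm(g, axis=1, keepdims=True), 1e-9)
    return np.repeat(g, int(round(fs * grid_s)), axis=0)[:n]


def _gait_bout(n: int, fs: float, f0: float, amplitude: float,
               rng: np.random.Generator) -> np.ndarray:
    """One walking bout: harmonic arm-swing oscillation mixed across axes."""
    t = np.arange(n, dtype=np.float64) / fs
    phases = rng.uniform(0, 2 * np.pi, size=3)
    weights = (1.0, 0.4, 0.15)
    nyq_guard = 0.45 * fs          # harmonics above this are filtered out by
    comp = np.stack([              # any real device's anti-aliasing stage
        w * np.sin(2 * np.pi * k * f0 * t + ph) if k * f0 < nyq_guard
        else np.zeros_like(t)
        for k, (w, ph) in enumerate(zip(weights, phases), start=1)
    ])                             # (3, n) harmonic components
    # slow amplitude modulation keeps bouts from being pure tones
    env = 1.0 + 0.15 * np.sin(2 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))
    mix = _random_rotation(rng)
    return (amplitude * (mix @ comp) * env).T.astype(np.float32)   # (n, 3)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    theta = rng.uniform(0, 2 * np.pi)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _activity_noise(n: int, fs: float, amplitude: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Broadband smooth arm movement: low-passed white noise, all axes."""
    if n == 0:
        return np.empty((0, 3), dtype=np.float32)
    cutoff = min(8.0, 0.45 * fs)
    sos = butter(2, cutoff, fs=fs, output="sos")
    x = rng.standard_normal((n, 3), dtype=np.float32)
    y = sosfilt(sos, x, axis=0).astype(np.float32)
    # renormalize to the requested RMS amplitude
    rms = max(float(y.std()), 1e-9)
    return (amplitude / rms) * y


def _place_bouts(active_start: float, active_end: float, target_gait_s: float,
                 cfg: SyntheticSubjectConfig, rng: np.random.Generator
                 ) -> list[tuple[float, float]]:
    """Sample non-overlapping bout intervals summing to ~target_gait_s."""
    span = active_end - active_start
    target = min(target_gait_s, 0.9 * span)
    if target < cfg.min_bout_s:
        return []
    mu = np.log(cfg.bout_mean_s) - cfg.bout_sigma ** 2 / 2.0
    durations: list[float] = []
    total = 0.0
    while total < target:
        d = float(rng.lognormal(mu, cfg.bout_sigma))
        d = max(cfg.min_bout_s, min(d, 300.0))
        if total + d > target:
            d = target - total
            if d < cfg.min_bout_s:
                break
        durations.append(d)
        total += d
    if not durations:
        return []
    free = span - total
    gaps = rng.exponential(1.0, size=len(durations) + 1)
    gaps *= free / gaps.sum()
    bouts = []
    cursor = active_start
    for d, gap in zip(durations, gaps[:-1]):
        cursor += gap
        bouts.append((cursor, cursor + d))
        cursor += d
    return bouts


# ---------------------------------------------------------------------------
# subject-level generation
# ---------------------------------------------------------------------------

def generate_subject(cfg: SyntheticSubjectConfig, days: int = 1,
                     subject_id: str = "synthetic",
                     start: datetime = datetime(2000, 1, 1)
                     ) -> tuple[AccelRecording, AnnotationTrack, dict]:
    """Simulate ``days`` full free-living days starting at midnight.

    Returns the recording, exact gait-bout annotations, and a metadata dict
    including the programmed per-day gait minutes (the recovery target for
    the daily-living stage).
    """
    if days < 1:
        raise ValueError("days must be at least 1")
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(days * SECONDS_PER_DAY * fs))
    f0 = cfg.step_frequency or float(rng.uniform(*cfg.step_frequency_range))

    sig = _drifting_gravity(n, fs, cfg.gravity_drift_period_s, rng)
    noise = rng.standard_normal((n, 3), dtype=np.float32)
    noise *= np.float32(cfg.noise_sd)
    sig += noise
    del noise

    a0, a1 = cfg.active_hours
    gait_intervals: list[tuple[float, float]] = []
    per_day_gait_s: list[float] = []
    for day in range(days):
        day_off = day * SECONDS_PER_DAY
        act_start = day_off + a0 * 3600.0
        act_end = day_off + a1 * 3600.0
        active_s = act_end - act_start
        if cfg.daily_walking_minutes is not None:
            target = cfg.daily_walking_minutes * 60.0
        else:
            target = cfg.gait_fraction * active_s
        target *= 1.0 + rng.uniform(-cfg.day_jitter, cfg.day_jitter)
        bouts = _place_bouts(act_start, act_end, target, cfg, rng)
        day_gait = 0.0
        for b0, b1 in bouts:
            i0, i1 = int(round(b0 * fs)), int(round(b1 * fs))
            sig[i0:i1] += _gait_bout(i1 - i0, fs, f0, cfg.arm_swing_amplitude, rng)
            gait_intervals.append((b0, b1))
            day_gait += b1 - b0
        per_day_gait_s.append(day_gait)

        # broadband non-gait arm activity in the inter-bout gaps
        gap_edges = [act_start] + [e for b in bouts for e in b] + [act_end]
        act_total = int(cfg.activity_fraction * active_s * fs)
        act_stream = _activity_noise(act_total, fs, cfg.activity_amplitude, rng)
        cursor = 0
        for g0, g1 in zip(gap_edges[::2], gap_edges[1::2]):
            gap = g1 - g0
            if gap < 2.0 or cursor >= act_total:
                continue
            seg = int(min(cfg.activity_fraction * gap * fs, act_total - cursor))
            off = rng.uniform(0, gap - seg / fs)
            i0 = int(round((g0 + off) * fs))
            sig[i0:i0 + seg] += act_stream[cursor:cursor + seg]
            cursor += seg

        if cfg.tremor_amplitude > 0:
            f_tr = float(rng.uniform(*cfg.tremor_band))
            i0, i1 = int(round(act_start * fs)), int(round(act_end * fs))
            t = np.arange(i1 - i0) / fs
            tremor = cfg.tremor_amplitude * np.sin(
                2 * np.pi * f_tr * t + rng.uniform(0, 2 * np.pi)
            ).astype(np.float32)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            sig[i0:i1] += tremor[:, None] * direction.astype(np.float32)

        # non-wear span placed in the night hours (no bout collisions there)
        if cfg.daily_nonwear_minutes > 0:
            dur = min(cfg.daily_nonwear_minutes * 60.0, (a0 - 1.0) * 3600)
            nw0 = day_off + rng.uniform(0.5 * 3600, a0 * 3600 - dur - 600)
            i0, i1 = int(round(nw0 * fs)), int(round((nw0 + dur) * fs))
            g_vec = sig[i0] / max(np.linalg.norm(sig[i0]), 1e-9)
            nw = rng.standard_normal((i1 - i0, 3), dtype=np.float32)
            nw *= np.float32(cfg.nonwear_noise_sd)
            nw += g_vec[None, :].astype(np.float32)
            sig[i0:i1] = nw

    rec = AccelRecording(samples=sig, fs=fs, t0=start, subject_id=subject_id)
    ann = AnnotationTrack(intervals=[(s, e, "gait") for s, e in gait_intervals])
    meta = {
        "subject_id": subject_id,
        "step_frequency": f0,
        "per_day_gait_minutes": [s / 60.0 for s in per_day_gait_s],
        "true_daily_walking_min": float(np.median([s / 60.0 for s in per_day_gait_s])),
    }
    return rec, ann, meta


def generate_active_recording(cfg: SyntheticSubjectConfig, duration_s: float,
                              subject_id: str = "synthetic"
                              ) -> tuple[AccelRecording, AnnotationTrack, dict]:
    """Short always-worn, always-active recording for labeled fixtures.

    Gait bouts cover ``gait_fraction`` of the whole duration; the rest is
    stillness and broadband activity.  Used to emulate the supervised
    recording sessions that provide fine-tuning labels.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(duration_s * fs))
    f0 = cfg.step_frequency or float(rng.uniform(*cfg.step_frequency_range))
    sig = _drifting_gravity(n, fs, cfg.gravity_drift_period_s, rng)
    noise = rng.standard_normal((n, 3), dtype=np.float32)
    noise *= np.float32(cfg.noise_sd)
    sig += noise
    del noise
    target = cfg.gait_fraction * duration_s
    bouts = _place_bouts(0.0, duration_s, target, cfg, rng)
    for b0, b1 in bouts:
        i0, i1 = int(round(b0 * fs)), int(round(b1 * fs))
        sig[i0:i1] += _gait_bout(i1 - i0, fs, f0, cfg.arm_swing_amplitude, rng)
    gap_edges = [0.0] + [e for b in bouts for e in b] + [duration_s]
    act_total = int(cfg.activity_fraction * duration_s * fs)
    act_stream = _activity_noise(act_total, fs, cfg.activity_amplitude, rng)
    cursor = 0
    for g0, g1 in zip(gap_edges[::2], gap_edges[1::2]):
        gap = g1 - g0
        if gap < 2.0 or cursor >= act_total:
            continue
        seg = int(min(cfg.activity_fraction * gap * fs, act_total - cursor))
        off = rng.uniform(0, gap - seg / fs)
        i0 = int(round((g0 + off) * fs))
        sig[i0:i0 + seg] += act_stream[cursor:cursor + seg]
        cursor += seg
    if cfg.tremor_amplitude > 0:
        f_tr = float(rng.uniform(*cfg.tremor_band))
        t = np.arange(n) / fs
        tremor = cfg.tremor_amplitude * np.sin(
            2 * np.pi * f_tr * t + rng.uniform(0, 2 * np.pi)).astype(np.float32)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        sig += tremor[:, None] * direction.astype(np.float32)
    rec = AccelRecording(samples=sig, fs=fs, t0=None, subject_id=subject_id)
    ann = AnnotationTrack(intervals=[(s, e, "gait") for s, e in bouts])
    gait_s = sum(e - s for s, e in bouts)
    meta = {"subject_id": subject_id, "step_frequency": f0,
            "gait_fraction_actual": gait_s / duration_s}
    return rec, ann, meta


def make_labeled_windows(rec: AccelRecording, ann: AnnotationTrack,
                         fs_target: float = 30.0, window_s: float = 10.0
                         ) -> WindowSet:
    """End-to-end fixture: resample -> segment -> half-or-more labeling."""
    return preprocess_recording(rec, ann, fs_target=fs_target, window_s=window_s)


def generate_labeled_cohort_windows(n_subjects: int, duration_s: float = 600.0,
                                    base_cfg: SyntheticSubjectConfig | None = None,
                                    seed: int = 0, fs_target: float = 30.0
                                    ) -> WindowSet:
    """Labeled windows pooled over ``n_subjects`` short recordings."""
    base = base_cfg or SyntheticSubjectConfig()
    sets = []
    for i in range(n_subjects):
        cfg = replace(base, seed=seed * 10000 + i)
        rec, ann, _ = generate_active_recording(cfg, duration_s, subject_id=f"s{seed}_{i:03d}")
        sets.append(make_labeled_windows(rec, ann, fs_target=fs_target))
    return WindowSet.concatenate(sets)


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------

def generate_cohort(cfg: SyntheticCohortConfig, seed: int = 0
                    ) -> tuple[list[tuple[SyntheticSubjectConfig, dict]], pd.DataFrame]:
    """Draw subject configurations and metadata for a programmed cohort.

    Signal realization is deferred (call :func:`generate_subject` on each
    returned config) so day-scale cohorts can be processed one subject at a
    time.  The returned table carries the ground-truth daily walking minutes
    for recovery tests.
    """
    if not cfg.groups:
        raise ValueError("cohort has no groups")
    rng = np.random.default_rng(seed)
    specs: list[tuple[SyntheticSubjectConfig, dict]] = []
    rows = []
    for gi, group in enumerate(cfg.groups):
        for si in range(group.n_subjects):
            sid = f"{group.name}_{si:03d}"
            walking = max(5.0, rng.normal(group.mean_daily_walking_min,
                                          cfg.between_subject_sd_min))
            age = rng.normal(cfg.age_mean + cfg.age_group_effect * gi, cfg.age_sd)
            sex = int(rng.random() < cfg.female_fraction)      # 1 = female
            bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd)
            sub_cfg = SyntheticSubjectConfig(
                fs=cfg.fs,
                daily_walking_minutes=walking,
                arm_swing_amplitude=group.arm_swing_amplitude,
                tremor_amplitude=group.tremor_amplitude,
                day_jitter=cfg.day_jitter,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            meta = {
                "subject_id": sid, "group": group.name,
                "mobility_score": group.mobility_score,
                "parkinsonian_signs": group.parkinsonian_signs,
                "age": float(age), "sex": sex, "bmi": float(bmi),
                "true_daily_walking_min": float(walking),
                "days": cfg.days,
            }
            specs.append((sub_cfg, meta))
            rows.append(meta)
    return specs, pd.DataFrame(rows).set_index("subject_id")
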