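"""Pretext augmentations for self-supervised training.

Four transforms make up the multi-task pretext (reverse, segment
permutation, time warp, per-axis scaling); a uniform random 3-D rotation
provides the contrastive view generator.  Every transform maps a (3, L)
window to a (3, L) window and is deterministic given its generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

FLAG_ORDER = ("reversed", "permuted", "time_warped", "scaled")


@dataclass(frozen=True)
class AugmentationFlags:
    """Which of the four pretext transforms were applied, in fixed order."""

    reversed: int = 0
    permuted: int = 0
    time_warped: int = 0
    scaled: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FLAG_ORDER], dtype=np.float64)


@dataclass
class AugmentationPolicy:
    """Per-transform application probability and transform parameters.

    ``p_apply=0.5`` gives the pretext classifier maximum label entropy.
    Warp strength and scale bounds are mild so augmented windows stay
    plausible wrist signals.
    """

    p_apply: float = 0.5
    permutation_segment_len: int = 10
    warp_knots: int = 4
    warp_max_stretch: float = 1.5
    scale_low: float = 0.7
    scale_high: float = 1.4

    def __post_init__(self):
        if not 0.0 <= self.p_apply <= 1.0:
            raise ValueError("p_apply must lie in [0, 1]")
        if self.permutation_segment_len < 1:
            raise ValueError("segment length must be positive")
        if self.warp_max_stretch <= 1.0:
            raise ValueError("warp_max_stretch must exceed 1")
        if not 0 < self.scale_low <= self.scale_high:
            raise ValueError("invalid scale bounds")


def _check_window(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=np.float64)
    if w.ndim != 2 or w.shape[0] != 3:
        raise ValueError("window must have shape (3, L)")
    return w


def reverse_signal(w: np.ndarray) -> np.ndarray:
    """Reverse the sample order of all three axes simultaneously."""
    return _check_window(w)[:, ::-1].copy()


def permute_segments(w: np.ndarray, segment_len: int = 10,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Shuffle consecutive fixed-length segments, identically on every axis.

    A trailing remainder shorter than ``segment_len`` is kept as a final
    short segment and shuffled with the rest.  Windows shorter than two
    segments are returned unchanged with a warning.
    """
    w = _check_window(w)
    rng = rng or np.random.default_rng()
    L = w.shape[1]
    if L < 2 * segment_len:
        warnings.warn("window too short to permute; returning input unchanged")
        return w.copy()
    bounds = np.arange(0, L, segment_len)
    segments = [w[:, b:b + segment_len] for b in bounds]
    order = rng.permutation(len(segments))
    return np.concatenate([segments[i] for i in order], axis=1)


def time_warp(w: np.ndarray, rng: np.random.Generator | None = None,
              policy: AugmentationPolicy | None = None,
              slopes: np.ndarray | None = None) -> np.ndarray:
    """Stretch and compress portions of the signal via a piecewise-linear time map.

    Interior knots split [0, L-1] into equal source segments whose slopes are
    drawn log-uniformly in [1/max_stretch, max_stretch]; the warped signal is
    linearly re-interpolated back to length L with fixed endpoints.  Explicit
    ``slopes`` (one per piece) override the random draw, e.g. all-ones gives
    the identity warp.
    """
    w = _check_window(w)
    rng = rng or np.random.default_rng()
    policy = policy or AugmentationPolicy()
    L = w.shape[1]
    k = policy.warp_knots + 1                      # number of linear pieces
    if slopes is None:
        slopes = np.exp(rng.uniform(np.log(1.0 / policy.warp_max_stretch),
                                    np.log(policy.warp_max_stretch), size=k))
    else:
        slopes = np.asarray(slopes, dtype=np.float64)
        if slopes.shape != (k,) or (slopes <= 0).any():
            raise ValueError(f"need {k} positive slopes")
    seg = np.full(k, (L - 1) / k)
    # cumulative warped time at the knots, rescaled so endpoints are fixed
    knots_src = np.concatenate([[0.0], np.cumsum(seg)])
    knots_dst = np.concatenate([[0.0], np.cumsum(seg * slopes)])
    knots_dst *= (L - 1) / knots_dst[-1]
    t_out = np.arange(L, dtype=np.float64)
    # invert the (strictly increasing) map: where do output samples fall in source time
    t_src = np.interp(t_out, knots_dst, knots_src)
    out = np.empty_like(w)
    for a in range(3):
        out[a] = np.interp(t_src, t_out, w[a])
    return out


def axis_scale(w: np.ndarray, rng: np.random.Generator | None = None,
               policy: AugmentationPolicy | None = None) -> np.ndarray:
    """Multiply each axis by an independent log-uniform random factor."""
    w = _check_window(w)
    rng = rng or np.random.default_rng()
    policy = policy or AugmentationPolicy()
    factors = np.exp(rng.uniform(np.log(policy.scale_low),
                                 np.log(policy.scale_high), size=3))
    return w * factors[:, None]


def apply_mtl(w: np.ndarray, policy: AugmentationPolicy | None = None,
              rng: np.random.Generator | None = None
              ) -> tuple[np.ndarray, AugmentationFlags]:
    """Apply each pretext transform independently with probability ``p_apply``
    in the fixed order reverse -> permute -> warp -> scale, recording flags."""
    w = _check_window(w)
    rng = rng or np.random.default_rng()
    policy = policy or AugmentationPolicy()
    draws = rng.random(4) < policy.p_apply
    out = w
    if draws[0]:
        out = reverse_signal(out)
    if draws[1]:
        out = permute_segments(out, policy.permutation_segment_len, rng)
    if draws[2]:
        out = time_warp(out, rng, policy)
    if draws[3]:
        out = axis_scale(out, rng, policy)
    flags = AugmentationFlags(*(int(d) for d in draws))
    return (out.copy() if out is w else out), flags


def random_rotation_matrix(rng: np.random.Generator,
                           max_angle: float = 2.0 * np.pi) -> np.ndarray:
    """Rotation about an axis uniform on the unit sphere by an angle uniform
    on [0, max_angle), via the Rodrigues formula."""
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    theta = rng.uniform(0.0, max_angle)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def random_rotation(w: np.ndarray, rng: np.random.Generator | None = None,
                    max_angle: float = 2.0 * np.pi) -> np.ndarray:
    """Apply one random 3-D rotation to every sample of the window, emulating
    a change of sensor orientation on the wrist."""
    w = _check_window(w)
    rng = rng or np.random.default_rng()
    R = random_rotation_matrix(rng, max_angle)
    return R @ w


def augment_batch_mtl(windows: np.ndarray, policy: AugmentationPolicy,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized convenience: augment a (n, 3, L) batch, returning the
    augmented batch and the (n, 4) flag matrix."""
    out = np.empty_like(windows)
    flags = np.empty((windows.shape[0], 4))
    for i, w in enumerate(windows):
        aug, fl = apply_mtl(w, policy, rng)
        out[i] = aug
        flags[i] = fl.as_array()
    return out, flags


def rotation_views(windows: np.ndarray, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Two independently rotated views of each window (the contrastive pair)."""
    view_a = np.empty_like(windows)
    view_b = np.empty_like(windows)
    for i, w in enumerate(windows):
        view_a[i] = random_rotation(w, rng)
        view_b[i] = random_rotation(w, rng)
    return view_a, view_b
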