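"""Training losses: averaged multi-task BCE and the NT-Xent contrastive loss."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, logsumexp

_NEG_INF = -1e9


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from raw logits: softplus(z) - z*y, stably."""
    t = Tensor(np.asarray(targets, dtype=np.float64))
    per_elem = logits.softplus() - logits * t
    return per_elem.mean()

def mtl_loss(logits: Tensor | np.ndarray, flags: np.ndarray) -> Tensor:
    """Averaged four-way augmentation-prediction loss.

    ``logits`` has one column per pretext task (reverse, permute, warp, scale);
    each column's binary cross-entropy is computed against its flag column and
    the four losses are averaged into one scalar.
    """
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    flags = np.asarray(flags, dtype=np.float64)
    if logits.data.shape != flags.shape:
        raise ValueError(f"shape mismatch: logits {logits.data.shape}, flags {flags.shape}")
    if flags.size and not np.isin(flags, (0.0, 1.0)).all():
        raise ValueError("augmentation flags must be binary")
    # Mean over tasks of (mean over batch) == mean over all entries.
    per_elem = logits.softplus() - logits * Tensor(flags)
    return per_elem.mean()


def ntxent_loss(embeddings: Tensor | np.ndarray, pairing: np.ndarray,
                temperature: float = 0.1) -> Tensor:
    """Normalized temperature-scaled cross-entropy over a batch of 2N views.

    ``pairing[i]`` is the index of view i's positive partner.  For each view,
    cosine similarities to every other view are scaled by ``temperature`` and
    the positive is scored against all 2N-1 non-self views; the loss is the
    mean over views.
    """
    if not isinstance(embeddings, Tensor):
        embeddings = Tensor(embeddings)
    pairing = np.asarray(pairing, dtype=np.intp)
    n_views = embeddings.data.shape[0]
    if n_views < 4:
        raise ValueError("need at least 4 views (2 source windows)")
    if pairing.shape != (n_views,) or (pairing[pairing] != np.arange(n_views)).any():
        raise ValueError("pairing must be an involution mapping each view to its positive")
    if (pairing == np.arange(n_views)).any():
        raise ValueError("a view cannot be its own positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    norms_sq = (embeddings.data ** 2).sum(axis=1)
    if (norms_sq < 1e-24).any():
        raise ValueError("zero-norm embedding: cosine similarity undefined")

    unit = embeddings * ((embeddings * embeddings).sum(axis=1, keepdims=True) ** -0.5)
    sim = (unit @ unit.transpose(1, 0)) * (1.0 / temperature)
    sim = sim + Tensor(np.eye(n_views) * _NEG_INF)      # exclude self-similarity
    rows = np.arange(n_views)
    pos = sim[rows, pairing]
    return (logsumexp(sim, axis=1) - pos).mean()


def simclr_pairing(n_windows: int) -> np.ndarray:
    """Pairing for views stacked as [view_a(0..N-1), view_b(0..N-1)]."""
    return np.concatenate([np.arange(n_windows) + n_windows, np.arange(n_windows)])
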