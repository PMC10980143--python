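"""Self-supervised pretraining: encoder construction, pretext losses, trainers.

Two pretext tasks are provided.  The multi-task (MTL) pretext augments each
window and asks a four-way binary head which transforms were applied; the
contrastive (SimCLR) pretext builds two rotated views per window and pulls
positive pairs together under the NT-Xent loss.  Both produce an encoder
whose weights seed the supervised gait fine-tuning stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .augment import AugmentationPolicy, augment_batch_mtl, rotation_views
from .io_preprocess import WindowSet
from .nn import (
    Adam,
    MLPHead,
    ResNetEncoder1d,
    Tensor,
    mtl_loss,
    ntxent_loss,
    simclr_pairing,
)

N_PRETEXT_TASKS = 4


@dataclass(frozen=True)
class EncoderConfig:
    """Geometry of the 1-D residual encoder.

    ``desk`` is the small CPU-friendly geometry used throughout the tests
    (4 residual blocks, 64-d embedding); ``full`` approximates the 18-layer
    ResNet-V2 geometry with a 1024-d embedding.
    """

    channels: tuple[int, ...] = (8, 16, 32, 64)
    strides: tuple[int, ...] = (2, 2, 2, 2)
    feature_dim: int = 64
    input_length: int = 300
    stem_kernel: int = 5
    stem_stride: int = 2

    def __post_init__(self):
        if self.feature_dim < 8:
            raise ValueError("feature_dim must be at least 8")
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")

    @staticmethod
    def desk(input_length: int = 300, feature_dim: int = 64) -> "EncoderConfig":
        return EncoderConfig(input_length=input_length, feature_dim=feature_dim)

    @staticmethod
    def full(input_length: int = 300) -> "EncoderConfig":
        return EncoderConfig(
            channels=(64, 64, 128, 128, 256, 256, 512, 512),
            strides=(1, 2, 1, 2, 1, 2, 1, 2),
            feature_dim=1024,
            input_length=input_length,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class ModelState:
    """Weights plus provenance for an encoder (and optionally a head)."""

    encoder_config: EncoderConfig
    encoder_state: dict[str, np.ndarray]
    head_state: dict[str, np.ndarray] | None = None
    frozen_encoder: bool = False
    provenance: dict = field(default_factory=dict)

    def save(self, path) -> None:
        meta = json.dumps({
            "encoder_config": asdict(self.encoder_config),
            "frozen_encoder": self.frozen_encoder,
            "provenance": self.provenance,
        })
        arrays = {f"enc:{k}": v for k, v in self.encoder_state.items()}
        if self.head_state is not None:
            arrays.update({f"head:{k}": v for k, v in self.head_state.items()})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @staticmethod
    def load(path) -> "ModelState":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            enc = {k[4:]: z[k] for k in z.files if k.startswith("enc:")}
            head = {k[5:]: z[k] for k in z.files if k.startswith("head:")}
        return ModelState(
            encoder_config=EncoderConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in meta["encoder_config"].items()
            }),
            encoder_state=enc,
            head_state=head or None,
            frozen_encoder=meta["frozen_encoder"],
            provenance=meta["provenance"],
        )


def build_encoder(cfg: EncoderConfig, seed: int = 0) -> ResNetEncoder1d:
    """Deterministically initialized residual encoder for (3, L) windows."""
    rng = np.random.default_rng(seed)
    return ResNetEncoder1d(
        in_channels=3,
        channels=list(cfg.channels),
        strides=list(cfg.strides),
        feature_dim=cfg.feature_dim,
        input_length=cfg.input_length,
        stem_kernel=cfg.stem_kernel,
        stem_stride=cfg.stem_stride,
        rng=rng,
    )


def parameter_count(module) -> int:
    return int(sum(p.data.size for p in module.parameters()))


def _as_windows(X) -> np.ndarray:
    arr = X.windows if isinstance(X, WindowSet) else np.asarray(X, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[1] != 3:
        raise ValueError("expected windows of shape (n, 3, L)")
    return arr


def _freeze(module, frozen: bool) -> None:
    for p in module.parameters():
        p.requires_grad = not frozen


class _BasePretrainer(TransformerMixin, BaseEstimator):
    """Shared fit/transform machinery for the two pretext estimators."""

    def __init__(self, encoder_config=None, n_epochs=20, batch_size=64, lr=1e-3,
                 freeze_encoder=False, encoder_init=None, random_state=0):
        self.encoder_config = encoder_config
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.lr = lr
        self.freeze_encoder = freeze_encoder
        self.encoder_init = encoder_init
        self.random_state = random_state

    # subclasses: build heads, compute one batch loss
    def _build_head(self, cfg, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    def _batch_loss(self, batch, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y=None):
        arr = _as_windows(X)
        if arr.shape[0] == 0:
            raise ValueError("cannot pretrain on an empty window set")
        cfg = self.encoder_config or EncoderConfig.desk(input_length=arr.shape[2])
        seed = int(self.random_state)
        rng = np.random.default_rng(seed)
        self.encoder_ = build_encoder(cfg, seed=seed)
        if self.encoder_init is not None:
            self.encoder_.load_state_dict(self.encoder_init)
        self.head_ = self._build_head(cfg, np.random.default_rng(seed + 1))
        if self.freeze_encoder:
            _freeze(self.encoder_, True)
            self.encoder_.eval()      # also freezes running statistics
        params = self.encoder_.parameters() + self.head_.parameters()
        opt = Adam(params, lr=self.lr)
        n = arr.shape[0]
        self.loss_history_ = []
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for lo in range(0, n, self.batch_size):
                batch = arr[order[lo:lo + self.batch_size]]
                if batch.shape[0] < 2:
                    continue
                opt.zero_grad()
                loss = self._batch_loss(batch, rng)
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            self.loss_history_.append(epoch_loss / max(n_batches, 1))
        self.encoder_config_ = cfg
        self.model_state_ = ModelState(
            encoder_config=cfg,
            encoder_state=self.encoder_.state_dict(),
            head_state=self.head_.state_dict(),
            frozen_encoder=self.freeze_encoder,
            provenance={
                "pretext": self._pretext_name,
                "seed": seed,
                "config_hash": cfg.config_hash(),
            },
        )
        return self

    def transform(self, X) -> np.ndarray:
        """Embed windows with the trained encoder (eval mode, batched)."""
        check_is_fitted(self, "encoder_")
        arr = _as_windows(X)
        self.encoder_.eval()
        out = []
        for lo in range(0, arr.shape[0], 256):
            out.append(self.encoder_(Tensor(arr[lo:lo + 256])).data)
        return np.concatenate(out) if out else np.empty((0, self.encoder_config_.feature_dim))

    def score_batch(self, X, rng_seed: int = 0) -> float:
        """Pretext loss of the current model on held-out windows."""
        check_is_fitted(self, "encoder_")
        arr = _as_windows(X)
        self.encoder_.eval()
        self.head_.eval()
        loss = self._batch_loss(arr, np.random.default_rng(rng_seed))
        self.head_.train()
        if not self.freeze_encoder:
            self.encoder_.train()
        return float(loss.data)


class MTLPretrainer(_BasePretrainer):
    """Multi-task augmentation-prediction pretext.

    Each window is independently reversed / permuted / time-warped / scaled
    with probability ``policy.p_apply``; a four-logit head predicts which
    transforms were applied and the four binary cross-entropies are averaged.
    """

    _pretext_name = "mtl"

    def __init__(self, encoder_config=None, policy=None, head_nonlinear=False,
                 n_epochs=20, batch_size=64, lr=1e-3, freeze_encoder=False,
                 encoder_init=None, random_state=0):
        super().__init__(encoder_config, n_epochs, batch_size, lr,
                         freeze_encoder, encoder_init, random_state)
        self.policy = policy
        self.head_nonlinear = head_nonlinear

    def _build_head(self, cfg, rng):
        return MLPHead(cfg.feature_dim, N_PRETEXT_TASKS,
                       nonlinear=self.head_nonlinear, rng=rng)

    def _batch_loss(self, batch, rng):
        policy = self.policy or AugmentationPolicy()
        aug, flags = augment_batch_mtl(batch, policy, rng)
        logits = self.head_(self.encoder_(Tensor(aug)))
        return mtl_loss(logits, flags)


class SimCLRPretrainer(_BasePretrainer):
    """Contrastive pretext with rotation views and the NT-Xent loss.

    Each window yields two independently rotated views; a batch of N windows
    becomes 2N views whose only positive pair is the sibling view.
    """

    _pretext_name = "simclr"

    def __init__(self, encoder_config=None, projection_dim=32, temperature=0.1,
                 n_epochs=20, batch_size=64, lr=1e-3, freeze_encoder=False,
                 encoder_init=None, random_state=0):
        super().__init__(encoder_config, n_epochs, batch_size, lr,
                         freeze_encoder, encoder_init, random_state)
        self.projection_dim = projection_dim
        self.temperature = temperature

    def _build_head(self, cfg, rng):
        return MLPHead(cfg.feature_dim, self.projection_dim, nonlinear=True, rng=rng)

    def _batch_loss(self, batch, rng):
        view_a, view_b = rotation_views(batch, rng)
        stacked = np.concatenate([view_a, view_b])
        z = self.head_(self.encoder_(Tensor(stacked)))
        return ntxent_loss(z, simclr_pairing(batch.shape[0]), self.temperature)


def pretrain_mtl(dataset, encoder_config=None, policy=None, seed: int = 0,
                 **kwargs) -> ModelState:
    """Train the MTL pretext and return the resulting model state."""
    est = MTLPretrainer(encoder_config=encoder_config, policy=policy,
                        random_state=seed, **kwargs)
    est.fit(dataset)
    return est.model_state_


def pretrain_simclr(dataset, encoder_config=None, seed: int = 0,
                    **kwargs) -> ModelState:
    """Train the SimCLR pretext and return the resulting model state."""
    est = SimCLRPretrainer(encoder_config=encoder_config, random_state=seed,
                           **kwargs)
    est.fit(dataset)
    return est.model_state_
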