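"""Supervised gait-detection fine-tuning.

Subject-wise data splitting (no window of a subject ever crosses a
subdivision boundary), grouped stratified cross-validation, early-stopped
full-weight training of the pretrained encoder with a linear binary head,
and per-window prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .augment import random_rotation_matrix
from .io_preprocess import WindowSet
from .nn import Adam, LinearHead, Tensor, bce_with_logits
from .ssl_core import EncoderConfig, ModelState, build_encoder


@dataclass
class SplitPlan:
    """Subject-level train/test split plus optional per-seed fold layouts."""

    train_subjects: list[str]
    test_subjects: list[str]
    folds: dict[int, list[list[str]]] = field(default_factory=dict)  # seed -> k lists
    k: int = 5
    seeds: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self):
        overlap = set(self.train_subjects) & set(self.test_subjects)
        if overlap:
            raise ValueError(f"subjects shared between train and test: {sorted(overlap)}")

    def validate_folds(self) -> None:
        for seed, folds in self.folds.items():
            flat = [s for fold in folds for s in fold]
            if sorted(flat) != sorted(self.train_subjects):
                raise ValueError(f"folds for seed {seed} do not partition the train subjects")


def split_subjects(subject_ids, test_fraction: float = 0.25, seed: int = 0,
                   cohorts: dict[str, str] | None = None,
                   min_per_cohort: int = 3) -> SplitPlan:
    """Random subject-level split honoring ``test_fraction``.

    With a ``cohorts`` mapping (subject -> cohort name), every cohort is
    guaranteed at least ``min_per_cohort`` subjects in the test set; cohorts
    too small to satisfy that are reported in the raised error.
    """
    subjects = sorted(set(str(s) for s in subject_ids))
    if len(subjects) < 4:
        raise ValueError("need at least 4 subjects to split")
    rng = np.random.default_rng(seed)
    if cohorts is None:
        n_test = int(round(test_fraction * len(subjects)))
        n_test = min(max(n_test, 1), len(subjects) - 1)
        perm = rng.permutation(len(subjects))
        test = sorted(subjects[i] for i in perm[:n_test])
    else:
        by_cohort: dict[str, list[str]] = {}
        for s in subjects:
            by_cohort.setdefault(cohorts.get(s, "default"), []).append(s)
        bad = [c for c, mem in by_cohort.items() if len(mem) < min_per_cohort + 1]
        if bad:
            raise ValueError(
                f"cohort constraint unsatisfiable (need {min_per_cohort} test + 1 train) "
                f"for cohorts: {sorted(bad)}"
            )
        test = []
        for c in sorted(by_cohort):
            members = by_cohort[c]
            n_c = max(min_per_cohort, int(round(test_fraction * len(members))))
            n_c = min(n_c, len(members) - 1)
            perm = rng.permutation(len(members))
            test.extend(members[i] for i in perm[:n_c])
        test = sorted(test)
    train = sorted(set(subjects) - set(test))
    return SplitPlan(train_subjects=train, test_subjects=test)


def make_folds(train_subjects, subject_prevalence: dict[str, float],
               k: int = 5, seed: int = 0) -> list[list[str]]:
    """Grouped stratified folds over subjects.

    Subjects are ordered by their gait-window prevalence, cut into quantile
    bins of size ``k``, and each bin is dealt randomly across the folds, so
    every fold sees a similar prevalence spectrum while each subject's
    windows stay within one fold.
    """
    subjects = sorted(set(str(s) for s in train_subjects))
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(subjects):
        raise ValueError(f"cannot make {k} folds from {len(subjects)} subjects")
    rng = np.random.default_rng(seed)
    jitter = rng.random(len(subjects))  # random tie-break within equal prevalence
    order = sorted(
        range(len(subjects)),
        key=lambda i: (subject_prevalence.get(subjects[i], 0.0), jitter[i]),
    )
    folds: list[list[str]] = [[] for _ in range(k)]
    for lo in range(0, len(subjects), k):
        bin_idx = order[lo:lo + k]
        deal = rng.permutation(k)[: len(bin_idx)]
        for f, i in zip(deal, bin_idx):
            folds[f].append(subjects[i])
    return [sorted(f) for f in folds]


def subject_gait_prevalence(ws: WindowSet) -> dict[str, float]:
    """Fraction of gait-labeled windows per subject."""
    if ws.labels is None or ws.subject_ids is None:
        raise ValueError("labeled windows with subject ids required")
    out: dict[str, float] = {}
    for s in np.unique(ws.subject_ids):
        mask = ws.subject_ids == s
        out[str(s)] = float(ws.labels[mask].mean())
    return out


class EarlyStopper:
    """Stop when the validation loss has not reached a new minimum for
    ``patience`` consecutive epochs; remembers the best epoch."""

    def __init__(self, patience: int = 5):
        if patience < 1:
            raise ValueError("patience must be at least 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch: int | None = None
        self.epochs_since_best = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record one epoch; return True when training should stop."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.epochs_since_best = 0
        else:
            self.epochs_since_best += 1
        return self.epochs_since_best >= self.patience


class GaitWindowClassifier(ClassifierMixin, BaseEstimator):
    """Per-window gait/non-gait classifier: residual encoder + linear head.

    All weights are trainable during fitting (no freezing); training
    minimizes binary cross-entropy and early-stops on the validation loss,
    restoring the best-epoch weights.  ``init_state`` accepts a pretrained
    :class:`ModelState` so the encoder can start from SSL weights.
    """

    def __init__(self, encoder_config=None, init_state: ModelState | None = None,
                 lr: float = 1e-3, max_epochs: int = 40, patience: int = 5,
                 batch_size: int = 64, threshold: float = 0.5,
                 val_fraction: float = 0.2, rotation_augment: bool = True,
                 random_state: int = 0):
        self.encoder_config = encoder_config
        self.init_state = init_state
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.threshold = threshold
        self.val_fraction = val_fraction
        self.rotation_augment = rotation_augment
        self.random_state = random_state

    # -- internals -----------------------------------------------------------
    def _val_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        self.encoder_.eval()
        self.head_.eval()
        total, n = 0.0, 0
        for lo in range(0, X.shape[0], 256):
            xb, yb = X[lo:lo + 256], y[lo:lo + 256]
            logits = self.head_(self.encoder_(Tensor(xb))).reshape(-1)
            total += float(bce_with_logits(logits, yb).data) * xb.shape[0]
            n += xb.shape[0]
        self.encoder_.train()
        self.head_.train()
        return total / max(n, 1)

    def _subject_val_split(self, groups: np.ndarray, rng: np.random.Generator):
        subjects = np.unique(groups)
        n_val = max(1, int(round(self.val_fraction * len(subjects))))
        if len(subjects) < 2:
            raise ValueError("need at least 2 subjects for a validation split")
        n_val = min(n_val, len(subjects) - 1)
        val_subjects = set(subjects[rng.permutation(len(subjects))[:n_val]])
        val_mask = np.isin(groups, list(val_subjects))
        return ~val_mask, val_mask

    def fit(self, X, y=None, groups=None, X_val=None, y_val=None):
        if isinstance(X, WindowSet):
            groups = X.subject_ids if groups is None else groups
            y = X.labels if y is None else y
            X = X.windows
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).reshape(-1)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.array([0, 1])
        rng = np.random.default_rng(self.random_state)
        if X_val is None:
            if groups is None:
                groups = np.arange(X.shape[0]) % 10  # pseudo-subjects as a fallback
            train_mask, val_mask = self._subject_val_split(np.asarray(groups), rng)
            X_tr, y_tr = X[train_mask], y[train_mask]
            X_val, y_val = X[val_mask], y[val_mask]
        else:
            X_tr, y_tr = X, y
            X_val = np.asarray(X_val, dtype=np.float64)
            y_val = np.asarray(y_val, dtype=np.float64).reshape(-1)
        if len(np.unique(y_tr)) < 2:
            raise ValueError("training labels contain a single class")

        cfg = (self.init_state.encoder_config if self.init_state is not None
               else self.encoder_config) or EncoderConfig.desk(input_length=X.shape[2])
        seed = int(self.random_state)
        self.encoder_ = build_encoder(cfg, seed=seed)
        if self.init_state is not None:
            self.encoder_.load_state_dict(self.init_state.encoder_state)
        self.head_ = LinearHead(cfg.feature_dim, 1, rng=np.random.default_rng(seed + 1))
        opt = Adam(self.encoder_.parameters() + self.head_.parameters(), lr=self.lr)
        stopper = EarlyStopper(self.patience)
        best_state = None
        self.history_ = []
        n = X_tr.shape[0]
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            ep_loss, nb = 0.0, 0
            for lo in range(0, n, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                if len(idx) < 2:
                    continue
                xb = X_tr[idx]
                if self.rotation_augment:
                    # random sensor re-orientation per window: the label is
                    # rotation-invariant, the raw signal is not
                    xb = np.stack([
                        random_rotation_matrix(rng) @ w if rng.random() < 0.5 else w
                        for w in xb
                    ])
                opt.zero_grad()
                logits = self.head_(self.encoder_(Tensor(xb))).reshape(-1)
                loss = bce_with_logits(logits, y_tr[idx])
                loss.backward()
                opt.step()
                ep_loss += float(loss.data)
                nb += 1
            val_loss = self._val_loss(X_val, y_val)
            self.history_.append(
                {"epoch": epoch, "train_loss": ep_loss / max(nb, 1), "val_loss": val_loss}
            )
            stop = stopper.update(epoch, val_loss)
            if stopper.best_epoch == epoch:
                best_state = (self.encoder_.state_dict(), self.head_.state_dict())
            if stop:
                break
        if best_state is not None:
            self.encoder_.load_state_dict(best_state[0])
            self.head_.load_state_dict(best_state[1])
        self.best_epoch_ = stopper.best_epoch
        self.stopped_epoch_ = self.history_[-1]["epoch"]
        self.encoder_config_ = cfg
        self.model_state_ = ModelState(
            encoder_config=cfg,
            encoder_state=self.encoder_.state_dict(),
            head_state=self.head_.state_dict(),
            provenance={
                "stage": "finetune",
                "seed": seed,
                "init": "pretrained" if self.init_state is not None else "random",
            },
        )
        return self

    @classmethod
    def from_state(cls, state: ModelState, threshold: float = 0.5
                   ) -> "GaitWindowClassifier":
        """Rebuild a fitted classifier from a saved encoder + linear head."""
        if state.head_state is None:
            raise ValueError("model state has no head weights")
        clf = cls(threshold=threshold)
        cfg = state.encoder_config
        clf.encoder_ = build_encoder(cfg, seed=0)
        clf.encoder_.load_state_dict(state.encoder_state)
        clf.head_ = LinearHead(cfg.feature_dim, 1)
        clf.head_.load_state_dict(state.head_state)
        clf.encoder_config_ = cfg
        clf.classes_ = np.array([0, 1])
        clf.model_state_ = state
        return clf

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "encoder_")
        arr = X.windows if isinstance(X, WindowSet) else np.asarray(X, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != self.encoder_config_.input_length:
            raise ValueError(
                f"expected windows of shape (n, 3, {self.encoder_config_.input_length})"
            )
        self.encoder_.eval()
        self.head_.eval()
        probs = []
        for lo in range(0, arr.shape[0], 256):
            logits = self.head_(self.encoder_(Tensor(arr[lo:lo + 256]))).data.reshape(-1)
            probs.append(1.0 / (1.0 + np.exp(-logits)))
        p1 = np.concatenate(probs) if probs else np.empty(0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(np.int8)


def finetune_model(init: ModelState | None, data: WindowSet,
                   train_subjects, val_subjects, lr: float = 1e-3,
                   max_epochs: int = 40, patience: int = 5,
                   batch_size: int = 64, seed: int = 0) -> GaitWindowClassifier:
    """Fine-tune on an explicit subject-wise train/validation division."""
    if data.labels is None or data.subject_ids is None:
        raise ValueError("labeled windows with subject ids required")
    tr = np.isin(data.subject_ids, list(train_subjects))
    va = np.isin(data.subject_ids, list(val_subjects))
    clf = GaitWindowClassifier(
        init_state=init, lr=lr, max_epochs=max_epochs, patience=patience,
        batch_size=batch_size, random_state=seed,
    )
    clf.fit(data.windows[tr], data.labels[tr],
            X_val=data.windows[va], y_val=data.labels[va])
    return clf


def predict_windows(model, ws: WindowSet, threshold: float = 0.5):
    """Per-window gait probabilities and thresholded binary labels."""
    probs = model.predict_proba(ws)[:, 1]
    return probs, (probs >= threshold).astype(np.int8)


def cross_validate(init: ModelState | None, data: WindowSet, k: int = 5,
                   seeds: tuple[int, ...] = (0, 1, 2), lr: float = 1e-3,
                   max_epochs: int = 40, patience: int = 5,
                   batch_size: int = 64) -> dict:
    """Grouped stratified k-fold CV repeated over seeds.

    For every seed the train subjects are re-dealt into k folds; each fold
    serves once as validation while the others train.  Per-fold window-level
    metrics are averaged (plain arithmetic mean over all fold runs) into the
    aggregate used for model selection by F1.
    """
    from .stats_eval import confusion_metrics

    if data.labels is None or data.subject_ids is None:
        raise ValueError("labeled windows with subject ids required")
    prevalence = subject_gait_prevalence(data)
    subjects = sorted(prevalence)
    runs = []
    for seed in seeds:
        folds = make_folds(subjects, prevalence, k=k, seed=seed)
        for fold_idx, val_subjects in enumerate(folds):
            train_subjects = [s for s in subjects if s not in set(val_subjects)]
            clf = finetune_model(init, data, train_subjects, val_subjects,
                                 lr=lr, max_epochs=max_epochs, patience=patience,
                                 batch_size=batch_size, seed=seed * 100 + fold_idx)
            va = np.isin(data.subject_ids, val_subjects)
            _, pred = predict_windows(clf, WindowSet(
                windows=data.windows[va], fs=data.fs, window_s=data.window_s))
            report = confusion_metrics(data.labels[va], pred)
            runs.append({"seed": seed, "fold": fold_idx, "report": report})
    agg = {
        m: float(np.mean([r["report"][m] for r in runs]))
        for m in ("accuracy", "specificity", "recall", "precision", "f1")
    }
    return {"runs": runs, "aggregate": agg}
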