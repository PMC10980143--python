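import numpy as np
import pytest

from wristgait.finetune import (
    EarlyStopper,
    GaitWindowClassifier,
    cross_validate,
    make_folds,
    predict_windows,
    split_subjects,
    subject_gait_prevalence,
)
from wristgait.io_preprocess import WindowSet
from wristgait.ssl_core import EncoderConfig

TINY_CFG = EncoderConfig(channels=(8, 8), strides=(2, 2), feature_dim=8,
                         input_length=60)


def tiny_labeled_set(n_subjects=6, per_subject=20, L=60, seed=0):
    """Separable micro-dataset: gait = 2 Hz sinusoid bursts, non-gait = noise."""
    gen = np.random.default_rng(seed)
    t = np.arange(L) / 30.0
    windows, labels, subjects = [], [], []
    for s in range(n_subjects):
        for i in range(per_subject):
            label = i % 2
            base = gen.normal(0, 0.05, size=(3, L))
            if label:
                base += np.sin(2 * np.pi * 2.0 * t + gen.uniform(0, 6))[None, :] * 0.5
            windows.append(base)
            labels.append(label)
            subjects.append(f"s{s:02d}")
    return WindowSet(windows=np.array(windows), fs=30.0, window_s=2.0,
                     labels=np.array(labels), subject_ids=np.array(subjects))


class TestSplitSubjects:
    def test_84_subjects_give_21_test(self):
        ids = [f"p{i}" for i in range(84)]
        plan = split_subjects(ids, 0.25, seed=0)
        assert len(plan.test_subjects) == 21
        assert len(plan.train_subjects) == 63

    def test_no_subject_in_both_sets(self):
        plan = split_subjects([f"p{i}" for i in range(40)], 0.25, seed=3)
        assert not set(plan.train_subjects) & set(plan.test_subjects)

    def test_same_seed_identical_split(self):
        ids = [f"p{i}" for i in range(30)]
        a = split_subjects(ids, 0.25, seed=9)
        b = split_subjects(ids, 0.25, seed=9)
        assert a.test_subjects == b.test_subjects

    def test_cohort_minimum_honored(self):
        ids = [f"p{i}" for i in range(40)]
        cohorts = {s: ("A" if i < 8 else "B") for i, s in enumerate(ids)}
        plan = split_subjects(ids, 0.25, seed=1, cohorts=cohorts, min_per_cohort=3)
        test_cohorts = [cohorts[s] for s in plan.test_subjects]
        assert test_cohorts.count("A") >= 3 and test_cohorts.count("B") >= 3

    def test_unsatisfiable_cohort_listed_in_error(self):
        ids = [f"p{i}" for i in range(10)]
        cohorts = {s: ("tiny" if i < 2 else "big") for i, s in enumerate(ids)}
        with pytest.raises(ValueError, match="tiny"):
            split_subjects(ids, 0.25, seed=0, cohorts=cohorts, min_per_cohort=3)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            split_subjects(["a", "b", "c"], 0.25, seed=0)


class TestMakeFolds:
    def test_20_subjects_5_folds_of_4(self):
        subs = [f"p{i}" for i in range(20)]
        prev = {s: i / 20 for i, s in enumerate(subs)}
        folds = make_folds(subs, prev, k=5, seed=0)
        assert all(len(f) == 4 for f in folds)

    def test_folds_partition_train_subjects(self):
        subs = [f"p{i}" for i in range(23)]
        prev = {s: (i % 7) / 7 for i, s in enumerate(subs)}
        folds = make_folds(subs, prev, k=5, seed=2)
        flat = [s for f in folds for s in f]
        assert sorted(flat) == sorted(subs)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not set(folds[i]) & set(folds[j])

    def test_k_larger_than_subjects_rejected(self):
        with pytest.raises(ValueError, match="cannot make"):
            make_folds(["a", "b"], {"a": 0.1, "b": 0.2}, k=5, seed=0)

    def test_stratified_folds_balance_prevalence_better_than_random(self):
        """Quantile stratification shrinks the fold-prevalence spread vs.
        unstratified random fold assignment on a skewed cohort."""
        gen = np.random.default_rng(0)
        subs = [f"p{i}" for i in range(30)]
        prev = {s: float(p) for s, p in zip(subs, gen.beta(0.4, 2.0, size=30))}
        spread_strat, spread_rand = [], []
        for seed in range(100):
            folds = make_folds(subs, prev, k=5, seed=seed)
            means = [np.mean([prev[s] for s in f]) for f in folds]
            spread_strat.append(max(means) - min(means))
            shuffled = np.random.default_rng(seed).permutation(subs)
            rand_folds = [shuffled[i::5] for i in range(5)]
            means = [np.mean([prev[s] for s in f]) for f in rand_folds]
            spread_rand.append(max(means) - min(means))
        assert np.mean(spread_strat) < np.mean(spread_rand)


class TestEarlyStopper:
    def test_plateau_at_epoch_7_halts_at_12_with_best_7(self):
        losses = [1.0, 0.9, 0.8, 0.7, 0.6, 0.55, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.4]
        stopper = EarlyStopper(patience=5)
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(epoch, loss):
                stopped_at = epoch
                break
        assert stopped_at == 12
        assert stopper.best_epoch == 7

    def test_strictly_decreasing_never_stops(self):
        stopper = EarlyStopper(patience=5)
        assert not any(stopper.update(e, 1.0 / e) for e in range(1, 50))

    def test_patience_floor(self):
        with pytest.raises(ValueError):
            EarlyStopper(patience=0)


@pytest.fixture(scope="module")
def data():
    return tiny_labeled_set()


@pytest.fixture(scope="module")
def fitted(data):
    clf = GaitWindowClassifier(encoder_config=TINY_CFG, max_epochs=8,
                               random_state=0)
    return clf.fit(data)


class TestGaitWindowClassifier:
    def test_single_class_labels_rejected(self, data):
        clf = GaitWindowClassifier(encoder_config=TINY_CFG)
        with pytest.raises(ValueError, match="single class"):
            clf.fit(data.windows, np.zeros(data.n_windows), groups=data.subject_ids)

    def test_zero_learning_rate_keeps_weights(self, data):
        """lr=0 leaves every parameter bit-identical; the validation loss is
        constant up to batch-norm running-statistic updates, which are
        buffers refreshed by the forward pass, not optimizer state."""
        clf = GaitWindowClassifier(encoder_config=TINY_CFG, lr=0.0, max_epochs=3,
                                   rotation_augment=False, random_state=0)
        clf.fit(data)
        from wristgait.ssl_core import build_encoder

        init = build_encoder(TINY_CFG, seed=0)
        for (name, p), (_, q) in zip(clf.encoder_.named_parameters(),
                                     init.named_parameters()):
            np.testing.assert_array_equal(p.data, q.data, err_msg=name)
        val_losses = [h["val_loss"] for h in clf.history_]
        assert np.ptp(val_losses) < 0.02

    def test_threshold_zero_predicts_all_gait(self, fitted, data):
        _, pred = predict_windows(fitted, data, threshold=0.0)
        assert pred.all()

    def test_threshold_one_predicts_none(self, fitted, data):
        _, pred = predict_windows(fitted, data, threshold=1.0)
        assert not pred.any()

    def test_predictions_invariant_to_batch_size(self, fitted, data):
        full = fitted.predict_proba(data.windows)[:, 1]
        singles = np.concatenate([
            fitted.predict_proba(data.windows[i:i + 1])[:, 1] for i in range(12)
        ])
        np.testing.assert_allclose(full[:12], singles, atol=1e-6)

    def test_window_length_mismatch_rejected(self, fitted, rng):
        with pytest.raises(ValueError, match="shape"):
            fitted.predict_proba(rng.normal(size=(2, 3, 90)))

    def test_validation_split_is_subject_wise(self, data):
        clf = GaitWindowClassifier(encoder_config=TINY_CFG, max_epochs=1,
                                   random_state=1)
        groups = np.asarray(data.subject_ids)
        train_mask, val_mask = clf._subject_val_split(groups, np.random.default_rng(0))
        assert not set(groups[train_mask]) & set(groups[val_mask])


class TestCrossValidate:
    def test_run_bookkeeping_and_aggregate(self):
        data = tiny_labeled_set(n_subjects=10, per_subject=12)
        result = cross_validate(None, data, k=5, seeds=(0, 1, 2), max_epochs=2,
                                batch_size=32)
        assert len(result["runs"]) == 15
        f1s = [r["report"]["f1"] for r in result["runs"]]
        assert result["aggregate"]["f1"] == pytest.approx(np.mean(f1s), abs=1e-9)

    def test_separable_data_reaches_high_f1_per_fold(self):
        data = tiny_labeled_set(n_subjects=10, per_subject=16, seed=4)
        result = cross_validate(None, data, k=5, seeds=(0,), max_epochs=12,
                                batch_size=32)
        fold_f1 = [r["report"]["f1"] for r in result["runs"]]
        assert min(fold_f1) >= 95.0

    def test_prevalence_table(self):
        data = tiny_labeled_set(n_subjects=4, per_subject=10)
        prev = subject_gait_prevalence(data)
        assert set(prev) == {f"s{i:02d}" for i in range(4)}
        assert all(v == pytest.approx(0.5) for v in prev.values())
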