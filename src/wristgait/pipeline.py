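"""End-to-end study pipelines composing the stage modules.

Two workflows: the supervised evaluation chain (synthetic labeled subjects
-> SSL pretraining -> fine-tuning -> held-out window metrics) and the
construct-validity chain (synthetic cohort -> detection -> non-wear/day
selection -> daily walking time -> nonparametric group statistics).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dailyliving import summarize_subject
from .finetune import GaitWindowClassifier, predict_windows, split_subjects
from .io_preprocess import WindowSet, segment_windows
from .ssl_core import ModelState, pretrain_mtl, pretrain_simclr
from .stats_eval import cohort_comparison, confusion_metrics, per_subject_metrics
from .synthetic import (
    CohortGroup,
    SyntheticCohortConfig,
    SyntheticSubjectConfig,
    generate_cohort,
    generate_labeled_cohort_windows,
    generate_subject,
)


def fit_spectral_detector(seed: int = 0, n_subjects: int = 4,
                          duration_s: float = 600.0, fs: float = 30.0):
    """Calibrate the band-power baseline on a small labeled synthetic set."""
    from .baseline import SpectralGaitDetector

    ws = generate_labeled_cohort_windows(
        n_subjects, duration_s=duration_s, seed=seed,
        base_cfg=SyntheticSubjectConfig(fs=fs), fs_target=fs,
    )
    return SpectralGaitDetector(fs=ws.fs).fit(ws)


def _subset(ws: WindowSet, mask: np.ndarray) -> WindowSet:
    return WindowSet(
        windows=ws.windows[mask], fs=ws.fs, window_s=ws.window_s,
        labels=None if ws.labels is None else ws.labels[mask],
        subject_ids=None if ws.subject_ids is None else ws.subject_ids[mask],
    )


def make_learning_corpus(n_train_subjects: int = 20, n_test_subjects: int = 10,
                         n_unlabeled_windows: int = 2000,
                         duration_s: float = 1200.0, seed: int = 0
                         ) -> tuple[WindowSet, WindowSet, np.ndarray]:
    """Labeled train/test window sets (subject-wise split) plus an unlabeled
    pretraining pool drawn from separate synthetic subjects."""
    labeled = generate_labeled_cohort_windows(
        n_train_subjects + n_test_subjects, duration_s=duration_s, seed=seed
    )
    plan = split_subjects(
        np.unique(labeled.subject_ids),
        test_fraction=n_test_subjects / (n_train_subjects + n_test_subjects),
        seed=seed,
    )
    tr_mask = np.isin(labeled.subject_ids, plan.train_subjects)
    windows_per_subject = max(1, int(duration_s // 10))
    n_unl_subjects = max(2, int(np.ceil(n_unlabeled_windows / windows_per_subject)))
    unlabeled = generate_labeled_cohort_windows(
        n_unl_subjects, duration_s=duration_s, seed=seed + 7919
    )
    return (_subset(labeled, tr_mask), _subset(labeled, ~tr_mask),
            unlabeled.windows[:n_unlabeled_windows])


def run_supervised_evaluation(
    n_train_subjects: int = 20,
    n_test_subjects: int = 10,
    n_unlabeled_windows: int = 2000,
    ssl_method: str = "mtl",
    ssl_epochs: int = 12,
    finetune_seeds: tuple[int, ...] = (0, 1, 2),
    max_epochs: int = 40,
    duration_s: float = 1200.0,
    use_pretraining: bool = True,
    seed: int = 0,
) -> dict:
    """Pretrain, fine-tune and evaluate on held-out synthetic subjects.

    The labeled pool is split subject-wise; SSL pretraining sees an
    unlabeled window set drawn from separate synthetic subjects.  Returns
    per-seed held-out metric reports and their median F1.
    """
    train_ws, test_ws, unl = make_learning_corpus(
        n_train_subjects, n_test_subjects, n_unlabeled_windows, duration_s, seed
    )
    init_state: ModelState | None = None
    if use_pretraining:
        if ssl_method == "mtl":
            init_state = pretrain_mtl(unl, n_epochs=ssl_epochs, seed=seed)
        elif ssl_method == "simclr":
            init_state = pretrain_simclr(unl, n_epochs=ssl_epochs, seed=seed)
        else:
            raise ValueError(f"unknown ssl method {ssl_method!r}")

    reports = []
    for ft_seed in finetune_seeds:
        clf = GaitWindowClassifier(
            init_state=init_state, max_epochs=max_epochs,
            random_state=seed * 1000 + ft_seed,
        )
        clf.fit(train_ws)
        _, pred = predict_windows(clf, test_ws)
        rep = confusion_metrics(test_ws.labels, pred)
        rep["per_subject"] = per_subject_metrics(test_ws.labels, pred, test_ws.subject_ids)
        reports.append(rep)
    return {
        "reports": reports,
        "median_f1": float(np.median([r["f1"] for r in reports])),
        "median_accuracy": float(np.median([r["accuracy"] for r in reports])),
        "pretrained": use_pretraining,
    }


def run_learning_study(seed: int = 0, finetune_seeds: tuple[int, ...] = (0, 1, 2),
                       efficiency_seeds: int = 5, n_efficiency_subjects: int = 5,
                       ssl_method: str = "mtl", ssl_epochs: int = 12,
                       max_epochs: int = 40) -> dict:
    """End-to-end learning recovery plus the label-efficiency comparison.

    Part A: SSL pretraining on ~2,000 unlabeled windows, fine-tuning on the
    20-subject labeled pool, evaluation on 10 held-out subjects (median F1
    over the fine-tuning seeds).  Part B: with only a handful of labeled
    subjects, the SSL-initialized model is compared against its
    randomly-initialized supervised counterpart over several seeds.
    """
    train_ws, test_ws, unl = make_learning_corpus(seed=seed)
    pretrain = pretrain_mtl if ssl_method == "mtl" else pretrain_simclr
    state = pretrain(unl, n_epochs=ssl_epochs, seed=seed)

    def evaluate(init, random_state, data):
        clf = GaitWindowClassifier(init_state=init, max_epochs=max_epochs,
                                   random_state=random_state)
        clf.fit(data)
        _, pred = predict_windows(clf, test_ws)
        return confusion_metrics(test_ws.labels, pred)

    part_a = [evaluate(state, seed * 1000 + s, train_ws) for s in finetune_seeds]

    few_subjects = sorted(np.unique(train_ws.subject_ids))[:n_efficiency_subjects]
    few_ws = _subset(train_ws, np.isin(train_ws.subject_ids, few_subjects))
    ssl_f1, rand_f1 = [], []
    for s in range(efficiency_seeds):
        ssl_f1.append(evaluate(state, seed * 2000 + s, few_ws)["f1"])
        rand_f1.append(evaluate(None, seed * 2000 + s, few_ws)["f1"])
    return {
        "heldout_reports": part_a,
        "median_f1": float(np.median([r["f1"] for r in part_a])),
        "median_accuracy": float(np.median([r["accuracy"] for r in part_a])),
        "fewshot_ssl_median_f1": float(np.median(ssl_f1)),
        "fewshot_random_median_f1": float(np.median(rand_f1)),
        "fewshot_ssl_f1": ssl_f1,
        "fewshot_random_f1": rand_f1,
    }


def default_cohort_config(means=(60.0, 45.0, 30.0), n_per_group: int = 20,
                          days: int = 4) -> SyntheticCohortConfig:
    """Three mobility-disability cohorts with decreasing daily walking."""
    groups = [
        CohortGroup(name=f"disability_{i}", mean_daily_walking_min=m,
                    n_subjects=n_per_group, mobility_score=i,
                    parkinsonian_signs=min(i, 2))
        for i, m in enumerate(means)
    ]
    return SyntheticCohortConfig(groups=groups, days=days)


def run_single_group_null(detector, n_subjects: int = 20, mean_minutes: float = 45.0,
                          n_pseudo_groups: int = 3, seed: int = 0,
                          fs: float = 10.0, days: int = 4) -> dict:
    """Null calibration: one homogeneous cohort split into pseudo-groups.

    All subjects share one walking-duration distribution; after detection
    and summarization they are randomly partitioned into ``n_pseudo_groups``
    and compared with Kruskal-Wallis.  Under the null the test should be
    non-significant at the nominal rate.
    """
    from .stats_eval import kruskal_wallis

    cfg = SyntheticCohortConfig(
        groups=[CohortGroup(name="all", mean_daily_walking_min=mean_minutes,
                            n_subjects=n_subjects)],
        fs=fs, days=days,
    )
    specs, _ = generate_cohort(cfg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    walking = []
    for sub_cfg, meta in specs:
        rec, _, _ = generate_subject(sub_cfg, days=meta["days"],
                                     subject_id=meta["subject_id"])
        ws = segment_windows(rec)
        _, pred = predict_windows(detector, ws)
        summary = summarize_subject(rec, ws.window_start_s, pred)
        if summary is not None:
            walking.append(summary.daily_walking_time)
    walking = np.asarray(walking)
    assign = rng.permutation(len(walking)) % n_pseudo_groups
    groups = [walking[assign == g] for g in range(n_pseudo_groups)]
    h, p = kruskal_wallis(groups)
    return {"kw_h": h, "kw_p": p, "n_included": len(walking)}


def run_construct_validity(cohort_cfg: SyntheticCohortConfig, detector,
                           seed: int = 0, window_s: float = 10.0,
                           group_col: str = "mobility_score") -> dict:
    """Cohort study: simulate subjects, detect gait, summarize, compare.

    Every subject's day-scale recording is realized, windowed, passed
    through the detector, masked for non-wear, reduced to the median daily
    walking time, and the cohort table is analyzed with Kruskal-Wallis,
    Dunn and partial correlation (adjusting for age, sex, BMI).
    """
    specs, table = generate_cohort(cohort_cfg, seed=seed)
    rows = []
    for sub_cfg, meta in specs:
        rec, _, smeta = generate_subject(
            sub_cfg, days=meta["days"], subject_id=meta["subject_id"]
        )
        # the cohort is generated at the pipeline rate, so no resampling here
        ws = segment_windows(rec, window_s)
        _, pred = predict_windows(detector, ws)
        summary = summarize_subject(rec, ws.window_start_s, pred, window_s=window_s)
        rows.append({
            "subject_id": meta["subject_id"],
            "daily_walking_time": np.nan if summary is None else summary.daily_walking_time,
            "included": summary is not None,
            "true_median_daily_min": float(np.median(smeta["per_day_gait_minutes"][:meta["days"]])),
        })
    result_table = table.join(pd.DataFrame(rows).set_index("subject_id"))
    included = result_table[result_table["included"]]
    stats = cohort_comparison(included, group_col=group_col)
    return {"table": result_table, "stats": stats}
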