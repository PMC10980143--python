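"""Window-level performance metrics and nonparametric cohort statistics.

Confusion-matrix metrics are reported in percent.  Group comparisons use
the Kruskal-Wallis rank test with Dunn's post-hoc z tests (tie-corrected,
Bonferroni-adjusted); associations adjusted for covariates use partial
correlation on least-squares residuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def confusion_metrics(y_true, y_pred) -> dict:
    """Accuracy, specificity, recall, precision and F1 (percent) plus counts.

    When no positives are predicted while positives exist, precision is
    reported as 0 and flagged degenerate so F1 stays defined.
    """
    y_true = np.asarray(y_true).astype(int).reshape(-1)
    y_pred = np.asarray(y_pred).astype(int).reshape(-1)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    n = tp + fp + fn + tn
    degenerate = (tp + fp) == 0 and (tp + fn) > 0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    specificity = tn / (tn + fp) if (tn + fp) > 0 else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return {
        "accuracy": 100.0 * (tp + tn) / n,
        "specificity": 100.0 * specificity,
        "recall": 100.0 * recall,
        "precision": 100.0 * precision,
        "f1": 100.0 * f1,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "degenerate_precision": degenerate,
    }


def per_subject_metrics(y_true, y_pred, subject_ids) -> pd.DataFrame:
    """Metrics computed per subject then reported one row per subject.

    Cohort-level results are the per-subject averages of these rows, which
    weights every participant equally regardless of recording length.
    """
    subject_ids = np.asarray(subject_ids)
    rows = []
    for s in np.unique(subject_ids):
        mask = subject_ids == s
        rep = confusion_metrics(np.asarray(y_true)[mask], np.asarray(y_pred)[mask])
        rep["subject_id"] = str(s)
        rows.append(rep)
    return pd.DataFrame(rows).set_index("subject_id")


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (df = g - 1).

    All observations identical across groups is a well-defined degenerate
    case here: H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=np.float64).reshape(-1) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    allvals = np.concatenate(groups)
    if allvals.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.ptp(allvals) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _tie_term(allvals: np.ndarray) -> float:
    _, counts = np.unique(allvals, return_counts=True)
    return float((counts ** 3 - counts).sum())


def dunn_posthoc(groups, labels=None, correction: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise mean-rank z tests after a Kruskal-Wallis rejection.

    z_ij = (R̄_i - R̄_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T the tie term Σ(t³ - t); two-sided normal p-values are Bonferroni
    multiplied by the number of pairs and capped at 1.
    """
    groups = [np.asarray(g, dtype=np.float64).reshape(-1) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(groups))]
    allvals = np.concatenate(groups)
    n_total = allvals.size
    ranks = sps.rankdata(allvals)
    sizes = [g.size for g in groups]
    mean_ranks = []
    lo = 0
    for s in sizes:
        mean_ranks.append(ranks[lo:lo + s].mean())
        lo += s
    var_base = n_total * (n_total + 1) / 12.0 - _tie_term(allvals) / (12.0 * (n_total - 1))
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p_raw = 2.0 * sps.norm.sf(abs(z))
            p_adj = min(1.0, p_raw * m) if correction == "bonferroni" else p_raw
            rows.append({
                "group_a": labels[i], "group_b": labels[j],
                "statistic": float(z), "p_raw": float(p_raw), "p_adj": float(p_adj),
            })
    return pd.DataFrame(rows)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    p = np.asarray(p_values, dtype=np.float64)
    m = m if m is not None else p.size
    return np.minimum(1.0, p * m)


def partial_correlation(x, y, covariates=None, method: str = "pearson"
                        ) -> tuple[float, float]:
    """Correlation of x and y after removing the least-squares projection on
    the covariates (plus intercept); p from t with df = n - n_cov - 2."""
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    if covariates is None:
        C = np.empty((x.size, 0))
    else:
        C = np.asarray(covariates, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
    n, k = C.shape[0] if C.size else x.size, C.shape[1]
    if x.size != y.size or (C.size and C.shape[0] != x.size):
        raise ValueError("x, y and covariates must have equal length")
    if x.size <= k + 2:
        raise ValueError("need n > n_covariates + 2 observations")
    design = np.column_stack([np.ones(x.size), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if np.std(rx) < 1e-12 * max(1.0, np.std(x)) or np.std(ry) < 1e-12 * max(1.0, np.std(y)):
        raise ValueError("residual variance is (near-)zero; correlation undefined")
    if method == "spearman":
        rx, ry = sps.rankdata(rx), sps.rankdata(ry)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    df = x.size - k - 2
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = rho_c * np.sqrt(df / (1.0 - rho_c ** 2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return rho, p


def compare_models(reports: dict[str, pd.DataFrame],
                   metrics=("accuracy", "specificity", "recall", "precision", "f1"),
                   alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis + Dunn across models on per-subject metric values.

    ``reports`` maps model name to a per-subject metric table (index:
    subject_id).  All models must cover the same subjects.  Output has one
    row per (metric, model pair) with the omnibus H/p attached.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 models to compare")
    names = sorted(reports)
    subj_sets = [frozenset(reports[n].index) for n in names]
    if len(set(subj_sets)) != 1:
        raise ValueError("models report different subject sets")
    rows = []
    for metric in metrics:
        groups = [reports[n][metric].to_numpy() for n in names]
        h, p_omni = kruskal_wallis(groups)
        dunn = dunn_posthoc(groups, labels=names)
        for _, r in dunn.iterrows():
            rows.append({
                "metric": metric, "group_a": r["group_a"], "group_b": r["group_b"],
                "kw_h": h, "kw_p": p_omni,
                "statistic": r["statistic"], "p_raw": r["p_raw"], "p_adj": r["p_adj"],
                "significant": bool(r["p_adj"] < alpha),
            })
    return pd.DataFrame(rows)


def cohort_comparison(table: pd.DataFrame, group_col: str,
                      outcome: str = "daily_walking_time",
                      covariate_cols=("age", "sex", "bmi")) -> dict:
    """Construct-validity battery on a cohort table.

    Kruskal-Wallis across the groups of ``group_col``, Dunn's post-hoc with
    Bonferroni, and the partial correlation of the (ordinal) group score with
    the outcome adjusted for the covariates present in the table.
    """
    sub = table.dropna(subset=[group_col, outcome])
    levels = sorted(sub[group_col].unique())
    groups = [sub.loc[sub[group_col] == g, outcome].to_numpy() for g in levels]
    h, p = kruskal_wallis(groups)
    dunn = dunn_posthoc(groups, labels=[str(g) for g in levels])
    result = {"kw_h": h, "kw_p": p, "dunn": dunn}
    covs = [c for c in covariate_cols if c in sub.columns]
    if covs and len(sub) > len(covs) + 2:
        score = pd.to_numeric(sub[group_col]).to_numpy()
        rho, p_rho = partial_correlation(
            score, sub[outcome].to_numpy(), sub[covs].to_numpy()
        )
        result["partial_rho"] = rho
        result["partial_p"] = p_rho
    return result
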