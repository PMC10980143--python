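import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wristgait.stats_eval import (
    bonferroni,
    cohort_comparison,
    compare_models,
    confusion_metrics,
    dunn_posthoc,
    kruskal_wallis,
    partial_correlation,
    per_subject_metrics,
)


def textbook_dunn(groups):
    """Independent double-loop Dunn implementation (mean ranks, tie term)."""
    allvals = np.concatenate(groups)
    n = allvals.size
    ranks = sps.rankdata(allvals)
    sizes = [len(g) for g in groups]
    means, lo = [], 0
    for s in sizes:
        means.append(ranks[lo:lo + s].mean())
        lo += s
    _, counts = np.unique(allvals, return_counts=True)
    tie = (counts ** 3 - counts).sum()
    rows = []
    m = len(groups) * (len(groups) - 1) // 2
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            var = (n * (n + 1) / 12 - tie / (12 * (n - 1))) * (1 / sizes[i] + 1 / sizes[j])
            z = (means[i] - means[j]) / np.sqrt(var)
            p = 2 * sps.norm.sf(abs(z))
            rows.append((z, p, min(1.0, p * m)))
    return rows


class TestConfusionMetrics:
    def test_perfect_predictions_are_100(self):
        rep = confusion_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        for key in ("accuracy", "specificity", "recall", "precision", "f1"):
            assert rep[key] == 100.0

    def test_worked_confusion_matrix(self):
        y_true = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 0, 1, 0, 0, 0, 0, 0, 0]   # TP=2 FP=1 FN=1 TN=6
        rep = confusion_metrics(y_true, y_pred)
        assert rep["accuracy"] == pytest.approx(80.00, abs=0.005)
        assert rep["precision"] == pytest.approx(66.67, abs=0.005)
        assert rep["recall"] == pytest.approx(66.67, abs=0.005)
        assert rep["specificity"] == pytest.approx(85.71, abs=0.005)
        assert rep["f1"] == pytest.approx(66.67, abs=0.005)

    def test_no_predicted_positives_flagged_degenerate(self):
        rep = confusion_metrics([1, 1, 0], [0, 0, 0])
        assert rep["precision"] == 0.0 and rep["degenerate_precision"]
        assert rep["f1"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_metrics([], [])

    def test_counts_sum_to_n_on_random_vectors(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        rep = confusion_metrics(y, p)
        assert rep["tp"] + rep["fp"] + rep["fn"] + rep["tn"] == 50

    def test_per_subject_rows(self):
        df = per_subject_metrics([1, 0, 1, 0], [1, 0, 0, 0], ["a", "a", "b", "b"])
        assert list(df.index) == ["a", "b"]
        assert df.loc["a", "f1"] == 100.0


class TestKruskalWallis:
    def test_matches_exact_rank_formula(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        h, p = kruskal_wallis(groups)
        # no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        h_hand = 12 / (9 * 10) * 3 * ((2 - 5) ** 2 + 0 + (8 - 5) ** 2)
        assert h == pytest.approx(h_hand, abs=1e-8)
        assert p == pytest.approx(sps.chi2.sf(h_hand, df=2), abs=1e-8)

    def test_identical_values_give_null_result(self):
        assert kruskal_wallis([[5, 5], [5, 5, 5]]) == (0.0, 1.0)

    def test_group_order_invariance(self, rng):
        groups = [rng.normal(size=7), rng.normal(size=5), rng.normal(size=9)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis(groups[::-1])
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_chi2_p_close_to_permutation_p(self):
        gen = np.random.default_rng(1)
        groups = [gen.normal(0, 1, 8), gen.normal(0.9, 1, 8), gen.normal(0.4, 1, 8)]
        h_obs, p_chi2 = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            gen.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            h, _ = kruskal_wallis(parts)
            count += h >= h_obs - 1e-12
        p_perm = count / n_perm
        assert abs(p_chi2 - p_perm) < 0.03

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestDunnPosthoc:
    def test_adjusted_never_below_raw(self, rng):
        groups = [rng.normal(size=8) for _ in range(4)]
        out = dunn_posthoc(groups)
        assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()
        assert (out["p_adj"] <= 1.0).all()

    def test_three_groups_make_three_pairs(self, rng):
        out = dunn_posthoc([rng.normal(size=5) for _ in range(3)])
        assert len(out) == 3

    def test_matches_textbook_formula_with_ties(self):
        gen = np.random.default_rng(8)
        groups = [gen.integers(0, 6, 10).astype(float) for _ in range(3)]
        ours = dunn_posthoc(groups)
        for row, (z, p, p_adj) in zip(ours.itertuples(), textbook_dunn(groups)):
            assert row.statistic == pytest.approx(z, abs=1e-8)
            assert row.p_raw == pytest.approx(p, abs=1e-8)
            assert row.p_adj == pytest.approx(p_adj, abs=1e-8)

    def test_bonferroni_props(self):
        p = np.array([0.01, 0.2, 0.5])
        adj = bonferroni(p)
        assert (adj <= 1).all()
        assert (np.diff(adj[np.argsort(p)]) >= 0).all()
        np.testing.assert_allclose(adj, [0.03, 0.6, 1.0])


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x = rng.normal(size=40)
        y = x * 0.5 + rng.normal(size=40)
        rho, p = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert rho == pytest.approx(r_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_orthogonal_covariates_leave_correlation(self):
        gen = np.random.default_rng(2)
        x = gen.normal(size=200)
        y = x + 0.5 * gen.normal(size=200)
        cov = gen.normal(size=(200, 2))      # independent of both
        rho_partial, _ = partial_correlation(x, y, cov)
        rho_raw = np.corrcoef(x, y)[0, 1]
        assert rho_partial == pytest.approx(rho_raw, abs=0.05)

    def test_collinear_outcome_rejected(self):
        gen = np.random.default_rng(3)
        cov = gen.normal(size=(30, 2))
        x = cov @ np.array([1.0, -2.0]) + 3
        y = gen.normal(size=30)
        with pytest.raises(ValueError, match="residual variance"):
            partial_correlation(x, y, cov)

    def test_rank_deficient_covariates_rejected(self):
        gen = np.random.default_rng(4)
        c = gen.normal(size=30)
        cov = np.column_stack([c, 2 * c])
        with pytest.raises(ValueError, match="rank-deficient"):
            partial_correlation(gen.normal(size=30), gen.normal(size=30), cov)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        gen = np.random.default_rng(5)
        df = pd.DataFrame({
            "x": gen.normal(size=60), "cv1": gen.normal(size=60),
            "cv2": gen.normal(size=60),
        })
        df["y"] = df.x * 0.6 + df.cv1 * 0.3 + gen.normal(size=60)
        rho, p = partial_correlation(df.x, df.y, df[["cv1", "cv2"]].to_numpy())
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["cv1", "cv2"])
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)


class TestCompareModels:
    @staticmethod
    def _report(values):
        return pd.DataFrame(
            {"accuracy": values, "specificity": values, "recall": values,
             "precision": values, "f1": values},
            index=[f"s{i}" for i in range(len(values))],
        )

    def test_identical_models_are_nonsignificant(self):
        vals = list(np.linspace(70, 95, 21))
        out = compare_models({"a": self._report(vals), "b": self._report(vals)})
        assert (out["p_adj"] == 1.0).all()

    def test_uniform_20_point_gap_is_significant(self, rng):
        base = rng.uniform(60, 75, size=21)
        out = compare_models({
            "weak": self._report(base), "strong": self._report(base + 20)
        })
        f1_rows = out[out["metric"] == "f1"]
        assert bool(f1_rows["significant"].iloc[0])

    def test_one_row_per_metric_pair(self, rng):
        reports = {m: self._report(rng.uniform(50, 90, 10)) for m in "abc"}
        out = compare_models(reports)
        assert len(out) == 5 * 3              # 5 metrics x 3 pairs

    def test_mismatched_subjects_rejected(self):
        a = self._report([1, 2, 3])
        b = self._report([1, 2, 3, 4])
        with pytest.raises(ValueError, match="different subject"):
            compare_models({"a": a, "b": b})


class TestCohortComparison:
    def test_partial_rho_sign_matches_programmed_trend(self):
        gen = np.random.default_rng(6)
        n = 90
        score = np.repeat([0, 1, 2], n // 3)
        table = pd.DataFrame({
            "mobility_score": score,
            "daily_walking_time": 60 - 12 * score + gen.normal(0, 8, n),
            "age": gen.normal(80, 6, n),
            "sex": gen.integers(0, 2, n),
            "bmi": gen.normal(27, 4, n),
        })
        res = cohort_comparison(table, "mobility_score")
        assert res["kw_p"] < 0.001
        assert res["partial_rho"] < -0.3
        extreme = res["dunn"][(res["dunn"].group_a == "0") & (res["dunn"].group_b == "2")]
        assert float(extreme["p_adj"].iloc[0]) < 0.05
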