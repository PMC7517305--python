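"""CV partitioning, ROC/PR analysis, aggregation and feature-set comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import auroc_pair_counting, best_f1_sweep, mann_whitney_u_bruteforce
from rearrest.evaluation import (
    aggregate_median_iqr,
    compare_feature_sets,
    compute_roc_pr,
    make_cv_partitions,
    metrics_at_best_f1,
    run_repeated_cv,
)


def _reference_labels():
    ids = np.array([f"p{i}" for i in range(162)])
    labels = np.r_[np.ones(55, int), np.zeros(107, int)]
    return ids, labels


class TestMakeCvPartitions:
    def test_reference_stratification(self):
        ids, labels = _reference_labels()
        parts = make_cv_partitions(ids, labels, k=5, n_reps=3, seed=0)
        lab = dict(zip(ids, labels))
        for part in parts:
            n_pos = sum(lab[p] for p in part.test_ids)
            n_neg = len(part.test_ids) - n_pos
            assert n_pos == 11
            assert n_neg in (21, 22)

    def test_folds_disjoint_and_cover(self):
        ids, labels = _reference_labels()
        parts = make_cv_partitions(ids, labels, k=5, n_reps=2, seed=1)
        for rep in (0, 1):
            folds = [set(p.test_ids) for p in parts if p.repetition == rep]
            assert set().union(*folds) == set(ids)
            for i in range(5):
                for j in range(i + 1, 5):
                    assert not folds[i] & folds[j]
                train = next(p for p in parts
                             if p.repetition == rep and p.fold == i)
                assert not set(train.train_ids) & set(train.test_ids)

    def test_repetitions_differ(self):
        ids, labels = _reference_labels()
        parts = make_cv_partitions(ids, labels, k=5, n_reps=2, seed=2)
        f0 = set(next(p.test_ids[0] for p in parts if p.repetition == 0
                      and p.fold == f) for f in range(5))
        assert any(
            set(p1.test_ids) != set(p2.test_ids)
            for p1 in parts if p1.repetition == 0
            for p2 in parts if p2.repetition == 1 and p2.fold == p1.fold
        )

    def test_too_few_patients_per_class(self):
        with pytest.raises(ValueError):
            make_cv_partitions(["a", "b", "c"], [1, 0, 0], k=5, n_reps=1, seed=0)


class TestComputeRocPr:
    def test_perfect_separation(self):
        out = compute_roc_pr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert out["auroc"] == 100.0
        assert out["auprc"] == 100.0

    def test_reversed_scores(self):
        out = compute_roc_pr([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert out["auroc"] == 0.0

    def test_worked_four_instance_case(self):
        out = compute_roc_pr([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0])
        assert out["auroc"] == pytest.approx(75.0, abs=1e-9)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # with ties
            got = compute_roc_pr(scores, labels)["auroc"]
            assert got == pytest.approx(auroc_pair_counting(scores, labels),
                                        abs=1e-9)

    def test_constant_scores_auprc_equals_prevalence(self):
        labels = np.r_[np.ones(55, int), np.zeros(107, int)]
        out = compute_roc_pr(np.full(162, 0.5), labels)
        assert out["auprc"] == pytest.approx(100 * 55 / 162, abs=1e-9)
        assert out["auroc"] == pytest.approx(50.0, abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 0, 1
        scores = rng.random(50)
        a = compute_roc_pr(scores, labels)["auroc"]
        b = compute_roc_pr(np.exp(scores), labels)["auroc"]
        assert a == pytest.approx(b, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_roc_pr([0.1, 0.2], [1, 1])


class TestMetricsAtBestF1:
    def test_perfect_separation(self):
        m = metrics_at_best_f1([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m["f1"] == 100.0
        assert m["se"] == 100.0
        assert m["sp"] == 100.0

    def test_constant_scores_closed_form(self):
        labels = np.r_[np.ones(55, int), np.zeros(107, int)]
        m = metrics_at_best_f1(np.full(162, 0.3), labels)
        prev = 55 / 162
        assert m["f1"] == pytest.approx(100 * 2 * prev / (1 + prev), abs=1e-9)
        assert m["se"] == 100.0

    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(6, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice(np.linspace(0, 1, 7), size=n)
            got = metrics_at_best_f1(scores, labels)
            want = best_f1_sweep(scores, labels)
            for k in ("f1", "se", "sp", "precision", "threshold"):
                assert got[k] == pytest.approx(want[k], abs=1e-9)


class TestAggregation:
    def test_known_vector(self):
        df = pd.DataFrame({"auroc": [1.0, 2.0, 3.0]})
        agg = aggregate_median_iqr(df)
        assert agg["auroc"]["median"] == 2.0
        assert agg["auroc"]["iqr"] == 1.0

    def test_single_repetition_zero_iqr(self):
        agg = aggregate_median_iqr(pd.DataFrame({"f1": [7.0]}))
        assert agg["f1"]["median"] == 7.0
        assert agg["f1"]["iqr"] == 0.0

    def test_matches_quantile_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.random(17) * 100
        agg = aggregate_median_iqr(pd.DataFrame({"m": vals}))
        assert agg["m"]["median"] == pytest.approx(np.median(vals))
        q1, q3 = np.percentile(vals, [25, 75])
        assert agg["m"]["iqr"] == pytest.approx(q3 - q1)


class TestCompareFeatureSets:
    def _report(self, vals):
        from rearrest.evaluation import CvReport

        df = pd.DataFrame({"auroc": vals})
        return CvReport(per_repetition=df, aggregates=aggregate_median_iqr(df),
                        curves={})

    def test_null_distributions_large_p(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(30):
            a = self._report(rng.normal(60, 3, size=20))
            b = self._report(rng.normal(60, 3, size=20))
            ps.append(compare_feature_sets(a, b))
        assert np.median(ps) > 0.10

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(5)
        detected = 0
        for _ in range(40):
            a = self._report(rng.normal(60, 2, size=20))
            b = self._report(rng.normal(66, 2, size=20))  # 3 sd shift
            detected += compare_feature_sets(a, b) < 0.05
        assert detected >= 38

    def test_u_statistic_matches_bruteforce(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        assert u == mann_whitney_u_bruteforce(a, b)

    def test_too_few_repetitions_rejected(self):
        a = self._report(np.arange(5, dtype=float))
        with pytest.raises(ValueError):
            compare_feature_sets(a, a)


class TestRunRepeatedCv:
    def _table(self, rng, n=60, informative=True):
        y = np.zeros(n, int)
        y[: n // 3] = 1
        X = rng.normal(size=(n, 6))
        if informative:
            X[:, 0] += 3.0 * y
            X[:, 1] += 2.0 * y
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(1, 7)])
        df["patient_id"] = [f"p{i}" for i in range(n)]
        df["label"] = y
        return df

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(7)
        df = self._table(rng)
        rep = run_repeated_cv(df, [f"v{i}" for i in range(1, 7)], n_reps=3,
                              n_trees=100, seed=0)
        assert rep.aggregates["auroc"]["median"] >= 80.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        df = self._table(rng)
        r1 = run_repeated_cv(df, [f"v{i}" for i in range(1, 7)], n_reps=2,
                             n_trees=50, seed=3)
        r2 = run_repeated_cv(df, [f"v{i}" for i in range(1, 7)], n_reps=2,
                             n_trees=50, seed=3)
        pd.testing.assert_frame_equal(r1.per_repetition, r2.per_repetition)

    def test_missing_values_imputed_leakage_safe(self):
        rng = np.random.default_rng(9)
        df = self._table(rng)
        df.loc[df.index[:10], "v3"] = np.nan
        rep = run_repeated_cv(df, [f"v{i}" for i in range(1, 7)], n_reps=1,
                              n_trees=30, seed=0)
        assert np.isfinite(rep.aggregates["auroc"]["median"])

    def test_median_repetition_selection(self):
        from rearrest.evaluation import CvReport

        df = pd.DataFrame({"auroc": [60.0, 70.0, 66.0, 64.0]})
        rep = CvReport(per_repetition=df, aggregates=aggregate_median_iqr(df),
                       curves={})
        # median is 65; repetitions 2 and 3 tie at distance 1 -> lower index
        assert rep.median_repetition() == 2
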