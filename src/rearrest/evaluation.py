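"""Repeated stratified patient-wise cross-validation and curve metrics.

Patients are split into 5 folds with per-class round-robin dealing after a
within-class shuffle, so positive counts differ by at most one across folds
and no patient ever contributes to both train and test of a fold.  The
two-stage balanced random forest is fitted per training fold (with
training-fold median imputation), test scores are pooled across the five
folds of each repetition, and ROC / precision-recall curves, the areas under
them, and the operating point maximizing F1 are computed per repetition.
Repetitions are summarized as median (IQR).  All metrics are reported on a
0--100 percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import TwoStageRandomForest

METRIC_NAMES = ("se", "sp", "precision", "f1", "auroc", "auprc", "threshold")


@dataclass
class CvPartition:
    """One train/test split of one repetition."""

    repetition: int
    fold: int
    train_ids: np.ndarray
    test_ids: np.ndarray


@dataclass
class CvReport:
    """Per-repetition metrics/curves and their median (IQR) aggregates."""

    per_repetition: pd.DataFrame
    aggregates: Dict[str, Dict[str, float]]
    curves: Dict[int, Dict[str, np.ndarray]]
    config: Dict = field(default_factory=dict)

    def median_repetition(self, metric: str = "auroc") -> int:
        """Repetition whose metric is closest to the median (ties: lower index)."""
        vals = self.per_repetition[metric].to_numpy()
        med = float(np.median(vals))
        return int(np.argmin(np.abs(vals - med)))

    def to_dict(self) -> Dict:
        return {
            "config": self.config,
            "aggregates": self.aggregates,
            "per_repetition": {
                k: [float(v) for v in self.per_repetition[k]]
                for k in self.per_repetition.columns
            },
        }


def make_cv_partitions(
    patient_ids: Sequence, labels: Sequence[int], k: int = 5, n_reps: int = 100,
    seed: int = 0,
) -> List[CvPartition]:
    """Stratified patient-wise k-fold partitions, repeated with reshuffling.

    Within each class the patients are shuffled and dealt round-robin into
    the k folds, so per-fold class counts differ by at most one.
    """
    patient_ids = np.asarray(patient_ids)
    labels = np.asarray(labels).astype(int)
    for cls in (0, 1):
        if np.sum(labels == cls) < k:
            raise ValueError(f"class {cls} has fewer than {k} patients")
    rng = np.random.default_rng(seed)
    partitions: List[CvPartition] = []
    for rep in range(n_reps):
        fold_members: List[list] = [[] for _ in range(k)]
        for cls in (1, 0):
            members = patient_ids[labels == cls]
            shuffled = rng.permutation(members)
            for i, pid in enumerate(shuffled):
                fold_members[i % k].append(pid)
        for f in range(k):
            test = np.asarray(fold_members[f])
            train = np.asarray(
                [p for g in range(k) if g != f for p in fold_members[g]]
            )
            partitions.append(CvPartition(rep, f, train, test))
    return partitions


def compute_roc_pr(scores, labels, pr_rule: str = "conservative_step") -> Dict:
    """ROC and PR curves with AUROC (trapezoid) and AUPRC (step rule).

    Thresholds are the sorted unique scores; an instance is predicted
    positive when its score >= threshold.  Curves and areas are on the
    0--100 scale.

    The PR area is a rectangular step rule; ``pr_rule`` selects the variant:

    * ``"conservative_step"`` (default): each recall increment is weighted by
      the precision at the previous threshold (flat extension at zero
      recall).  This keeps the expected area of a random classifier at the
      class prevalence -- the upper-step rule counts each newly retrieved
      positive in its own precision and is biased upward by ~2 points at
      this cohort size.
    * ``"average_precision"``: the classical upper-step (AP) rule.

    Both avoid the documented optimism of PR trapezoids.
    """
    tp, fp, n_pos, n_neg = _confusion_path(scores, labels)
    tpr_a = np.concatenate([[0.0], tp / n_pos])
    fpr_a = np.concatenate([[0.0], fp / n_neg])
    auroc = float(np.trapezoid(tpr_a, fpr_a))
    rec_a = tp / n_pos
    with np.errstate(invalid="ignore"):
        prec_a = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 1.0)
    rec_prev = np.concatenate([[0.0], rec_a[:-1]])
    if pr_rule == "conservative_step":
        prec_w = np.concatenate([[prec_a[0]], prec_a[:-1]])
    elif pr_rule == "average_precision":
        prec_w = prec_a
    else:
        raise ValueError(f"unknown pr_rule {pr_rule!r}")
    auprc = float(np.sum((rec_a - rec_prev) * prec_w))
    return {
        "roc": np.column_stack([fpr_a * 100, tpr_a * 100]),
        "pr": np.column_stack([rec_a * 100, prec_a * 100]),
        "auroc": auroc * 100,
        "auprc": auprc * 100,
    }


def _confusion_path(scores, labels) -> tuple[np.ndarray, np.ndarray, int, int]:
    """TP/FP counts when predicting positive at >=threshold, per unique score.

    Thresholds run from the highest score down, so the counts are cumulative
    over instances sorted by decreasing score, evaluated at the last instance
    of each distinct score value.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to compute curves")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    boundary = np.nonzero(np.diff(s))[0]
    boundary = np.concatenate([boundary, [s.size - 1]])
    tp = np.cumsum(y)[boundary].astype(float)
    fp = boundary + 1.0 - tp
    return tp, fp, n_pos, n_neg


def metrics_at_best_f1(scores, labels) -> Dict[str, float]:
    """Operating-point metrics at the F1-maximizing threshold.

    Every unique score is tried as a >=-threshold; ties in F1 resolve toward
    the higher specificity.  Returns Se, Sp, precision and F1 in percent.
    """
    scores = np.asarray(scores, dtype=float)
    tp, fp, n_pos, n_neg = _confusion_path(scores, labels)
    se = tp / n_pos
    sp = (n_neg - fp) / n_neg
    with np.errstate(invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        denom = prec + se
        f1 = np.where(denom > 0, 2 * prec * se / np.maximum(denom, 1e-300), 0.0)
    # maximize F1; ties resolve toward the higher specificity
    best = max(range(f1.size), key=lambda i: (f1[i], sp[i]))
    thresholds = np.sort(np.unique(scores))[::-1]
    return {
        "se": float(se[best]) * 100,
        "sp": float(sp[best]) * 100,
        "precision": float(prec[best]) * 100,
        "f1": float(f1[best]) * 100,
        "threshold": float(thresholds[best]),
    }


def aggregate_median_iqr(per_rep: pd.DataFrame) -> Dict[str, Dict[str, float]]:
    """Median and interquartile range of each metric over repetitions."""
    out = {}
    for col in per_rep.columns:
        vals = per_rep[col].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[col] = {"median": float(med), "iqr": float(q3 - q1)}
    return out


def compare_feature_sets(report_a: CvReport, report_b: CvReport,
                         metric: str = "auroc") -> float:
    """Two-sided Mann-Whitney U on per-repetition metric distributions."""
    a = report_a.per_repetition[metric].to_numpy()
    b = report_b.per_repetition[metric].to_numpy()
    if a.size < 10 or b.size < 10:
        raise ValueError("need at least 10 repetitions per report")
    if a.size != b.size:
        import warnings

        warnings.warn("reports have unequal repetition counts", stacklevel=2)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _impute_train_median(train: np.ndarray, test: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Median imputation fitted on the training fold only (leakage-safe)."""
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    tr = np.where(np.isnan(train), med, train)
    te = np.where(np.isnan(test), med, test)
    return tr, te


def run_repeated_cv(
    features: pd.DataFrame,
    feature_columns: Sequence[str],
    k: int = 5,
    n_reps: int = 100,
    nf: Optional[int] = None,
    n_trees: int = 300,
    per_tree_fraction: float = 0.05,
    seed: int = 0,
    label_column: str = "label",
    id_column: str = "patient_id",
) -> CvReport:
    """Repeated stratified patient-wise CV of the two-stage balanced forest.

    Per fold: training-fold median imputation, two-stage fit on training
    patients only, likelihood scores for test patients.  Scores are pooled
    over the five folds of each repetition before curves and the
    F1-operating point are computed.
    """
    if features.shape[0] < 10:
        raise ValueError("need at least 10 patients")
    ids = features[id_column].to_numpy()
    labels = features[label_column].to_numpy().astype(int)
    X_all = features[list(feature_columns)].to_numpy(dtype=float)
    id_to_row = {pid: i for i, pid in enumerate(ids)}

    partitions = make_cv_partitions(ids, labels, k=k, n_reps=n_reps, seed=seed)
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.spawn(len(partitions))

    rows = []
    curves: Dict[int, Dict[str, np.ndarray]] = {}
    for rep in range(n_reps):
        pooled_scores = []
        pooled_labels = []
        for f in range(k):
            part = partitions[rep * k + f]
            tr_rows = np.asarray([id_to_row[p] for p in part.train_ids])
            te_rows = np.asarray([id_to_row[p] for p in part.test_ids])
            assert not set(part.train_ids) & set(part.test_ids), "patient leakage"
            y_tr = labels[tr_rows]
            if np.unique(y_tr).size < 2:
                raise ValueError("training fold with a single class")
            X_tr, X_te = _impute_train_median(X_all[tr_rows], X_all[te_rows])
            fold_seed = int(fold_seeds[rep * k + f].generate_state(1)[0] % (2**31 - 1))
            model = TwoStageRandomForest(
                nf=nf, n_trees=n_trees, per_tree_fraction=per_tree_fraction,
                random_state=fold_seed,
            ).fit(X_tr, y_tr)
            pooled_scores.append(model.predict_likelihood(X_te))
            pooled_labels.append(labels[te_rows])
        scores = np.concatenate(pooled_scores)
        y = np.concatenate(pooled_labels)
        cur = compute_roc_pr(scores, y)
        op = metrics_at_best_f1(scores, y)
        rows.append({**op, "auroc": cur["auroc"], "auprc": cur["auprc"]})
        curves[rep] = {"roc": cur["roc"], "pr": cur["pr"]}
    per_rep = pd.DataFrame(rows)
    return CvReport(
        per_repetition=per_rep,
        aggregates=aggregate_median_iqr(per_rep),
        curves=curves,
        config={
            "k": k, "n_reps": n_reps, "nf": nf, "n_trees": n_trees,
            "per_tree_fraction": per_tree_fraction, "seed": seed,
            "feature_columns": list(feature_columns),
        },
    )
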