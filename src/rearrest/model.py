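"""Class-balanced random forest and the univariate logistic baseline.

The forest is an ensemble of B unpruned CART trees, each grown on a tiny
bootstrap (5% of the training instances, drawn with replacement) that is
then balanced to exactly 50/50 by oversampling the minority class within the
bootstrap.  The fraction of trees voting positive is the rearrest
likelihood, so scores are multiples of 1/B.  Feature importance is the
classical out-of-bag permutation z-score: the mean increase in OOB error
after permuting a feature, divided by its SD over trees.  A two-stage
variant retrains on the top-Nf features of the first stage's ranking.

Everything is exposed as sklearn-style estimators (fit / predict /
predict_proba / get_params), so the models compose with sklearn pipelines
and model selection; the module-level functions are thin wrappers kept for
script use.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import sklearn
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y length mismatch")
    return X, y


class BalancedRandomForest(BaseEstimator, ClassifierMixin):
    """Random forest over balanced 5% bootstraps with OOB importance.

    Parameters
    ----------
    n_trees : int
        Ensemble size B; likelihoods are multiples of 1/B.
    per_tree_fraction : float
        Fraction of the training set drawn (with replacement) per tree
        before balancing.
    features_per_split : int or None
        Features examined at each split; ``None`` uses ceil(sqrt(p)).
    random_state : int
        Seed for bootstraps, balancing and tree construction.

    Attributes
    ----------
    trees_ : list of fitted DecisionTreeClassifier
    oob_indices_ : list of ndarray
        Instances absent from each tree's pre-oversampling bootstrap.
    feature_indices_ : ndarray
        Columns of the training matrix the model uses.
    """

    def __init__(
        self,
        n_trees: int = 300,
        per_tree_fraction: float = 0.05,
        features_per_split: Optional[int] = None,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.per_tree_fraction = per_tree_fraction
        self.features_per_split = features_per_split
        self.random_state = random_state

    def _balanced_bootstrap(self, y: np.ndarray, rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray]:
        """Draw the 5% bootstrap, then oversample the minority to 50/50.

        A bootstrap this small can miss a class entirely: redraw up to 50
        times, then force-include one random instance of the absent class.
        Returns (training indices incl. oversampling, pre-balance bootstrap).
        """
        n = y.size
        size = max(int(math.ceil(self.per_tree_fraction * n)), 2)
        for _ in range(50):
            boot = rng.integers(0, n, size=size)
            if np.unique(y[boot]).size == 2:
                break
        else:
            missing = 1 - int(y[boot[0]])
            pool = np.nonzero(y == missing)[0]
            boot = np.concatenate([boot[:-1], [rng.choice(pool)]])
        classes, counts = np.unique(y[boot], return_counts=True)
        n_max = counts.max()
        train = [boot]
        for cls, cnt in zip(classes, counts):
            if cnt < n_max:
                members = boot[y[boot] == cls]
                extra = rng.choice(members, size=n_max - cnt, replace=True)
                train.append(extra)
        return np.concatenate(train), boot

    def fit(self, X, y) -> "BalancedRandomForest":
        X, y = _as_xy(X, y)
        n, p = X.shape
        if n < 10:
            raise ValueError("need at least 10 training instances")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("y must contain both classes")
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute before fitting")
        rng = np.random.default_rng(self.random_state)
        mtry = self.features_per_split or int(math.ceil(math.sqrt(p)))
        mtry = min(mtry, p)

        self.classes_ = classes
        self.n_features_in_ = p
        self.feature_indices_ = np.arange(p)
        self.trees_ = []
        self.oob_indices_ = []
        all_idx = np.arange(n)
        # float32 + check_input=False skips sklearn's per-call validation,
        # which dominates runtime for hundreds of tiny trees
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        with sklearn.config_context(skip_parameter_validation=True):
            for b in range(self.n_trees):
                train_idx, boot = self._balanced_bootstrap(y, rng)
                tree = DecisionTreeClassifier(
                    criterion="gini",
                    max_features=mtry,
                    random_state=np.random.RandomState(int(rng.integers(0, 2**31 - 1))),
                )
                tree.fit(X32[train_idx], y[train_idx], check_input=False)
                self.trees_.append(tree)
                self.oob_indices_.append(
                    np.setdiff1d(all_idx, boot, assume_unique=False)
                )
        self._fit_X = X
        self._fit_y = y
        return self

    def _votes(self, X: np.ndarray) -> np.ndarray:
        """Per-tree positive votes, shape (n_trees, n_instances)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has shape {X.shape}, model expects (*, {self.n_features_in_})"
            )
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        return np.stack([
            t.predict(X32, check_input=False) == self.classes_[1]
            for t in self.trees_
        ])

    def predict_likelihood(self, X) -> np.ndarray:
        """Fraction of trees voting positive, per instance (multiples of 1/B)."""
        check_is_fitted(self, "trees_")
        return self._votes(X).mean(axis=0)

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.predict_likelihood(X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        """Majority vote; a 0.5 tie resolves to the negative class."""
        p1 = self.predict_likelihood(X)
        return np.where(p1 > 0.5, self.classes_[1], self.classes_[0])

    def permutation_importance(self, X=None, y=None) -> dict:
        """OOB permutation importance per feature.

        For each tree, the OOB misclassification error is compared before
        and after permuting one feature within the OOB rows; the importance
        is the mean increase over trees divided by its SD (0 when the SD is
        0).  The raw mean increase is returned alongside.
        """
        check_is_fitted(self, "trees_")
        X = self._fit_X if X is None else np.asarray(X, dtype=float)
        y = self._fit_y if y is None else np.asarray(y).astype(int)
        if all(oob.size == 0 for oob in self.oob_indices_):
            raise ValueError("no out-of-bag instances retained; cannot compute importance")
        p = X.shape[1]
        rng = np.random.default_rng(self.random_state + 1)
        increases = np.full((len(self.trees_), p), np.nan)
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        for t_idx, (tree, oob) in enumerate(zip(self.trees_, self.oob_indices_)):
            if oob.size == 0:
                continue
            Xo, yo = X32[oob], y[oob]
            n_oob = oob.size
            perm = rng.permutation(n_oob)
            # one batched predict per tree: base matrix plus one permuted
            # copy per feature, stacked row-wise
            stack = np.tile(Xo, (p + 1, 1))
            for j in range(p):
                stack[(j + 1) * n_oob:(j + 2) * n_oob, j] = Xo[perm, j]
            pred = tree.predict(np.ascontiguousarray(stack), check_input=False)
            errs = (pred.reshape(p + 1, n_oob) != yo[None, :]).mean(axis=1)
            increases[t_idx, :] = errs[1:] - errs[0]
        mean_inc = np.nanmean(increases, axis=0)
        sd_inc = np.nanstd(increases, axis=0, ddof=1)
        z = np.where(sd_inc > 0, mean_inc / np.where(sd_inc > 0, sd_inc, 1.0), 0.0)
        # zero-variance features can never change a prediction
        const = np.all(X == X[0:1, :], axis=0)
        z[const] = 0.0
        return {"importance": z, "mean_increase": mean_inc, "sd_increase": sd_inc}


class TwoStageRandomForest(BaseEstimator, ClassifierMixin):
    """Train, rank features by OOB permutation importance, retrain on top Nf.

    Stage 1 fits a :class:`BalancedRandomForest` on all features and ranks
    them by importance (ties broken toward the lower feature index); stage 2
    refits on the ``nf`` best.  Scoring uses the stage-2 model only.
    """

    def __init__(
        self,
        nf: Optional[int] = None,
        n_trees: int = 300,
        per_tree_fraction: float = 0.05,
        features_per_split: Optional[int] = None,
        random_state: int = 0,
    ):
        self.nf = nf
        self.n_trees = n_trees
        self.per_tree_fraction = per_tree_fraction
        self.features_per_split = features_per_split
        self.random_state = random_state

    def fit(self, X, y) -> "TwoStageRandomForest":
        X, y = _as_xy(X, y)
        p = X.shape[1]
        nf = p if self.nf is None else self.nf
        if not (1 <= nf <= p):
            raise ValueError(f"nf must lie in [1, {p}]")
        ss = np.random.SeedSequence(self.random_state)
        s1, s2 = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
        stage1 = BalancedRandomForest(
            self.n_trees, self.per_tree_fraction, self.features_per_split, s1
        ).fit(X, y)
        imp = stage1.permutation_importance()["importance"]
        # stable sort descending; ties keep the lower feature index first
        order = np.argsort(-imp, kind="stable")
        self.ranking_ = order
        self.importances_ = imp
        self.selected_features_ = np.sort(order[:nf])
        self.stage1_ = stage1
        self.model_ = BalancedRandomForest(
            self.n_trees, self.per_tree_fraction, self.features_per_split, s2
        ).fit(X[:, self.selected_features_], y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = p
        return self

    def predict_likelihood(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        return self.model_.predict_likelihood(X[:, self.selected_features_])

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.predict_likelihood(X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p1 = self.predict_likelihood(X)
        return np.where(p1 > 0.5, self.classes_[1], self.classes_[0])


class UnivariateLogistic(BaseEstimator, ClassifierMixin):
    """Cost-sensitive logistic regression on a single feature.

    Class weights are inversely proportional to class frequencies.  A
    constant feature is degenerate: the model is flagged and returns
    chance-level scores (0.5).
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, x, y) -> "UnivariateLogistic":
        x = np.asarray(x, dtype=float).reshape(-1, 1)
        y = np.asarray(y).astype(int)
        if np.unique(y).size != 2:
            raise ValueError("y must contain both classes")
        self.degenerate_ = bool(np.all(x == x[0]))
        if not self.degenerate_:
            self.model_ = LogisticRegression(
                class_weight="balanced", random_state=self.random_state
            ).fit(x, y)
            self.coef_ = float(self.model_.coef_[0, 0])
        self.classes_ = np.unique(y)
        return self

    def predict_likelihood(self, x) -> np.ndarray:
        check_is_fitted(self, "degenerate_")
        x = np.asarray(x, dtype=float).reshape(-1, 1)
        if self.degenerate_:
            return np.full(x.shape[0], 0.5)
        return self.model_.predict_proba(x)[:, 1]

    def predict_proba(self, x) -> np.ndarray:
        p1 = self.predict_likelihood(x)
        return np.column_stack([1 - p1, p1])

    def predict(self, x) -> np.ndarray:
        return (self.predict_likelihood(x) > 0.5).astype(int)


# ---------------------------------------------------------------------------
# thin functional wrappers


def train_rf(X, y, n_trees: int = 300, per_tree_fraction: float = 0.05,
             features_per_split: Optional[int] = None, seed: int = 0
             ) -> BalancedRandomForest:
    return BalancedRandomForest(n_trees, per_tree_fraction, features_per_split, seed).fit(X, y)


def predict_likelihood(model, X) -> np.ndarray:
    return model.predict_likelihood(X)


def permutation_importance(model: BalancedRandomForest, X=None, y=None) -> np.ndarray:
    return model.permutation_importance(X, y)["importance"]


def select_and_retrain(X, y, nf: Optional[int] = None, n_trees: int = 300,
                       per_tree_fraction: float = 0.05, seed: int = 0
                       ) -> TwoStageRandomForest:
    return TwoStageRandomForest(nf, n_trees, per_tree_fraction, None, seed).fit(X, y)


def fit_univariate_logistic(x, y, seed: int = 0) -> UnivariateLogistic:
    return UnivariateLogistic(seed).fit(x, y)
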