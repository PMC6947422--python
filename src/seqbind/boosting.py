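"""Gradient-boosted trees with a regularized second-order objective.

The additive model is ``margin(x) = base + eta * sum_k f_k(x)`` with binary
logistic loss; each regression tree is grown greedily with the exact split
search.  For a leaf with gradient sums ``G = sum g_i`` and ``H = sum h_i``
(logistic loss: ``g_i = p_i - y_i``, ``h_i = p_i (1 - p_i)``):

* optimal leaf weight     ``w* = -G / (H + lambda)``
* tree objective          ``-1/2 sum_j G_j^2 / (H_j + lambda) + gamma * T``
* split gain              ``1/2 [G_L^2/(H_L+l) + G_R^2/(H_R+l)
                          - (G_L+G_R)^2/(H_L+H_R+l)] - gamma``

These primitives are exposed directly (:func:`leaf_weight`,
:func:`tree_objective`, :func:`split_gain`) and used by the pure-Python
exact-greedy reference trainer.  Full-scale training can delegate to the
xgboost backend, which optimizes the identical objective; the reference
trainer is the ground truth the backend is checked against on small
instances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .dataset import LabeledDataset


@dataclass
class SplitStats:
    """Gradient statistics of a sample set (one leaf or one split side)."""

    g_sum: float
    h_sum: float
    count: int = 0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")

    def __add__(self, other: "SplitStats") -> "SplitStats":
        return SplitStats(self.g_sum + other.g_sum,
                          self.h_sum + other.h_sum,
                          self.count + other.count)


def leaf_weight(s: SplitStats, lambda_l2: float) -> float:
    """Optimal leaf weight ``-G / (H + lambda)``."""
    denom = s.h_sum + lambda_l2
    if denom <= 0:
        raise ValueError(f"h_sum + lambda must be > 0, got {denom}")
    return -s.g_sum / denom


def tree_objective(leaves: list[SplitStats], lambda_l2: float,
                   gamma: float) -> float:
    """Structure score of a tree: ``-1/2 sum G^2/(H+lambda) + gamma*T``."""
    total = 0.0
    for s in leaves:
        denom = s.h_sum + lambda_l2
        if denom <= 0:
            raise ValueError(f"h_sum + lambda must be > 0, got {denom}")
        total += s.g_sum**2 / denom
    return -0.5 * total + gamma * len(leaves)


def split_gain(left: SplitStats, right: SplitStats, lambda_l2: float,
               gamma: float) -> float:
    """Loss reduction of splitting a parent into (left, right); a useless
    split costs exactly ``gamma`` (the price of the extra leaf)."""
    parent = left + right
    for s in (left, right, parent):
        if s.h_sum + lambda_l2 <= 0:
            raise ValueError("h_sum + lambda must be > 0 on both sides")
    return 0.5 * (left.g_sum**2 / (left.h_sum + lambda_l2)
                  + right.g_sum**2 / (right.h_sum + lambda_l2)
                  - parent.g_sum**2 / (parent.h_sum + lambda_l2)) - gamma


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


# ---------------------------------------------------------------------------
# Reference exact-greedy trainer
# ---------------------------------------------------------------------------

def _grow_tree(X, g, h, rows, features, depth, max_depth, lambda_l2, gamma):
    """Recursive exact-greedy tree construction.

    Thresholds are midpoints between distinct sorted feature values, so tied
    values can never be separated.  Ties in gain break toward the lowest
    feature index, then the lowest threshold.  Returns a nested dict:
    ``{"leaf": w}`` or ``{"feature", "threshold", "left", "right"}``.
    """
    stats = SplitStats(float(g[rows].sum()), float(h[rows].sum()), rows.size)
    leaf = {"leaf": leaf_weight(stats, lambda_l2)}
    if depth >= max_depth or rows.size < 2:
        return leaf

    best_gain = 0.0
    best = None  # (feature, threshold, left_rows, right_rows)
    for f in features:
        vals = X[rows, f]
        order = np.argsort(vals, kind="stable")
        sv = vals[order]
        sg = g[rows][order]
        sh = h[rows][order]
        cg = np.cumsum(sg)
        ch = np.cumsum(sh)
        # candidate split after position i (0-based) where value changes
        change = np.flatnonzero(sv[1:] != sv[:-1])
        for i in change:
            left = SplitStats(float(cg[i]), float(ch[i]), i + 1)
            right = SplitStats(float(cg[-1] - cg[i]), float(ch[-1] - ch[i]),
                               rows.size - i - 1)
            gain = split_gain(left, right, lambda_l2, gamma)
            thr = 0.5 * (sv[i] + sv[i + 1])
            if gain > best_gain + 1e-12 or (
                best is not None
                and abs(gain - best_gain) <= 1e-12
                and (f, thr) < (best[0], best[1])
            ):
                best_gain = gain
                best = (f, thr, rows[order[: i + 1]], rows[order[i + 1:]])
    if best is None:
        return leaf
    f, thr, lrows, rrows = best
    return {
        "feature": int(f),
        "threshold": float(thr),
        "gain": float(best_gain),
        "left": _grow_tree(X, g, h, lrows, features, depth + 1, max_depth,
                           lambda_l2, gamma),
        "right": _grow_tree(X, g, h, rrows, features, depth + 1, max_depth,
                            lambda_l2, gamma),
    }


def _tree_predict(node: dict, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    idx = np.arange(X.shape[0])

    def rec(nd, rows):
        if "leaf" in nd:
            out[rows] = nd["leaf"]
            return
        mask = X[rows, nd["feature"]] <= nd["threshold"]
        rec(nd["left"], rows[mask])
        rec(nd["right"], rows[~mask])

    rec(node, idx)
    return out


class GradientBoostedTreesClassifier(ClassifierMixin, BaseEstimator):
    """Binary boosted-tree classifier with an L2/complexity-regularized
    second-order objective.

    Parameters
    ----------
    n_estimators : int, default 100
        Number of boosting rounds K.
    learning_rate : float in (0, 1], default 0.1
        Shrinkage eta applied to each tree's contribution.
    max_depth : int, default 4
        Maximum tree depth.
    reg_lambda : float >= 0, default 1.0
        L2 penalty on leaf weights.
    gamma : float >= 0, default 0.0
        Per-leaf complexity penalty; the minimum gain a split must earn.
    subsample, colsample_bytree : float in (0, 1], default 1.0
        Per-tree row / feature subsampling fractions.
    base_score : float or None
        Initial probability; ``None`` uses the training prevalence
        (logit 0 on a balanced set).
    backend : {"reference", "xgboost"}, default "reference"
        "reference" is the exact-greedy pure-Python trainer; "xgboost"
        delegates fitting to xgboost with the matched objective (use it for
        anything beyond toy sizes).
    random_state : int or None
        Seed for subsampling (and the backend).

    Attributes
    ----------
    classes_ : (2,) array
    trees_ : list of nested-dict trees (reference backend)
    base_score_ : float, the initial probability
    n_features_in_ : int
    """

    def __init__(self, n_estimators: int = 100, learning_rate: float = 0.1,
                 max_depth: int = 4, reg_lambda: float = 1.0,
                 gamma: float = 0.0, subsample: float = 1.0,
                 colsample_bytree: float = 1.0, base_score: float | None = None,
                 backend: str = "reference", random_state: int | None = None):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.reg_lambda = reg_lambda
        self.gamma = gamma
        self.subsample = subsample
        self.colsample_bytree = colsample_bytree
        self.base_score = base_score
        self.backend = backend
        self.random_state = random_state

    # -- validation ---------------------------------------------------------
    def _check_params(self):
        if self.n_estimators < 0:
            raise ValueError("n_estimators must be >= 0")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.reg_lambda < 0 or self.gamma < 0:
            raise ValueError("reg_lambda and gamma must be >= 0")
        for name in ("subsample", "colsample_bytree"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.backend not in ("reference", "xgboost"):
            raise ValueError(f"unknown backend {self.backend!r}")

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y):
        self._check_params()
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"binary labels required, got classes {self.classes_.tolist()}"
            )
        yb = (y == self.classes_[1]).astype(float)
        self.n_features_in_ = X.shape[1]
        prev = float(yb.mean())
        self.base_score_ = prev if self.base_score is None else float(self.base_score)
        if self.backend == "xgboost":
            self._fit_xgboost(X, yb)
        else:
            self._fit_reference(X, yb)
        return self

    def _fit_reference(self, X, y):
        rng = np.random.default_rng(self.random_state)
        n, d = X.shape
        base_margin = _logit(self.base_score_)
        margin = np.full(n, base_margin)
        self.trees_ = []
        for _ in range(self.n_estimators):
            p = _sigmoid(margin)
            g = p - y
            h = p * (1 - p)
            rows = np.arange(n)
            if self.subsample < 1.0:
                m = max(1, int(round(self.subsample * n)))
                rows = np.sort(rng.choice(n, size=m, replace=False))
            feats = np.arange(d)
            if self.colsample_bytree < 1.0:
                m = max(1, int(round(self.colsample_bytree * d)))
                feats = np.sort(rng.choice(d, size=m, replace=False))
            tree = _grow_tree(X, g, h, rows, feats, 0, self.max_depth,
                              self.reg_lambda, self.gamma)
            self.trees_.append(tree)
            margin += self.learning_rate * _tree_predict(tree, X)
        return self

    def _fit_xgboost(self, X, y):
        import xgboost as xgb

        self._xgb_ = xgb.XGBClassifier(
            n_estimators=max(self.n_estimators, 1),
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            reg_lambda=self.reg_lambda,
            gamma=self.gamma,
            subsample=self.subsample,
            colsample_bytree=self.colsample_bytree,
            min_child_weight=0,
            tree_method="exact",
            objective="binary:logistic",
            base_score=self.base_score_,
            n_jobs=1,
            random_state=0 if self.random_state is None else int(self.random_state),
        )
        if self.n_estimators == 0:
            # keep a constant model: one tree with zero learning rate
            self._xgb_.set_params(n_estimators=1, learning_rate=0.0)
        self._xgb_.fit(X, y.astype(int))

    # -- prediction ---------------------------------------------------------
    def decision_function(self, X):
        """Ensemble margin (log-odds)."""
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was trained with "
                f"{self.n_features_in_}"
            )
        if self.backend == "xgboost":
            raw = self._xgb_.get_booster().inplace_predict(
                X, predict_type="margin")
            return np.asarray(raw, dtype=float)
        margin = np.full(X.shape[0], _logit(self.base_score_))
        for tree in self.trees_:
            margin += self.learning_rate * _tree_predict(tree, X)
        return margin

    def predict_proba(self, X):
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        """Self-describing tree dump: predictions are reproducible from the
        dump alone, without the training backend."""
        check_is_fitted(self)
        if self.backend == "xgboost":
            trees = [json.loads(t)
                     for t in self._xgb_.get_booster().get_dump(dump_format="json")]
            trees = [_from_xgb_node(t) for t in trees]
            scale = 1.0  # xgboost leaf values already include the shrinkage
        else:
            trees = self.trees_
            scale = self.learning_rate
        return json.dumps({
            "base_score": self.base_score_,
            "leaf_scale": scale,
            "classes": self.classes_.tolist(),
            "n_features": int(self.n_features_in_),
            "params": self.get_params(),
            "trees": trees,
        })

    @classmethod
    def from_json(cls, payload: str) -> "GradientBoostedTreesClassifier":
        obj = json.loads(payload)
        params = {k: v for k, v in obj["params"].items()}
        params["backend"] = "reference"
        model = cls(**params)
        model.base_score_ = obj["base_score"]
        model.classes_ = np.asarray(obj["classes"])
        model.n_features_in_ = obj["n_features"]
        model.trees_ = obj["trees"]
        model.learning_rate = obj["leaf_scale"]
        return model


def _from_xgb_node(node: dict) -> dict:
    """Convert an xgboost JSON dump node to the reference tree layout.

    xgboost routes ``x < threshold`` to the ``yes`` child; the reference
    layout routes ``x <= threshold`` left.  Nudging the threshold down by one
    ulp makes the two rules agree for every representable input.
    """
    if "leaf" in node:
        return {"leaf": float(node["leaf"])}
    thr = float(node["split_condition"])
    kids = {c["nodeid"]: c for c in node["children"]}
    return {
        "feature": int(str(node["split"]).lstrip("f")),
        "threshold": float(np.nextafter(thr, -np.inf)),
        "left": _from_xgb_node(kids[node["yes"]]),
        "right": _from_xgb_node(kids[node["no"]]),
    }


def fit_gbt(train: LabeledDataset, **params) -> GradientBoostedTreesClassifier:
    """Fit a boosted-tree model on a labelled dataset (functional wrapper)."""
    model = GradientBoostedTreesClassifier(**params)
    return model.fit(train.X, train.y)


def predict_proba(model: GradientBoostedTreesClassifier, X) -> np.ndarray:
    """Probability of the binding class for each row."""
    return model.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

DEFAULT_GRID = [
    {"max_depth": d, "learning_rate": lr, "n_estimators": k,
     "subsample": s, "colsample_bytree": c}
    for d in range(3, 9)
    for lr in (0.05, 0.1, 0.3)
    for k in (100, 300, 500)
    for s in (0.8, 1.0)
    for c in (0.8, 1.0)
]


def grid_search_cv(train: LabeledDataset, grid: list[dict] | None = None,
                   folds: int = 5, metric: str = "auc",
                   seed: int | None = None, balancer=None,
                   backend: str = "xgboost"):
    """Stratified k-fold grid search; balancing is applied inside each fold's
    training split only (never to the validation split).

    Returns ``(best_params, scores)`` where ``scores`` is a list of
    ``(params, mean_metric, per_fold)`` in grid order.  Ties break toward
    fewer trees, then shallower depth, then grid order.
    """
    from .evaluation import roc_auc, select_threshold

    if grid is None:
        grid = DEFAULT_GRID
    if not grid:
        raise ValueError("empty parameter grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if metric not in ("auc", "mcc_max"):
        raise ValueError(f"unknown metric {metric!r}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(train.X, train.y))
    for tr, va in splits:
        if np.unique(train.y[va]).size < 2 or np.unique(train.y[tr]).size < 2:
            raise ValueError(
                "a fold contains a single class; use stratified folds and "
                "check the minority count"
            )

    scores = []
    for params in grid:
        fold_scores = []
        for tr, va in splits:
            ds_tr = train.subset(tr)
            if balancer is not None:
                ds_tr = balancer(ds_tr)
            model = GradientBoostedTreesClassifier(
                backend=backend, random_state=seed, **params)
            model.fit(ds_tr.X, ds_tr.y)
            s = model.predict_proba(train.X[va])[:, 1]
            if metric == "auc":
                fold_scores.append(roc_auc(s, train.y[va]))
            else:
                _, rep = select_threshold(s, train.y[va], criterion="max_mcc")
                fold_scores.append(rep.mcc)
        scores.append((params, float(np.mean(fold_scores)), fold_scores))

    def sort_key(item):
        i, (params, mean, _) = item
        return (-mean, params.get("n_estimators", 0),
                params.get("max_depth", 0), i)

    best_idx = min(enumerate(scores), key=sort_key)[0]
    return scores[best_idx][0], scores
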