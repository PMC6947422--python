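"""Residue-level evaluation: confusion metrics, ROC/AUC, threshold moving
and the cross-validation protocol.

Metrics follow the usual confusion-matrix definitions::

    SN  = TP / (TP + FN)                 (sensitivity / recall, %)
    SP  = TN / (TN + FP)                 (specificity, %)
    ACC = (TP + TN) / n                  (%)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

A residue is called binding when its score is >= the threshold.  Because the
classes are heavily imbalanced, the operating threshold is chosen post hoc
("threshold moving"): maximize MCC, balance SN against SP, or cap the
false-positive rate at a given level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .dataset import LabeledDataset


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def positives(self) -> int:
        return self.TP + self.FN

    @property
    def negatives(self) -> int:
        return self.TN + self.FP


@dataclass
class EvalReport:
    """Threshold, percent metrics, MCC/AUC and the underlying counts."""

    threshold: float
    sn: float  # %
    sp: float  # %
    acc: float  # %
    mcc: float
    auc: float | None
    counts: ConfusionCounts
    criterion: str = "fixed"
    mcc_defined: bool = True

    def to_dict(self) -> dict:
        d = {
            "threshold": self.threshold,
            "SN": self.sn, "SP": self.sp, "ACC": self.acc,
            "MCC": self.mcc, "AUC": self.auc,
            "TP": self.counts.TP, "FP": self.counts.FP,
            "TN": self.counts.TN, "FN": self.counts.FN,
            "criterion": self.criterion,
            "mcc_defined": self.mcc_defined,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def __str__(self) -> str:  # display precision: 1 decimal on percentages
        auc = "-" if self.auc is None else f"{self.auc:.3f}"
        return (f"T={self.threshold:.3f} SN={self.sn:.1f}% SP={self.sp:.1f}% "
                f"ACC={self.acc:.1f}% MCC={self.mcc:.3f} AUC={auc}")


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    """Counts under the convention: predicted binding iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError(
            f"scores ({scores.shape}) and labels ({labels.shape}) differ"
        )
    if scores.size == 0:
        raise ValueError("empty inputs")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def metrics(c: ConfusionCounts, threshold: float = 0.5, auc: float | None = None,
            criterion: str = "fixed") -> EvalReport:
    """Exact formula evaluation; full precision kept internally.

    MCC with a zero denominator (an empty marginal) is reported as 0 with
    ``mcc_defined=False``.
    """
    nP, nN = c.positives, c.negatives
    if nP == 0 or nN == 0:
        raise ValueError("need at least one positive and one negative")
    sn = 100.0 * c.TP / nP
    sp = 100.0 * c.TN / nN
    acc = 100.0 * (c.TP + c.TN) / (nP + nN)
    # integer arithmetic keeps the product exact before the single sqrt
    prod = nP * nN * (c.TP + c.FP) * (c.TN + c.FN)
    if prod == 0:
        mcc, defined = 0.0, False
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(prod)
        defined = True
    return EvalReport(threshold=threshold, sn=sn, sp=sp, acc=acc, mcc=mcc,
                      auc=auc, counts=c, criterion=criterion,
                      mcc_defined=defined)


def counts_from_rates(sn_pct: float, sp_pct: float, nP: int, nN: int) -> ConfusionCounts:
    """Reconstruct integer counts from printed SN/SP percentages and class
    sizes (rounding to the nearest count)."""
    if not (0 <= sn_pct <= 100 and 0 <= sp_pct <= 100):
        raise ValueError("rates must lie in [0, 100]")
    TP = round(sn_pct * nP / 100.0)
    TN = round(sp_pct * nN / 100.0)
    return ConfusionCounts(TP=TP, FP=nN - TN, TN=TN, FN=nP - TP)


def roc_auc(scores, labels) -> float:
    """AUC in the Mann-Whitney formulation (ties credited 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores plus sentinels at the ends
    (everything-positive and everything-negative)."""
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    lo = distinct[0]                      # >= min: all positive
    hi = np.nextafter(distinct[-1], np.inf)  # above max: all negative
    return np.concatenate([[lo], mids, [hi]])


def select_threshold(scores, labels, criterion: str = "max_mcc",
                     alpha: float = 0.05) -> tuple[float, EvalReport]:
    """Threshold moving over every candidate cutoff.

    criterion:
      * ``max_mcc``     — argmax MCC; ties toward the higher threshold.
      * ``sen_eq_spec`` — minimize \\|SN - SP\\|; ties toward the higher threshold.
      * ``fpr_at``      — among thresholds with FPR <= ``alpha``, maximize SN;
        ties toward the higher threshold (lower FPR).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("threshold selection needs both classes present")
    auc = roc_auc(scores, labels)
    best_key = None
    best: tuple[float, EvalReport] | None = None
    for t in _candidate_thresholds(scores):
        rep = metrics(confusion(scores, labels, t), threshold=float(t), auc=auc,
                      criterion=criterion)
        fpr = 100.0 - rep.sp
        if criterion == "max_mcc":
            key = (rep.mcc, t)
        elif criterion == "sen_eq_spec":
            key = (-abs(rep.sn - rep.sp), t)
        elif criterion == "fpr_at":
            if fpr > 100.0 * alpha:
                continue
            key = (rep.sn, t)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if best_key is None or key > best_key:
            best_key, best = key, (float(t), rep)
    if best is None:  # fpr_at: the all-negative sentinel always qualifies
        raise AssertionError("no candidate threshold satisfied the criterion")
    return best


def evaluate(scores, labels, threshold: float | None = 0.5,
             criterion: str = "fixed", alpha: float = 0.05) -> EvalReport:
    """Evaluate at a fixed threshold or at a criterion-selected one."""
    if criterion == "fixed":
        auc = roc_auc(scores, labels)
        return metrics(confusion(scores, labels, threshold), threshold=threshold,
                       auc=auc, criterion="fixed")
    _, rep = select_threshold(scores, labels, criterion=criterion, alpha=alpha)
    return rep


def roc_points(scores, labels) -> list[tuple[float, float, float]]:
    """(threshold, FPR, TPR) swept over every candidate threshold."""
    out = []
    for t in _candidate_thresholds(np.asarray(scores, dtype=float)):
        c = confusion(scores, labels, t)
        out.append((float(t), c.FP / c.negatives, c.TP / c.positives))
    return out


# ---------------------------------------------------------------------------
# Cross-validation protocol
# ---------------------------------------------------------------------------

def kfold_cv(ds: LabeledDataset, k: int = 5, make_model=None, balancer=None,
             criterion: str = "max_mcc", threshold: float = 0.5,
             n_replicates: int = 1, seed: int | None = None,
             grouped: bool | None = None) -> dict:
    """Stratified k-fold cross-validation with in-fold balancing.

    * folds are stratified by class, and grouped by protein id when
      ``group_ids`` are present (a protein never straddles folds);
    * ``balancer`` (a callable dataset -> dataset, e.g. a SMOTE or RUS
      wrapper) is applied to each fold's TRAINING portion only;
    * repeated over ``n_replicates`` seeds and averaged, since both the
      balancing and the trainer are stochastic.

    Returns a dict with per-replicate fold reports, pooled reports (scores
    pooled over folds, threshold re-selected on the pool), and the means of
    the pooled metrics across replicates.
    """
    from .boosting import GradientBoostedTreesClassifier

    if make_model is None:
        def make_model(rep_seed):
            return GradientBoostedTreesClassifier(backend="xgboost",
                                                  random_state=rep_seed)
    if grouped is None:
        grouped = ds.group_ids is not None and len(set(ds.group_ids)) >= k
    rng = np.random.default_rng(seed)
    replicates = []
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if grouped:
            skf = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                       random_state=rep_seed)
            splits = skf.split(ds.X, ds.y, groups=ds.group_ids)
        else:
            skf = StratifiedKFold(n_splits=k, shuffle=True,
                                  random_state=rep_seed)
            splits = skf.split(ds.X, ds.y)
        fold_reports = []
        pooled_scores = np.empty(ds.n_rows)
        for tr, va in splits:
            if np.unique(ds.y[va]).size < 2:
                raise ValueError(
                    "a validation fold lacks one class; too few positives "
                    "for this k"
                )
            ds_tr = ds.subset(tr)
            if balancer is not None:
                ds_tr = balancer(ds_tr, rep_seed)
            model = make_model(rep_seed)
            model.fit(ds_tr.X, ds_tr.y)
            s = model.predict_proba(ds.X[va])[:, 1]
            pooled_scores[va] = s
            fold_reports.append(
                evaluate(s, ds.y[va], threshold=threshold, criterion=criterion))
        pooled = evaluate(pooled_scores, ds.y, threshold=threshold,
                          criterion=criterion)
        fixed_pooled = evaluate(pooled_scores, ds.y, threshold=threshold,
                                criterion="fixed")
        replicates.append({
            "seed": rep_seed,
            "folds": fold_reports,
            "pooled": pooled,
            "pooled_fixed": fixed_pooled,
        })
    mean = {
        key: float(np.mean([getattr(r["pooled"], key) for r in replicates]))
        for key in ("sn", "sp", "acc", "mcc", "auc")
    }
    return {"replicates": replicates, "mean_pooled": mean, "k": k,
            "grouped": grouped}
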