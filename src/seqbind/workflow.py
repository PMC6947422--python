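"""End-to-end convenience wrappers: simulate -> features -> balance ->
train -> evaluate.

These are the building blocks the command line drives; they are also handy
for calibration studies on synthetic data.
"""

from __future__ import annotations

import numpy as np

from .boosting import GradientBoostedTreesClassifier
from .dataset import LabeledDataset
from .evaluation import EvalReport, evaluate
from .features import FeatureConfig, assemble_many
from .sampling import RandomUnderSampler, SMOTESampler
from .simulate import SimConfig, simulate_dataset


def split_by_protein(ds: LabeledDataset, test_fraction: float = 0.3,
                     seed: int | None = None) -> tuple[LabeledDataset, LabeledDataset]:
    """Grouped train/test split: whole proteins go to one side or the other."""
    if ds.group_ids is None:
        raise ValueError("dataset has no protein ids to group by")
    rng = np.random.default_rng(seed)
    ids = np.array(sorted(set(ds.group_ids)))
    rng.shuffle(ids)
    n_test = max(1, int(round(test_fraction * ids.size)))
    test_ids = set(ids[:n_test].tolist())
    mask = np.array([g in test_ids for g in ds.group_ids])
    return ds.subset(np.flatnonzero(~mask)), ds.subset(np.flatnonzero(mask))


def make_balancer(kind: str | None, target_per_class: int = 19000,
                  k_neighbors: int = 5, replace_majority: bool = False):
    """A callable ``(dataset, seed) -> balanced dataset`` or None."""
    if kind in (None, "none"):
        return None
    if kind == "smote":
        def bal(ds, seed=None):
            return SMOTESampler(target_per_class=target_per_class,
                                k_neighbors=k_neighbors,
                                random_state=seed,
                                replace_majority=replace_majority).fit_resample(ds)
        return bal
    if kind == "rus":
        def bal(ds, seed=None):
            return RandomUnderSampler(random_state=seed).fit_resample(ds)
        return bal
    raise ValueError(f"unknown balancing scheme {kind!r}")


def train_and_evaluate(train: LabeledDataset, test: LabeledDataset,
                       balance: str | None = "smote",
                       target_per_class: int | None = None,
                       model_params: dict | None = None,
                       criterion: str = "fixed", threshold: float = 0.5,
                       seed: int | None = None) -> tuple[EvalReport,
                                                         GradientBoostedTreesClassifier]:
    """Balance the training set, fit the booster, evaluate on the test set.

    ``target_per_class=None`` with SMOTE balances to the training majority
    count capped at 19,000 (so small synthetic runs need no replacement).
    """
    counts = train.class_counts()
    if balance == "smote":
        maj = max(counts.values())
        tgt = min(maj, 19000) if target_per_class is None else target_per_class
        balancer = make_balancer("smote", target_per_class=tgt)
    else:
        balancer = make_balancer(balance)
    ds_bal = train if balancer is None else balancer(train, seed)
    params = {"backend": "xgboost", "n_estimators": 100, "max_depth": 4,
              "learning_rate": 0.1}
    params.update(model_params or {})
    model = GradientBoostedTreesClassifier(random_state=seed, **params)
    model.fit(ds_bal.X, ds_bal.y)
    scores = model.predict_proba(test.X)[:, 1]
    report = evaluate(scores, test.y, threshold=threshold, criterion=criterion)
    return report, model


def simulated_run(sim_cfg: SimConfig | None = None,
                  feat_cfg: FeatureConfig | None = None,
                  balance: str | None = "smote",
                  target_per_class: int | None = None,
                  model_params: dict | None = None,
                  test_fraction: float = 0.3,
                  seed: int | None = None) -> EvalReport:
    """One full synthetic experiment; returns the test-set report (threshold
    0.5; the AUC field is threshold-free)."""
    sim_cfg = sim_cfg or SimConfig()
    records, pssms, psas = simulate_dataset(sim_cfg)
    ds = assemble_many(records, pssms, psas, feat_cfg or FeatureConfig())
    train, test = split_by_protein(ds, test_fraction=test_fraction,
                                   seed=sim_cfg.seed)
    report, _ = train_and_evaluate(train, test, balance=balance,
                                   target_per_class=target_per_class,
                                   model_params=model_params,
                                   seed=seed if seed is not None else sim_cfg.seed)
    return report
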