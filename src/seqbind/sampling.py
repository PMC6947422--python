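"""Class balancing for heavily imbalanced residue datasets.

Binding residues are rare (roughly 1 positive per 25 negatives in typical
ligand benchmarks), so training sets are rebalanced before boosting:

* :class:`SMOTESampler` — synthesize minority points on segments between
  minority nearest neighbours until the minority class reaches a fixed
  target (default 19,000 per class), and uniformly under-sample the
  majority class down to the same target.
* :class:`RandomUnderSampler` — plain RUS: majority down to minority count.

Balancing must only ever be applied to training data; test sets stay
untouched and imbalanced.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .dataset import ORIGINAL, SYNTHETIC, LabeledDataset


def _classes(y: np.ndarray) -> tuple[int, int]:
    """Return (minority_label, majority_label); ties break toward label 1
    as minority (the binding class is the rare one by construction)."""
    labels, counts = np.unique(y, return_counts=True)
    if labels.size != 2:
        raise ValueError(
            f"balancing needs exactly two classes, got labels {labels.tolist()}"
        )
    if counts[0] == counts[1]:
        order = np.argsort(labels)[::-1]  # label 1 treated as minority
    else:
        order = np.argsort(counts)
    return int(labels[order[0]]), int(labels[order[1]])


class SMOTESampler(BaseEstimator):
    """SMOTE over-sampling of the minority class combined with uniform
    under-sampling of the majority class to a fixed per-class size.

    Each synthetic point is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``
    and ``x_nn`` one of the ``k_neighbors`` Euclidean nearest minority
    neighbours of ``x``; synthetic points therefore stay on segments inside
    the minority class.

    Parameters
    ----------
    target_per_class : int, default 19000
        Exact per-class size of the balanced output.
    k_neighbors : int, default 5
        Neighbour pool per minority point; must be < minority count.
    random_state : int or None
        Seed for neighbour choice, interpolation and under-sampling.
    replace_majority : bool, default False
        Permit sampling the majority class with replacement when it is
        smaller than the target (otherwise an error).
    """

    def __init__(self, target_per_class: int = 19000, k_neighbors: int = 5,
                 random_state: int | None = None,
                 replace_majority: bool = False):
        self.target_per_class = target_per_class
        self.k_neighbors = k_neighbors
        self.random_state = random_state
        self.replace_majority = replace_majority

    def fit_resample(self, ds: LabeledDataset) -> LabeledDataset:
        rng = np.random.default_rng(self.random_state)
        target = int(self.target_per_class)
        y = ds.y
        min_lab, maj_lab = _classes(y)
        min_idx = np.flatnonzero(y == min_lab)
        maj_idx = np.flatnonzero(y == maj_lab)

        if min_idx.size < 2:
            raise ValueError("SMOTE needs at least 2 minority samples")
        if self.k_neighbors >= min_idx.size:
            raise ValueError(
                f"k_neighbors={self.k_neighbors} must be < minority count "
                f"{min_idx.size}"
            )
        if maj_idx.size < target and not self.replace_majority:
            raise ValueError(
                f"majority count {maj_idx.size} < target {target}; "
                "set replace_majority=True to sample with replacement"
            )

        # --- minority: keep originals, synthesize up to the target ---------
        Xmin = ds.X[min_idx]
        if min_idx.size >= target:
            keep = rng.choice(min_idx.size, size=target, replace=False)
            min_part = ds.subset(min_idx[np.sort(keep)])
            synth_X = np.empty((0, ds.n_features))
        else:
            n_synth = target - min_idx.size
            nn = NearestNeighbors(n_neighbors=self.k_neighbors + 1).fit(Xmin)
            # column 0 is the point itself
            neigh = nn.kneighbors(Xmin, return_distance=False)[:, 1:]
            base = rng.integers(0, Xmin.shape[0], size=n_synth)
            pick = rng.integers(0, self.k_neighbors, size=n_synth)
            u = rng.uniform(0.0, 1.0, size=n_synth)
            x = Xmin[base]
            x_nn = Xmin[neigh[base, pick]]
            synth_X = x + u[:, None] * (x_nn - x)
            min_part = ds.subset(min_idx)

        # --- majority: uniform sample without (or with) replacement --------
        take = rng.choice(maj_idx.size, size=target,
                          replace=maj_idx.size < target)
        maj_part = ds.subset(maj_idx[np.sort(take)])

        X = np.vstack([min_part.X, synth_X, maj_part.X])
        y_out = np.concatenate([
            np.full(min_part.n_rows, min_lab),
            np.full(synth_X.shape[0], min_lab),
            np.full(maj_part.n_rows, maj_lab),
        ])
        prov = np.concatenate([
            min_part.provenance,
            np.array([SYNTHETIC] * synth_X.shape[0], dtype=object),
            maj_part.provenance,
        ])

        gids = None
        poss = None
        if ds.group_ids is not None and ds.group_ids.size:
            gids = np.concatenate([
                min_part.group_ids,
                np.array(["synthetic"] * synth_X.shape[0], dtype=object),
                maj_part.group_ids,
            ])
        if ds.positions is not None and np.size(ds.positions):
            poss = np.concatenate([
                min_part.positions,
                np.zeros(synth_X.shape[0], dtype=int),
                maj_part.positions,
            ])
        return LabeledDataset(X=X, y=y_out, feature_names=list(ds.feature_names),
                              provenance=prov, group_ids=gids, scheme=ds.scheme,
                              positions=poss)


class RandomUnderSampler(BaseEstimator):
    """Uniform majority under-sampling down to the minority count."""

    def __init__(self, random_state: int | None = None):
        self.random_state = random_state

    def fit_resample(self, ds: LabeledDataset) -> LabeledDataset:
        rng = np.random.default_rng(self.random_state)
        min_lab, maj_lab = _classes(ds.y)
        min_idx = np.flatnonzero(ds.y == min_lab)
        maj_idx = np.flatnonzero(ds.y == maj_lab)
        take = rng.choice(maj_idx.size, size=min_idx.size, replace=False)
        keep = np.sort(np.concatenate([min_idx, maj_idx[take]]))
        return ds.subset(keep)


def smote_balance(ds: LabeledDataset, target_per_class: int = 19000,
                  k_neighbors: int = 5, seed: int | None = None,
                  replace_majority: bool = False) -> LabeledDataset:
    """Functional wrapper over :class:`SMOTESampler`."""
    return SMOTESampler(target_per_class=target_per_class,
                        k_neighbors=k_neighbors, random_state=seed,
                        replace_majority=replace_majority).fit_resample(ds)


def random_undersample(ds: LabeledDataset, seed: int | None = None) -> LabeledDataset:
    """Functional wrapper over :class:`RandomUnderSampler`."""
    return RandomUnderSampler(random_state=seed).fit_resample(ds)
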