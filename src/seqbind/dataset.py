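"""Residue-level feature dataset container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: provenance values; "synthetic" marks minority rows created by over-sampling
ORIGINAL = "original"
SYNTHETIC = "synthetic"


@dataclass
class LabeledDataset:
    """n residues x d features, with binary binding labels and provenance.

    Parameters
    ----------
    X : (n, d) float array
        Per-residue feature vectors.
    y : (n,) int array
        1 = binding residue, 0 = non-binding, -1 = unlabeled.
    feature_names : list of str
        Column names, length d.
    provenance : (n,) str array
        "original" or "synthetic" (SMOTE-generated) per row.
    group_ids : (n,) str array, optional
        Protein id of each row, used for grouped cross-validation.
    scheme : str
        Feature scheme the columns were produced by (e.g. "pssm_dct_psa").
    positions : (n,) int array, optional
        1-based residue position within the source protein.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    provenance: np.ndarray | None = None
    group_ids: np.ndarray | None = None
    scheme: str = ""
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        n = self.X.shape[0]
        self.y = np.asarray(self.y, dtype=int)
        if self.y.shape != (n,):
            raise ValueError(f"y has {self.y.shape[0] if self.y.ndim else 0} rows, X has {n}")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length does not match number of columns")
        if self.provenance is None:
            self.provenance = np.array([ORIGINAL] * n, dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
            if self.provenance.shape != (n,):
                raise ValueError("provenance length does not match number of rows")
        for name in ("group_ids", "positions"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (n,):
                    raise ValueError(f"{name} length does not match number of rows")
                setattr(self, name, v)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        """Row subset preserving all aligned fields."""
        idx = np.asarray(idx)
        return LabeledDataset(
            X=self.X[idx],
            y=self.y[idx],
            feature_names=list(self.feature_names),
            provenance=self.provenance[idx],
            group_ids=None if self.group_ids is None else self.group_ids[idx],
            scheme=self.scheme,
            positions=None if self.positions is None else self.positions[idx],
        )


def concat(datasets: list[LabeledDataset]) -> LabeledDataset:
    """Stack datasets row-wise; schemes and column counts must agree."""
    if not datasets:
        raise ValueError("nothing to concatenate")
    first = datasets[0]
    for ds in datasets[1:]:
        if ds.n_features != first.n_features:
            raise ValueError("column count mismatch between datasets")
        if ds.scheme != first.scheme:
            raise ValueError("feature scheme mismatch between datasets")

    def _cat(attr):
        vals = [getattr(d, attr) for d in datasets]
        if any(v is None for v in vals):
            return None
        return np.concatenate(vals)

    return LabeledDataset(
        X=np.vstack([d.X for d in datasets]),
        y=np.concatenate([d.y for d in datasets]),
        feature_names=list(first.feature_names),
        provenance=np.concatenate([d.provenance for d in datasets]),
        group_ids=_cat("group_ids"),
        scheme=first.scheme,
        positions=_cat("positions"),
    )
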