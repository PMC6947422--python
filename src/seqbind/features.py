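"""Per-residue feature engineering from PSSM and PSA profiles.

A sliding window of ``w`` PSSM rows centred on the target residue (the
"sparse evolution image": positions past either terminus are all-zero rows)
is either flattened directly, compressed with a 2-D type-II orthonormal DCT
keeping the first ``r`` rows, or summarised by a 4-level discrete wavelet
cascade per PSSM column.  The three-state solvent-accessibility probabilities
of the centre residue can be appended to any scheme.

Output dimensions at defaults (w=17, r=9, 4-level db4):

====================  ==========
scheme                dimension
====================  ==========
pssm                  340
pssm_dct              180
pssm_dwt              1040
pssm_psa              343
pssm_dct_psa          183
pssm_dwt_psa          1043
pssm_dct_dwt_psa      1223
====================  ==========
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pywt
from scipy.fft import dctn

from .dataset import LabeledDataset
from .io import PSAProfile, PSSMProfile

SCHEMES = (
    "pssm",
    "pssm_dct",
    "pssm_dwt",
    "pssm_psa",
    "pssm_dct_psa",
    "pssm_dwt_psa",
    "pssm_dct_dwt_psa",
)

#: per wavelet level: 5 leading approximation coefficients + 4 statistics of
#: the approximation band + 4 statistics of the detail band
_DWT_PER_LEVEL = 13
_DWT_LEAD = 5
_PSA_NAMES = ("psa_buried", "psa_intermediate", "psa_exposed")


@dataclass
class FeatureConfig:
    """Feature-scheme configuration.

    Parameters
    ----------
    window_w : odd int, default 17
        Sliding-window size (residues); the centre residue plus
        ``(w - 1) / 2`` neighbours on each side.
    dct_rows_r : int, default 9
        Number of leading DCT rows kept by the ``pssm_dct`` schemes.
    dwt_levels : int, default 4
        Depth of the wavelet cascade.
    dwt_wavelet : str, default "db4"
        PyWavelets wavelet name; must leave >= 5 coefficients in every
        approximation band at the configured window size.
    scheme : str, default "pssm_dct_psa"
        One of :data:`SCHEMES`.
    pssm_sigmoid : bool, default False
        Optionally squash raw log-odds through 1 / (1 + e^-x) before any
        transform.
    """

    window_w: int = 17
    dct_rows_r: int = 9
    dwt_levels: int = 4
    dwt_wavelet: str = "db4"
    scheme: str = "pssm_dct_psa"
    pssm_sigmoid: bool = False

    def __post_init__(self) -> None:
        if self.window_w < 1 or self.window_w % 2 == 0:
            raise ValueError(f"window_w must be odd and >= 1, got {self.window_w}")
        if not 1 <= self.dct_rows_r <= self.window_w:
            raise ValueError(
                f"dct_rows_r must lie in 1..window_w, got {self.dct_rows_r}"
            )
        if self.dwt_levels < 1:
            raise ValueError("dwt_levels must be >= 1")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")

    @property
    def uses_psa(self) -> bool:
        return self.scheme.endswith("_psa")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ResidueWindow:
    """w x 20 slice of a PSSM centred on one residue; out-of-range rows are
    zero padding."""

    matrix: np.ndarray
    center_index: int  # 1-based residue position

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError(f"window must be w x 20, got {self.matrix.shape}")


def feature_dim(cfg: FeatureConfig) -> int:
    """Output dimension as a pure function of the configuration."""
    parts = {
        "pssm": cfg.window_w * 20,
        "dct": cfg.dct_rows_r * 20,
        "dwt": cfg.dwt_levels * _DWT_PER_LEVEL * 20,
        "psa": 3,
    }
    return sum(parts[p] for p in _scheme_parts(cfg.scheme))


def _scheme_parts(scheme: str) -> list[str]:
    parts = []
    tokens = scheme.split("_")
    if tokens[0] != "pssm":
        raise ValueError(f"unknown scheme {scheme!r}")
    rest = tokens[1:]
    if not rest or rest[0] == "psa":
        parts.append("pssm")
    for tok in rest:
        if tok in ("dct", "dwt", "psa"):
            parts.append(tok)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    return parts


def extract_window(pssm: PSSMProfile, pos: int, cfg: FeatureConfig) -> ResidueWindow:
    """Window of ``cfg.window_w`` PSSM rows centred on residue ``pos`` (1-based).

    Rows whose index falls outside [1, L] are all-zero padding.
    """
    L = pssm.length
    if not 1 <= pos <= L:
        raise IndexError(f"residue position {pos} outside [1, {L}]")
    w = cfg.window_w
    half = (w - 1) // 2
    out = np.zeros((w, 20))
    lo = pos - half  # 1-based index of the first window row
    for k in range(w):
        idx = lo + k
        if 1 <= idx <= L:
            out[k] = pssm.scores[idx - 1]
    if cfg.pssm_sigmoid:
        out = 1.0 / (1.0 + np.exp(-out))
    return ResidueWindow(out, pos)


def dct2(mat: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D type-II DCT.

    Energy is preserved (Parseval) and the transform inverts exactly via the
    type-III DCT with the same normalization.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.size == 0:
        raise ValueError(f"dct2 needs a non-empty 2-D matrix, got shape {mat.shape}")
    return dctn(mat, type=2, norm="ortho")


def dct_feature(win: ResidueWindow, cfg: FeatureConfig) -> np.ndarray:
    """2-D DCT of the window, first ``r`` rows kept, row-major flatten."""
    return dct2(win.matrix)[: cfg.dct_rows_r].ravel()


def dwt_cascade(signal: np.ndarray, wavelet: str, levels: int):
    """Level-by-level single-scale DWT: returns (approximations, details).

    ``approximations[k]`` / ``details[k]`` are the bands after level ``k+1``;
    each level decomposes the previous approximation.
    """
    approx, detail = [], []
    cur = np.asarray(signal, dtype=float)
    for _ in range(levels):
        cA, cD = pywt.dwt(cur, wavelet, mode="symmetric")
        approx.append(cA)
        detail.append(cD)
        cur = cA
    return approx, detail


def dwt_reconstruct(approx_last: np.ndarray, details: list[np.ndarray],
                    wavelet: str, length: int) -> np.ndarray:
    """Invert :func:`dwt_cascade` from the deepest approximation band.

    ``length`` is the original signal length; intermediate lengths are
    re-derived from the detail bands (idwt can overshoot by one sample under
    symmetric extension).
    """
    lengths = [length] + [len(d) for d in details[:-1]]
    cur = approx_last
    for cD, target in zip(reversed(details), reversed(lengths)):
        cur = pywt.idwt(cur[: len(cD)], cD, wavelet, mode="symmetric")
        cur = cur[:target]
    return cur


def _band_stats(band: np.ndarray) -> list[float]:
    return [float(band.std()), float(band.mean()),
            float(band.max()), float(band.min())]


def dwt_feature(win: ResidueWindow, cfg: FeatureConfig) -> np.ndarray:
    """Multilevel wavelet summary of each PSSM column of the window.

    Per column (a length-w signal) and per level: the first five
    approximation coefficients plus {std, mean, max, min} of the
    approximation band, and {std, mean, max, min} of the detail band —
    13 values per level, 52 per column at 4 levels, 1040 in total over the
    20 columns.
    """
    out: list[float] = []
    for col in range(20):
        approx, detail = dwt_cascade(win.matrix[:, col], cfg.dwt_wavelet,
                                     cfg.dwt_levels)
        for lvl, (cA, cD) in enumerate(zip(approx, detail), start=1):
            if len(cA) < _DWT_LEAD:
                raise ValueError(
                    f"wavelet {cfg.dwt_wavelet!r} leaves only {len(cA)} "
                    f"approximation coefficients at level {lvl} "
                    f"(need >= {_DWT_LEAD}); use a longer filter or fewer levels"
                )
            out.extend(float(v) for v in cA[:_DWT_LEAD])
            out.extend(_band_stats(cA))
            out.extend(_band_stats(cD))
    return np.asarray(out)


def _feature_names(cfg: FeatureConfig) -> list[str]:
    names: list[str] = []
    for part in _scheme_parts(cfg.scheme):
        if part == "pssm":
            names += [f"pssm_w{i}_{a}" for i in range(cfg.window_w)
                      for a in range(20)]
        elif part == "dct":
            names += [f"dct_r{i}_c{j}" for i in range(cfg.dct_rows_r)
                      for j in range(20)]
        elif part == "dwt":
            per_level = ([f"a{k}" for k in range(_DWT_LEAD)]
                         + ["a_std", "a_mean", "a_max", "a_min",
                            "d_std", "d_mean", "d_max", "d_min"])
            names += [f"dwt_c{c}_l{l}_{s}" for c in range(20)
                      for l in range(1, cfg.dwt_levels + 1) for s in per_level]
        elif part == "psa":
            names += list(_PSA_NAMES)
    return names


def residue_vector(pssm: PSSMProfile, psa: PSAProfile | None, pos: int,
                   cfg: FeatureConfig) -> np.ndarray:
    """Feature vector of one residue under the configured scheme."""
    win = extract_window(pssm, pos, cfg)
    blocks: list[np.ndarray] = []
    for part in _scheme_parts(cfg.scheme):
        if part == "pssm":
            blocks.append(win.matrix.ravel())
        elif part == "dct":
            blocks.append(dct_feature(win, cfg))
        elif part == "dwt":
            blocks.append(dwt_feature(win, cfg))
        elif part == "psa":
            assert psa is not None
            blocks.append(psa.acc[pos - 1])
    return np.concatenate(blocks)


def assemble_features(pssm: PSSMProfile, psa: PSAProfile | None = None,
                      labels: np.ndarray | None = None,
                      cfg: FeatureConfig | None = None) -> LabeledDataset:
    """One feature row per residue of a protein.

    The PSA block, when the scheme requests it, is the centre residue's three
    probabilities only (the window applies to the PSSM alone).
    """
    cfg = cfg or FeatureConfig()
    if cfg.uses_psa and psa is None:
        raise ValueError(f"scheme {cfg.scheme!r} needs a PSA profile")
    if psa is not None and psa.length != pssm.length:
        raise ValueError(
            f"PSA length {psa.length} ≠ PSSM length {pssm.length} "
            f"for {pssm.protein_id!r}"
        )
    L = pssm.length
    if labels is not None:
        labels = np.asarray(labels, dtype=int)
        if labels.shape != (L,):
            raise ValueError(f"labels length {labels.size} ≠ protein length {L}")
    X = np.vstack([residue_vector(pssm, psa, pos, cfg) for pos in range(1, L + 1)])
    y = labels if labels is not None else np.full(L, -1, dtype=int)
    return LabeledDataset(
        X=X,
        y=y,
        feature_names=_feature_names(cfg),
        group_ids=np.array([pssm.protein_id] * L, dtype=object),
        scheme=cfg.scheme,
        positions=np.arange(1, L + 1),
    )


def assemble_many(records, pssms: dict, psas: dict | None,
                  cfg: FeatureConfig | None = None) -> LabeledDataset:
    """Stack :func:`assemble_features` over a list of protein records."""
    from .dataset import concat

    cfg = cfg or FeatureConfig()
    parts = []
    for rec in records:
        pssm = pssms[rec.id]
        psa = (psas or {}).get(rec.id)
        parts.append(assemble_features(pssm, psa, rec.labels, cfg))
    return concat(parts)
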