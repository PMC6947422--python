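"""Synthetic proteins, PSSMs, PSA profiles and binding labels.

The generator emulates the shape of real inputs so the whole pipeline is
testable without external tools or databases:

* binding residues come in contiguous sequence patches (binding sites
  cluster along the chain), at a configurable overall positive rate
  (default 0.04, the ~1:25 imbalance typical of ligand benchmarks);
* PSSM entries are integer log-odds: round(Normal(0, noise_sd)) clipped to
  [-10, 13], the typical PSI-BLAST range; binding-residue rows get an
  ``effect_size`` shift added to the first ``n_signal_cols`` columns before
  rounding, so the class-conditional signal strength is a dial;
* PSA rows are Dirichlet(2, 2, 2) probabilities; binding-residue rows are
  mixed toward the fully-exposed corner with weight ``psa_effect``.

It does NOT emulate real evolutionary profiles (column covariances, alignment
depth effects, residue-type composition): pipeline performance on this data
shows the machinery works end to end, not what it achieves on real profiles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io import (PSAProfile, PSSMProfile, ProteinRecord, write_fasta_with_labels,
                 write_psa, write_pssm_ascii)

_AA = "ARNDCQEGHILKMFPSTWYV"
PSSM_MIN, PSSM_MAX = -10, 13


@dataclass
class SimConfig:
    """Synthetic-dataset settings.

    positive_rate is the target fraction of binding residues (default 0.04);
    effect_size is the mean log-odds shift applied to ``n_signal_cols`` PSSM
    columns of binding rows; psa_effect in [0, 1] mixes binding rows' PSA
    toward fully exposed; noise_sd is the log-odds standard deviation of the
    background profile.
    """

    n_proteins: int = 20
    length_range: tuple[int, int] = (60, 200)
    positive_rate: float = 0.04
    patch_len_range: tuple[int, int] = (4, 12)
    effect_size: float = 4.0
    n_signal_cols: int = 6
    psa_effect: float = 0.3
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        plo, phi = self.patch_len_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid length_range {self.length_range}")
        if not (1 <= plo <= phi):
            raise ValueError(f"invalid patch_len_range {self.patch_len_range}")
        if not 0 < self.positive_rate < 1:
            raise ValueError("positive_rate must lie in (0, 1)")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be >= 0")
        if not 0 <= self.psa_effect <= 1:
            raise ValueError("psa_effect must lie in [0, 1]")
        if not 0 <= self.n_signal_cols <= 20:
            raise ValueError("n_signal_cols must lie in 0..20")
        if plo > hi:
            raise ValueError(
                f"minimum patch length {plo} exceeds maximum protein "
                f"length {hi}"
            )
        if self.positive_rate * hi < 1 and self.positive_rate * lo < 1:
            # not even one binding residue expected in the longest protein
            raise ValueError(
                "positive_rate too low for the configured protein lengths"
            )


def _patch_labels(L: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Contiguous binding patches covering ~positive_rate of the protein.

    Stochastic rounding of the per-protein target keeps the realized overall
    rate unbiased even when rate * L is far below one patch.
    """
    labels = np.zeros(L, dtype=int)
    target_f = cfg.positive_rate * L
    target = int(np.floor(target_f))
    if rng.uniform() < target_f - target:
        target += 1
    tries = 0
    while labels.sum() < target and tries < 100 * (target + 1):
        tries += 1
        plen = int(rng.integers(cfg.patch_len_range[0],
                                cfg.patch_len_range[1] + 1))
        # the last patch is truncated so the realized rate tracks the target
        plen = min(plen, L, target - int(labels.sum()))
        start = int(rng.integers(0, L - plen + 1))
        labels[start:start + plen] = 1
    if labels.sum() < target:  # pathological overlap; top up deterministically
        zeros = np.flatnonzero(labels == 0)
        labels[zeros[: target - int(labels.sum())]] = 1
    return labels


def simulate_dataset(cfg: SimConfig | None = None):
    """Generate (records, pssms, psas): lists/dicts keyed by protein id.

    Fully reproducible under ``cfg.seed``.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    records: list[ProteinRecord] = []
    pssms: dict[str, PSSMProfile] = {}
    psas: dict[str, PSAProfile] = {}
    for i in range(cfg.n_proteins):
        pid = f"synth{i:04d}"
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq = "".join(rng.choice(list(_AA), size=L))
        labels = _patch_labels(L, cfg, rng)

        scores = rng.normal(0.0, cfg.noise_sd, size=(L, 20))
        if cfg.n_signal_cols and cfg.effect_size:
            scores[labels == 1, : cfg.n_signal_cols] += cfg.effect_size
        scores = np.clip(np.rint(scores), PSSM_MIN, PSSM_MAX)

        acc = rng.dirichlet((2.0, 2.0, 2.0), size=L)
        if cfg.psa_effect:
            exposed = np.array([0.0, 0.0, 1.0])
            mask = labels == 1
            acc[mask] = (1 - cfg.psa_effect) * acc[mask] + cfg.psa_effect * exposed

        records.append(ProteinRecord(pid, seq, labels))
        pssms[pid] = PSSMProfile(pid, scores)
        psas[pid] = PSAProfile(pid, acc)
    return records, pssms, psas


def write_fixtures(records, pssms, psas, outdir, cfg: SimConfig | None = None) -> dict:
    """Write FASTA(+labels), one ASCII PSSM and one PSA TSV per protein, and
    a JSON manifest; everything round-trips through the package readers."""
    outdir = Path(outdir)
    (outdir / "pssm").mkdir(parents=True, exist_ok=True)
    (outdir / "psa").mkdir(parents=True, exist_ok=True)
    fasta = outdir / "proteins.fasta"
    write_fasta_with_labels(records, fasta)
    manifest = {
        "fasta": fasta.name,
        "pssm": {},
        "psa": {},
        "config": None if cfg is None else asdict(cfg),
    }
    for rec in records:
        ppath = outdir / "pssm" / f"{rec.id}.pssm"
        apath = outdir / "psa" / f"{rec.id}.tsv"
        write_pssm_ascii(pssms[rec.id], rec.sequence, ppath)
        write_psa(psas[rec.id], rec.sequence, apath)
        manifest["pssm"][rec.id] = str(ppath.relative_to(outdir))
        manifest["psa"][rec.id] = str(apath.relative_to(outdir))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
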