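"""Readers and writers for the on-disk artifacts of the pipeline.

Formats
-------
* FASTA with an optional per-record 0/1 label line (1 = binding residue).
* PSI-BLAST ASCII PSSM (the ``-out_ascii_pssm`` layout) or a bare L x 20
  numeric TSV holding just the log-odds block.
* Per-residue three-state solvent-accessibility TSV
  (index, residue, p_buried, p_intermediate, p_exposed).
* A self-describing residue-level feature table (TSV with ``#`` headers)
  that round-trips :class:`~seqbind.dataset.LabeledDataset` losslessly.

All readers and writers accept ``.gz`` paths transparently.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import ORIGINAL, LabeledDataset

# PSI-BLAST ASCII column order for the 20 standard residues.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

# Sequence alphabet: the 20 standard residues plus X for unknown.
AA_ALPHABET = frozenset(PSSM_ALPHABET + "X")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class ProteinRecord:
    """One protein sequence with optional per-residue binding labels."""

    id: str
    sequence: str
    labels: np.ndarray | None = None  # (L,) 0/1 ints

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - AA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.sequence),):
                raise FormatError(
                    f"record {self.id!r}: label length {self.labels.size} "
                    f"≠ sequence length {len(self.sequence)}"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise FormatError(f"record {self.id!r}: labels must be 0/1")


@dataclass
class PSSMProfile:
    """L x 20 log-odds profile; row i is residue i (1-based), columns in
    PSI-BLAST order ``ARNDCQEGHILKMFPSTWYV``."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise FormatError(
                f"PSSM for {self.protein_id!r} must be L x 20, got {self.scores.shape}"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class PSAProfile:
    """L x 3 predicted solvent-accessibility probabilities
    (buried, intermediate, exposed); rows sum to 1."""

    protein_id: str
    acc: np.ndarray

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise FormatError(
                f"PSA for {self.protein_id!r} must be L x 3, got {self.acc.shape}"
            )
        if (self.acc < 0).any():
            raise FormatError(f"PSA for {self.protein_id!r}: negative probability")
        sums = self.acc.sum(axis=1)
        bad = (sums < 0.95) | (sums > 1.05)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise FormatError(
                f"PSA for {self.protein_id!r}: row {row} sums to {sums[bad][0]:.3f}, "
                "outside [0.95, 1.05]"
            )
        # renormalize only rows that need it, so exact files round-trip
        off = np.abs(sums - 1.0) > 1e-12
        if off.any():
            self.acc = self.acc.copy()
            self.acc[off] = self.acc[off] / sums[off, None]

    @property
    def length(self) -> int:
        return self.acc.shape[0]


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA with label lines
# ---------------------------------------------------------------------------

def read_fasta_with_labels(path) -> list[ProteinRecord]:
    """Parse FASTA where each record may be followed by a same-length 0/1 line.

    Sequence and label lines may both be wrapped; lines consisting solely of
    the characters ``0``/``1`` are treated as label lines (no amino-acid code
    is a digit, so the two cannot collide).
    """
    records: list[ProteinRecord] = []
    cur_id: str | None = None
    seq_parts: list[str] = []
    lab_parts: list[str] = []

    def flush():
        if cur_id is None:
            return
        seq = "".join(seq_parts)
        labels = None
        if lab_parts:
            lab = "".join(lab_parts)
            if len(lab) != len(seq):
                raise FormatError(
                    f"record {cur_id!r}: label length {len(lab)} "
                    f"≠ sequence length {len(seq)}"
                )
            labels = np.fromiter((int(c) for c in lab), dtype=int)
        records.append(ProteinRecord(cur_id, seq, labels))

    with _open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0] if line[1:].strip() else ""
                seq_parts, lab_parts = [], []
            elif set(line) <= {"0", "1"}:
                lab_parts.append(line)
            else:
                seq_parts.append(line)
        flush()
    return records


def write_fasta_with_labels(records: list[ProteinRecord], path) -> None:
    with _open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
            if rec.labels is not None:
                fh.write("".join(str(int(v)) for v in rec.labels) + "\n")


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

def read_pssm(path, dialect: str = "auto", protein_id: str | None = None,
              sequence: str | None = None) -> PSSMProfile:
    """Read a PSSM from PSI-BLAST ASCII output or a bare numeric TSV.

    Only the first 20-column block (log-odds) of the ASCII layout is used.
    When ``sequence`` is given, residue letters in the file are cross-checked
    against it.
    """
    if protein_id is None:
        protein_id = Path(path).name.split(".")[0]
    if dialect == "auto":
        with _open(path) as fh:
            head = fh.read(4096)
        dialect = "psiblast_ascii" if ("Last position-specific" in head
                                       or "position-specific scoring matrix" in head
                                       ) else "tsv"
    if dialect == "psiblast_ascii":
        return _read_pssm_ascii(path, protein_id, sequence)
    if dialect == "tsv":
        return _read_pssm_tsv(path, protein_id)
    raise ValueError(f"unknown PSSM dialect {dialect!r}")


def _read_pssm_ascii(path, protein_id: str, sequence: str | None) -> PSSMProfile:
    rows: list[list[float]] = []
    letters: list[str] = []
    in_body = False
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            fields = raw.split()
            if not in_body:
                # the column-header line carries the 40 residue letters
                if len(fields) == 40 and all(f in PSSM_ALPHABET for f in fields):
                    in_body = True
                continue
            if not fields:
                break  # blank line ends the body; footer stats ignored
            if not fields[0].isdigit():
                break
            numeric = fields[2:]
            if len(numeric) != 42:
                raise FormatError(
                    f"{path}: line {lineno}: expected 42 numeric fields "
                    f"(20 log-odds + 20 percentages + 2 stats), got {len(numeric)}"
                )
            try:
                rows.append([float(v) for v in numeric[:20]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            letters.append(fields[1])
    if not in_body:
        raise FormatError(f"{path}: no PSI-BLAST column-header line found")
    if not rows:
        raise FormatError(f"{path}: no PSSM rows found")
    if sequence is not None:
        got = "".join(letters)
        if got.upper() != sequence.upper():
            raise FormatError(
                f"{path}: residues in PSSM ({got[:12]}...) do not match the "
                "provided sequence"
            )
    return PSSMProfile(protein_id, np.array(rows))


def _read_pssm_tsv(path, protein_id: str) -> PSSMProfile:
    rows = []
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 20:
                raise FormatError(
                    f"{path}: line {lineno}: expected 20 fields, got {len(fields)}"
                )
            rows.append([float(v) for v in fields])
    if not rows:
        raise FormatError(f"{path}: empty PSSM")
    return PSSMProfile(protein_id, np.array(rows))


def write_pssm_tsv(profile: PSSMProfile, path) -> None:
    with _open(path, "wt") as fh:
        for row in profile.scores:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_pssm_ascii(profile: PSSMProfile, sequence: str, path) -> None:
    """Write a PSSM in the PSI-BLAST ``-out_ascii_pssm`` layout.

    The percentage block and per-row statistics are filled with zeros; the
    log-odds block round-trips exactly through :func:`read_pssm`.
    """
    if len(sequence) != profile.length:
        raise ValueError("sequence length does not match PSSM row count")
    with _open(path, "wt") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        hdr = "      " + "".join(f"{a:>4}" for a in PSSM_ALPHABET) * 2
        fh.write(hdr + "\n")
        for i, (res, row) in enumerate(zip(sequence, profile.scores), start=1):
            cells = "".join(f"{int(round(v)):>4d}" for v in row)
            pct = "".join(f"{0:>4d}" for _ in range(20))
            fh.write(f"{i:>5d} {res}{cells}{pct}  0.00 0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------

def read_psa(path, protein_id: str | None = None) -> PSAProfile:
    """Read index/residue/p_buried/p_intermediate/p_exposed TSV rows.

    Rows are renormalized to sum 1 when the raw sum lies in [0.95, 1.05];
    anything outside that band (or a negative entry) is a validation error.
    """
    if protein_id is None:
        protein_id = Path(path).name.split(".")[0]
    rows = []
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 5:
                raise FormatError(
                    f"{path}: line {lineno}: expected 5 fields "
                    "(index residue p_b p_i p_e), got "
                    f"{len(fields)}"
                )
            rows.append([float(v) for v in fields[2:5]])
    if not rows:
        raise FormatError(f"{path}: empty PSA file")
    return PSAProfile(protein_id, np.array(rows))


def write_psa(profile: PSAProfile, sequence: str, path) -> None:
    if len(sequence) != profile.length:
        raise ValueError("sequence length does not match PSA row count")
    with _open(path, "wt") as fh:
        for i, (res, row) in enumerate(zip(sequence, profile.acc), start=1):
            fh.write(f"{i}\t{res}\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    # %.17g round-trips IEEE doubles exactly
    return format(float(v), ".17g")


def write_features(ds: LabeledDataset, path, extra_header: dict | None = None) -> None:
    """Write a dataset as a TSV with a self-describing ``#`` header."""
    with _open(path, "wt") as fh:
        fh.write(f"# scheme={ds.scheme}\n")
        fh.write(f"# n_rows={ds.n_rows}\n")
        fh.write(f"# n_cols={ds.n_features}\n")
        for k, v in (extra_header or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write(f"# columns={','.join(ds.feature_names)}\n")
        fh.write("protein_id\tposition\tlabel\tprovenance\t"
                 + "\t".join(ds.feature_names) + "\n")
        gids = ds.group_ids if ds.group_ids is not None else ["-"] * ds.n_rows
        poss = ds.positions if ds.positions is not None else [0] * ds.n_rows
        for i in range(ds.n_rows):
            fh.write(
                f"{gids[i]}\t{int(poss[i])}\t{int(ds.y[i])}\t{ds.provenance[i]}\t"
                + "\t".join(_fmt(v) for v in ds.X[i]) + "\n"
            )


def read_features(path) -> LabeledDataset:
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    y: list[int] = []
    prov: list[str] = []
    gids: list[str] = []
    poss: list[int] = []
    names: list[str] | None = None
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = val
                continue
            fields = line.split("\t")
            if names is None:
                names = fields[4:]
                continue
            if len(fields) != 4 + len(names):
                raise FormatError(
                    f"{path}: line {lineno}: expected {4 + len(names)} fields, "
                    f"got {len(fields)}"
                )
            gids.append(fields[0])
            poss.append(int(fields[1]))
            y.append(int(fields[2]))
            prov.append(fields[3])
            rows.append([float(v) for v in fields[4:]])
    if names is None:
        raise FormatError(f"{path}: missing column header line")
    declared = header.get("columns")
    if declared is not None and declared.split(",") != names and declared != "":
        raise FormatError(f"{path}: header column list does not match table header")
    n_cols = header.get("n_cols")
    if n_cols is not None and int(n_cols) != len(names):
        raise FormatError(
            f"{path}: header says {n_cols} columns, file has {len(names)}"
        )
    n_rows = header.get("n_rows")
    if n_rows is not None and int(n_rows) != len(rows):
        raise FormatError(
            f"{path}: header says {n_rows} rows, file has {len(rows)}"
        )
    X = np.array(rows, dtype=float) if rows else np.empty((0, len(names)))
    return LabeledDataset(
        X=X,
        y=np.array(y, dtype=int),
        feature_names=names,
        provenance=np.array(prov, dtype=object),
        group_ids=np.array(gids, dtype=object) if gids else np.empty(0, dtype=object),
        scheme=header.get("scheme", ""),
        positions=np.array(poss, dtype=int) if poss else np.empty(0, dtype=int),
    )
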