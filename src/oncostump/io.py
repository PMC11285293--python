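"""Readers and writers for every external representation the toolkit touches.

Alignments are read through Biopython.  The external-tool parsers accept one
documented minimal dialect per tool (real outputs vary across tool versions;
the dialects below keep the semantically load-bearing content):

* FoldX stability scan: whitespace/tab-delimited lines ``<mutation> <ddG>``;
  repeated runs of the same mutation are averaged.  Lines starting with
  ``#`` or a ``mutation`` header are skipped.
* Rosetta ddg_monomer: lines ``ddG: <mutation> <value>``.
* PROPKA: a ``SUMMARY OF THIS PREDICTION`` section with lines
  ``<RES> <position> [chain] <pKa>``.
* P2Rank: CSV with header containing ``name``, ``rank`` and ``residue_ids``
  columns; residue ids are whitespace-separated integers, optionally
  ``CHAIN_`` prefixed.
* Docking (Vina-style): per-ligand blocks opened by ``Ligand: <id>``
  followed by pose lines ``<mode> <energy> ...``.

Mutation codes follow ``{WT}{position}{MUT}`` (e.g. ``N666T``),
case-insensitive on parse and upper-case on write.  All residue positions
are 1-based UniProt numbering.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment
from Bio import AlignIO

from .constants import (
    AMINO_ACIDS,
    MODEL_SCHEMA,
    MODES,
    MSA_ALPHABET,
    SEQ_FEATURES,
    STR_FEATURES,
)
from .errors import AlignmentError, FormatError, ParseError, SchemaError
from .boosting import Stump, StumpBoostingClassifier

__all__ = [
    "Msa",
    "LabeledDataset",
    "read_msa",
    "write_msa",
    "parse_mutation_code",
    "format_mutation_code",
    "parse_foldx_ddg",
    "parse_rosetta_ddg",
    "parse_propka",
    "parse_p2rank_pockets",
    "parse_docking_scores",
    "load_labeled_dataset",
    "save_labeled_dataset",
    "save_model",
    "load_model",
]


@dataclass
class Msa:
    """A multiple sequence alignment: parallel lists of ids and aligned rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if not self.rows:
            raise AlignmentError("alignment has no sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        if next(iter(lengths)) < 1:
            raise AlignmentError("alignment has zero columns")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - MSA_ALPHABET
            if bad:
                raise FormatError(
                    f"unknown residue character {sorted(bad)[0]!r} in sequence {rid!r}"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, col: int) -> str:
        return "".join(row[col] for row in self.rows)


def read_msa(path, format: str = "fasta") -> Msa:
    """Read a FASTA or Clustal alignment; rows keep file order."""
    path = Path(path)
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        records = list(SeqIO.parse(str(path), format))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    if not records:
        raise FormatError(f"no sequences found in {path}")
    return Msa(
        ids=[r.id for r in records],
        rows=[str(r.seq).upper() for r in records],
    )


def write_msa(msa: Msa, path, format: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(row), id=rid, description="")
        for rid, row in zip(msa.ids, msa.rows)
    ]
    if format == "fasta":
        SeqIO.write(records, str(path), "fasta")
    elif format == "clustal":
        AlignIO.write(MultipleSeqAlignment(records), str(path), "clustal")
    else:
        raise ValueError(f"unsupported alignment format {format!r}")


_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_mutation_code(code: str) -> tuple[str, int, str]:
    m = _MUTATION_RE.match(code.strip())
    if not m:
        raise FormatError(f"invalid mutation code {code!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if wt not in AMINO_ACIDS or mut not in AMINO_ACIDS:
        raise FormatError(f"non-canonical residue in mutation code {code!r}")
    return wt, pos, mut


def format_mutation_code(wt: str, position: int, mut: str) -> str:
    return f"{wt.upper()}{position}{mut.upper()}"


def _data_lines(text: str) -> list[str]:
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]


def parse_foldx_ddg(text: str) -> dict[str, float]:
    """Parse a FoldX stability-scan result; repeated runs are averaged."""
    runs: dict[str, list[float]] = {}
    for line in _data_lines(text):
        parts = line.replace("\t", " ").split()
        if parts[0].lower() in ("mutation", "mut"):
            continue  # header
        if len(parts) < 2:
            raise FormatError(f"unparsable FoldX line: {line!r}")
        wt, pos, mut = parse_mutation_code(parts[0])
        try:
            value = float(parts[1])
        except ValueError as exc:
            raise FormatError(f"non-numeric ddG in line: {line!r}") from exc
        runs.setdefault(format_mutation_code(wt, pos, mut), []).append(value)
    if not runs:
        raise FormatError("no parsable FoldX rows found")
    # mean over sorted run values: bit-identical under any row order
    return {code: float(np.mean(sorted(values))) for code, values in runs.items()}


def parse_rosetta_ddg(text: str) -> dict[str, float]:
    """Parse ddg_monomer output lines ``ddG: <mutation> <value>``."""
    out: dict[str, float] = {}
    for line in _data_lines(text):
        if not line.startswith("ddG:"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise FormatError(f"unparsable Rosetta line: {line!r}")
        wt, pos, mut = parse_mutation_code(parts[1])
        code = format_mutation_code(wt, pos, mut)
        value = float(parts[2])
        if code in out and out[code] != value:
            raise ParseError(f"conflicting ddG values for mutation {code}")
        out[code] = value
    if not out:
        raise FormatError("no parsable Rosetta ddG records found")
    return out


_PROPKA_SUMMARY = "SUMMARY OF THIS PREDICTION"


def parse_propka(text: str) -> dict[int, float]:
    """Extract per-residue pKa values from a PROPKA summary section."""
    lines = text.splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if _PROPKA_SUMMARY in ln)
    except StopIteration:
        raise FormatError("PROPKA summary section not found") from None
    out: dict[int, float] = {}
    for ln in lines[start + 1:]:
        stripped = ln.strip()
        if not stripped or set(stripped) <= {"-"}:
            if out:
                break
            continue
        parts = stripped.split()
        if parts[0].lower() in ("group", "residue"):
            continue  # column header
        if len(parts) < 3:
            raise FormatError(f"unparsable PROPKA summary line: {ln!r}")
        try:
            pos = int(parts[1])
        except ValueError as exc:
            raise FormatError(f"bad residue number in PROPKA line: {ln!r}") from exc
        # optional chain id between position and pKa
        pka_field = parts[3] if len(parts) > 3 and not _is_float(parts[2]) else parts[2]
        try:
            pka = float(pka_field)
        except ValueError as exc:
            raise FormatError(f"bad pKa value in PROPKA line: {ln!r}") from exc
        if pos in out:
            raise ParseError(f"residue {pos} listed twice in PROPKA summary")
        out[pos] = pka
    if not out:
        raise FormatError("PROPKA summary section holds no residues")
    return out


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def parse_p2rank_pockets(text: str) -> list[set[int]]:
    """Parse pocket residue sets from P2Rank-style CSV, in file rank order."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    header = [c.strip().lower() for c in lines[0].split(",")]
    try:
        rid_col = header.index("residue_ids")
    except ValueError:
        raise FormatError("P2Rank CSV lacks a residue_ids column") from None
    pockets: list[set[int]] = []
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(",")]
        if len(cells) <= rid_col:
            raise FormatError(f"short P2Rank row: {ln!r}")
        residues: set[int] = set()
        for token in cells[rid_col].split():
            token = token.split("_")[-1]  # strip optional chain prefix
            try:
                residues.add(int(token))
            except ValueError as exc:
                raise FormatError(f"malformed residue id {token!r} in P2Rank row") from exc
        pockets.append(residues)
    return pockets


def parse_docking_scores(text: str) -> dict[str, float]:
    """Best (minimum) binding energy per ligand from concatenated blocks."""
    out: dict[str, float] = {}
    ligand: str | None = None
    energies: list[float] = []

    def _close():
        if ligand is None:
            return
        if not energies:
            raise FormatError(f"ligand {ligand!r} has no scored poses")
        out[ligand] = min(energies)

    for ln in text.splitlines():
        stripped = ln.strip()
        if stripped.startswith("Ligand:"):
            _close()
            ligand = stripped.split(":", 1)[1].strip()
            energies = []
        elif stripped and ligand is not None:
            parts = stripped.split()
            if len(parts) >= 2 and _is_float(parts[1]):
                energies.append(float(parts[1]))
    _close()
    if not out:
        raise FormatError("no ligand blocks found in docking output")
    return out


@dataclass
class LabeledDataset:
    """Encoded feature matrix with labels and (protein, position) group keys."""

    matrix: np.ndarray
    labels: np.ndarray
    groups: list[tuple[str, int]]
    feature_names: list[str]
    mode: str
    sources: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        expected = SEQ_FEATURES if self.mode == "SEQ" else STR_FEATURES
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(expected):
            raise SchemaError(
                f"{self.mode} matrix must have {len(expected)} columns, "
                f"got {self.matrix.shape}"
            )
        if list(self.feature_names) != list(expected):
            raise SchemaError(f"feature names must match the {self.mode} schema")
        n = self.matrix.shape[0]
        if len(self.labels) != n or len(self.groups) != n:
            raise SchemaError("labels/groups length mismatch with matrix")
        if np.isnan(self.matrix).any():
            raise SchemaError("feature matrix contains missing values")
        if not np.isin(self.labels, [0, 1]).all():
            raise SchemaError("labels must be binary (1=Oncogenic, 0=Benign)")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def class_counts(self) -> tuple[int, int]:
        """(n_oncogenic, n_benign)."""
        n_onc = int(self.labels.sum())
        return n_onc, int(len(self.labels) - n_onc)


_LABEL_MAP = {"oncogenic": 1, "benign": 0, "1": 1, "0": 0}


def load_labeled_dataset(path, mode: str, column_map: dict[str, str] | None = None) -> LabeledDataset:
    """Load a labeled feature table from delimited text.

    ``column_map`` maps canonical column names (``label``, ``protein``,
    ``position`` and the feature schema) to the file's actual header names,
    so deposits with a different naming convention can be loaded without
    rewriting the file.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    column_map = column_map or {}
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    # round_trip parsing keeps load(save(ds)) bit-exact
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    feature_names = list(SEQ_FEATURES if mode == "SEQ" else STR_FEATURES)
    required = ["label", "protein", "position"] + feature_names
    rename = {column_map.get(c, c): c for c in required}
    missing = [column_map.get(c, c) for c in required if column_map.get(c, c) not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df.rename(columns=rename)

    labels = []
    for raw in df["label"]:
        key = str(raw).strip().lower()
        if key not in _LABEL_MAP:
            raise SchemaError(f"non-binary label value {raw!r}")
        labels.append(_LABEL_MAP[key])
    matrix = df[feature_names].to_numpy(dtype=float)
    if np.isnan(matrix).any():
        raise SchemaError("feature matrix contains missing values")
    groups = [(str(p), int(pos)) for p, pos in zip(df["protein"], df["position"])]
    return LabeledDataset(
        matrix=matrix,
        labels=np.asarray(labels),
        groups=groups,
        feature_names=feature_names,
        mode=mode,
    )


def save_labeled_dataset(dataset: LabeledDataset, path) -> None:
    """Write a labeled dataset as CSV with the canonical header."""
    df = pd.DataFrame(dataset.matrix, columns=dataset.feature_names)
    df.insert(0, "label", np.where(dataset.labels == 1, "Oncogenic", "Benign"))
    df.insert(1, "protein", [g[0] for g in dataset.groups])
    df.insert(2, "position", [g[1] for g in dataset.groups])
    # %.17g guarantees bit-exact float round trips through the text table
    df.to_csv(path, index=False, float_format="%.17g")


def save_model(model: StumpBoostingClassifier, path, *, mode: str | None = None,
               feature_names: list[str] | None = None, seed: int | None = None) -> None:
    """Serialise a fitted stump ensemble as versioned JSON (full precision)."""
    payload = {
        "schema": MODEL_SCHEMA,
        "base_score": model.base_score_,
        "eta": model.eta,
        "lambda_": model.lambda_,
        "gamma_": model.gamma_,
        "n_rounds": model.n_rounds,
        "stumps": [
            {
                "feature_index": s.feature_index,
                "threshold": s.threshold,
                "left_weight": s.left_weight,
                "right_weight": s.right_weight,
            }
            for s in model.stumps_
        ],
        "metadata": {"mode": mode, "feature_names": feature_names, "seed": seed},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> tuple[StumpBoostingClassifier, dict]:
    """Load a serialised ensemble; returns (model, metadata)."""
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("schema") != MODEL_SCHEMA:
        raise FormatError(
            f"model schema mismatch: expected {MODEL_SCHEMA!r}, "
            f"got {payload.get('schema')!r}"
        )
    model = StumpBoostingClassifier(
        n_rounds=payload["n_rounds"],
        eta=payload["eta"],
        lambda_=payload["lambda_"],
        gamma_=payload["gamma_"],
    )
    model.base_score_ = payload["base_score"]
    model.stumps_ = [
        Stump(
            feature_index=s["feature_index"],
            threshold=s["threshold"],
            left_weight=s["left_weight"],
            right_weight=s["right_weight"],
        )
        for s in payload["stumps"]
    ]
    meta = payload.get("metadata") or {}
    names = meta.get("feature_names")
    model.n_features_in_ = len(names) if names else (
        max((s.feature_index for s in model.stumps_), default=-1) + 1
    )
    model.classes_ = np.array([0, 1])
    return model, meta
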