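"""Plain-text I/O: count tables, condition labels, p-value lists, result
tables with ``#`` metadata headers, and JSON run-config sidecars."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .count_model import CountMatrix


def read_count_table(path) -> pd.DataFrame:
    """Tab-delimited counts: header of sample names, first column gene ids.

    Duplicate gene ids and negative or non-integer counts are rejected with
    the offending line number (1-based, header is line 1).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.index.is_unique:
        pos = int(np.flatnonzero(df.index.duplicated())[0])
        raise ValueError(
            f"duplicated gene id {df.index[pos]!r} (line {pos + 2}) in {path}"
        )
    if df.isna().any().any():
        row, col = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing count at line {row + 2}, column {df.columns[col]!r} in {path}"
        )
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        row, col = np.argwhere(coerced.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric count {df.iat[row, col]!r} at line {row + 2}, "
            f"column {df.columns[col]!r} in {path}"
        )
    bad = (vals < 0) | (vals != np.floor(vals))
    if bad.any():
        row, col = np.argwhere(bad)[0]
        raise ValueError(
            f"count {df.iat[row, col]!r} at line {row + 2}, column "
            f"{df.columns[col]!r} in {path} is not a non-negative integer"
        )
    return df.astype(np.int64)


def conditions_from_string(spec: str, samples) -> pd.Series:
    """Comma-separated labels aligned with the count-table columns."""
    labels = [s.strip() for s in spec.split(",")]
    if len(labels) != len(samples):
        raise ValueError(
            f"{len(labels)} condition labels given for {len(samples)} samples"
        )
    return pd.Series(labels, index=pd.Index(samples), name="condition")


def read_conditions(path, samples) -> pd.Series:
    """Two-column (sample, condition) TSV; must cover every sample."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "condition"],
                     dtype=str, comment="#")
    mapping = df.set_index("sample")["condition"]
    missing = [s for s in samples if s not in mapping.index]
    if missing:
        raise ValueError(f"samples missing from {path}: {missing}")
    return pd.Series([mapping[s] for s in samples], index=pd.Index(samples),
                     name="condition")


def make_count_matrix(df: pd.DataFrame, conditions: pd.Series) -> CountMatrix:
    return CountMatrix(df, conditions)


def read_pvalues(path) -> np.ndarray:
    """One p-value per line; blank lines and ``#`` comments ignored."""
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(f"malformed p-value {text!r} at line {lineno} of {path}")
    p = np.asarray(values)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError(f"p-values in {path} must lie in [0, 1]")
    return p


def write_results(path, table: pd.DataFrame, metadata: dict | None = None) -> None:
    """Tab-delimited results with ``# key=value`` metadata header lines."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        table.to_csv(fh, sep="\t")


def read_results(path) -> tuple[pd.DataFrame, dict]:
    """Read a results table, returning (table, metadata)."""
    metadata = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            metadata[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t", index_col=0)
    return table, metadata


def write_truth(path, truth) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.Series:
    """Truth table -> boolean is_de Series indexed by gene."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene")["is_de"].astype(bool)


@dataclass
class RunConfig:
    """Serializable record of one CLI invocation (JSON sidecar)."""

    subcommand: str
    seed: int | None = None
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
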