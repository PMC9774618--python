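"""Validated CSV/JSON interchange and shipped reference data.

All tables are UTF-8, comma-separated, "." decimal, with a header row.  Each
reader checks the header against its schema, validates categorical columns
against their enumerations, and reports offending row numbers (1-based, not
counting the header).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DilemmaCell
from .errors import ValidationError

__all__ = [
    "TableSchema",
    "DECISIONS_SCHEMA",
    "JUDGMENTS_SCHEMA",
    "SCALES_SCHEMA",
    "DEMOGRAPHICS_SCHEMA",
    "COUNTS_SCHEMA",
    "read_table",
    "write_table",
    "load_table2_counts",
    "load_scenario_bank",
    "write_manifest",
    "file_sha256",
]

_CELL_NAMES = frozenset(c.name for c in DilemmaCell)


@dataclass(frozen=True)
class TableSchema:
    """Column contract for one long-format table."""

    name: str
    required: tuple
    optional: tuple = ()
    categorical: Mapping[str, frozenset] = None  # column -> allowed values
    binary: tuple = ()                           # columns restricted to {0, 1}
    unique_key: tuple = ()                       # composite key columns

    def validate(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.required if c not in df.columns]
        if missing:
            raise ValidationError(
                f"{self.name}: missing required column(s) {missing}; "
                f"found {list(df.columns)}"
            )
        for col, allowed in (self.categorical or {}).items():
            if col not in df.columns:
                continue
            bad = ~df[col].astype(str).isin(allowed)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
                raise ValidationError(
                    f"{self.name}: row {row}: invalid {col} value "
                    f"{df[col].iloc[row - 1]!r}; allowed: {sorted(allowed)}"
                )
        for col in self.binary:
            if col not in df.columns:
                continue
            bad = ~df[col].isin([0, 1])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
                raise ValidationError(
                    f"{self.name}: row {row}: {col} must be 0 or 1, got "
                    f"{df[col].iloc[row - 1]!r}"
                )
        if self.unique_key:
            dup = df.duplicated(subset=list(self.unique_key))
            if dup.any():
                row = int(np.flatnonzero(dup.to_numpy())[0]) + 1
                key = tuple(df.iloc[row - 1][list(self.unique_key)])
                raise ValidationError(
                    f"{self.name}: row {row}: duplicate key {key} over "
                    f"{self.unique_key}"
                )
        return df


DECISIONS_SCHEMA = TableSchema(
    name="decisions",
    required=("participant_id", "framework_id", "cell", "accept"),
    optional=("latency_s",),
    categorical={"cell": _CELL_NAMES},
    binary=("accept",),
    unique_key=("participant_id", "framework_id", "cell"),
)

JUDGMENTS_SCHEMA = TableSchema(
    name="judgments",
    required=("participant_id", "framework_id", "cell", "option"),
    categorical={"cell": _CELL_NAMES, "option": frozenset("ABCD")},
    unique_key=("participant_id", "framework_id", "cell"),
)

SCALES_SCHEMA = TableSchema(
    name="scales",
    required=("participant_id", "scale_id", "item_id", "value"),
    unique_key=("participant_id", "item_id"),
)

DEMOGRAPHICS_SCHEMA = TableSchema(
    name="demographics",
    required=("participant_id", "gender", "age", "relationship_status",
              "imc_pass", "total_latency_s"),
    optional=("latency_outlier",),
    unique_key=("participant_id",),
)

COUNTS_SCHEMA = TableSchema(
    name="counts",
    required=("framework_id", "cell", "n_consistent", "n_total"),
    optional=("short_name",),
    categorical={"cell": _CELL_NAMES},
    unique_key=("framework_id", "cell"),
)


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate one CSV table against its schema."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{schema.name}: file not found: {path}")
    df = pd.read_csv(path)
    if "imc_pass" in df.columns:
        df["imc_pass"] = df["imc_pass"].astype(bool)
    if "latency_outlier" in df.columns:
        df["latency_outlier"] = df["latency_outlier"].astype(bool)
    return schema.validate(df)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as UTF-8 comma-separated CSV without the index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_table2_counts() -> pd.DataFrame:
    """The shipped published validation-count fixture.

    13 candidate scene frameworks x 4 cells, each judged by 209 raters;
    ``n_consistent`` counts raters whose structure judgment matched the
    designed cell.  Counts, not the printed test statistics, are the ground
    truth (two published statistics are inconsistent with their counts).
    """
    with resources.files("moralcan.data").joinpath("table2_counts.csv").open("rb") as f:
        return COUNTS_SCHEMA.validate(pd.read_csv(f))


def load_scenario_bank() -> dict:
    """The shipped scenario bank: 13 candidate frameworks, four cells each.

    Includes the fully worked public-smoking framework text; other free-text
    fields are optional metadata.
    """
    with resources.files("moralcan.data").joinpath("scenario_bank.json").open(
        "r", encoding="utf-8"
    ) as f:
        bank = json.load(f)
    for fw in bank["frameworks"]:
        cells = {c["cell"] for c in fw["cells"]}
        if cells != _CELL_NAMES:
            raise ValidationError(
                f"scenario bank framework {fw['id']!r} has cells {sorted(cells)}"
            )
    return bank


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(run_dir, config: Mapping, seed, inputs: Sequence = ()) -> Path:
    """Write manifest.json echoing the resolved configuration and input hashes."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "config": _jsonable(config),
        "inputs": [
            {"path": str(p), "sha256": file_sha256(p)} for p in inputs
        ],
    }
    path = run_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return {
            k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__
        }
    return obj
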