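"""CSV interchange with metadata comment headers and schema validation.

Every output CSV starts with ``# key=value`` comment lines recording at
least the config hash and seed, so any artifact can be traced back to
the run that produced it.  ``validate_observations`` returns row-level
findings rather than raising, so a whole file can be audited in one
pass.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BH_COLUMNS, DEMO_COLUMNS, OBS_COLUMNS, SOURCE_TYPES

__all__ = [
    "read_csv",
    "write_csv",
    "read_observations",
    "write_observations",
    "Finding",
    "validate_observations",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV, returning (frame, metadata) from # key=value headers."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    return df, meta


def write_observations(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    write_csv(df[OBS_COLUMNS], path, metadata)


def read_observations(path) -> tuple[pd.DataFrame, dict]:
    df, meta = read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: observation table missing columns {missing}")
    df["excluded"] = df["excluded"].astype(bool)
    return df, meta


@dataclass
class Finding:
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    row: int | None
    column: str | None
    severity: str
    message: str


def validate_observations(path) -> list[Finding]:
    """Audit an observation CSV against the schema invariants.

    Checks column presence, value positivity, SE nonnegativity and
    source-type vocabulary; returns one finding per violation, located
    by row (0-based data row) and column.
    """
    try:
        df, _ = read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    findings: list[Finding] = []
    for col in OBS_COLUMNS:
        if col not in df.columns:
            findings.append(Finding(None, col, "error", f"missing column {col!r}"))
    if findings:
        return findings
    for i, row in df.iterrows():
        if not np.isfinite(row["value_per1000"]) or row["value_per1000"] <= 0:
            findings.append(Finding(int(i), "value_per1000", "error", "value must be positive"))
        if not np.isfinite(row["sampling_se"]) or row["sampling_se"] < 0:
            findings.append(Finding(int(i), "sampling_se", "error", "sampling_se must be nonnegative"))
        if row["source_type"] not in SOURCE_TYPES:
            findings.append(
                Finding(int(i), "source_type", "error", f"unknown source_type {row['source_type']!r}")
            )
        if not np.isfinite(row["ref_time"]):
            findings.append(Finding(int(i), "ref_time", "error", "ref_time must be a decimal year"))
    return findings


def read_demographics(path) -> tuple[pd.DataFrame, dict]:
    df, meta = read_csv(path)
    missing = [c for c in DEMO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: demographic table missing columns {missing}")
    return df, meta


def read_birth_histories(path) -> tuple[pd.DataFrame, dict]:
    df, meta = read_csv(path)
    missing = [c for c in BH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: birth-history table missing columns {missing}")
    return df, meta
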