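"""Trial-log CSV format and run configuration.

Trial logs are tidy UTF-8 CSV files with a header row, '.' decimals
and '#'-prefixed metadata lines (the first of which stamps the schema
version). One row is one report.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .observers import LOG_COLUMNS, ARCHITECTURES

__all__ = ["SchemaError", "RunConfig", "read_trial_log", "write_trial_log", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

_FLOAT_FORMAT = "%.6f"


class SchemaError(ValueError):
    """A trial log violates the schema; the message names column and row."""


class RunConfig(BaseModel):
    """Validated configuration for an end-to-end simulation run."""

    model_config = ConfigDict(extra="forbid")

    preset: str = "exp1b"
    architecture: str = "exclusive"
    n_observers: int = Field(default=4, ge=2)
    seed: int = 0
    deviation_convention: str = "direction_change"
    alpha: float = Field(default=0.05, gt=0, lt=1)
    jitter: float = Field(default=0.1, ge=0)

    def model_post_init(self, _ctx) -> None:
        if self.preset not in ("exp1a", "exp1b", "exp2", "exp3"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.deviation_convention not in ("direction_change", "interior_angle"):
            raise ValueError(f"unknown deviation convention {self.deviation_convention!r}")


def write_trial_log(records: pd.DataFrame, path) -> None:
    """Write a response log with the schema header comment."""
    path = Path(path)
    missing = [c for c in LOG_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"log is missing columns {missing}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# motmem trial log schema v{SCHEMA_VERSION}\n")
        records[LOG_COLUMNS].to_csv(fh, index=False, float_format=_FLOAT_FORMAT)


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Schema violations raise :class:`SchemaError` naming the offending
    column and row; an empty file returns an empty frame with a
    warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty; returning an empty log")
        return pd.DataFrame(columns=LOG_COLUMNS)
    if df.empty:
        warnings.warn(f"{path} contains no records")
        return pd.DataFrame(columns=LOG_COLUMNS)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"log is missing columns {missing}")

    def _fail_rows(mask: pd.Series, column: str, why: str):
        if mask.any():
            row = int(df.index[mask][0])
            raise SchemaError(f"column {column!r}, row {row}: {why}")

    for col in ("error_deg", "tp", "true_dir_deg", "reported_dir_deg", "cue_delay_ms"):
        _fail_rows(~np.isfinite(df[col]), col, "non-finite value")
    _fail_rows((df["error_deg"] <= -180) | (df["error_deg"] > 180), "error_deg",
               "outside (-180, 180]")
    _fail_rows((df["tp"] < 0) | (df["tp"] > 1), "tp", "outside [0, 1]")
    _fail_rows(df["report_order"] < 1, "report_order", "must be >= 1")
    _fail_rows(df["report_order"] > df["set_size"], "report_order", "exceeds set size")
    return df
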