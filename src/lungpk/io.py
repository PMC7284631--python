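"""Long-format record I/O, configuration loading, and report writing.

The interchange format everywhere is a long-format CSV with columns
``drug, matrix, time_h, conc`` — one observation per row, uniform across
drugs and matrices.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .domain import MATRICES
from .estimation import FitResult

__all__ = [
    "COLUMNS",
    "SchemaError",
    "validate_records",
    "read_records",
    "write_records",
    "profiles_to_frame",
    "load_config",
    "write_fit_report",
    "config_hash",
]

COLUMNS = ("drug", "matrix", "time_h", "conc")


class SchemaError(ValueError):
    """A record table violates the long-format schema."""


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    for col in COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r}")
    bad_matrix = ~df["matrix"].isin(MATRICES)
    if bad_matrix.any():
        row = int(df.index[bad_matrix][0])
        raise SchemaError(
            f"row {row}, column 'matrix': unknown matrix {df.loc[row, 'matrix']!r}"
        )
    for col, ok in (("time_h", df["time_h"] >= 0), ("conc", df["conc"] >= 0)):
        bad = ~ok
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(f"row {row}, column {col!r}: negative value")
    return df


def read_records(path) -> pd.DataFrame:
    """Read and schema-check a long-format record CSV."""
    return validate_records(pd.read_csv(path))


def write_records(df: pd.DataFrame, path) -> None:
    validate_records(df)
    df.to_csv(path, index=False)


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Flatten simulated profiles into the long record format."""
    rows = []
    for prof in profiles:
        for t, c in zip(prof.times, prof.concs):
            rows.append({"drug": prof.drug, "matrix": prof.matrix, "time_h": t, "conc": c})
    return pd.DataFrame(rows, columns=list(COLUMNS))


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("config file must contain a mapping")
    return cfg


def write_fit_report(fit: FitResult, stem) -> None:
    """Write a fit as aligned text (<stem>.txt) and JSON (<stem>.json)."""
    stem = Path(stem)
    lines = [f"{'parameter':<24}{'estimate':>14}{'cv_percent':>12}"]
    for name in fit.param_names:
        lines.append(
            f"{name:<24}{fit.estimates[name]:>14.6g}{fit.cv_percent[name]:>12.3g}"
        )
    lines.append(f"objective {fit.objective:.6g}  n_obs {fit.n_obs}")
    stem.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    payload = {
        "estimates": fit.estimates,
        "cv_percent": fit.cv_percent,
        "objective": fit.objective,
        "n_obs": fit.n_obs,
    }
    stem.with_suffix(".json").write_text(json.dumps(payload, indent=2) + "\n")


def config_hash(mapping: dict) -> str:
    """Short deterministic hash of a configuration mapping, for run logs."""
    blob = json.dumps(mapping, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
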