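"""Delimited-text interchange for cohorts, epoch series and run manifests.

Everything is plain UTF-8 CSV with '.' decimals; floats round-trip exactly
(shortest-repr serialisation). Unknown columns are preserved.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ParseError, SchemaError
from .config import CohortConfig, config_hash

__all__ = [
    "MANDATORY_COLUMNS",
    "read_cohort",
    "write_cohort",
    "read_epoch_series",
    "write_epoch_series",
    "build_manifest",
    "spawn_seeds",
]

# the raw measures every scoring stage consumes
MANDATORY_COLUMNS: tuple[str, ...] = (
    "pid", "sex", "age",
    "fcsrt", "logical_memory", "dsst", "fluency", "mattis",
    "education", "fnart", "occupation", "sport", "leisure",
    "bdi", "bai",
    "sbp", "heart_rate", "pulse_pressure", "sdann", "rmssd",
    "bmi", "whr", "ldl", "hdl", "triglycerides",
    "hba1c", "glucose", "crp", "il6",
    "dheas", "cortisol", "adrenaline", "noradrenaline", "serum_creatinine",
    "iv", "psqi", "ess",
)

_INT_COLUMNS = {"pid", "sex"}


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV (floats serialised to full precision)."""
    table.to_csv(path, index=False)


def read_cohort(path: str | Path, require: tuple[str, ...] = MANDATORY_COLUMNS) -> pd.DataFrame:
    """Read a cohort CSV, validating the column dictionary and every cell.

    Raises a schema error naming any missing mandatory column, and a parse
    error addressed by row and column for an unparseable cell. NA cells are
    preserved. Unknown columns pass through untouched.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in require if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} missing mandatory column(s): {', '.join(missing)}")
    out = {}
    for col in df.columns:
        if col not in require:
            out[col] = df[col]
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"unparseable cell at row {row + 2}, column {col!r}: {df[col][row]!r}"
            )
        if col in _INT_COLUMNS and parsed.notna().all():
            parsed = parsed.astype(int)
        out[col] = parsed
    return pd.DataFrame(out)[list(df.columns)]


def write_epoch_series(values: np.ndarray, path: str | Path, value_name: str = "value") -> None:
    """Two-column delimited series: epoch index, value."""
    pd.DataFrame({"index": np.arange(len(values)), value_name: values}).to_csv(path, index=False)


def read_epoch_series(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"epoch file {path} must have (index, value) columns")
    return df.iloc[:, 1].to_numpy(dtype=float)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan a single seed out into per-stage child seeds (deterministic)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def build_manifest(
    config: CohortConfig, seed: int, counts: dict[str, int], outputs: dict[str, str]
) -> dict:
    from . import __version__

    return {
        "package": "cogload",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config.model_dump(mode="json"),
        "row_counts": counts,
        "outputs": outputs,
        "created": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
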