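"""Delimited-file dialect and configuration handling shared by all stages.

Matrices travel as comma-separated UTF-8 text with a header row and
``subject_id`` as the first column; '.' is the decimal separator.  Every run
directory contains an exact echo of its resolved configuration so a pipeline
is reproducible bitwise from the echo and the seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import DeltaMatrix, CohortTable


def read_matrix_csv(path: str | Path, modality: str = "region") -> DeltaMatrix:
    """Read a subjects x features matrix, validating shape and ids.

    Ragged rows, non-numeric cells and duplicate subject ids are hard errors
    reported with a line number (header is line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    if df.columns[0] != "subject_id":
        raise ValueError(f"{path}: first column must be 'subject_id'")
    dup = df["subject_id"].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise ValueError(
            f"{path}:{line}: duplicate subject id {df.loc[dup.idxmax(), 'subject_id']!r}"
        )
    feature_cols = list(df.columns[1:])
    values = np.empty((len(df), len(feature_cols)))
    for j, col in enumerate(feature_cols):
        for i, cell in enumerate(df[col]):
            try:
                # float() is correctly rounded, so write/read is lossless
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}:{i + 2}: non-numeric cell in column {col!r}"
                ) from None
    return DeltaMatrix(values, list(df["subject_id"]), feature_cols, modality)


def write_matrix_csv(matrix: DeltaMatrix, path: str | Path) -> None:
    # default float repr is shortest-round-trip, so reading back is lossless
    matrix.to_frame().to_csv(path)


def read_cohort_csv(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, dtype={"subject_id": str})
    return CohortTable(df)


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, index=False)


def write_sidecar(path: str | Path, payload: dict) -> None:
    """JSON sidecar (column stats, dropped subjects, traces, config echoes)."""
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def resolve_config(defaults: dict, file_path: str | Path | None = None,
                   flags: dict | None = None) -> dict:
    """Merge defaults < YAML file < CLI flags; unknown keys and type
    mismatches are hard errors naming the key."""
    resolved = dict(defaults)
    for source_name, source in (
        ("config file", _load_yaml(file_path)),
        ("flags", {k: v for k, v in (flags or {}).items() if v is not None}),
    ):
        for key, value in source.items():
            if key not in defaults:
                raise KeyError(f"unknown configuration key {key!r} in {source_name}")
            expected = type(defaults[key])
            if defaults[key] is not None and not isinstance(value, expected):
                if expected is float and isinstance(value, int):
                    value = float(value)
                else:
                    raise TypeError(
                        f"configuration key {key!r}: expected {expected.__name__}, "
                        f"got {type(value).__name__}"
                    )
            resolved[key] = value
    return resolved


def _load_yaml(path: str | Path | None) -> dict:
    if path is None:
        return {}
    loaded = yaml.safe_load(Path(path).read_text())
    return loaded or {}
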