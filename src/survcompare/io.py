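"""Cohort CSV / schema-file reading and validated report writing.

Cohort CSV dialect: comma-separated UTF-8 with a mandatory header, columns
``time`` (positive hours, ``.`` decimal) and ``event`` (0/1) first, then
one column per covariate; no index column.  The schema file is YAML
mapping each covariate name to ``numeric`` or an ordered level list
(first level = reference).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortDataset, CohortError, CovariateSchema
from .compare import ComparisonReport, _sig6

logger = logging.getLogger(__name__)


def read_schema(path: str | Path) -> CovariateSchema:
    """Read a covariate schema from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise CohortError(f"schema file {path} must map covariate names to kinds")
    covariates: dict[str, str | tuple[str, ...]] = {}
    for name, kind in raw.items():
        if isinstance(kind, str):
            covariates[str(name)] = kind
        elif isinstance(kind, (list, tuple)):
            covariates[str(name)] = tuple(str(v) for v in kind)
        else:
            raise CohortError(
                f"schema entry {name!r}: expected 'numeric' or a level list, got {kind!r}"
            )
    return CovariateSchema(covariates)


def write_schema(schema: CovariateSchema, path: str | Path) -> None:
    payload = {
        name: ("numeric" if schema.is_numeric(name) else list(schema.levels(name)))
        for name in schema.names
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_cohort_csv(path: str | Path, schema: CovariateSchema) -> CohortDataset:
    """Read and validate a cohort CSV against a schema.

    Errors name the offending row (1-based, excluding the header): missing
    or nonpositive times, events outside {0, 1}, unknown categorical levels.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("time", "event"):
        if col not in frame.columns:
            raise CohortError(f"{path}: required column {col!r} missing")
    missing = frame.index[frame["time"].isna() | frame["event"].isna()]
    if len(missing):
        raise CohortError(
            f"{path}: missing time/event at row(s) {[int(i) + 1 for i in missing]}"
        )
    times = pd.to_numeric(frame["time"], errors="coerce")
    if times.isna().any() or (times <= 0).any():
        bad = frame.index[times.isna() | (times <= 0)]
        raise CohortError(f"{path}: nonpositive time at row(s) {[int(i) + 1 for i in bad]}")
    events = pd.to_numeric(frame["event"], errors="coerce")
    if events.isna().any() or (~events.isin((0, 1))).any():
        bad = frame.index[events.isna() | ~events.isin((0, 1))]
        raise CohortError(f"{path}: event not in {{0,1}} at row(s) {[int(i) + 1 for i in bad]}")
    try:
        return CohortDataset.from_frame(frame, schema)
    except CohortError as exc:
        raise CohortError(f"{path}: {exc}") from exc


def write_cohort_csv(data: CohortDataset, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False)


def _round_floats(obj):
    if isinstance(obj, float):
        return _sig6(obj)
    if isinstance(obj, (np.floating,)):
        return _sig6(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_round_floats(v) for v in obj.tolist()]
    return obj


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Write a comparison report or a plain summary mapping to disk.

    JSON output uses stable (sorted) key order and floats rounded to 6
    significant digits; CSV is available for the table-shaped comparison
    report (columns ``model, error_rate, c_index, most_predictive_variables``).
    """
    path = Path(path)
    if format not in ("json", "csv"):
        raise ValueError(f"unknown report format {format!r}")
    if isinstance(report, ComparisonReport):
        text = report.to_json() if format == "json" else report.to_csv()
    elif format == "json":
        text = json.dumps(_round_floats(report), indent=2, sort_keys=True)
    else:
        raise ValueError("csv output is only defined for comparison reports")
    try:
        path.write_text(text if text.endswith("\n") else text + "\n", encoding="utf-8")
    except OSError as exc:
        raise CohortError(f"cannot write report to {path}: {exc}") from exc
    logger.info("wrote %s report to %s", format, path)
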