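"""Right-censored cohort container and covariate schema.

A cohort is a collection of ``(time, event, covariates)`` records where
``time`` is a positive duration (hours in the motivating application),
``event`` is the death/censoring indicator delta (1 = event observed,
0 = right-censored), and the covariates are a mix of numeric and
categorical variables described by a :class:`CovariateSchema`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("time", "event")

NUMERIC = "numeric"


class CohortError(ValueError):
    """Raised when a cohort or schema violates its invariants."""


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered description of cohort covariates.

    Parameters
    ----------
    covariates
        Mapping of covariate name to either the string ``"numeric"`` or an
        ordered sequence of categorical levels.  The first level of a
        categorical covariate is its reference level.  Insertion order is
        meaningful: it fixes design-matrix column order and split-search
        tie-breaking.
    """

    covariates: dict[str, str | tuple[str, ...]]

    def __post_init__(self) -> None:
        cleaned: dict[str, str | tuple[str, ...]] = {}
        for name, kind in self.covariates.items():
            if name in RESERVED_COLUMNS:
                raise CohortError(
                    f"covariate name {name!r} is reserved for the time/event columns"
                )
            if isinstance(kind, str):
                if kind != NUMERIC:
                    raise CohortError(
                        f"covariate {name!r}: kind must be 'numeric' or a level list, got {kind!r}"
                    )
                cleaned[name] = NUMERIC
            else:
                levels = tuple(str(v) for v in kind)
                if len(levels) < 2:
                    raise CohortError(f"categorical covariate {name!r} needs >=2 levels")
                if len(set(levels)) != len(levels):
                    raise CohortError(f"categorical covariate {name!r} has duplicate levels")
                cleaned[name] = levels
        object.__setattr__(self, "covariates", cleaned)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.covariates)

    def is_numeric(self, name: str) -> bool:
        return self.covariates[name] == NUMERIC

    def levels(self, name: str) -> tuple[str, ...]:
        kind = self.covariates[name]
        if kind == NUMERIC:
            raise CohortError(f"covariate {name!r} is numeric, it has no levels")
        return kind  # type: ignore[return-value]

    def reference_level(self, name: str) -> str:
        return self.levels(name)[0]


@dataclass
class CohortDataset:
    """Right-censored time-to-event records with a covariate schema.

    Invariants: all times strictly positive, events in {0, 1}, every record
    carries a value for every schema covariate, and categorical values belong
    to the declared level lists.
    """

    times: np.ndarray
    events: np.ndarray
    covariates: pd.DataFrame
    schema: CovariateSchema = field(repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events)
        if self.times.ndim != 1:
            raise CohortError("times must be one-dimensional")
        if len(self.times) == 0:
            raise CohortError("cohort has no records")
        if len(self.times) != len(self.events) or len(self.times) != len(self.covariates):
            raise CohortError("times, events and covariates must have equal length")
        if not np.all(np.isfinite(self.times)) or np.any(self.times <= 0):
            bad = np.flatnonzero(~np.isfinite(self.times) | (self.times <= 0))
            raise CohortError(f"nonpositive or non-finite time at record(s) {bad.tolist()}")
        if not np.all(np.isin(self.events, (0, 1))):
            bad = np.flatnonzero(~np.isin(self.events, (0, 1)))
            raise CohortError(f"event indicator not in {{0,1}} at record(s) {bad.tolist()}")
        self.events = self.events.astype(np.int8)
        self.covariates = self.covariates.reset_index(drop=True)
        for name in self.schema.names:
            if name not in self.covariates.columns:
                raise CohortError(f"covariate column {name!r} missing from records")
            col = self.covariates[name]
            if self.schema.is_numeric(name):
                values = pd.to_numeric(col, errors="coerce")
                if values.isna().any():
                    bad = values.index[values.isna()].tolist()
                    raise CohortError(f"non-numeric value for {name!r} at record(s) {bad}")
                self.covariates[name] = values.astype(float)
            else:
                levels = self.schema.levels(name)
                col = col.astype(str)
                unknown = ~col.isin(levels)
                if unknown.any():
                    bad = col.index[unknown].tolist()
                    raise CohortError(
                        f"value(s) {sorted(set(col[unknown]))} for covariate {name!r} "
                        f"not in declared levels {list(levels)} (record(s) {bad})"
                    )
                self.covariates[name] = col
        # drop any extra columns so the frame mirrors the schema exactly
        self.covariates = self.covariates[list(self.schema.names)]

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def subset(self, indices: Iterable[int] | np.ndarray) -> "CohortDataset":
        """Row subset (keeps order of ``indices``; duplicates allowed)."""
        idx = np.asarray(list(indices) if not isinstance(indices, np.ndarray) else indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CohortDataset(
            times=self.times[idx],
            events=self.events[idx],
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            schema=self.schema,
        )

    def drop(self, indices: Iterable[int]) -> "CohortDataset":
        """Complement subset: the cohort without the given record positions."""
        drop = set(int(i) for i in indices)
        keep = [i for i in range(len(self)) if i not in drop]
        if not keep:
            raise CohortError("dropping all records leaves an empty cohort")
        return self.subset(np.asarray(keep))

    def to_frame(self) -> pd.DataFrame:
        """Flat DataFrame with ``time``, ``event`` and covariate columns."""
        out = pd.DataFrame({"time": self.times, "event": self.events})
        for name in self.schema.names:
            out[name] = self.covariates[name].to_numpy()
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, schema: CovariateSchema) -> "CohortDataset":
        for col in RESERVED_COLUMNS:
            if col not in frame.columns:
                raise CohortError(f"required column {col!r} missing")
        return cls(
            times=frame["time"].to_numpy(dtype=float),
            events=frame["event"].to_numpy(),
            covariates=frame[[c for c in frame.columns if c not in RESERVED_COLUMNS]].copy(),
            schema=schema,
        )


def validate_pattern(schema: CovariateSchema, covariates: Mapping[str, object]) -> dict[str, object]:
    """Validate a single covariate pattern (e.g. for prediction) against a schema."""
    pattern: dict[str, object] = {}
    for name in schema.names:
        if name not in covariates:
            raise CohortError(f"pattern is missing covariate {name!r}")
        value = covariates[name]
        if schema.is_numeric(name):
            pattern[name] = float(value)  # type: ignore[arg-type]
        else:
            value = str(value)
            if value not in schema.levels(name):
                raise CohortError(
                    f"value {value!r} for covariate {name!r} not in levels {list(schema.levels(name))}"
                )
            pattern[name] = value
    return pattern
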