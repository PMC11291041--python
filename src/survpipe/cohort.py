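"""Tabular survival cohorts: schema, reading/writing, encoding, perturbation.

A cohort is a CSV table with one row per patient: a positive duration column
(time to event or censoring), a binary event indicator, and an arbitrary mix
of continuous and categorical covariates that may contain missing cells
(empty string or ``NA``).  The :class:`SurvivalDataset` carries the covariate
table together with its missingness mask; :func:`encode` turns a complete
dataset into a numeric design matrix with leakage-safe standardisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from survpipe import audit

logger = logging.getLogger(__name__)

KINDS = ("continuous", "categorical", "duration", "event", "treatment")
NA_VALUES = ("", "NA")


@dataclass(frozen=True)
class ColumnSchema:
    """Declared role of one cohort column.

    Parameters
    ----------
    name : column name as it appears in the CSV header.
    kind : one of ``continuous``, ``categorical``, ``duration``, ``event``,
        ``treatment``.  Treatment columns behave like categorical covariates
        but are singled out for counterfactual prediction.
    units : free-text time units; required for the duration column.
    levels : ordered category labels; required for categorical/treatment.
    """

    name: str
    kind: str
    units: str | None = None
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown column kind {self.kind!r} for {self.name!r}")
        if self.kind in ("categorical", "treatment"):
            if not self.levels:
                raise ValueError(f"column {self.name!r}: levels required for {self.kind}")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"column {self.name!r}: duplicate levels")
            object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))


def validate_schema(schema: Sequence[ColumnSchema]) -> None:
    """Enforce the one-duration/one-event invariant and unique names."""
    names = [c.name for c in schema]
    if len(set(names)) != len(names):
        raise ValueError("duplicate column names in schema")
    for kind in ("duration", "event"):
        n = sum(c.kind == kind for c in schema)
        if n != 1:
            raise ValueError(f"schema must declare exactly one {kind} column, found {n}")


def schema_from_dicts(entries: Iterable[Mapping]) -> list[ColumnSchema]:
    schema = [
        ColumnSchema(
            name=e["name"],
            kind=e["kind"],
            units=e.get("units"),
            levels=tuple(e["levels"]) if e.get("levels") else None,
        )
        for e in entries
    ]
    validate_schema(schema)
    return schema


def load_schema(path: str) -> list[ColumnSchema]:
    """Load a schema from a YAML file (a list of column blocks)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["columns"] if isinstance(doc, dict) else doc
    return schema_from_dicts(entries)


def _covariate_columns(schema: Sequence[ColumnSchema]) -> list[ColumnSchema]:
    return [c for c in schema if c.kind in ("continuous", "categorical", "treatment")]


@dataclass
class SurvivalDataset:
    """A cohort: covariate table + durations + event indicators.

    ``values`` holds covariate columns only (continuous as float with NaN for
    missing, categorical as string with NaN).  ``durations`` may contain NaN
    only for prediction-time rows constructed in memory; rows read from disk
    always have complete outcomes.
    """

    schema: list[ColumnSchema]
    values: pd.DataFrame
    durations: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        validate_schema(self.schema)
        self.durations = np.asarray(self.durations, dtype=float)
        self.events = np.asarray(self.events, dtype=float)
        n = len(self.values)
        if len(self.durations) != n or len(self.events) != n:
            raise ValueError("durations/events length mismatch with covariate table")
        obs = ~np.isnan(self.durations)
        if np.any(self.durations[obs] <= 0):
            raise ValueError("durations must be positive")
        ev = self.events[~np.isnan(self.events)]
        if not np.all(np.isin(ev, (0.0, 1.0))):
            raise ValueError("events must be 0 or 1")
        cov_names = [c.name for c in _covariate_columns(self.schema)]
        if list(self.values.columns) != cov_names:
            raise ValueError("covariate table columns must match schema order")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True exactly where a covariate value is absent."""
        return self.values.isna()

    @property
    def duration_column(self) -> ColumnSchema:
        return next(c for c in self.schema if c.kind == "duration")

    @property
    def event_column(self) -> ColumnSchema:
        return next(c for c in self.schema if c.kind == "event")

    def covariate_schema(self) -> list[ColumnSchema]:
        return _covariate_columns(self.schema)

    def subset(self, index: np.ndarray) -> "SurvivalDataset":
        """Row subset (positional indices or boolean mask)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SurvivalDataset(
            schema=self.schema,
            values=self.values.iloc[index].reset_index(drop=True),
            durations=self.durations[index],
            events=self.events[index],
        )

    def copy(self) -> "SurvivalDataset":
        return SurvivalDataset(
            schema=list(self.schema),
            values=self.values.copy(),
            durations=self.durations.copy(),
            events=self.events.copy(),
        )


def read_cohort(path: str, schema: Sequence[ColumnSchema]) -> SurvivalDataset:
    """Read a cohort CSV, dropping rows with unusable outcome data.

    Rows with a missing duration or event are dropped (count logged); rows
    with a non-positive duration, a non-binary event or an unrecognised
    categorical level are rejected individually with a logged reason.
    Missing covariate cells (empty or ``NA``) populate the missingness mask.
    """
    schema = list(schema)
    validate_schema(schema)
    raw = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=list(NA_VALUES)
    )
    missing_cols = [c.name for c in schema if c.name not in raw.columns]
    if missing_cols:
        raise ValueError(f"CSV header missing schema columns: {missing_cols}")

    dur_col = next(c for c in schema if c.kind == "duration")
    ev_col = next(c for c in schema if c.kind == "event")

    durations = pd.to_numeric(raw[dur_col.name], errors="coerce")
    events = pd.to_numeric(raw[ev_col.name], errors="coerce")

    keep = np.ones(len(raw), dtype=bool)
    n_outcome_missing = int((durations.isna() | events.isna()).sum())
    keep &= ~(durations.isna() | events.isna()).to_numpy()
    if n_outcome_missing:
        logger.info("dropped %d rows with missing duration/event", n_outcome_missing)
        audit.record("rows_dropped", reason="missing_outcome", count=n_outcome_missing)

    bad_dur = keep & (durations.to_numpy() <= 0)
    for i in np.flatnonzero(bad_dur):
        logger.warning("row %d rejected: duration %s <= 0", i, durations.iloc[i])
    keep &= ~bad_dur
    bad_ev = keep & ~np.isin(events.to_numpy(), (0.0, 1.0))
    for i in np.flatnonzero(bad_ev):
        logger.warning("row %d rejected: event %s not in {0,1}", i, events.iloc[i])
    keep &= ~bad_ev

    cov_schema = _covariate_columns(schema)
    frames = {}
    for col in cov_schema:
        s = raw[col.name]
        if col.kind == "continuous":
            vals = pd.to_numeric(s, errors="coerce")
            bad = keep & s.notna().to_numpy() & vals.isna().to_numpy()
            for i in np.flatnonzero(bad):
                logger.warning("row %d rejected: %r not numeric in %s", i, s.iloc[i], col.name)
            keep &= ~bad
            frames[col.name] = vals.astype(float)
        else:
            bad = keep & s.notna().to_numpy() & ~s.isin(col.levels).to_numpy()
            for i in np.flatnonzero(bad):
                logger.warning(
                    "row %d rejected: unknown level %r in %s", i, s.iloc[i], col.name
                )
            keep &= ~bad
            frames[col.name] = s.astype(object).where(s.notna(), np.nan)

    idx = np.flatnonzero(keep)
    values = pd.DataFrame({c.name: frames[c.name].iloc[idx].reset_index(drop=True) for c in cov_schema})
    ds = SurvivalDataset(
        schema=schema,
        values=values,
        durations=durations.to_numpy()[idx],
        events=events.to_numpy()[idx],
    )
    audit.record("read_cohort", path=str(path), n=ds.n, dropped=int(len(raw) - ds.n))
    return ds


def write_cohort(dataset: SurvivalDataset, path: str) -> None:
    """Write a cohort to CSV in the same dialect read_cohort accepts."""
    out = dataset.values.copy()
    out[dataset.duration_column.name] = dataset.durations
    out[dataset.event_column.name] = dataset.events.astype(int)
    # restore schema column order
    out = out[[c.name for c in dataset.schema]]
    out.to_csv(path, index=False, na_rep="NA")


@dataclass(frozen=True)
class ColumnProvenance:
    """Where one design-matrix column came from."""

    source: str
    kind: str  # "continuous" | "indicator"
    level: str | None = None
    mu: float | None = None
    sigma: float | None = None


@dataclass
class DesignMatrix:
    """Numeric, complete matrix ready for model fitting.

    Continuous columns are standardised with the *training-set* mean and
    population (1/n) standard deviation stored in the provenance; categorical
    columns are expanded to one indicator per level (no reference drop).
    """

    matrix: np.ndarray
    provenance: list[ColumnProvenance]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def q(self) -> int:
        return self.matrix.shape[1]


def fit_encoding(dataset: SurvivalDataset) -> list[ColumnProvenance]:
    """Derive standardisation stats and level maps from a complete dataset."""
    prov: list[ColumnProvenance] = []
    for col in dataset.covariate_schema():
        if col.kind == "continuous":
            x = dataset.values[col.name].to_numpy(dtype=float)
            mu = float(np.mean(x))
            sigma = float(np.std(x))  # population sd by convention
            if sigma == 0.0:
                raise ValueError(f"zero-variance continuous column {col.name!r}")
            prov.append(ColumnProvenance(col.name, "continuous", mu=mu, sigma=sigma))
        else:
            for level in col.levels:
                prov.append(ColumnProvenance(col.name, "indicator", level=level))
    return prov


def encode(
    dataset: SurvivalDataset,
    fit_stats: Sequence[ColumnProvenance] | None = None,
) -> DesignMatrix:
    """Encode a complete dataset to a design matrix.

    When ``fit_stats`` is given (the provenance of a training-set encoding)
    its means/sds and level sets are reused verbatim — validation data never
    refits the encoder.
    """
    if dataset.missing_mask.to_numpy().any():
        raise ValueError("dataset has missing covariates; impute before encoding")
    refit = fit_stats is None
    prov = fit_encoding(dataset) if refit else list(fit_stats)
    audit.record("encode", n=dataset.n, refit=refit)

    levels_by_source: dict[str, list[str]] = {}
    for p in prov:
        if p.kind == "indicator":
            levels_by_source.setdefault(p.source, []).append(p.level)

    cols = []
    for p in prov:
        if p.kind == "continuous":
            x = dataset.values[p.source].to_numpy(dtype=float)
            cols.append((x - p.mu) / p.sigma)
        else:
            s = dataset.values[p.source].astype(str)
            unknown = set(s.unique()) - set(levels_by_source[p.source])
            if unknown:
                raise ValueError(
                    f"levels {sorted(unknown)} of {p.source!r} absent from encoding provenance"
                )
            cols.append((s == p.level).to_numpy(dtype=float))
    matrix = np.column_stack(cols) if cols else np.empty((dataset.n, 0))
    return DesignMatrix(matrix=matrix, provenance=prov)


def encode_row(row: pd.Series, schema: Sequence[ColumnSchema], prov: Sequence[ColumnProvenance]) -> np.ndarray:
    """Encode a single covariate row (as a Series) with frozen stats."""
    frame = pd.DataFrame([row])
    dummy = SurvivalDataset(
        schema=list(schema),
        values=frame[[c.name for c in _covariate_columns(schema)]].reset_index(drop=True),
        durations=np.array([1.0]),
        events=np.array([1.0]),
    )
    return encode(dummy, fit_stats=prov).matrix[0]


def shuffle_covariates(dataset: SurvivalDataset, seed: int) -> SurvivalDataset:
    """Independently permute each covariate column across rows.

    Durations and events are untouched; this severs every covariate–outcome
    relationship while preserving each column's marginal, the standard
    negative-control construction for ablation experiments.
    """
    rng = np.random.default_rng(seed)
    values = dataset.values.copy()
    for name in values.columns:
        perm = rng.permutation(dataset.n)
        values[name] = values[name].to_numpy()[perm]
    audit.record("shuffle_covariates", seed=seed, n=dataset.n)
    return SurvivalDataset(
        schema=list(dataset.schema),
        values=values,
        durations=dataset.durations.copy(),
        events=dataset.events.copy(),
    )
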