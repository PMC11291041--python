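"""Quartile-grid synthetic patients and per-patient best-treatment choice.

To explore how a trained model would treat the space of plausible patients,
every continuous covariate is summarised by four within-quartile medians and
every categorical covariate by its levels; the Cartesian product of those
representatives (excluding the treatment column) is the patient grid.  For
each synthetic patient the treatment level with the largest predicted median
survival is recommended.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from survpipe.bagging import ModelBag, bag_predict
from survpipe.cohort import ColumnSchema, SurvivalDataset, encode_row
from survpipe.hazard import median_survival

logger = logging.getLogger(__name__)


def quartile_representatives(values: np.ndarray) -> list[float]:
    """Within-quartile medians of the observed values.

    Values are bucketed by the 25/50/75% quantiles; each bucket contributes
    its median.  Columns with fewer than 4 distinct values fall back to their
    distinct values (logged by the caller).
    """
    values = np.asarray(values, dtype=float)
    q25, q50, q75 = np.quantile(values, [0.25, 0.5, 0.75])
    buckets = [
        values[values <= q25],
        values[(values > q25) & (values <= q50)],
        values[(values > q50) & (values <= q75)],
        values[values > q75],
    ]
    return [float(np.median(b)) for b in buckets if len(b)]


@dataclass
class PatientGrid:
    """Synthetic patients spanning covariate-representative combinations."""

    rows: pd.DataFrame
    representatives: dict[str, list] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.rows)


def quartile_grid(dataset: SurvivalDataset) -> PatientGrid:
    """All combinations of per-covariate representatives (treatment excluded)."""
    if dataset.missing_mask.to_numpy().any():
        raise ValueError("dataset must be complete (impute first)")
    reps: dict[str, list] = {}
    for col in dataset.covariate_schema():
        if col.kind == "treatment":
            continue
        if col.kind == "continuous":
            vals = dataset.values[col.name].to_numpy(dtype=float)
            distinct = np.unique(vals)
            if len(distinct) < 4:
                logger.warning("covariate %s has %d distinct values; using them directly",
                               col.name, len(distinct))
                reps[col.name] = [float(v) for v in distinct]
            else:
                reps[col.name] = quartile_representatives(vals)
        else:
            reps[col.name] = list(col.levels)
    if not any(c.kind == "continuous" for c in dataset.covariate_schema()):
        raise ValueError("at least one continuous covariate required")
    names = list(reps)
    combos = list(itertools.product(*(reps[n] for n in names)))
    rows = pd.DataFrame(combos, columns=names)
    return PatientGrid(rows=rows, representatives=reps)


@dataclass
class TreatmentRecommendation:
    patient: dict
    medians: dict[str, float]
    recommended: str
    margin: float
    extrapolated: dict[str, bool] = field(default_factory=dict)


def best_treatment(
    bag: ModelBag,
    patient: pd.Series | dict,
    schema: list[ColumnSchema],
    treatment: ColumnSchema,
) -> TreatmentRecommendation:
    """Predict median survival under every treatment level; recommend the max.

    Extrapolated medians (curve never reaching 0.5 on its mesh) are flagged
    per level rather than suppressed.
    """
    if treatment.kind != "treatment" or len(treatment.levels) < 2:
        raise ValueError("treatment column must have >= 2 levels")
    if bag.encode_stats is None:
        raise ValueError("bag lacks encoding provenance; train with encode_stats")
    patient = pd.Series(dict(patient))
    medians: dict[str, float] = {}
    extrapolated: dict[str, bool] = {}
    for level in treatment.levels:
        row = patient.copy()
        row[treatment.name] = level
        x = encode_row(row, schema, bag.encode_stats)
        m = median_survival(bag_predict(bag, x))
        medians[level] = m.time
        extrapolated[level] = m.extrapolated
    ordered = sorted(medians.values(), reverse=True)
    # tie-break lexicographically so the choice is invariant to level order
    best = max(sorted(treatment.levels), key=lambda lv: medians[lv])
    margin = ordered[0] - ordered[1] if len(ordered) > 1 else 0.0
    return TreatmentRecommendation(
        patient=dict(patient),
        medians=medians,
        recommended=best,
        margin=float(margin),
        extrapolated=extrapolated,
    )


def recommend_grid(
    bag: ModelBag,
    grid: PatientGrid,
    schema: list[ColumnSchema],
    treatment: ColumnSchema,
) -> pd.DataFrame:
    """Best treatment for every synthetic patient; one output row each."""
    records = []
    for _, row in grid.rows.iterrows():
        rec = best_treatment(bag, row, schema, treatment)
        entry = dict(rec.patient)
        for level, med in rec.medians.items():
            entry[f"median_{level}"] = med
            entry[f"extrapolated_{level}"] = rec.extrapolated[level]
        entry["recommended"] = rec.recommended
        entry["margin"] = rec.margin
        records.append(entry)
    return pd.DataFrame(records)
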