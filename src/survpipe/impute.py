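"""Iterative random-forest imputation of mixed-type covariates.

One round initialises missing cells (column mean / mode), then repeatedly
refits one forest per incomplete column — visited in ascending order of
missing count — predicting that column's missing cells from all other
columns (optionally plus the outcome), until the imputed matrix first
diverges.  Cell values are averaged over several independently seeded rounds
(majority vote for categoricals).  A mask-and-score harness measures how
well held-out observed values are recovered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from survpipe import audit
from survpipe.cohort import ColumnSchema, SurvivalDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for iterative forest imputation."""

    rounds: int = 10
    max_iterations: int = 10
    trees: int = 100
    include_outcome: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.trees < 1:
            raise ValueError("trees must be >= 1")


@dataclass
class CovariateScore:
    name: str
    kind: str  # continuous | categorical
    r: float  # Pearson r (continuous) or accuracy (categorical)
    p: float | None
    n_pairs: int


@dataclass
class ImputationReport:
    scores: dict[str, CovariateScore]
    points_per_round: int
    rounds: int
    shortfalls: dict[str, int] = field(default_factory=dict)


def _is_continuous(col: ColumnSchema) -> bool:
    return col.kind == "continuous"


def _mode_lowest(series: pd.Series, levels: tuple[str, ...]) -> str:
    """Most frequent observed level; ties broken by lowest level index."""
    counts = series.dropna().value_counts()
    best, best_count = None, -1
    for level in levels:
        c = int(counts.get(level, 0))
        if c > best_count:
            best, best_count = level, c
    return best


def _predictor_matrix(
    values: pd.DataFrame,
    cov_schema: list[ColumnSchema],
    exclude: str,
    outcome: np.ndarray | None,
) -> np.ndarray:
    """Numeric predictor matrix from the current imputed table, minus one column."""
    cols = []
    for col in cov_schema:
        if col.name == exclude:
            continue
        if _is_continuous(col):
            cols.append(values[col.name].to_numpy(dtype=float))
        else:
            s = values[col.name].astype(str)
            for level in col.levels:
                cols.append((s == level).to_numpy(dtype=float))
    if outcome is not None:
        cols.append(outcome[:, 0])
        cols.append(outcome[:, 1])
    return np.column_stack(cols)


def _one_round(
    dataset: SurvivalDataset,
    config: ImputationConfig,
    rng: np.random.Generator,
    outcome: np.ndarray | None,
) -> pd.DataFrame:
    cov_schema = dataset.covariate_schema()
    mask = dataset.missing_mask
    values = dataset.values.copy()

    # initial fill
    for col in cov_schema:
        miss = mask[col.name]
        if not miss.any():
            continue
        if _is_continuous(col):
            values.loc[miss, col.name] = float(values[col.name].mean())
        else:
            values.loc[miss, col.name] = _mode_lowest(dataset.values[col.name], col.levels)

    order = sorted(
        (c for c in cov_schema if mask[c.name].any()),
        key=lambda c: int(mask[c.name].sum()),
    )
    if not order:
        return values

    prev_change = np.inf
    prev_values = values.copy()
    for _ in range(config.max_iterations):
        change_num = 0.0
        change_den = 0.0
        cat_changed = 0
        cat_total = 0
        before = values.copy()
        for col in order:
            miss = mask[col.name].to_numpy()
            obs = ~miss
            X = _predictor_matrix(values, cov_schema, col.name, outcome)
            forest_seed = int(rng.integers(2**31 - 1))
            if _is_continuous(col):
                forest = RandomForestRegressor(
                    n_estimators=config.trees, random_state=forest_seed, n_jobs=1
                )
                y = values[col.name].to_numpy(dtype=float)
                forest.fit(X[obs], y[obs])
                values.loc[miss, col.name] = forest.predict(X[miss])
            else:
                forest = RandomForestClassifier(
                    n_estimators=config.trees, random_state=forest_seed, n_jobs=1
                )
                y = values[col.name].astype(str).to_numpy()
                forest.fit(X[obs], y[obs])
                values.loc[miss, col.name] = forest.predict(X[miss])
        for col in order:
            miss = mask[col.name].to_numpy()
            if _is_continuous(col):
                new = values[col.name].to_numpy(dtype=float)[miss]
                old = before[col.name].to_numpy(dtype=float)[miss]
                change_num += float(np.sum((new - old) ** 2))
                change_den += float(np.sum(new**2))
            else:
                new = values[col.name].astype(str).to_numpy()[miss]
                old = before[col.name].astype(str).to_numpy()[miss]
                cat_changed += int(np.sum(new != old))
                cat_total += len(new)
        change = (change_num / change_den if change_den else 0.0) + (
            cat_changed / cat_total if cat_total else 0.0
        )
        if change >= prev_change:
            return prev_values  # first divergence: keep the previous iteration
        prev_change = change
        prev_values = values.copy()
        if change == 0.0:
            break
    return prev_values


def _outcome_matrix(dataset: SurvivalDataset) -> np.ndarray:
    if np.any(np.isnan(dataset.durations)):
        raise ValueError("include_outcome requires complete durations")
    return np.column_stack([np.log(dataset.durations), dataset.events])


def missforest_impute(dataset: SurvivalDataset, config: ImputationConfig) -> SurvivalDataset:
    """Impute every missing covariate cell; observed cells are never altered.

    The final value of a cell is the mean (continuous) or modal value
    (categorical, ties to the lowest level index) over ``config.rounds``
    independently seeded rounds.
    """
    mask = dataset.missing_mask
    for col in dataset.covariate_schema():
        col_mask = mask[col.name]
        if col_mask.all() and len(col_mask):
            raise ValueError(f"column {col.name!r} is entirely missing")
    audit.record("missforest_impute", n=dataset.n, include_outcome=config.include_outcome,
                 n_missing=int(mask.to_numpy().sum()))
    if not mask.to_numpy().any():
        return dataset.copy()

    outcome = _outcome_matrix(dataset) if config.include_outcome else None
    seeds = np.random.SeedSequence(config.seed).spawn(config.rounds)
    round_tables = [
        _one_round(dataset, config, np.random.default_rng(s), outcome) for s in seeds
    ]

    values = dataset.values.copy()
    for col in dataset.covariate_schema():
        miss = mask[col.name].to_numpy()
        if not miss.any():
            continue
        if _is_continuous(col):
            stacked = np.vstack([t[col.name].to_numpy(dtype=float)[miss] for t in round_tables])
            values.loc[miss, col.name] = stacked.mean(axis=0)
        else:
            stacked = np.vstack([t[col.name].astype(str).to_numpy()[miss] for t in round_tables])
            votes = np.zeros((len(col.levels), stacked.shape[1]), dtype=int)
            for li, level in enumerate(col.levels):
                votes[li] = (stacked == level).sum(axis=0)
            winners = np.argmax(votes, axis=0)  # argmax takes the lowest index on ties
            values.loc[miss, col.name] = np.asarray(col.levels, dtype=object)[winners]

    return SurvivalDataset(
        schema=list(dataset.schema),
        values=values,
        durations=dataset.durations.copy(),
        events=dataset.events.copy(),
    )


def impute_validation_patient(
    train: SurvivalDataset,
    patient: SurvivalDataset,
    config: ImputationConfig,
) -> SurvivalDataset:
    """Impute one held-out patient against the training set without leakage.

    The imputation runs on the concatenation of the training rows and exactly
    this patient; only the patient's row is returned.  The patient's own
    outcome never feeds the forests: in include-outcome mode their outcome
    predictor cells are replaced by training-set averages.
    """
    if patient.n != 1:
        raise ValueError("patient must be a single-row dataset")
    if [c.name for c in patient.schema] != [c.name for c in train.schema]:
        raise ValueError("patient schema does not match training schema")
    audit.record("impute_validation_patient", include_outcome=config.include_outcome)
    if not patient.missing_mask.to_numpy().any():
        return patient.copy()
    if config.include_outcome and np.isnan(patient.durations[0]):
        raise ValueError(
            "patient outcome unavailable; it never feeds imputation — "
            "run with a placeholder duration or include_outcome=False"
        )

    # placeholder outcome so the combined dataset validates; neutralised below
    pat_dur = patient.durations.copy()
    pat_ev = patient.events.copy()
    if np.isnan(pat_dur[0]):
        pat_dur[0] = float(np.exp(np.mean(np.log(train.durations))))
        pat_ev[0] = float(np.round(train.events.mean()))

    combined = SurvivalDataset(
        schema=list(train.schema),
        values=pd.concat([train.values, patient.values], ignore_index=True),
        durations=np.concatenate([train.durations, pat_dur]),
        events=np.concatenate([train.events, pat_ev]),
    )
    if config.include_outcome:
        # neutralise the patient's outcome predictors with training averages
        outcome = _outcome_matrix(combined)
        outcome[-1, 0] = float(np.mean(np.log(train.durations)))
        outcome[-1, 1] = float(np.mean(train.events))
    else:
        outcome = None

    seeds = np.random.SeedSequence(config.seed).spawn(config.rounds)
    round_tables = [
        _one_round(combined, config, np.random.default_rng(s), outcome) for s in seeds
    ]
    mask = combined.missing_mask
    values = patient.values.copy()
    row = combined.n - 1
    for col in combined.covariate_schema():
        if not mask[col.name].iloc[row]:
            continue
        if _is_continuous(col):
            values.loc[values.index[0], col.name] = float(
                np.mean([t[col.name].iloc[row] for t in round_tables])
            )
        else:
            draws = [str(t[col.name].iloc[row]) for t in round_tables]
            counts = [(draws.count(level), -li) for li, level in enumerate(col.levels)]
            best = max(range(len(col.levels)), key=lambda li: counts[li])
            values.loc[values.index[0], col.name] = col.levels[best]

    return SurvivalDataset(
        schema=list(patient.schema),
        values=values.reset_index(drop=True),
        durations=patient.durations.copy(),
        events=patient.events.copy(),
    )


def mask_and_score(
    dataset: SurvivalDataset,
    points_per_covariate: int = 50,
    rounds: int = 50,
    config: ImputationConfig = ImputationConfig(),
) -> ImputationReport:
    """Hold out observed cells at random, impute, and score the recovery.

    Per round, ``points_per_covariate`` observed cells of every eligible
    covariate are masked, the whole table re-imputed, and (imputed, true)
    pairs pooled across rounds.  Continuous covariates are scored by Pearson
    r with its two-sided p-value; categoricals by accuracy.
    """
    cov_schema = dataset.covariate_schema()
    mask = dataset.missing_mask
    eligible = []
    shortfalls: dict[str, int] = {}
    for col in cov_schema:
        n_obs = int((~mask[col.name]).sum())
        if n_obs <= points_per_covariate:
            logger.warning("covariate %s excluded: only %d observed values", col.name, n_obs)
            shortfalls[col.name] = n_obs
            continue
        eligible.append(col)
    if not eligible:
        raise ValueError("no covariate has enough observed values to score")

    seeds = np.random.SeedSequence([config.seed, 0xA5]).spawn(rounds)
    pairs: dict[str, list[tuple[object, object]]] = {c.name: [] for c in eligible}
    for rs in seeds:
        rng = np.random.default_rng(rs)
        masked = dataset.copy()
        held: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for col in eligible:
            obs_idx = np.flatnonzero(~mask[col.name].to_numpy())
            pick = rng.choice(obs_idx, size=points_per_covariate, replace=False)
            truth = dataset.values[col.name].to_numpy()[pick]
            masked.values.loc[masked.values.index[pick], col.name] = np.nan
            held[col.name] = (pick, truth)
        round_cfg = ImputationConfig(
            rounds=config.rounds, max_iterations=config.max_iterations,
            trees=config.trees, include_outcome=config.include_outcome,
            seed=int(np.random.default_rng(rs).integers(2**31 - 1)),
        )
        imputed = missforest_impute(masked, round_cfg)
        for col in eligible:
            pick, truth = held[col.name]
            est = imputed.values[col.name].to_numpy()[pick]
            pairs[col.name].extend(zip(est, truth))

    scores: dict[str, CovariateScore] = {}
    for col in eligible:
        est, truth = zip(*pairs[col.name])
        if _is_continuous(col):
            est = np.asarray(est, dtype=float)
            truth = np.asarray(truth, dtype=float)
            if np.std(est) == 0 or np.std(truth) == 0:
                r, p = 0.0, 1.0
            else:
                r, p = stats.pearsonr(est, truth)
            scores[col.name] = CovariateScore(col.name, "continuous", float(r), float(p), len(est))
        else:
            acc = float(np.mean([e == t for e, t in zip(est, truth)]))
            scores[col.name] = CovariateScore(col.name, "categorical", acc, None, len(est))
    return ImputationReport(
        scores=scores, points_per_round=points_per_covariate, rounds=rounds,
        shortfalls=shortfalls,
    )
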