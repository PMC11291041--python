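"""Rank-combined model selection and staged nested hyperparameter search.

Configurations are compared on three outcome measures — concordance (higher
is better), median absolute difference and normalised median absolute
difference (lower is better).  Each measure ranks the configurations (ties
share the mean rank); the configuration with the lowest rank sum wins.

The nested search splits the data 80/20; every candidate is evaluated by
training models on 10 random 80% subsamples of the inner 80%, aggregating
their survival curves by pointwise median, and scoring the aggregated
prediction on the outer 20%.  The search proceeds in stages (model family,
then layer structure, then learning rate, then interval/knot count), fixing
each stage's winner before the next, which keeps the number of evaluated
configurations to the sum — not the product — of the stage sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from survpipe import bagging
from survpipe.evaluate import MetricReport, full_report
from survpipe.hazard import HazardNetConfig, median_survival


@dataclass
class TuningResult:
    labels: list[str]
    reports: dict[str, MetricReport]
    ranks: dict[str, tuple[float, float, float]]
    rank_sums: dict[str, float]
    selected: str
    selected_config: object | None = None
    trace: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "selected": self.selected,
            "rank_sums": self.rank_sums,
            "ranks": {k: list(v) for k, v in self.ranks.items()},
            "reports": {k: v.as_dict() for k, v in self.reports.items()},
            "trace": self.trace,
        }


def rank_select(reports: dict[str, MetricReport]) -> TuningResult:
    """Pick the configuration with the lowest rank sum across the measures.

    Ties in a metric share the mean rank; ties in the rank sum are broken by
    c-index, then mad, then input order.
    """
    if not reports:
        raise ValueError("no configurations to rank")
    labels = list(reports)
    c = np.array([reports[l].c_index for l in labels], dtype=float)
    mad = np.array([reports[l].mad for l in labels], dtype=float)
    nmad = np.array([reports[l].nmad for l in labels], dtype=float)
    r_c = rankdata(-c)  # higher concordance -> lower rank
    r_mad = rankdata(mad)
    r_nmad = rankdata(nmad)
    sums = r_c + r_mad + r_nmad
    order = sorted(
        range(len(labels)),
        key=lambda i: (sums[i], -c[i], mad[i], i),
    )
    best = order[0]
    return TuningResult(
        labels=labels,
        reports=dict(reports),
        ranks={l: (float(r_c[i]), float(r_mad[i]), float(r_nmad[i])) for i, l in enumerate(labels)},
        rank_sums={l: float(sums[i]) for i, l in enumerate(labels)},
        selected=labels[best],
    )


@dataclass(frozen=True)
class StagedGrid:
    """Search space explored one axis at a time.

    ``families`` seeds stage 1; later stages vary one hyperparameter of the
    winning family (layer structure and learning rate apply to the hazard
    network only; the knot axis maps to interval count for the network and
    internal knot count for the spline family).
    """

    families: tuple[bagging.FamilyConfig, ...]
    hidden_options: tuple[tuple[int, ...], ...] = ()
    lr_options: tuple[float, ...] = ()
    knot_options: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("grid must contain at least one model family")


def _label(config: object) -> str:
    if isinstance(config, HazardNetConfig):
        return (f"pchazard(hidden={list(config.hidden)},lr={config.learning_rate},"
                f"m={config.m})")
    return f"spline(knots={config.internal_knots})"


def _evaluate(
    config: bagging.FamilyConfig,
    X_in: np.ndarray, t_in: np.ndarray, d_in: np.ndarray,
    X_out: np.ndarray, t_out: np.ndarray, d_out: np.ndarray,
    inner_folds: int, seed: int,
) -> MetricReport:
    bag = bagging.train_bag(config, X_in, t_in, d_in, bag_size=inner_folds,
                            subsample=0.8, seed=seed)
    curves = [bagging.bag_predict(bag, x) for x in X_out]
    medians = np.array([median_survival(c).time for c in curves])
    return full_report(curves, medians, t_out, d_out)


def nested_tune(
    grid: StagedGrid,
    X: np.ndarray,
    durations: np.ndarray,
    events: np.ndarray,
    seed: int = 0,
    inner_folds: int = 10,
    outer_fraction: float = 0.8,
) -> TuningResult:
    """Staged nested search; returns the winner with its outer-split metrics."""
    X = np.asarray(X, dtype=float)
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=float)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_in = int(round(outer_fraction * n))
    inner, outer = perm[:n_in], perm[n_in:]
    X_in, t_in, d_in = X[inner], durations[inner], events[inner]
    X_out, t_out, d_out = X[outer], durations[outer], events[outer]

    trace: list[dict] = []
    eval_seeds = iter(np.random.SeedSequence(seed).spawn(4096))

    def run_stage(stage: str, candidates: list[bagging.FamilyConfig]) -> tuple[object, MetricReport]:
        if not candidates:
            raise ValueError(f"stage {stage!r} has no candidates")
        reports: dict[str, MetricReport] = {}
        by_label: dict[str, object] = {}
        for cand in candidates:
            label = _label(cand)
            if label in reports:
                continue
            s = int(np.random.default_rng(next(eval_seeds)).integers(2**31 - 1))
            rep = _evaluate(cand, X_in, t_in, d_in, X_out, t_out, d_out,
                            inner_folds, s)
            reports[label] = rep
            by_label[label] = cand
            trace.append({"stage": stage, "config": label, **rep.as_dict()})
        sel = rank_select(reports)
        return by_label[sel.selected], reports[sel.selected]

    single_family = len(grid.families) == 1
    later_stages = bool(
        grid.knot_options
        or (isinstance(grid.families[0], HazardNetConfig)
            and (grid.hidden_options or grid.lr_options))
    )
    if single_family and later_stages:
        # nothing to compare at the family stage; spend evaluations on the axes
        winner, report = grid.families[0], None
    else:
        winner, report = run_stage("family", list(grid.families))

    if isinstance(winner, HazardNetConfig):
        if grid.hidden_options:
            winner, report = run_stage(
                "hidden", [replace(winner, hidden=tuple(h)) for h in grid.hidden_options]
            )
        if grid.lr_options:
            winner, report = run_stage(
                "learning_rate", [replace(winner, learning_rate=lr) for lr in grid.lr_options]
            )
        if grid.knot_options:
            winner, report = run_stage(
                "knots", [replace(winner, m=k) for k in grid.knot_options if k >= 1]
            )
    else:
        if grid.knot_options:
            winner, report = run_stage(
                "knots", [bagging.ParametricConfig(internal_knots=k) for k in grid.knot_options]
            )

    if report is None:  # every later stage was empty after filtering
        winner, report = run_stage("family", [winner])

    label = _label(winner)
    return TuningResult(
        labels=[label],
        reports={label: report},
        ranks={label: (1.0, 1.0, 1.0)},
        rank_sums={label: 3.0},
        selected=label,
        selected_config=winner,
        trace=trace,
    )
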