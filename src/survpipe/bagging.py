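"""Bags of independently trained survival models.

Each member is trained on its own random ~80% subsample with its own seed;
the bag's prediction for a patient is the pointwise median of the member
survival curves on a shared time mesh.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from survpipe import hazard as hz
from survpipe import parametric as pm
from survpipe.cohort import ColumnProvenance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParametricConfig:
    """Configuration for the spline/Weibull baseline family."""

    internal_knots: int = 0


FamilyConfig = Union[hz.HazardNetConfig, ParametricConfig]


def _fit_family(config: FamilyConfig, X, durations, events, seed: int,
                encode_stats: list[ColumnProvenance] | None):
    if isinstance(config, hz.HazardNetConfig):
        cfg = replace(config, seed=seed)
        return hz.fit_pchazard(X, durations, events, cfg, encode_stats=encode_stats)
    if isinstance(config, ParametricConfig):
        return pm.fit_royston_parmar(X, durations, events, config.internal_knots)
    raise TypeError(f"unknown model family config {type(config).__name__}")


def _member_curve(model, x: np.ndarray) -> hz.SurvivalCurve:
    if isinstance(model, hz.HazardModel):
        return hz.predict_curve(model, x)
    return model.predict_curve(x)


@dataclass
class ModelBag:
    """Fixed-size collection of models trained on random subsamples."""

    members: list
    member_seeds: list[int]
    config: FamilyConfig
    encode_stats: list[ColumnProvenance] | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def train_bag(
    config: FamilyConfig,
    X: np.ndarray,
    durations: np.ndarray,
    events: np.ndarray,
    bag_size: int = 10,
    subsample: float = 0.8,
    seed: int = 0,
    encode_stats: list[ColumnProvenance] | None = None,
) -> ModelBag:
    """Train ``bag_size`` models, each on a random ``subsample`` fraction."""
    X = np.asarray(X, dtype=float)
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=float)
    n = X.shape[0]
    k = n if subsample >= 1.0 else max(2, int(round(subsample * n)))
    ss = np.random.SeedSequence(seed).spawn(bag_size)
    members, member_seeds = [], []
    for s in ss:
        rng = np.random.default_rng(s)
        member_seed = int(rng.integers(2**31 - 1))
        idx = rng.choice(n, size=k, replace=False) if k < n else np.arange(n)
        members.append(
            _fit_family(config, X[idx], durations[idx], events[idx], member_seed, encode_stats)
        )
        member_seeds.append(member_seed)
    return ModelBag(members=members, member_seeds=member_seeds, config=config,
                    encode_stats=encode_stats)


def bag_predict(bag: ModelBag, x: np.ndarray) -> hz.SurvivalCurve:
    """Pointwise-median survival curve of the bag members on a shared mesh.

    Medians of non-increasing curves are non-increasing, so the monotonicity
    clip below is a numerical safety net; if it ever fires it is logged.
    """
    curves = [_member_curve(m, x) for m in bag.members]
    mesh = np.unique(np.concatenate([c.times for c in curves]))
    stacked = np.vstack([c.at(mesh) for c in curves])
    med = np.median(stacked, axis=0)
    med[mesh == 0.0] = 1.0
    if np.any(np.diff(med) > 1e-12):
        logger.warning("pointwise-median curve violated monotonicity; clipping")
        med = np.minimum.accumulate(med)
    return hz.SurvivalCurve(times=mesh, survival=np.clip(med, 0.0, 1.0))


def bag_median_survival(bag: ModelBag, x: np.ndarray) -> hz.MedianSurvival:
    return hz.median_survival(bag_predict(bag, x))
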