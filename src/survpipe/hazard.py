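"""Piecewise-constant-hazard neural survival model.

The model discretises follow-up time into ``m`` intervals and maps a design
row to one non-negative hazard per interval (softplus head on a small MLP).
Training minimises the exact piecewise-exponential negative log-likelihood;
predictions are survival curves ``S(t) = exp(-H(t))`` that are log-linear
within intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from survpipe._mlp import MLP
from survpipe.cohort import ColumnProvenance, DesignMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscretizationGrid:
    """Ordered cut points 0 = tau_0 < tau_1 < ... < tau_m."""

    cuts: np.ndarray  # length m + 1, cuts[0] == 0

    def __post_init__(self) -> None:
        cuts = np.asarray(self.cuts, dtype=float)
        object.__setattr__(self, "cuts", cuts)
        if cuts[0] != 0.0:
            raise ValueError("grid must start at 0")
        if not np.all(np.diff(cuts) > 0):
            raise ValueError("grid cuts must be strictly increasing")

    @property
    def m(self) -> int:
        return len(self.cuts) - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.cuts)

    def locate(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interval index k (0-based) and within-interval fraction rho for each t.

        Valid for t in (0, tau_m]; raises outside.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0) or np.any(t > self.cuts[-1]):
            raise ValueError("times must lie in (0, tau_m]")
        k = np.searchsorted(self.cuts, t, side="left") - 1
        rho = (t - self.cuts[k]) / self.widths[k]
        return k, rho


def make_grid(durations: np.ndarray, m: int) -> DiscretizationGrid:
    """Quantile-based grid: cuts at the j/m quantiles of observed durations.

    The final cut is the maximum duration so that every observation falls
    inside the grid.  Duplicate quantiles (possible with heavily tied data)
    are collapsed, reducing ``m`` with a logged warning.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise ValueError("durations empty")
    if m < 1:
        raise ValueError("m must be >= 1")
    n_distinct = len(np.unique(durations))
    if m > n_distinct:
        raise ValueError(f"m={m} exceeds {n_distinct} distinct durations")
    qs = np.quantile(durations, np.arange(1, m + 1) / m)
    qs[-1] = durations.max()
    cuts = np.concatenate([[0.0], qs])
    uniq = np.unique(cuts)
    if len(uniq) < len(cuts):
        logger.warning("collapsed %d duplicate grid cuts (m=%d -> %d)",
                       len(cuts) - len(uniq), m, len(uniq) - 1)
    if len(uniq) < 2:
        raise ValueError("degenerate grid: all durations identical")
    return DiscretizationGrid(cuts=uniq)


def cumulative_hazard(hazards: np.ndarray, grid: DiscretizationGrid, t: np.ndarray) -> np.ndarray:
    """H(t) for one subject's piecewise-constant hazards (length m)."""
    hazards = np.asarray(hazards, dtype=float)
    if hazards.shape != (grid.m,):
        raise ValueError("hazards must have one value per grid interval")
    k, rho = grid.locate(t)
    widths = grid.widths
    csum = np.concatenate([[0.0], np.cumsum(hazards * widths)])
    return csum[k] + rho * hazards[k] * widths[k]


def pchazard_nll(hazards: np.ndarray, grid: DiscretizationGrid, t: float, d: int) -> float:
    """Exact piecewise-exponential negative log-likelihood for one subject.

    With k the interval containing t, ``H(t) = sum_{j<k} lam_j * w_j +
    rho * lam_k * w_k``; returns ``-d*log(lam_k) + H(t)``.
    """
    hazards = np.asarray(hazards, dtype=float)
    if hazards.shape != (grid.m,):
        raise ValueError("hazards must have one value per grid interval")
    if np.any(hazards < 0):
        raise ValueError("hazards must be non-negative")
    if not (0 < t <= grid.cuts[-1]):
        raise ValueError(f"t={t} outside grid (0, {grid.cuts[-1]}]")
    k, rho = grid.locate(np.array([t]))
    k, rho = int(k[0]), float(rho[0])
    widths = grid.widths
    H = float(np.dot(hazards[:k], widths[:k]) + rho * hazards[k] * widths[k])
    if d:
        if hazards[k] == 0.0:
            raise ValueError("event in an interval with zero hazard: infinite loss")
        return -float(np.log(hazards[k])) + H
    return H


@dataclass(frozen=True)
class HazardNetConfig:
    """Architecture and optimisation settings for the hazard network."""

    hidden: tuple[int, ...] = (32,)
    dropout: float = 0.0
    batch_norm: bool = False
    learning_rate: float = 0.01
    epochs: int = 200
    batch_size: int = 256
    m: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden):
            raise ValueError("hidden sizes must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass
class SurvivalCurve:
    """Survival probabilities on an increasing time mesh; S(0) = 1.

    Between mesh points the curve is interpreted as piecewise-exponential
    (log-linear), which is exact for hazard-grid models and a standard
    interpolation otherwise.
    """

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times[0] != 0.0 or self.survival[0] != 1.0:
            raise ValueError("curve must start at (0, 1)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.survival < 0) or np.any(self.survival > 1):
            raise ValueError("survival must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Evaluate S(t), log-linear within segments, extrapolating the last
        segment's hazard rate beyond the mesh."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        logS = np.log(np.clip(self.survival, 1e-300, 1.0))
        out = np.interp(t, self.times, logS)
        beyond = t > self.times[-1]
        if np.any(beyond):
            rate = self._tail_rate()
            out[beyond] = logS[-1] - rate * (t[beyond] - self.times[-1])
        return np.exp(out)

    def _tail_rate(self) -> float:
        logS = np.log(np.clip(self.survival, 1e-300, 1.0))
        dt = self.times[-1] - self.times[-2]
        return float((logS[-2] - logS[-1]) / dt)


@dataclass
class MedianSurvival:
    """Median survival time with an extrapolation flag."""

    time: float
    extrapolated: bool = False

    def __float__(self) -> float:
        return self.time


def median_survival(curve: SurvivalCurve) -> MedianSurvival:
    """First time with S(t) <= 0.5, solved exactly on the log-linear curve.

    If the curve never reaches 0.5 on its mesh, the last segment's constant
    hazard is extrapolated and the result flagged; a zero tail hazard leaves
    the median undefined and raises.
    """
    S = curve.survival
    times = curve.times
    target = np.log(0.5)
    logS = np.log(np.clip(S, 1e-300, 1.0))
    below = np.flatnonzero(logS <= target)
    if below.size:
        i = below[0]
        if logS[i] == target:
            return MedianSurvival(time=float(times[i]))
        t0, t1 = times[i - 1], times[i]
        s0, s1 = logS[i - 1], logS[i]
        t = t0 + (s0 - target) / (s0 - s1) * (t1 - t0)
        return MedianSurvival(time=float(t))
    rate = curve._tail_rate()
    if rate <= 0:
        raise ValueError("median undefined: survival never reaches 0.5 and tail hazard is 0")
    t = times[-1] + (logS[-1] - target) / rate
    return MedianSurvival(time=float(t), extrapolated=True)


@dataclass
class HazardModel:
    """A trained piecewise-constant-hazard network."""

    net: MLP
    grid: DiscretizationGrid
    config: HazardNetConfig
    encode_stats: list[ColumnProvenance] | None = None
    loss_history: list[float] = field(default_factory=list)

    def predict_hazards(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = self.net.forward(X, training=False)
        return _softplus(z)

    def copy(self) -> "HazardModel":
        return HazardModel(
            net=self.net.clone(),
            grid=self.grid,
            config=self.config,
            encode_stats=self.encode_stats,
            loss_history=list(self.loss_history),
        )


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _nll_batch(lam: np.ndarray, widths: np.ndarray, k: np.ndarray, rho: np.ndarray, d: np.ndarray):
    """Vectorised mean NLL and gradient w.r.t. hazards for a batch.

    lam: (n, m) hazards; k/rho/d: per-subject interval index, fraction, event.
    """
    n, m = lam.shape
    idx = np.arange(n)
    # exposure of each interval: full width before k, fractional at k, 0 after
    exposure = np.tile(widths, (n, 1))
    mask_after = np.arange(m)[None, :] > k[:, None]
    exposure[mask_after] = 0.0
    exposure[idx, k] = rho * widths[k]
    H = np.sum(lam * exposure, axis=1)
    lam_k = lam[idx, k]
    loss = H - d * np.log(np.clip(lam_k, 1e-30, None))
    grad = exposure.copy()
    grad[idx, k] -= d / np.clip(lam_k, 1e-30, None)
    return float(np.mean(loss)), grad / n


def fit_pchazard(
    design: DesignMatrix | np.ndarray,
    durations: np.ndarray,
    events: np.ndarray,
    config: HazardNetConfig,
    grid: DiscretizationGrid | None = None,
    encode_stats: list[ColumnProvenance] | None = None,
) -> HazardModel:
    """Train the hazard network by mini-batch Adam on the mean NLL.

    Deterministic for a fixed config seed.  The loss trajectory is stored on
    the returned model; a non-finite loss aborts with a diagnostic.
    """
    if isinstance(design, DesignMatrix):
        if encode_stats is None:
            encode_stats = design.provenance
        X = design.matrix
    else:
        X = np.asarray(design, dtype=float)
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=float)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty dataset")
    if grid is None:
        grid = make_grid(durations, config.m)
    k, rho = grid.locate(durations)
    widths = grid.widths

    rng = np.random.default_rng(config.seed)
    net = MLP(
        in_dim=X.shape[1], hidden=tuple(config.hidden), out_dim=grid.m,
        dropout=config.dropout, batch_norm=config.batch_norm, rng=rng,
    )
    model = HazardModel(net=net, grid=grid, config=config, encode_stats=encode_stats)
    _train(model, X, k, rho, events, epochs=config.epochs, lr=config.learning_rate,
           batch_size=config.batch_size, rng=rng)
    return model


def continue_training(
    model: HazardModel,
    X: np.ndarray,
    durations: np.ndarray,
    events: np.ndarray,
    epochs: int,
    lr: float | None = None,
    seed: int = 0,
) -> HazardModel:
    """Fine-tune a copy of a trained model on new rows (grid frozen)."""
    out = model.copy()
    if epochs <= 0:
        return out
    k, rho = model.grid.locate(np.asarray(durations, dtype=float))
    rng = np.random.default_rng(seed)
    out.net.reset_optimizer()
    _train(out, np.asarray(X, dtype=float), k, rho, np.asarray(events, dtype=float),
           epochs=epochs, lr=lr if lr is not None else model.config.learning_rate,
           batch_size=model.config.batch_size, rng=rng)
    return out


def _train(model, X, k, rho, events, *, epochs, lr, batch_size, rng):
    n = X.shape[0]
    widths = model.grid.widths
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            b = order[start : start + batch_size]
            z = model.net.forward(X[b], training=True, rng=rng)
            lam = _softplus(z)
            loss, grad_lam = _nll_batch(lam, widths, k[b], rho[b], events[b])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: lr={lr}, batch={len(b)}"
                )
            grad_z = grad_lam * expit(z)
            grads = model.net.backward(grad_z)
            model.net.adam_step(grads, lr=lr)
            epoch_loss += loss * len(b)
        model.loss_history.append(epoch_loss / n)


def predict_curve(model: HazardModel, x: np.ndarray, points_per_interval: int = 8) -> SurvivalCurve:
    """Survival curve S(t) = exp(-H(t)) for one design row.

    The mesh contains every grid cut plus ``points_per_interval`` interior
    points; S is exactly piecewise-exponential so the interior points are
    redundant for downstream math but convenient for plotting.
    """
    lam = model.predict_hazards(x)[0]
    cuts = model.grid.cuts
    widths = model.grid.widths
    H_at_cuts = np.concatenate([[0.0], np.cumsum(lam * widths)])
    mesh = [np.array([0.0])]
    Hs = [np.array([0.0])]
    for j in range(model.grid.m):
        ts = np.linspace(cuts[j], cuts[j + 1], points_per_interval + 1)[1:]
        mesh.append(ts)
        Hs.append(H_at_cuts[j] + lam[j] * (ts - cuts[j]))
    times = np.concatenate(mesh)
    S = np.exp(-np.concatenate(Hs))
    return SurvivalCurve(times=times, survival=np.minimum(S, 1.0))
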