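"""Prediction metrics: tie-adjusted time-dependent concordance and
median-absolute-difference measures.

The concordance is time-dependent: a pair (i, j) is comparable when i has an
observed event before j's time (or at the same time with j censored), and is
scored by comparing the two predicted survival probabilities evaluated at
i's event time; tied predictions contribute weight 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from survpipe.hazard import SurvivalCurve


@dataclass
class MetricReport:
    """Triple of outcome measures plus evaluation counts."""

    c_index: float | None
    mad: float | None
    nmad: float | None
    n_evaluated: int
    n_censored_excluded: int

    def as_dict(self) -> dict:
        return {
            "c_index": self.c_index,
            "mad": self.mad,
            "nmad": self.nmad,
            "n_evaluated": self.n_evaluated,
            "n_censored_excluded": self.n_censored_excluded,
        }


def concordance(
    curves: list[SurvivalCurve],
    durations: np.ndarray,
    events: np.ndarray,
    tie_tol: float = 1e-12,
) -> float:
    """Tie-adjusted time-dependent concordance index.

    Comparable pairs: (i, j) with d_i=1 and T_i < T_j, plus (i, j) with
    T_i = T_j, d_i=1, d_j=0.  A pair is concordant when the patient with the
    earlier event has the lower predicted survival at that event time; equal
    predictions (within ``tie_tol``) count 0.5.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=float)
    n = len(curves)
    if not (len(durations) == len(events) == n):
        raise ValueError("curves/durations/events length mismatch")

    # S_matrix[i, j] = predicted survival of patient j at time T_i
    S = np.empty((n, n))
    for j, curve in enumerate(curves):
        S[:, j] = curve.at(durations)

    concordant = 0.0
    comparable = 0
    for i in range(n):
        if events[i] != 1:
            continue
        later = durations > durations[i]
        tied_cens = (durations == durations[i]) & (events == 0)
        js = np.flatnonzero(later | tied_cens)
        for j in js:
            diff = S[i, i] - S[i, j]
            if diff < -tie_tol:
                concordant += 1.0
            elif diff <= tie_tol:
                concordant += 0.5
            comparable += 1
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return concordant / comparable


def mad_metrics(
    medians: np.ndarray,
    durations: np.ndarray,
    events: np.ndarray,
) -> MetricReport:
    """Median absolute difference and its time-normalised variant.

    Censored patients are excluded: their true time-to-event is unknown, so
    an absolute difference is undefined for them.
    """
    medians = np.asarray(medians, dtype=float)
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=float)
    obs = events == 1
    n_excl = int((~obs).sum())
    if not obs.any():
        raise ValueError("no uncensored patients to evaluate")
    err = np.abs(medians[obs] - durations[obs])
    return MetricReport(
        c_index=None,
        mad=float(np.median(err)),
        nmad=float(np.median(err / durations[obs])),
        n_evaluated=int(obs.sum()),
        n_censored_excluded=n_excl,
    )


def full_report(
    curves: list[SurvivalCurve],
    medians: np.ndarray,
    durations: np.ndarray,
    events: np.ndarray,
) -> MetricReport:
    """All three outcome measures in one report."""
    base = mad_metrics(medians, durations, events)
    base.c_index = concordance(curves, durations, events)
    return base
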