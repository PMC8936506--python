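"""Recurrence structure of embedded states: matrix, periods, probabilities.

The binary recurrence matrix marks pairs of states closer than a radius
``eps`` (expressed as a percentage of the raw window's standard deviation).
A *recurrence period of the second type* is the time a trajectory spends
outside the eps-neighborhood of a reference state before re-entering: the
length of a vertical white run in the recurrence plot.  Runs of length one
are excluded (tangential motion), and a run is only counted when bounded by
recurrence points on both sides, so unfinished excursions at the window edge
do not contribute.

The SREPS diagnostic repeats the period histogram over a grid of
neighborhood sizes to locate the noise floor (tiny eps: near-uniform P(T))
and the stable spectral ridge, whose modal period drifts to smaller T by
about two samples per state-to-state distance added to eps.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import cdist

from .embedding import EmbeddingParams, StateMatrix, delay_embed
from .series import Series

__all__ = [
    "RecurrenceMatrix",
    "RecurrenceEvent",
    "PeriodDistribution",
    "state_distance",
    "pairwise_distances",
    "recurrence_matrix",
    "recurrence_periods",
    "period_distribution",
    "sreps",
    "SrepsResult",
    "mean_step_distance",
    "predicted_period_shift",
]

_CDIST_NAME = {"euclidean": "euclidean", "maximum": "chebyshev"}


def _cdist_metric(metric: str) -> str:
    try:
        return _CDIST_NAME[metric]
    except KeyError:
        raise ValueError(f"metric must be one of {sorted(_CDIST_NAME)}, got {metric!r}")


def state_distance(a, b, metric: str = "maximum") -> float:
    """Distance between two states: Euclidean norm or maximum (Chebyshev) norm."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"state dimensions differ: {a.shape} vs {b.shape}")
    if metric == "euclidean":
        return float(np.sqrt(np.sum((a - b) ** 2)))
    if metric == "maximum":
        return float(np.max(np.abs(a - b)))
    _cdist_metric(metric)  # raises with the standard message
    raise AssertionError("unreachable")


def pairwise_distances(states: StateMatrix | np.ndarray, metric: str = "maximum") -> np.ndarray:
    X = states.states if isinstance(states, StateMatrix) else np.asarray(states, float)
    return cdist(X, X, metric=_cdist_metric(metric))


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Binary recurrence matrix with the neighborhood radius that produced it.

    ``entries[i, j]`` is True when states i and j are within ``eps_abs`` of
    each other; the matrix is symmetric with a unit diagonal.  ``degenerate``
    marks windows with zero variance, where no radius can be formed.
    """

    entries: np.ndarray
    eps_abs: float
    eps_pct: float
    metric: str
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.entries.shape[0]


class RecurrenceEvent(NamedTuple):
    """One detected recurrence: the trajectory left the neighborhood of state
    ``ref_index`` and re-entered ``period`` samples later.  ``span`` holds the
    (inclusive) state indices of the two bounding recurrence points, so the
    loop covers ``n_span = period + 2`` states."""

    ref_index: int
    period: int
    span: tuple[int, int]
    n_span: int


@dataclass(frozen=True)
class PeriodDistribution:
    """Histogram R(T) and probability P(T) of recurrence periods on a grid."""

    T_grid: np.ndarray
    counts: np.ndarray
    prob: np.ndarray
    n_events: int
    degenerate: bool = False


def recurrence_matrix(states: StateMatrix | np.ndarray, eps_pct: float,
                      metric: str = "maximum",
                      window_std: float | None = None) -> RecurrenceMatrix:
    """Threshold pairwise state distances at ``eps = eps_pct/100 * window_std``.

    ``window_std`` is the standard deviation of the *raw* samples the states
    were embedded from (the analysis window); when omitted, the first
    embedding coordinate is used as a stand-in for the raw window.  Distances
    exactly equal to eps count as recurrent.  A zero-variance window yields
    an empty matrix flagged degenerate.
    """
    X = states.states if isinstance(states, StateMatrix) else np.asarray(states, float)
    if eps_pct <= 0:
        raise ValueError("eps_pct must be positive")
    if window_std is None:
        window_std = float(X[:, 0].std())
    if window_std <= 0:
        return RecurrenceMatrix(entries=np.zeros((0, 0), dtype=bool), eps_abs=0.0,
                                eps_pct=float(eps_pct), metric=metric, degenerate=True)
    eps_abs = (eps_pct / 100.0) * window_std
    d = cdist(X, X, metric=_cdist_metric(metric))
    return RecurrenceMatrix(entries=d <= eps_abs, eps_abs=float(eps_abs),
                            eps_pct=float(eps_pct), metric=metric)


def recurrence_periods(matrix: RecurrenceMatrix) -> list[RecurrenceEvent]:
    """Extract recurrence events from the white runs of a recurrence matrix.

    For each reference column ``t`` only forward times are scanned (the
    matrix is symmetric).  Recurrence points at time offsets
    ``0 = p_0 < p_1 < ...`` delimit white runs of length ``p_{k+1}-p_k-1``;
    every run of length >= 2 becomes one event with that period.  Runs of
    length one are discarded, and the trailing run after the last recurrence
    point is unbounded and therefore dropped.
    """
    m = matrix.entries
    if matrix.degenerate or m.size == 0:
        return []
    n = m.shape[0]
    events: list[RecurrenceEvent] = []
    for t in range(n):
        ones = np.flatnonzero(m[t:, t])  # offsets; ones[0] == 0 (unit diagonal)
        if ones.size < 2:
            continue
        gaps = np.diff(ones) - 1
        for k in np.flatnonzero(gaps >= 2):
            T = int(gaps[k])
            a = t + int(ones[k])
            b = t + int(ones[k + 1])
            events.append(RecurrenceEvent(ref_index=t, period=T, span=(a, b),
                                          n_span=T + 2))
    return events


def period_distribution(events, t_min: int = 0, t_max: int = 0,
                        n_states: int | None = None) -> PeriodDistribution:
    """Histogram of event periods over ``t_min..t_max`` with P(T) normalized
    over the grid only (events outside the grid are dropped first).

    ``(t_min, t_max) == (0, 0)`` maps to the full feasible grid
    ``2 .. n_states-1`` and then requires ``n_states``.
    """
    if t_min == 0 and t_max == 0:
        if n_states is None:
            raise ValueError("n_states is required to resolve the (0, 0) full-grid default")
        t_min, t_max = 2, max(2, int(n_states) - 1)
    if t_min < 2:
        raise ValueError("t_min must be >= 2 (periods of one are excluded)")
    if t_max < t_min:
        raise ValueError("t_max must be >= t_min")
    grid = np.arange(t_min, t_max + 1)
    counts = np.zeros(grid.size, dtype=np.int64)
    periods = np.fromiter((e.period for e in events), dtype=np.int64,
                          count=len(events) if hasattr(events, "__len__") else -1)
    inside = (periods >= t_min) & (periods <= t_max)
    np.add.at(counts, periods[inside] - t_min, 1)
    n_events = int(counts.sum())
    if n_events == 0:
        return PeriodDistribution(T_grid=grid, counts=counts,
                                  prob=np.zeros(grid.size), n_events=0, degenerate=True)
    return PeriodDistribution(T_grid=grid, counts=counts,
                              prob=counts / n_events, n_events=n_events)


@dataclass(frozen=True)
class SrepsResult:
    """P(T) per neighborhood size: rows follow ``eps_grid``, columns ``T_grid``."""

    eps_grid: np.ndarray
    T_grid: np.ndarray
    prob: np.ndarray
    degenerate_rows: np.ndarray


def sreps(series: Series, params: EmbeddingParams, eps_grid,
          t_min: int = 0, t_max: int = 0, metric: str = "maximum") -> SrepsResult:
    """Spatially resolved recurrence period spectrum.

    Recomputes P(T) for every neighborhood size in ``eps_grid`` (percent of
    the raw-series standard deviation, strictly increasing).  The pairwise
    distance matrix is computed once and re-thresholded per eps, so memory
    scales with ``n_states**2``.
    """
    eps_grid = np.asarray(eps_grid, dtype=float)
    if eps_grid.size == 0 or np.any(np.diff(eps_grid) <= 0) or eps_grid[0] <= 0:
        raise ValueError("eps_grid must be a nonempty, positive, increasing sequence")
    states = delay_embed(series, params)
    sd = series.std
    if t_min == 0 and t_max == 0:
        t_min, t_max = 2, states.n_states - 1
    grid = np.arange(t_min, t_max + 1)
    d = cdist(states.states, states.states, metric=_cdist_metric(metric))
    prob = np.zeros((eps_grid.size, grid.size))
    degen = np.zeros(eps_grid.size, dtype=bool)
    for r, eps in enumerate(eps_grid):
        rm = RecurrenceMatrix(entries=d <= (eps / 100.0) * sd,
                              eps_abs=(eps / 100.0) * sd, eps_pct=float(eps),
                              metric=metric, degenerate=sd <= 0)
        dist = period_distribution(recurrence_periods(rm), t_min, t_max)
        prob[r] = dist.prob
        degen[r] = dist.degenerate
    return SrepsResult(eps_grid=eps_grid, T_grid=grid, prob=prob, degenerate_rows=degen)


def mean_step_distance(states: StateMatrix | np.ndarray, metric: str = "maximum") -> float:
    """Average phase-space distance between consecutive states (the unit of the
    eps-induced period shift)."""
    X = states.states if isinstance(states, StateMatrix) else np.asarray(states, float)
    diff = np.diff(X, axis=0)
    if metric == "euclidean":
        steps = np.sqrt((diff ** 2).sum(axis=1))
    elif metric == "maximum":
        steps = np.abs(diff).max(axis=1)
    else:
        _cdist_metric(metric)
        raise AssertionError("unreachable")
    return float(steps.mean())


def predicted_period_shift(eps_base: float, q: int, step_dist: float) -> tuple[float, int]:
    """Predicted SREPS ridge drift: growing the neighborhood by ``q`` multiples
    of the state-to-state distance shortens the detected period by about
    ``2q`` samples.  Returns ``(eps_err, T_shift)``."""
    if q < 0:
        raise ValueError("q must be >= 0")
    return float(eps_base + q * step_dist), -2 * int(q)
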