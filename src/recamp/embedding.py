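"""Phase-space reconstruction of scalar time series by time-delay embedding.

A scalar series ``x_t`` is lifted to d-dimensional states by stacking
time-lagged copies, ``[x_t, x_{t+tau}, ..., x_{t+(d-1)tau}]``.  The delay
``tau`` is chosen at the first minimum of the auto-mutual information (AMI)
and the dimension ``d`` with the false-nearest-neighbors (FNN) criterion,
the standard automatic parameter-selection route for recurrence analysis.

States are stored oldest-lag-first and state index ``i`` is anchored to raw
sample index ``i`` (``origin_offset`` 0), so recurrence times downstream are
plain index differences.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .series import Series

__all__ = [
    "DegenerateSeriesError",
    "EmbeddingParams",
    "StateMatrix",
    "auto_mutual_information",
    "select_delay",
    "false_nearest_neighbors",
    "select_dimension",
    "delay_embed",
    "auto_embedding_params",
]

# Defaults for the automatic parameter search (Kennel-style tolerances).
DEFAULT_D_MAX = 10
DEFAULT_R_TOL = 10.0
DEFAULT_A_TOL = 2.0
DEFAULT_FNN_THRESHOLD = 0.01
MAX_AMI_BINS = 64


class DegenerateSeriesError(ValueError):
    """Raised when a (sub-)series is constant so that MI/FNN are undefined.

    Callers fall back to ``dim=1, tau=1`` and flag the window instead of
    failing the whole run.
    """


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters: dimension ``dim`` and delay ``tau`` (samples)."""

    dim: int
    tau: int

    def __post_init__(self) -> None:
        if int(self.dim) < 1 or int(self.tau) < 1:
            raise ValueError("dim and tau must be integers >= 1")
        object.__setattr__(self, "dim", int(self.dim))
        object.__setattr__(self, "tau", int(self.tau))

    @property
    def span(self) -> int:
        """Number of raw samples consumed beyond the first, ``(dim-1)*tau``."""
        return (self.dim - 1) * self.tau

    def validate_for(self, n: int) -> None:
        if self.span >= n:
            raise ValueError(
                f"cannot embed N={n} samples with dim={self.dim}, tau={self.tau}: "
                f"(dim-1)*tau = {self.span} must be < N"
            )


@dataclass(frozen=True)
class StateMatrix:
    """Delay-embedded states, one row per reconstructed phase-space point.

    Row ``i`` is ``[x_i, x_{i+tau}, ..., x_{i+(dim-1)tau}]``;
    ``origin_offset`` records the raw index mapped to state 0 (always 0 for
    matrices produced here, kept explicit so downstream code never guesses).
    """

    states: np.ndarray
    params: EmbeddingParams
    origin_offset: int = 0

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    @property
    def dim(self) -> int:
        return self.states.shape[1]


def _as_samples(series) -> np.ndarray:
    return np.asarray(getattr(series, "samples", series), dtype=float).ravel()


def _embed_array(x: np.ndarray, dim: int, tau: int, n_states: int | None = None) -> np.ndarray:
    m = x.size - (dim - 1) * tau if n_states is None else n_states
    idx = np.arange(m)[:, None] + np.arange(dim)[None, :] * tau
    return x[idx]


def auto_mutual_information(series, max_lag: int | None = None,
                            n_bins: int | None = None) -> np.ndarray:
    """Auto-mutual information (bits) of a series for lags ``0..max_lag``.

    The joint distribution of ``(x_t, x_{t+lag})`` is estimated with an
    equal-width histogram over the observed range of the series.  Defaults:
    ``n_bins = ceil(sqrt(N))`` capped at 64, ``max_lag = min(N//2, fs)``
    (one second of lag when the input carries a sampling rate).

    Raises
    ------
    DegenerateSeriesError
        If the series is constant, in which case MI is undefined and the
        caller should use a fixed fallback delay.
    """
    x = _as_samples(series)
    n = x.size
    if max_lag is None:
        fs = getattr(series, "fs", None)
        max_lag = n // 2 if fs is None else min(n // 2, int(round(fs)))
        max_lag = max(2, max_lag)
    if not 0 < max_lag < n:
        raise ValueError(f"max_lag must be in 1..{n - 1}, got {max_lag}")
    if n_bins is None:
        n_bins = min(MAX_AMI_BINS, int(np.ceil(np.sqrt(n))))
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise DegenerateSeriesError("constant series: auto-mutual information undefined")

    # Quantize once; per-lag joint counts via bincount on combined bin codes.
    edges = np.linspace(lo, hi, n_bins + 1)
    codes = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)

    mi = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = codes[: n - lag] if lag else codes
        b = codes[lag:]
        joint = np.bincount(a * n_bins + b, minlength=n_bins * n_bins).astype(float)
        joint = joint.reshape(n_bins, n_bins)
        total = joint.sum()
        p = joint / total
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        nz = p > 0
        denom = np.outer(px, py)
        mi[lag] = float(np.sum(p[nz] * np.log2(p[nz] / denom[nz])))
    return mi


def _smooth_reflect(a: np.ndarray, w: int) -> np.ndarray:
    """Moving average with reflected ends (no phase shift, no edge decay)."""
    if w <= 1:
        return a.copy()
    pad = np.r_[a[w // 2:0:-1], a, a[-2:-w // 2 - 2:-1]]
    return np.convolve(pad, np.ones(w) / w, "valid")


def select_delay(ami: np.ndarray) -> int:
    """Embedding delay from an AMI curve: the first local minimum.

    Histogram MI estimates carry lag-to-lag jitter, so the curve is lightly
    smoothed (moving average whose width grows with the curve length, capped
    at 15 lags) before searching for the first minimum; a candidate must also
    be the smallest value within +/-2 lags, and minima inside the smoothing
    edge zone are ignored.  Falls back to the first lag where the raw MI
    drops below ``MI(0)/e`` if no minimum exists, and finally to 1.
    """
    ami = np.asarray(ami, dtype=float)
    if ami.size < 3:
        raise ValueError("AMI vector must have at least 3 lags")
    w = 5 if ami.size >= 15 else 3
    sm = _smooth_reflect(ami, w)
    stop = sm.size - 1 - max(1, w // 2)
    # equal-width-binned MI of periodic signals shows shallow ripple minima
    # before the true basin; only accept a minimum that reaches near the
    # curve's floor (within 10% of the MI(0)-to-floor drop)
    floor = sm[1:stop].min() if stop > 2 else float(sm.min())
    accept = floor + 0.1 * max(sm[0] - floor, 1e-12)
    for lag in range(1, stop):
        if not (sm[lag] < sm[lag - 1] and sm[lag] < sm[lag + 1]):
            continue
        lo, hi = max(0, lag - 2), min(sm.size, lag + 3)
        if sm[lag] <= sm[lo:hi].min() and sm[lag] <= accept:
            return lag
    below = np.flatnonzero(ami < ami[0] / np.e)
    if below.size:
        return int(below[0])
    return 1


def false_nearest_neighbors(series, tau: int, d_max: int = DEFAULT_D_MAX,
                            r_tol: float = DEFAULT_R_TOL,
                            a_tol: float = DEFAULT_A_TOL,
                            stop_below: float | None = None) -> np.ndarray:
    """Fraction of false nearest neighbors for candidate dimensions ``1..d_max``.

    For each candidate ``d``, every state's nearest neighbor in d dimensions
    is re-examined when the ``(d+1)``-th coordinate is appended.  A neighbor
    is false if the extra coordinate blows the distance up relative to the
    d-dimensional distance (``> r_tol``) or relative to the signal extent
    (grown distance ``> a_tol`` standard deviations).

    ``stop_below`` optionally truncates the scan once a fraction falls under
    the given threshold (the selected dimension is unaffected because the
    smallest passing ``d`` is taken anyway).
    """
    x = _as_samples(series)
    n = x.size
    if tau < 1:
        raise ValueError("tau must be >= 1")
    feasible = (n - 2) // tau  # need at least 2 states with a (d+1)-th coordinate
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    if feasible < d_max:
        raise ValueError(
            f"series of length {n} with tau={tau} supports FNN testing only up "
            f"to dimension {max(feasible, 0)} (requested d_max={d_max})"
        )
    sd = float(x.std())
    if sd == 0.0:
        warnings.warn("constant series: all phase-space distances are zero; "
                      "FNN fractions degenerate to 0", RuntimeWarning)
        return np.zeros(d_max)

    tiny = np.finfo(float).tiny
    fracs = []
    for d in range(1, d_max + 1):
        m = n - d * tau  # states that still have a (d+1)-th coordinate
        emb = _embed_array(x, d, tau, n_states=m)
        tree = cKDTree(emb)
        dist, idx = tree.query(emb, k=2)
        nd, nj = dist[:, 1], idx[:, 1]
        extra = np.abs(x[np.arange(m) + d * tau] - x[nj + d * tau])
        # guard against exact duplicate states (periodic signals): a ratio of
        # two round-off-sized distances is meaningless
        meaningful = extra > 1e-10 * sd
        ratio_false = meaningful & (extra > r_tol * np.maximum(nd, tiny))
        size_false = np.hypot(nd, extra) / sd > a_tol
        fracs.append(float(np.mean(ratio_false | size_false)))
        if stop_below is not None and fracs[-1] < stop_below:
            break
    return np.asarray(fracs)


def select_dimension(fnn: np.ndarray, threshold: float = DEFAULT_FNN_THRESHOLD) -> int:
    """Smallest dimension whose FNN fraction falls below ``threshold``.

    If no candidate passes, the largest tested dimension is returned with a
    warning (the series may lack a finite attractor dimension, e.g. noise).
    """
    fnn = np.asarray(fnn, dtype=float)
    if fnn.size == 0:
        raise ValueError("FNN vector is empty")
    passing = np.flatnonzero(fnn < threshold)
    if passing.size:
        return int(passing[0]) + 1
    warnings.warn(
        f"no embedding dimension up to {fnn.size} reached FNN < {threshold}; "
        f"using d={fnn.size}", RuntimeWarning)
    return int(fnn.size)


def delay_embed(series, params: EmbeddingParams) -> StateMatrix:
    """Delay-embed a series into a :class:`StateMatrix`.

    Produces ``N - (dim-1)*tau`` states; row ``i`` holds the lagged tuple
    ``[x_i, x_{i+tau}, ..., x_{i+(dim-1)tau}]``.
    """
    x = _as_samples(series)
    params.validate_for(x.size)
    return StateMatrix(states=_embed_array(x, params.dim, params.tau),
                       params=params, origin_offset=0)


def auto_embedding_params(series, tau: int = 0, dim: int = 0,
                          d_max: int = DEFAULT_D_MAX,
                          r_tol: float = DEFAULT_R_TOL,
                          a_tol: float = DEFAULT_A_TOL,
                          threshold: float = DEFAULT_FNN_THRESHOLD,
                          max_lag: int | None = None,
                          n_bins: int | None = None) -> EmbeddingParams:
    """Resolve embedding parameters, optimizing any of ``tau``/``dim`` set to 0.

    The delay comes from the AMI first minimum, the dimension from FNN.
    Both are clipped so the embedding stays feasible for the series length.
    Raises :class:`DegenerateSeriesError` for constant input.
    """
    x = _as_samples(series)
    n = x.size
    if float(x.std()) == 0.0:
        raise DegenerateSeriesError("constant series")
    if tau == 0:
        ami = auto_mutual_information(series, max_lag=max_lag, n_bins=n_bins)
        tau = select_delay(ami)
    tau = int(min(tau, max(1, (n - 2) // 2)))
    if dim == 0:
        feasible = max(1, min(d_max, (n - 2) // tau))
        fnn = false_nearest_neighbors(x, tau, d_max=feasible, r_tol=r_tol,
                                      a_tol=a_tol, stop_below=threshold)
        dim = select_dimension(fnn, threshold)
    # keep a handful of states available even for extreme parameter requests
    if (dim - 1) * tau >= n - 4:
        dim = max(1, (n - 4) // tau + 1)
    return EmbeddingParams(dim=int(dim), tau=int(tau))
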