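"""Recurrence amplitude spectra: single-window and time-resolved estimation.

The amplitude of one recurrence is the maximum phase-space diameter of its
loop (the largest pairwise distance among the states it visits, bounding
recurrence points included).  Averaging over the ``q`` recurrences of each
period T gives the mean amplitude ``abar(T)``, and weighting by the
recurrence probability yields the expected amplitude per frequency bin,

    A(T) = P(T) * abar(T),        f = fs / T.

Sliding the estimator over short overlapping windows produces a
time-frequency representation analogous to a spectrogram, but built from
state recurrences instead of sinusoidal projections — so a sawtooth and a
sine of equal period land in the same frequency bin with no harmonic
stack.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import find_peaks
from scipy.spatial.distance import cdist

from .config import RunConfig
from .embedding import (DegenerateSeriesError, EmbeddingParams, StateMatrix,
                        auto_embedding_params, delay_embed)
from .recurrence import (PeriodDistribution, RecurrenceMatrix, period_distribution,
                         recurrence_matrix, recurrence_periods)
from .series import Series
from .template import WaveformTemplate, event_gains

logger = logging.getLogger(__name__)

__all__ = [
    "RecurrenceAmplitudes",
    "RecurrenceSpectrum",
    "TimeFrequencySpectrum",
    "recurrence_amplitude",
    "weight_spectrum",
    "apply_template",
    "recurrence_spectrum",
    "windowed_spectrum",
    "frequency_axis",
    "scale_output",
    "min_resolvable_frequency",
    "spectral_peaks",
    "DB_FLOOR",
]

DB_FLOOR = -120.0  # dB value substituted for zero amplitudes
_MIN_STATES = 8    # fewer reconstructed states than this flags the window


@dataclass(frozen=True)
class RecurrenceAmplitudes:
    """Mean loop diameter ``abar`` and recurrence count ``q`` per period bin."""

    T_grid: np.ndarray
    abar: np.ndarray
    q_counts: np.ndarray


@dataclass(frozen=True)
class RecurrenceSpectrum:
    """Single-window spectrum: P(T), abar(T) and the weighted A(T) = P * abar."""

    T_grid: np.ndarray
    q_counts: np.ndarray
    abar: np.ndarray
    prob: np.ndarray
    weighted: np.ndarray
    fs: float
    params: EmbeddingParams | None = None
    degenerate: bool = False

    @property
    def freq(self) -> np.ndarray:
        return frequency_axis(self.T_grid, self.fs)


@dataclass(frozen=True)
class TimeFrequencySpectrum:
    """Windowed recurrence amplitude spectrum.

    ``values[i, j]`` is the spectrum of the window centered at ``times[i]``
    for period ``T_grid[j]``, already scaled per ``scale``/``db``.  Adjacent
    centers differ by ``window_len * (1 - overlap)`` samples.
    """

    times: np.ndarray
    T_grid: np.ndarray
    values: np.ndarray
    fs: float
    window_len: int
    overlap: float
    scale: str = "amp"
    db: bool = False
    params_per_window: tuple = ()
    degenerate_windows: tuple = ()
    config: RunConfig | None = None

    @property
    def freqs(self) -> np.ndarray:
        return frequency_axis(self.T_grid, self.fs)

    def segment_mean(self, t0: float, t1: float) -> np.ndarray:
        """Average spectrum over windows lying fully inside ``[t0, t1]`` seconds."""
        half = self.window_len / (2 * self.fs)
        inside = (self.times - half >= t0 - 1e-9) & (self.times + half <= t1 + 1e-9)
        if not inside.any():
            raise ValueError(f"no window lies fully inside [{t0}, {t1}] s")
        return self.values[inside].mean(axis=0)


def _event_arrays(events):
    periods = np.fromiter((e.period for e in events), dtype=np.int64, count=len(events))
    starts = np.fromiter((e.span[0] for e in events), dtype=np.int64, count=len(events))
    return periods, starts


def _event_amplitudes(events, states: StateMatrix, metric: str) -> np.ndarray:
    """Maximum phase-space diameter of each event's loop (span inclusive)."""
    X = states.states
    periods, starts = _event_arrays(events)
    amps = np.empty(len(events))
    if metric == "maximum":
        # max-norm diameter separates per coordinate: max over coords of
        # (max - min) within the span; vectorized per distinct span length.
        lengths = periods + 2
        for L in np.unique(lengths):
            sel = lengths == L
            sw = sliding_window_view(X, int(L), axis=0)   # (n-L+1, dim, L)
            seg = sw[starts[sel]]
            amps[sel] = (seg.max(axis=-1) - seg.min(axis=-1)).max(axis=-1)
    elif metric == "euclidean":
        for k, e in enumerate(events):
            a, b = e.span
            amps[k] = cdist(X[a:b + 1], X[a:b + 1]).max()
    else:
        raise ValueError(f"metric must be 'euclidean' or 'maximum', got {metric!r}")
    return amps


def recurrence_amplitude(events, states: StateMatrix, metric: str = "maximum",
                         gains: np.ndarray | None = None,
                         t_grid: np.ndarray | None = None) -> RecurrenceAmplitudes:
    """Mean recurrence amplitude per period.

    Each event's amplitude is its loop's maximum pairwise state distance;
    optional per-event ``gains`` (waveform-template filter) multiply the
    amplitudes *before* averaging.  With ``t_grid`` given, results align to
    that grid (events outside it are dropped); otherwise the grid is the
    sorted set of observed periods.
    """
    if len(events) == 0:
        grid = np.asarray(t_grid if t_grid is not None else [], dtype=np.int64)
        z = np.zeros(grid.size)
        return RecurrenceAmplitudes(T_grid=grid, abar=z, q_counts=z.astype(np.int64))
    amps = _event_amplitudes(events, states, metric)
    if gains is not None:
        amps = amps * np.asarray(gains, dtype=float)
    periods, _ = _event_arrays(events)
    if t_grid is None:
        t_grid = np.unique(periods)
    t_grid = np.asarray(t_grid, dtype=np.int64)
    lo = int(t_grid[0])
    inside = (periods >= lo) & (periods <= int(t_grid[-1]))
    sums = np.zeros(t_grid.size)
    counts = np.zeros(t_grid.size, dtype=np.int64)
    np.add.at(sums, periods[inside] - lo, amps[inside])
    np.add.at(counts, periods[inside] - lo, 1)
    abar = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return RecurrenceAmplitudes(T_grid=t_grid, abar=abar, q_counts=counts)


def weight_spectrum(dist: PeriodDistribution, amps: RecurrenceAmplitudes,
                    fs: float, params: EmbeddingParams | None = None) -> RecurrenceSpectrum:
    """Combine P(T) and abar(T) into the weighted spectrum A(T) = P * abar."""
    if not np.array_equal(dist.T_grid, amps.T_grid):
        raise ValueError("period distribution and amplitudes use different T grids")
    weighted = dist.prob * amps.abar
    return RecurrenceSpectrum(T_grid=dist.T_grid, q_counts=amps.q_counts,
                              abar=amps.abar, prob=dist.prob, weighted=weighted,
                              fs=fs, params=params, degenerate=dist.degenerate)


def apply_template(events, states: StateMatrix, series_samples,
                   template: WaveformTemplate, metric: str = "maximum",
                   t_grid: np.ndarray | None = None) -> RecurrenceAmplitudes:
    """Amplitudes with the waveform-template gain applied per event.

    The correlation runs on the raw (unembedded) samples spanning each
    event; with ``alpha == 0`` every gain is 1 and the result is identical
    to the unfiltered amplitudes.
    """
    gains = event_gains(events, series_samples, template)
    return recurrence_amplitude(events, states, metric=metric, gains=gains,
                                t_grid=t_grid)


def frequency_axis(t_grid, fs: float, ref_period: float | None = None) -> np.ndarray:
    """Frequency per period bin: ``fs / T``, or ``ref_period / T`` in
    normalized mode (frequency relative to a reference orbit period)."""
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 1):
        raise ValueError("periods must be >= 1 sample")
    if ref_period is not None:
        return ref_period / t
    return fs / t


def min_resolvable_frequency(window_samples: int, fs: float) -> float:
    """Lowest recurrence frequency a window can hold one full period of."""
    if window_samples < 2:
        raise ValueError("window must hold at least 2 samples")
    return fs / window_samples


def scale_output(values, outp: str = "amp", db: bool = False,
                 floor_db: float = DB_FLOOR) -> np.ndarray:
    """Scale nonnegative amplitudes to magnitude/power, optionally decibel.

    Power is amplitude squared; dB uses 20*log10 for magnitudes and
    10*log10 for power (so both agree).  Zeros map to ``floor_db``.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("amplitudes must be nonnegative")
    if outp == "pow":
        v = v ** 2
        factor = 10.0
    elif outp == "amp":
        factor = 20.0
    else:
        raise ValueError("outp must be 'amp' or 'pow'")
    if not db:
        return v
    with np.errstate(divide="ignore"):
        out = factor * np.log10(v)
    return np.maximum(np.where(np.isfinite(out), out, floor_db), floor_db)


def _resolve_grid(cfg: RunConfig, window_len: int) -> np.ndarray:
    if (cfg.min_period, cfg.max_period) == (0, 0):
        return np.arange(2, max(3, window_len))
    return np.arange(cfg.min_period, cfg.max_period + 1)


def _window_spectrum(x: np.ndarray, fs: float, cfg: RunConfig,
                     t_grid: np.ndarray, eps_std: float | None = None):
    """Raw (amp-scale) spectrum of one window on a fixed period grid.

    Returns ``(values, params, degenerate)``; degenerate windows yield a
    zero row (constant signal, or too few reconstructable states).
    """
    zero = np.zeros(t_grid.size)
    sd = float(x.std()) if eps_std is None else eps_std
    try:
        params = auto_embedding_params(x, tau=cfg.tau, dim=cfg.dim, d_max=cfg.d_max,
                                       r_tol=cfg.r_tol, a_tol=cfg.a_tol,
                                       threshold=cfg.fnn_threshold,
                                       max_lag=min(x.size // 2, max(2, int(round(fs)))))
    except DegenerateSeriesError:
        return zero, EmbeddingParams(1, 1), True
    states = delay_embed(x, params)
    if states.n_states < _MIN_STATES:
        return zero, params, True
    rm = recurrence_matrix(states, cfg.en, metric=cfg.metric, window_std=sd)
    if rm.degenerate:
        return zero, params, True
    events = recurrence_periods(rm)
    t_min, t_max = int(t_grid[0]), int(t_grid[-1])
    dist = period_distribution(events, t_min, t_max)
    if not cfg.amplitudes:
        return dist.prob.copy(), params, dist.degenerate
    if cfg.template is not None and cfg.template.alpha > 0:
        amps = apply_template(events, states, x, cfg.template, metric=cfg.metric,
                              t_grid=dist.T_grid)
    else:
        amps = recurrence_amplitude(events, states, metric=cfg.metric,
                                    t_grid=dist.T_grid)
    values = dist.prob * amps.abar
    if cfg.peak_rescale:
        values = values / 2.0
    return values, params, dist.degenerate


def recurrence_spectrum(series: Series, cfg: RunConfig | None = None,
                        **overrides) -> RecurrenceSpectrum:
    """Whole-series (single-window) weighted recurrence amplitude spectrum.

    Convenience entry point for non-time-resolved analysis; keyword
    overrides are applied on top of ``cfg`` (or the defaults).
    """
    cfg = replace(cfg or RunConfig(), **overrides)
    x = series.samples
    sd = series.std
    t_grid = _resolve_grid(cfg, x.size)
    try:
        params = auto_embedding_params(x, tau=cfg.tau, dim=cfg.dim, d_max=cfg.d_max,
                                       r_tol=cfg.r_tol, a_tol=cfg.a_tol,
                                       threshold=cfg.fnn_threshold,
                                       max_lag=min(x.size // 2, max(2, int(round(series.fs)))))
    except DegenerateSeriesError:
        z = np.zeros(t_grid.size)
        return RecurrenceSpectrum(T_grid=t_grid, q_counts=z.astype(np.int64), abar=z,
                                  prob=z, weighted=z, fs=series.fs,
                                  params=EmbeddingParams(1, 1), degenerate=True)
    states = delay_embed(x, params)
    rm = recurrence_matrix(states, cfg.en, metric=cfg.metric, window_std=sd)
    events = recurrence_periods(rm)
    t_min, t_max = int(t_grid[0]), min(int(t_grid[-1]), max(2, states.n_states - 1))
    dist = period_distribution(events, t_min, t_max)
    if cfg.template is not None and cfg.template.alpha > 0:
        amps = apply_template(events, states, x, cfg.template, metric=cfg.metric,
                              t_grid=dist.T_grid)
    else:
        amps = recurrence_amplitude(events, states, metric=cfg.metric,
                                    t_grid=dist.T_grid)
    return weight_spectrum(dist, amps, series.fs, params=params)


def windowed_spectrum(series: Series, cfg: RunConfig | None = None,
                      **overrides) -> TimeFrequencySpectrum:
    """Time-resolved recurrence amplitude spectrum over sliding windows.

    Each window is (re-)embedded with its own automatically selected
    parameters (unless fixed in the config), thresholded at
    ``en`` percent of its own standard deviation, and reduced to A(T) on a
    period grid shared by all windows.  Output rows sit at window centers;
    the trailing partial window is dropped.  Degenerate windows produce
    zero rows and are listed in ``degenerate_windows``.
    """
    cfg = replace(cfg or RunConfig(), **overrides)
    x = series.samples
    fs = series.fs
    n = x.size
    win = int(round((cfg.window / 1000.0) * fs)) if cfg.window else n // 10
    if win < 4:
        raise ValueError(f"window of {win} samples is too short (minimum 4)")
    if win > n:
        raise ValueError(f"window of {win} samples exceeds series length {n}")
    hop = max(1, int(round(win * (1 - cfg.overlap))))
    starts = np.arange(0, n - win + 1, hop)
    t_grid = _resolve_grid(cfg, win)
    eps_std = series.std if cfg.global_std else None

    values = np.zeros((starts.size, t_grid.size))
    params_pw: list[tuple[int, int]] = []
    degenerate: list[int] = []
    for i, s in enumerate(starts):
        row, params, degen = _window_spectrum(x[s:s + win], fs, cfg, t_grid,
                                              eps_std=eps_std)
        values[i] = row
        params_pw.append((params.dim, params.tau))
        if degen:
            degenerate.append(i)
        logger.info("window %d/%d [%d:%d]: d=%d tau=%d%s", i + 1, starts.size,
                    s, s + win, params.dim, params.tau,
                    " (degenerate)" if degen else "")

    centers = (starts + win / 2.0) / fs
    # average rows whose centers coincide (possible only for pathological hops)
    uniq, inv = np.unique(np.round(centers, 9), return_inverse=True)
    if uniq.size != centers.size:
        agg = np.zeros((uniq.size, t_grid.size))
        cnt = np.zeros(uniq.size)
        np.add.at(agg, inv, values)
        np.add.at(cnt, inv, 1.0)
        values = agg / cnt[:, None]
        centers = uniq
    values = scale_output(values, outp=cfg.outp, db=cfg.db)
    return TimeFrequencySpectrum(times=centers, T_grid=t_grid, values=values,
                                 fs=fs, window_len=win, overlap=cfg.overlap,
                                 scale=cfg.outp, db=cfg.db,
                                 params_per_window=tuple(params_pw),
                                 degenerate_windows=tuple(degenerate), config=cfg)


def spectral_peaks(values: np.ndarray, t_grid: np.ndarray, fs: float,
                   t_above: int | None = None):
    """Local maxima of a spectrum, tallest first.

    Returns ``(T, frequency, height)`` triples from
    :func:`scipy.signal.find_peaks`; ``t_above`` restricts the search to
    periods strictly greater than the given one (used to hunt subharmonics
    below the fundamental)."""
    v = np.asarray(values, dtype=float)
    idx, _ = find_peaks(v)
    if t_above is not None:
        idx = idx[t_grid[idx] > t_above]
    order = np.argsort(v[idx])[::-1]
    idx = idx[order]
    return [(int(t_grid[i]), float(fs / t_grid[i]), float(v[i])) for i in idx]
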