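"""Waveform-template gain: make the recurrence spectrum shape-specific.

Each recurrence carries a raw-signal segment (one loop through phase
space).  Its gain is the maximal Pearson correlation between that segment
and a template waveform resampled so that one template cycle spans the
recurrence period, searched over all cyclic phase offsets.  Raising the
gain to a power ``alpha`` sharpens the filter; ``alpha = 0`` disables it
(all gains exactly 1).  Negative best correlations clamp to 0: an
anti-correlated waveform should be suppressed, not sign-flipped.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["WaveformTemplate", "template_gain", "event_gains"]


@dataclass(frozen=True)
class WaveformTemplate:
    """Template waveform of ``n_cycles`` identical cycles plus the filter
    exponent ``alpha``."""

    shape_samples: np.ndarray
    alpha: float = 1.0
    n_cycles: int = 1

    def __post_init__(self) -> None:
        z = np.asarray(self.shape_samples, dtype=float).ravel()
        if z.size < 4:
            raise ValueError("template must hold at least 4 samples")
        if float(z.std()) == 0.0:
            raise ValueError("template must be nonconstant")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if int(self.n_cycles) < 1:
            raise ValueError("n_cycles must be >= 1")
        object.__setattr__(self, "shape_samples", z)
        object.__setattr__(self, "n_cycles", int(self.n_cycles))

    @classmethod
    def from_wave(cls, shape: str = "sine", n_cycles: int = 5, alpha: float = 5.0,
                  samples_per_cycle: int = 200) -> "WaveformTemplate":
        """Build a sine/sawtooth/rectangle template of ``n_cycles`` cycles."""
        from . import synth  # local import to avoid a cycle

        spec = synth.WaveSpec(shape=shape, freq=1.0, amplitude=1.0,
                              duration=float(n_cycles), fs=float(samples_per_cycle))
        return cls(shape_samples=synth.make_wave(spec).samples,
                   alpha=alpha, n_cycles=n_cycles)


def _one_cycle(template: WaveformTemplate, period: int) -> np.ndarray:
    """Resample the template so a single cycle spans ``period`` samples.

    Linear interpolation with periodic wrap keeps sharp waveform features
    (e.g. rectangle edges) free of ringing.
    """
    z = template.shape_samples
    cycle_len = z.size / template.n_cycles
    pos = np.arange(period) * (cycle_len / period)
    return np.interp(pos, np.arange(z.size), z, period=float(z.size))


def template_gain(segment, template: WaveformTemplate, period: int | None = None) -> float:
    """Gain ``G**alpha`` for one raw-signal segment.

    ``period`` is the cycle length the template is stretched to (defaults to
    the segment length).  G is the maximum over all cyclic offsets of the
    Pearson correlation between the segment and a same-length template
    window; negative maxima clamp to 0.  A zero-variance segment gets gain 0
    (degenerate: no waveform to correlate).
    """
    seg = np.asarray(segment, dtype=float).ravel()
    L = seg.size
    if L < 3:
        raise ValueError("segment must hold at least 3 samples")
    if template.alpha == 0:
        return 1.0
    s_std = float(seg.std())
    if s_std == 0.0:
        return 0.0
    T = int(period) if period is not None else L
    if T < 2:
        return 0.0
    cyc = _one_cycle(template, T)
    reps = int(np.ceil((L + T) / T))
    tiled = np.tile(cyc, reps)
    wins = sliding_window_view(tiled, L)[:T]          # offsets 0 .. T-1
    wm = wins.mean(axis=1)
    ws = wins.std(axis=1)
    cov = wins @ seg / L - wm * seg.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(ws > 0, cov / (ws * s_std), 0.0)
    g = max(float(r.max()), 0.0)
    return g ** template.alpha


def event_gains(events, samples: np.ndarray, template: WaveformTemplate) -> np.ndarray:
    """Per-event gains from the raw samples spanning each recurrence loop.

    The segment runs from the first to the second bounding recurrence point
    (state indices equal raw indices for origin-offset-0 embeddings); the
    template cycle length is ``period + 1``, the loop's true cycle (the two
    bounding points sit one full cycle apart).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if template.alpha == 0:
        return np.ones(len(events))
    gains = np.empty(len(events))
    for k, e in enumerate(events):
        a, b = e.span
        gains[k] = template_gain(x[a:b + 1], template, period=e.period + 1)
    return gains
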