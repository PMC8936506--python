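"""Short-time Fourier and Morlet-wavelet spectrograms.

Reference implementations for side-by-side comparisons with the recurrence
amplitude spectrum; they reproduce the qualitative behavior of standard
toolboxes (harmonic stacks for non-sinusoidal waveforms, broadband bursts
at sharp transitions) without aiming for numeric parity with any one of
them.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import ShortTimeFFT, fftconvolve, get_window

from .series import Series

__all__ = ["Spectrogram", "stft_spectrogram", "morlet_spectrogram"]


@dataclass(frozen=True)
class Spectrogram:
    times: np.ndarray          # s
    freqs: np.ndarray          # Hz
    power: np.ndarray          # time x freq, PSD-scaled for STFT
    method: str
    params: dict


def stft_spectrogram(series: Series, window_ms: float, overlap: float = 0.5,
                     window: str = "hann") -> Spectrogram:
    """Windowed Fourier power (one-sided PSD) on overlapping segments."""
    fs = series.fs
    nperseg = int(round(window_ms * fs / 1000.0))
    if not 4 <= nperseg <= series.n:
        raise ValueError(f"window of {nperseg} samples is infeasible for n={series.n}")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    hop = max(1, int(round(nperseg * (1 - overlap))))
    win = get_window(window, nperseg)
    sft = ShortTimeFFT(win, hop=hop, fs=fs, scale_to="psd")
    power = sft.spectrogram(series.samples)          # (freq, time), |S|^2 PSD
    # one-sided PSD convention: double every bin except DC (and Nyquist for
    # even segment lengths) so the integral over frequency gives the variance
    last = power.shape[0] - 1 if nperseg % 2 == 0 else power.shape[0]
    power[1:last] *= 2.0
    return Spectrogram(times=sft.t(series.n), freqs=sft.f, power=power.T,
                       method="stft", params={"window_ms": window_ms,
                                              "overlap": overlap, "window": window})


def _morlet_kernel(f: float, fs: float, n_cycles: float) -> np.ndarray:
    sigma_t = n_cycles / (2 * np.pi * f)
    half = int(np.ceil(3.5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(2j * np.pi * f * t) * np.exp(-t ** 2 / (2 * sigma_t ** 2))
    return kernel / np.linalg.norm(kernel)


def morlet_spectrogram(series: Series, freqs, n_cycles: float = 7.0) -> Spectrogram:
    """Complex Morlet convolution power at the requested frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= series.fs / 2):
        raise ValueError("frequencies must lie strictly inside (0, fs/2)")
    x = series.samples - series.samples.mean()
    power = np.empty((series.n, freqs.size))
    for i, f in enumerate(freqs):
        c = fftconvolve(x, _morlet_kernel(f, series.fs, n_cycles), mode="same")
        power[:, i] = np.abs(c) ** 2
    return Spectrogram(times=series.time(), freqs=freqs, power=power,
                       method="morlet", params={"n_cycles": n_cycles})
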