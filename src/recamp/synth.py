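"""Synthetic validation signals: waveform compounds, frequency steps, noise,
and a chaotic (Lorenz) trajectory.

These generators define the study conditions for the validation
experiments: 33-Hz sine/sawtooth/rectangle compounds of 5 s each, a
five-step frequency staircase (14/33/41/52/67 Hz, 3 s each), seeded uniform
measurement noise referenced to the signal amplitude, and a slow 3-Hz
signal with 8 %-STD noise for the eps-scan diagnostic.  All fixtures use
fs = 1000 Hz.  Every generator is deterministic given its arguments and
seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .series import Series

__all__ = [
    "WaveSpec",
    "make_wave",
    "concat",
    "add_uniform_noise",
    "lorenz_series",
    "load_bz",
    "fig4_compound",
    "fig5_steps",
    "fig6_noise",
    "fig3_slow",
    "BZ_URL",
]

FIXTURE_FS = 1000.0
BZ_URL = "https://complex.umd.edu/data/bzflow2.zip"


@dataclass(frozen=True)
class WaveSpec:
    """One periodic waveform: shape, frequency (Hz), amplitude, duration (s),
    sampling rate (Hz) and initial phase (rad)."""

    shape: str
    freq: float
    amplitude: float = 1.0
    duration: float = 1.0
    fs: float = FIXTURE_FS
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("sine", "sawtooth", "rectangle"):
            raise ValueError("shape must be 'sine', 'sawtooth' or 'rectangle'")
        if self.freq >= self.fs / 2:
            raise ValueError(
                f"frequency {self.freq} Hz aliases at fs={self.fs} Hz (Nyquist {self.fs / 2})")
        if round(self.duration * self.fs) < 2:
            raise ValueError("duration*fs must be at least 2 samples")


def make_wave(spec: WaveSpec) -> Series:
    """Generate one waveform.

    sine: ``A*sin(2*pi*f*t + phase)``; sawtooth: rising ramp from -A to +A
    per cycle; rectangle: ±A square wave with 50 % duty cycle.
    """
    n = int(round(spec.duration * spec.fs))
    arg = 2 * np.pi * spec.freq * np.arange(n) / spec.fs + spec.phase
    if spec.shape == "sine":
        y = np.sin(arg)
    elif spec.shape == "sawtooth":
        y = _sig.sawtooth(arg)
    else:
        y = _sig.square(arg)
    return Series(spec.amplitude * y, spec.fs, label=f"{spec.shape}@{spec.freq}Hz")


def concat(parts: list[Series]) -> Series:
    """Sample-wise concatenation; transitions are sharp by design (they probe
    broadband edge artifacts in the baseline methods)."""
    if not parts:
        raise ValueError("nothing to concatenate")
    fs = parts[0].fs
    for p in parts:
        if p.fs != fs:
            raise ValueError(f"sampling rates differ: {p.fs} vs {fs}")
    return Series(np.concatenate([p.samples for p in parts]), fs,
                  label="+".join(p.label for p in parts if p.label))


def add_uniform_noise(series: Series, level_pct: float,
                      reference: str = "amplitude",
                      seed: int | np.random.Generator | None = None) -> Series:
    """Add iid uniform noise on ``[-L, +L]``.

    ``L = (level_pct/100) * ref`` where ``ref`` is the signal's peak
    amplitude (``max |x|``, the default, matching noise quoted in percent of
    amplitude) or its standard deviation.  ``level_pct = 0`` returns the
    series unchanged.
    """
    if level_pct < 0:
        raise ValueError("noise level must be >= 0")
    if level_pct == 0:
        return series
    if reference == "amplitude":
        ref = float(np.max(np.abs(series.samples)))
    elif reference == "std":
        ref = series.std
    else:
        raise ValueError("reference must be 'amplitude' or 'std'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bound = (level_pct / 100.0) * ref
    noise = rng.uniform(-bound, bound, size=series.n)
    return Series(series.samples + noise, series.fs, series.label)


def _lorenz_rhs(v: np.ndarray, sigma: float, rho: float, beta: float) -> np.ndarray:
    x, y, z = v
    return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])


def lorenz_series(n: int, dt: float = 0.01, init=None,
                  seed: int | None = None, coord: int = 0,
                  discard: int = 1000) -> Series:
    """One coordinate of a Lorenz trajectory, fixed-step RK4.

    Classical chaotic parameters sigma=10, rho=28, beta=8/3; an initial
    transient of ``discard`` steps is dropped so the trajectory sits on the
    attractor.  ``init=None`` draws a start point near the attractor from
    ``seed``.  The nominal sampling rate is ``1/dt``.
    """
    if n < 100:
        raise ValueError("need at least 100 samples")
    sigma, rho, beta = 10.0, 28.0, 8.0 / 3.0
    if init is None:
        rng = np.random.default_rng(seed)
        init = np.array([1.0, 1.0, 20.0]) + rng.normal(0, 0.5, 3)
    v = np.asarray(init, dtype=float)
    out = np.empty(n)
    for k in range(discard + n):
        k1 = _lorenz_rhs(v, sigma, rho, beta)
        k2 = _lorenz_rhs(v + 0.5 * dt * k1, sigma, rho, beta)
        k3 = _lorenz_rhs(v + 0.5 * dt * k2, sigma, rho, beta)
        k4 = _lorenz_rhs(v + dt * k3, sigma, rho, beta)
        v = v + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(v)) or np.max(np.abs(v)) > 1e6:
            raise FloatingPointError("Lorenz integration diverged; reduce dt")
        if k >= discard:
            out[k - discard] = v[coord]
    return Series(out, fs=1.0 / dt, label="lorenz")


def load_bz(path) -> Series:
    """Load the Belousov–Zhabotinsky benchmark series (first 40,000 samples
    of the first channel of a delimited text file).

    The file is an external download and is never fetched automatically;
    a missing file raises an error naming the source URL.
    """
    import pathlib

    p = pathlib.Path(path)
    if not p.exists():
        raise FileNotFoundError(
            f"BZ data file not found at {p}; download it from {BZ_URL} and unpack "
            "the series as delimited text")
    data = np.loadtxt(p)
    if data.ndim > 1:
        data = data[:, 0]
    return Series(data[:40000], fs=1.0, label="belousov-zhabotinsky")


# --------------------------------------------------------------------------
# Named fixtures shared by tests, docs and the validation experiments.

def fig4_compound(fs: float = FIXTURE_FS) -> Series:
    """5 s sine + 5 s sawtooth + 5 s rectangle, all 33 Hz, amplitude 2."""
    return concat([make_wave(WaveSpec(shape=s, freq=33.0, amplitude=2.0,
                                      duration=5.0, fs=fs))
                   for s in ("sine", "sawtooth", "rectangle")])


def fig5_steps(fs: float = FIXTURE_FS) -> Series:
    """Five 3-s sinusoids at 14, 33, 41, 52 and 67 Hz, amplitude 1."""
    return concat([make_wave(WaveSpec(shape="sine", freq=f, amplitude=1.0,
                                      duration=3.0, fs=fs))
                   for f in (14.0, 33.0, 41.0, 52.0, 67.0)])


def fig6_noise(level_pct: float, seed: int | None = 0, fs: float = FIXTURE_FS) -> Series:
    """The waveform compound plus uniform noise at ``level_pct`` percent of
    the signal amplitude."""
    return add_uniform_noise(fig4_compound(fs), level_pct,
                             reference="amplitude", seed=seed)


def fig3_slow(seed: int | None = 0, duration: float = 50.0,
              fs: float = FIXTURE_FS) -> Series:
    """50 s of a 3-Hz sinusoid with 8 %-STD uniform noise (eps-scan input)."""
    base = make_wave(WaveSpec(shape="sine", freq=3.0, amplitude=1.0,
                              duration=duration, fs=fs))
    return add_uniform_noise(base, 8.0, reference="std", seed=seed)
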