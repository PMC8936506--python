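"""Evenly sampled scalar time-series container used throughout the package."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Series:
    """One evenly sampled channel together with its sampling rate.

    Parameters
    ----------
    samples : array-like
        Signal values in arbitrary (but consistent) physical units.
    fs : float
        Sampling rate in Hz. Must be positive.
    label : str, optional
        Free-text channel description carried through to outputs.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float).ravel()
        if x.size < 2:
            raise ValueError("a series needs at least two samples")
        if not np.all(np.isfinite(x)):
            raise ValueError("series contains non-finite samples")
        if not float(self.fs) > 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", x)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n / self.fs

    @property
    def std(self) -> float:
        """Standard deviation of the raw samples (used to scale the
        recurrence neighborhood radius)."""
        return float(self.samples.std())

    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) / self.fs

    def scaled(self, c: float) -> "Series":
        """Return a copy with every sample multiplied by ``c``."""
        return Series(self.samples * c, self.fs, self.label)
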