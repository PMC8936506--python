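"""Run configuration for the windowed recurrence-spectrum pipeline.

Field names and defaults mirror the method's canonical configuration
surface: ``tau``/``dim`` 0 for automatic optimization, neighborhood size
``en`` in percent of the window standard deviation (default 5), maximum
norm, a sliding window of 1/10 the data length when unset, amplitudes on,
the full period range, decibel output of amplitude magnitudes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

from .template import WaveformTemplate

_METRICS = ("euclidean", "maximum")
_OUTPUTS = ("amp", "pow")


@dataclass
class RunConfig:
    tau: int = 0                      # embedding delay, samples; 0 = auto (AMI)
    dim: int = 0                      # embedding dimension; 0 = auto (FNN)
    en: float = 5.0                   # neighborhood size, % of window STD
    metric: str = "maximum"           # phase-space distance norm
    window: Optional[float] = None    # sliding-window length in ms; None = N/10
    overlap: float = 0.5              # window overlap fraction in [0, 1)
    amplitudes: bool = True           # False: export probabilities P(T) only
    min_period: int = 0               # (0, 0) = all feasible periods
    max_period: int = 0
    db: bool = True                   # export in decibel
    outp: str = "amp"                 # "amp" magnitude or "pow" power
    template: Optional[WaveformTemplate] = None  # optional waveform-shape filter
    seed: int = 0                     # recorded in metadata; generators use it
    global_std: bool = False          # scale eps by whole-recording STD instead
    peak_rescale: bool = False        # divide diameters by 2 (peak amplitude)
    d_max: int = 10                   # FNN search depth
    r_tol: float = 10.0               # FNN distance-ratio tolerance
    a_tol: float = 2.0                # FNN size-ratio tolerance
    fnn_threshold: float = 0.01       # accept dimension below this FNN fraction

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")
        if self.outp not in _OUTPUTS:
            raise ValueError(f"outp must be one of {_OUTPUTS}")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.en <= 0:
            raise ValueError("en (neighborhood size, % STD) must be positive")
        if self.tau < 0 or self.dim < 0:
            raise ValueError("tau and dim must be >= 0 (0 = automatic)")
        if (self.min_period, self.max_period) != (0, 0):
            if self.min_period < 2 or self.max_period < self.min_period:
                raise ValueError("period range must satisfy 2 <= min <= max, or (0, 0)")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.template is not None:
            d["template"] = {"n_samples": int(self.template.shape_samples.size),
                             "n_cycles": self.template.n_cycles,
                             "alpha": self.template.alpha}
        return d
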