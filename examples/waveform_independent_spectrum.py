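"""Recover one 33-Hz rhythm from three different waveform shapes.

A 15-s signal concatenates a sine, a sawtooth and a rectangle wave, all at
33 Hz with amplitude 2.  A Fourier spectrogram of the non-sinusoidal
segments shows harmonic stacks at 66/99 Hz; the recurrence amplitude
spectrum puts all three segments into the same period bin with no
harmonics.
"""
import numpy as np

from recamp import RunConfig, stft_spectrogram, windowed_spectrum
from recamp import synth

sig = synth.fig4_compound()                       # 5 s sine + sawtooth + rectangle
cfg = RunConfig(en=10.0, window=600, overlap=0.5, db=False)
tfs = windowed_spectrum(sig, cfg)
stft = stft_spectrogram(sig, 600, 0.5)

print("segment      recurrence peak   harmonic/fundamental (recurrence | STFT)")
for name, (t0, t1) in [("sine", (0, 5)), ("sawtooth", (5, 10)), ("rectangle", (10, 15))]:
    m = tfs.segment_mean(t0, t1)
    T = tfs.T_grid[np.argmax(m)]
    rec_harm = m[(tfs.freqs > 55) & (tfs.freqs < 110)].max() / m.max()
    sel = (stft.times >= t0 + 0.5) & (stft.times <= t1 - 0.5)
    sm = stft.power[sel].mean(axis=0)
    fund = sm[np.argmin(np.abs(stft.freqs - 33))]
    # sawtooth has all harmonics, rectangle only odd ones: check 66 and 99 Hz
    harm = max(sm[np.argmin(np.abs(stft.freqs - 66))],
               sm[np.argmin(np.abs(stft.freqs - 99))])
    print(f"{name:<12} {sig.fs / T:6.2f} Hz (T={T})   {rec_harm:.3f} | {harm / fund:.3f}")

print("\nA recurrence peak near 33 Hz for every shape, with a harmonic ratio")
print("of ~0 (vs ~0.25 for the STFT sawtooth), is the waveform-independence")
print("property: the estimator tracks state recurrences, not sinusoid fits.")
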