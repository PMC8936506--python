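"""Choosing the neighborhood size with an eps-resolved period spectrum.

P(T) is computed over a grid of neighborhood radii (percent of the signal
STD).  Tiny radii leave only noise-driven recurrences (flat distribution);
huge radii swallow whole cycles (mass at tiny periods); in between, a
stable spectral ridge marks the rhythm, drifting to smaller periods by
about two samples per state-to-state distance added to eps.
"""
import numpy as np

from recamp import (EmbeddingParams, auto_embedding_params, delay_embed,
                    mean_step_distance, predicted_period_shift, sreps)
from recamp import synth

sig = synth.fig3_slow(seed=1, duration=5.0)        # 3 Hz + 8% STD noise
params = auto_embedding_params(sig.samples, max_lag=500)
print(f"auto embedding: d={params.dim}, tau={params.tau}")

# restrict to periods of interest (>= 50 samples, i.e. <= 20 Hz) so the
# tangential short-period regime does not dominate the histogram
res = sreps(sig, params, [2.0, 20.0, 60.0, 150.0, 300.0], t_min=50, t_max=600)
for eps, row, degen in zip(res.eps_grid, res.prob, res.degenerate_rows):
    if degen:
        print(f"eps {eps:5.0f}% STD: degenerate (neighborhood engulfs the whole "
              f"phase space, no excursions left)")
        continue
    T = res.T_grid[np.argmax(row)]
    print(f"eps {eps:5.0f}% STD: modal T={T:4d} ({sig.fs / T:6.1f} Hz), "
          f"max P(T)={row.max():.3f}")

states = delay_embed(sig, params)
step_pct = 100 * mean_step_distance(states) / sig.std
eps_err, shift = predicted_period_shift(20.0, 2, step_pct)
print(f"\npredicted ridge drift: growing eps from 20% to {eps_err:.0f}% "
      f"(two step-distances) shifts the modal period by {shift} samples.")
print("The 3-Hz rhythm (T~333) is the stable ridge: it drifts to smaller")
print("periods as eps grows and vanishes once the neighborhood engulfs the")
print("attractor.  (On the full period grid, tiny eps instead shows the")
print("flat noise-floor distribution.)")
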