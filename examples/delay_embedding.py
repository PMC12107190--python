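"""Predictability analysis when only one observable is measured.

Often a single scalar series is all that is available (one sensor, one
station).  Takens-style delay embedding reconstructs a phase space from
lagged copies of the series; the recurrence machinery then applies
unchanged.  Here a scalar Lorenz-63 x-coordinate series is embedded in 3-D
and its predictability index is compared with the full-state result.
"""

import numpy as np

from tlrec import (RecurrenceParams, alpha_sweep, delay_embed,
                   simulate_lorenz63)

full = simulate_lorenz63(n_steps=40_000, dt=5e-3, discard=10_000)
x_only = full.states[:, 0]

emb = delay_embed(x_only, dim=3, lag=10, dt=full.dt)
print(f"scalar series: {x_only.size} samples -> embedded trajectory "
      f"{emb.n_steps} x {emb.n_vars} (lag 10 steps = 0.05 time units)")

params = RecurrenceParams(q=0.99, w=50)
horizons = [11, 44, 220]
f_full = alpha_sweep(full, 400, horizons, params, seed=0)
f_emb = alpha_sweep(emb, 400, horizons, params, seed=0)

print("horizon L | mean alpha (full state) | mean alpha (embedded x)")
for j, L in enumerate(horizons):
    print(f"   {L:4d}   |          {f_full.mean_alpha()[j]:.3f}          |"
          f"          {f_emb.mean_alpha()[j]:.3f}")
print()
print("The reconstructed phase space reproduces the decay of predictability")
print("with horizon seen in the full state space, as Takens' theorem leads")
print("us to expect for a generic observable.")
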