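"""Local dimension and persistence alongside the predictability index.

From each reference state's recurrences the package also estimates the
local dimension d (inverse scale of the exponential exceedance fit — the
active degrees of freedom near the state) and the persistence Theta
(inverse Sueveges extremal index — mean consecutive steps the trajectory
lingers in the neighbourhood).  High d / low Theta is often read as "less
predictable"; comparing with alpha makes that intuition testable.
"""

import numpy as np

from tlrec import RecurrenceParams, compute_indices_table, simulate_lorenz63

traj = simulate_lorenz63(n_steps=40_000, dt=5e-3, discard=10_000)
params = RecurrenceParams(q=0.99, w=50)

table = compute_indices_table(traj, refs=400, horizons_steps=[11, 440],
                              params=params, seed=0)

print(table[["d", "theta", "Theta", "alpha_L11", "alpha_L440"]]
      .describe().loc[["mean", "std", "min", "max"]].round(3))
print()
print(f"Mean local dimension {table['d'].mean():.2f} is close to the "
      "attractor's fractal dimension (~2.06).")
corr = np.corrcoef(table["theta"], table["alpha_L11"])[0, 1]
print(f"Correlation of inverse persistence theta with alpha at L=11: "
      f"{corr:+.2f} — on this system, fast-moving wing states (high theta) "
      "can still be highly predictable at short horizons.")
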