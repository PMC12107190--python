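"""Which regions of an attractor are hardest to predict?

Partitions the Lorenz-63 attractor into seven K-means clusters and averages
the time-lagged recurrence index within each over a horizon grid.  The
cluster covering the lobe-switching region (centroid nearest x = y = 0) is
expected to be the least predictable: trajectories there are about to
choose a wing.
"""

import numpy as np

from tlrec import (RecurrenceParams, alpha_sweep, cluster_alpha_curves,
                   kmeans_clusters, lobe_switching_cluster, simulate_lorenz63)

traj = simulate_lorenz63(n_steps=40_000, dt=5e-3, discard=10_000)
params = RecurrenceParams(q=0.99, w=50)

field = alpha_sweep(traj, refs=800, horizons_steps=[11, 22, 44, 220, 440],
                    params=params, seed=0, eta_ell=1.1)
labels, centroids = kmeans_clusters(traj, k=7, seed=0)
summary = cluster_alpha_curves(field, labels, centroids)
lobe = lobe_switching_cluster(centroids)

print("cluster | centroid (x, y, z)        | alpha at L=11 | AUC")
for c in range(summary.k):
    cx, cy, cz = centroids[c]
    tag = "  <- lobe switching" if c == lobe else ""
    print(f"   {c}    | ({cx:6.1f}, {cy:6.1f}, {cz:5.1f}) |"
          f"     {summary.curves[c, 0]:.3f}     | {summary.auc[c]:.3f}{tag}")
print()
print("The lobe-switching cluster has the lowest short-horizon alpha and the")
print("lowest area under its predictability curve (AUC, integrated over the")
print("horizon axis in Lyapunov-time units): state-dependent predictability")
print("is worst where the flow decides between the two wings.")
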