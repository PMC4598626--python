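"""Cluster and colocalization statistics on dual-channel localization tables.

Two channels share all cluster parents (strong co-clustering).  Ripley's
L(r)-r shows each channel's sub-synaptic clustering against a CSR envelope;
the k=10 nearest-neighbour distribution against the second channel, compared
with its toroidal-shift null, shows the cross-channel colocalization.
"""

import numpy as np

import svspread as sv

win = (0.0, 0.0, 1000.0, 1000.0)  # nm
table = sv.simulate_point_pattern(
    "clustered", win,
    n_parents=10, mean_offspring=20, cluster_sigma=50.0,  # ~50-nm cluster radius
    channels=("NEP", "AP180"), shared_parent_fraction=1.0, seed=7,
)

radii = np.arange(20.0, 320.0, 20.0)
for ch in table.channels:
    res = sv.L_minus_r(sv.ripley_K(table.channel(ch), win, radii))
    env = sv.csr_envelope(win, res.N, radii, n_sim=10, seed=1)
    r_peak = radii[int(np.argmax(res.L_minus_r))]
    print(f"{ch:6s}: N={res.N:4d}  max L(r)-r = {res.L_minus_r.max():6.1f} nm at r = {r_peak:.0f} nm"
          f"  (CSR envelope there: {env[int(np.argmax(res.L_minus_r))]:.1f} nm)")

q, ref = table.channel("NEP"), table.channel("AP180")
obs = sv.knn_cross(q, ref, k=10)
null = sv.knn_cross(q, sv.toroidal_shift(ref, win), k=10)
below = np.mean(obs.distances < 50.0)
below_null = np.mean(null.distances < 50.0)
print(f"\nk=10 NN mass below 50 nm: observed {below:.2f} vs toroidal null {below_null:.2f}")
print("L(r)-r above the CSR envelope marks sub-synaptic clustering; k-NN mass")
print("above the shifted null marks genuine cross-channel colocalization.")
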