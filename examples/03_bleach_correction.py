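"""Per-pixel photobleaching correction of a time-lapse stack.

Each pixel's pre-stimulus trace is fit with I(t) = bg + a·exp(-t/tau); the
bleach rate lambda = 1/tau then rescales the whole sequence,
I_bc = bg + (I - bg)·e^(lambda·t).  On a synthetically bleached stack the
corrected pre-stimulus signal is flat.
"""

import numpy as np

import svspread as sv

params = sv.FusionGroundTruth(
    D=0.0,
    event_times=(30.0,),
    molecules_per_event=200,
    bouton_radius=1.0,
    resting_molecules=300,  # residual surface pool -> bleachable baseline
    bleach_lifetime=30.0,
    background=20.0,
    noise_sd=0.5,
    frame_interval=1.0,
    stim_start=30.0,  # baseline spans a full bleach lifetime
    stim_end=31.0,
    n_frames=40,
    image_shape=(24, 24),
    seed=2,
)
seq, _ = sv.simulate_fusion_sequence(params)
model = sv.fit_bleach_model(seq)
corrected = sv.bleach_correct(seq, model)

ok = model.fit_ok
print(f"pixels with a usable bleach fit: {ok.sum()} / {ok.size}")
# note: (bg, a, tau) trade off strongly on a finite baseline, so per-pixel tau
# is noisy — what matters is that the fitted curve, hence the correction,
# matches the decay, which the flat corrected baseline below demonstrates

pre = seq.times < params.stim_start
raw = seq.frames[pre][:, ok].mean(axis=1)
fix = corrected.frames[pre][:, ok].mean(axis=1)
print("\ntime_s  raw_mean  corrected_mean")
for t, r, c in zip(seq.times[pre], raw, fix):
    print(f"{t:5.1f}  {r:8.2f}  {c:12.2f}")
print("\nThe raw baseline decays; the corrected one is flat, so any later")
print("intensity change reflects exocytosis rather than photobleaching.")
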