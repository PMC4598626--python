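"""Simulate a stimulated bouton and track the spread of exocytosed protein.

A 40-event fusion train (20 Hz, 2 s) deposits pHluorin-tagged molecules at the
active zone; they diffuse at D = 0.30 um²/s inside a reflecting bouton of
radius 1.15 um.  We subtract the baseline, detect the responding synapse, fit
every dF frame with a rotated 2D Gaussian and print the FWHM² trace — the
spread readout: it rises during stimulation and plateaus once the protein
fills the bouton.
"""

import numpy as np

import svspread as sv

params = sv.FusionGroundTruth(
    D=0.30,
    event_times=sv.default_event_times(stim_start=2.0),  # 40 APs at 20 Hz
    molecules_per_event=100,
    bouton_radius=1.15,
    background=100.0,
    noise_sd=2.0,
    frame_interval=0.4,  # 2.5 Hz imaging
    stim_start=2.0,
    stim_end=4.0,
    n_frames=30,
    seed=1,
)
seq, truth = sv.simulate_fusion_sequence(params)
dF = sv.compute_deltaF(seq)
roi = sv.detect_responding_synapses(dF)[0]
trace = sv.extract_fwhm_trace(dF, roi, margin_px=16)

print("time_s  fwhm2_um2")
for t, f2, ok in zip(trace.times, trace.fwhm2, trace.valid):
    print(f"{t:6.1f}  {f2:9.3f}" if ok else f"{t:6.1f}       (no fit)")

plateau = np.nanmean(trace.fwhm2[20:])
print(f"\nplateau FWHM^2 ~ {plateau:.2f} um^2")
print("The trace rises during the 2-4 s stimulus (free spread) and then")
print("plateaus: the protein is confined within the bouton membrane.")
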