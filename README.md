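# svspread

Quantitative analysis of the diffusional fate of **newly exocytosed
synaptic-vesicle (SV) proteins** in presynaptic boutons, from two kinds of
data:

* **pHluorin time-lapse imaging** of stimulated neurons — where newly
  exocytosed protein first spreads by free diffusion, is then confined within
  the ~2 µm² bouton membrane, and finally re-clusters slowly at the
  periactive zone; and
* **dual-channel single-molecule localization tables** (e.g. dSTORM) — where
  the sub-synaptic clustering of the newly exocytosed pool and its
  colocalization with endocytic proteins are read out with spatial
  statistics.

The package is aimed at imaging labs and modellers who want the full analysis
chain — photobleaching correction, ΔF extraction, Gaussian spread tracking,
diffusion-coefficient estimation and point-pattern statistics — as tested,
reusable Python, together with a forward simulator that generates every input
with known ground truth.

## The measurements

**Spread tracking.** Each background/bleach-corrected frame of a responding
synapse is fit with a rotated 2D Gaussian

    I(x,y) = I₀ + A·exp(−(a(x−x₀)² + 2b(x−x₀)(y−y₀) + c(y−y₀)²)),

and the squared full width at half maximum of the major axis,
FWHM = 2√(2 ln2)·σ, is tracked over time. FWHM²(t) rises during stimulation
(diffusional spread), plateaus (confinement) and decays (reclustering);
maximal spread, final FWHM² and the half-time t½ of the decay are read from
median-filtered traces, pooled hierarchically (synapses → neuron medians →
experiment medians → mean ± s.e.m.).

**Bleach correction.** Pre-stimulus pixel traces are fit with
I(t) = bg + a·e^(−t/τ); the bleach rate λ = 1/τ rescales the whole sequence
as I_bc(t) = bg + (I(t) − bg)·e^(λt), exactly inverting the decay.

**Diffusion coefficient.** Successive fusion events are modelled as Gaussian
intensity distributions added one per frame, each weighted by the measured
frame-to-frame ΔF increase and widening as σ²(t) = σ₀² + 2D·Δt under free
2D diffusion. The summed profile is re-fit with a single Gaussian and D is
the value whose model FWHM² slope matches the measured slope over a window
during stimulation (default 0.8–2.0 s). For orientation,
√(2·D·t) at D = 0.25 µm²/s gives 1 µm of r.m.s. displacement in one 2-s
stimulus — the scale that makes presynaptic confinement necessary.

**Point statistics.** Edge-corrected Ripley's
K(r) = (A/N²)·ΣᵢΣⱼ≠ᵢ 1(dᵢⱼ<r)/w(lᵢ,lⱼ) with the isotropic correction, its
normalization L(r)−r = √(K/π)−r (0 under complete spatial randomness),
pointwise CSR envelopes, cross-channel k-nearest-neighbour distributions with
a toroidal-shift null, radial intensity profiles, and diffraction-limited
rendering of localization tables. The K estimator agrees with R's
`spatial::Kfn` to machine precision and with an explicit double-sum oracle to
1e-9.

**Simulator.** `simcore` renders fusion–diffusion image sequences (Brownian
steps, reflecting bouton boundary, optional axon strip, reclustering drift,
per-pixel photobleaching, camera background/noise at 105-nm pixels) plus
clustered/CSR localization patterns — bit-reproducible from a single seed, so
every analysis stage is testable against ground truth.

## Worked example

```bash
python examples/02_estimate_diffusion_coefficient.py
```

prints (seed 4):

```
true D        : 0.300 um^2/s
estimated D   : 0.335 um^2/s
measured slope: 0.920 um^2/s over the 0.8-2.0 s window
rms 1D displacement in 2 s at this D: 1.16 um
```

i.e. the pipeline simulated a 40-event, 2-s stimulation at D = 0.30 µm²/s,
detected the responding synapse, tracked FWHM²(t), and recovered the
diffusion coefficient within ~12% by slope matching. The other scripts in
`examples/` walk through spread tracking and confinement
(`01_simulate_and_track_spread.py`, plateau ≈ 3.2 µm² for a 1.15-µm bouton on
a 5-µm field), bleach correction (`03`), reclustering half-time recovery
(`04`, 17.6 s measured for a configured 15 s), and cluster/colocalization
statistics (`05`, L(r)−r peaking near the 100-nm cluster scale and k=10-NN
mass far above the toroidal null for co-clustered channels).

A thin CLI mirrors the pipeline stages
(`svspread simulate|analyze|pointstats|report`); the Python API is the
primary interface.

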