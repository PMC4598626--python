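# Methods

This note documents the models, estimators and numerical choices behind
`svspread`, and what the synthetic-data tests do and do not establish about
real microscopy data.

## Forward simulation of fusion–diffusion dynamics

`simcore.simulate_fusion_sequence` integrates point molecules in 2D with a
fixed sub-frame step Δt = frame_interval/10 (ten Brownian sub-steps per
rendered frame keep the boundary-reflection error well below the rendering
resolution). Stages of one molecule's life:

* **Deposition.** Each fusion event places `molecules_per_event` molecules at
  the bouton centre (optionally scattered with sd `fusion_scatter`; single
  release sites are the default because single-active-zone boutons are the
  typical imaging target). The default event train is 40 events at 20 Hz
  starting at stimulus onset — one event per action potential of a standard
  2-s field stimulus.
* **Free diffusion.** Per-axis displacement variance 2·D·Δt. Default
  D = 0.30 µm²/s, the scale measured for newly exocytosed SV proteins and for
  mobile postsynaptic receptors.
* **Confinement.** Reflecting boundary at `bouton_radius` (radial mirror:
  r → 2R − r per sub-step). Default R = 1.15 µm, chosen so the equilibrium
  spread, 8 ln2·(R²/4 + σ_psf²) ≈ 2 µm² in moment terms, matches the
  confinement area of an average bouton. (The *fitted* plateau of the
  disk-shaped equilibrium is larger and depends on the fit patch — see
  "Shape effects" below.) An optional `AxonGeometry` opens a transmitting gap
  into a rectangular strip, reproducing partial axonal escape.
* **Reclustering.** After stimulus end, when `recluster_rate` k > 0, each
  molecule moves by the deterministic exponential map
  x → s + (x − s)·e^(−kΔt) toward its nearest recluster site, superposed with
  diffusion at `recluster_D` (default 0.004 µm²/s). The reduced mobility is
  deliberate: with the free D and the slow observed recluster rates, an
  Ornstein–Uhlenbeck process would have stationary variance D/k far larger
  than the bouton and no contraction would ever be visible; biophysically the
  captured protein is adaptor-associated and nearly immobile. Because
  positions contract as e^(−kt), the ensemble variance — and hence the
  FWHM² trace — contracts as e^(−2kt); `recluster_rate_for_halftime`
  therefore maps a desired trace half-time to k = ln2/(2·t½).
* **Rendering.** Frames sum unit-peak Gaussian PSFs (σ default 0.15 µm)
  evaluated analytically on the 105-nm pixel grid within ±4σ, are scaled by
  the bleaching factor e^(−t/τ), and receive constant background plus
  additive Gaussian camera noise (sCMOS regime; a Poisson option was judged
  unnecessary for a contrast-based analysis). An optional `resting_molecules`
  pool (uniform on the bouton disk at t = 0) emulates the residual
  un-eclipsed surface fluorescence that the bleach-correction stage needs.

All stochasticity flows from one `numpy` PCG64 generator seeded by `seed`;
identical parameters give bit-identical stacks and trajectories.

Localization patterns (`simulate_point_pattern`) are either CSR (uniform,
fixed-N or Poisson) or a parent–offspring cluster process: uniform parents,
Poisson-distributed offspring displaced by an isotropic Gaussian of sd
`cluster_sigma` (out-of-window offspring are redrawn, conserving counts).
Dual-channel tables share a configurable fraction of parents (offspring
counts shared, displacements independent), giving a colocalization dial from
independent (0) to fully co-clustered (1).

## Pre-processing

* **Bleach fit (per pixel, pre-stimulus only).** I(t) = bg + a·e^(−t/τ) is
  fit by variable projection: for fixed τ the (bg, a) pair is a linear
  least-squares solve, so only log τ is searched (coarse grid, then bounded
  Brent to xatol 1e-12). This reaches machine precision on noiseless decays,
  which the exact-inversion tests require. A pixel is flagged unusable
  (`fit_ok=False`, λ = 0, passed through uncorrected) when the amplitude — at
  the start *or at the end* of the baseline — does not clear a noise floor of
  3× the fit residual sd: a decay that vanishes inside the fit window leaves
  λ unconstrained, and e^(λt) would amplify noise without bound over the rest
  of the sequence.
* **Correction.** I_bc(t) = bg + (I(t) − bg)·e^(λt). This form exactly
  inverts the fitted decay and leaves the background stationary; anchoring
  the correction at the intensity at time zero instead would also invert a
  noiseless decay, but would rescale the background — the bg-anchored form is
  used throughout and is the one the exact-inversion tests pin down.
  Note that on a finite baseline (bg, a, τ) trade off strongly; per-pixel τ
  is a noisy quantity, but the correction only requires the fitted *curve* to
  match the decay over the sequence, which is much better conditioned.
* **ΔF.** Per-pixel subtraction of the median of the last five pre-stimulus
  frames (count configurable).
* **Responding synapses.** Otsu's threshold on the differential image (mean
  of the five frames after stimulus end minus mean of the five before onset),
  connected components above 0.3 µm². The threshold is accepted only when
  the foreground mean exceeds the background mean by 3 background sds, so a
  stack without a response yields zero ROIs instead of noise components.
* **Axonal escape.** Mean ΔF over a square region of 0.9 µm² placed 1.2 µm
  from the ROI centre along a stated direction (both defaults configurable);
  placement is automatic for reproducibility.

Coordinates are 0-based pixels, half-open boxes, physical units = pixel
centre × pixel size.

## Spread fitting and trace metrics

The rotated elliptical Gaussian with offset is fit per frame by bounded
`least_squares` (moment-based initialisation; σ bounds 0.25 pixel to twice
the patch extent; xtol/ftol 1e-14, which the < 1e-6 inversion tests need).
Axes are ordered σ_major ≥ σ_minor, θ normalised to [0, π) and set to 0 at
exact isotropy, where the angle is unidentifiable. A fit with amplitude
below 3× its residual r.m.s. is marked unconverged and the frame invalid.
The spread readout is the square of the major-axis FWHM, the interpretation
of "maximum FWHM²" that is monotone in spread.

Trace metrics use a 5-frame running median (`mode="nearest"` so the
endpoints stay unbiased — the final value is itself a metric). t½ is the
time after the filtered maximum at which the trace first falls to
(max + last)/2, linearly interpolated between frames, and is flagged
undefined when never crossed. It is measured from the maximum, not from
stimulus onset, because it characterises the decay (reclustering) phase.

Hierarchical pooling takes medians over synapses within neuron, then over
neurons within experiment, then mean ± s.e.m. across experiments, so unequal
synapse counts cannot weight one neuron or experiment over another.

## Diffusion model and D estimation

At frame m the model profile is the increment-weighted, mass-normalised sum
of isotropic Gaussians, component n carrying variance
σ_n² = σ₀² + 2·D·(t_m − t_n + f/2). Two defaults matter and are both
configurable:

* **Half-frame age offset.** The vesicles behind frame n's intensity
  increase fused throughout that frame, not at its timestamp; omitting the
  f/2 term (set `age_offset=0`) creates an artificial zero-age component
  whose narrow spike dominates the profile fit.
* **Area-weighted profile fit.** The single-Gaussian re-fit of the summed
  profile samples r uniformly (200 points to 3× the widest σ) but weights
  each sample by r — the continuum limit of fitting the 2D image over a
  disk, which is what the measurement pipeline does pixel-by-pixel. A
  uniform-weight 1D radial fit (`weighting="uniform"`) is available but is
  dominated by the narrow fresh components and systematically mismatches the
  image-level measurement (it underestimates recovered D several-fold).

The profile is normalised to unit peak before fitting, which makes the
fitted width exactly invariant under scaling all increments. D is found by
bounded 1D minimisation (default bracket 0.01–2.0 µm²/s, tolerance 1e-4) of
the squared difference between the OLS slopes of measured and modelled FWHM²
over the fit window (default 0.8–2.0 s after onset, inside the stimulation
period). Negative frame-to-frame increments are clipped to zero — they are
noise, and the weights represent non-negative release. A non-positive
measured slope yields a flagged, NaN estimate.

## Point statistics

Ripley's K uses the A/N² normalisation (matching the R `splancs`/`spatial`
estimators) and the isotropic edge correction: w is the fraction of the
circle of radius d_ij centred on point i inside the rectangular window,
computed in closed form from the blocked arcs of the nearest vertical and
horizontal edges minus their corner overlap — exact for r up to half the
shorter window side, beyond which radii are truncated with a warning.
L(r) − r = √(K/π) − r is the normalisation under which CSR gives 0 in
expectation (the A/N² estimator carries a small O(1/N) negative bias, ≈
−0.25 nm at r = 100 nm with N = 200, well inside the Monte-Carlo error of
the null tests). Envelopes are pointwise maxima over n_sim CSR simulations
(default 10, so a CSR pattern falls below the envelope with probability
≈ 10/11 per radius).

k-NN colocalization queries each point of one channel against the k-th
nearest point of the other (k = 10 by default, so isolated noise
localizations cannot score short distances; 10-nm histogram bins). The
null is the same query against the reference channel toroidally shifted by
half the window width along x, which preserves each channel's internal
clustering while destroying cross-channel alignment. Identical points in
query and reference are *not* excluded — self-coincidence (distance 0 at
k = 1 for identical channels) is the intended degenerate behaviour.

Radial profiles bin per-channel pixel intensities by distance to the nearest
reference-channel maximum (3×3-neighbourhood maxima above a relative
threshold, or caller-supplied coordinates); empty bins are omitted, not
reported as zero. Diffraction-limited rendering bins localizations at the
105-nm camera pixel and blurs with σ_render = √(σ_widefield² − σ_loc²),
where σ_widefield comes from the Abbe wide-field FWHM λ/(2·NA); the blur
kernel is normalised and truncated at 6σ with a matching margin, so total
intensity equals the localization count to float precision.

## Shape effects and what the tests show

The Gaussian-fit FWHM² equals 8 ln2 × the underlying position variance
(plus PSF) only while the intensity distribution stays in the Gaussian shape
family. Two documented departures:

* **Confined plateau.** The equilibrium distribution on a reflecting disk is
  a top-hat; its best-fit Gaussian width exceeds the moment width and grows
  with the fit patch. The plateau test therefore compares the simulated
  plateau against a Gaussian fit of the *analytically computed* equilibrium
  image on the same grid (agreement within 5%), not against the moment
  formula.
* **Reclustering half-time.** The half-time recovery benchmark uses a
  single-burst release so the cloud is Gaussian throughout and the
  configured t½ is an exact property of the trace. When the decay starts
  from a top-hat (confined) or multi-age mixture, the shape relaxation adds
  its own apparent decay or lag (of order ±20–50% of t½ in the regimes
  explored); measured half-times on such traces characterise the trace, not
  the drift rate alone.

Problem sizes in the tests and acceptance script (48–64-pixel fields, 50–100
molecules per event, 8–20 replicate seeds, 100 CSR patterns of 200 points)
were chosen as the smallest sets at which the Monte-Carlo standard errors are
comfortably inside the stated tolerances.

The simulator emulates what the analysis assumes — Brownian motion, a hard
reflecting boundary, Gaussian PSF, additive Gaussian noise, exponential
bleaching, single release sites. It does not emulate anomalous diffusion,
vesicle docking/priming kinetics, calcium dynamics, membrane curvature, 3D
effects, sCMOS fixed-pattern noise, or localization-precision heterogeneity;
passing tests therefore validate the estimators under the stated model, and
say nothing about departures from it in real preparations.

## Known limitations

* The D estimator assumes free diffusion over the fit window; confinement
  that sets in earlier biases it downward (use a window inside the free
  phase, or an unbounded control simulation).
* Recovered D carries a small positive bias (≈ +15% at the default study
  conditions) from finite-sampling lumpiness of the rendered mixtures and
  the domain dependence of Gaussian fits to non-Gaussian profiles.
* Per-pixel bleach lifetimes are ill-conditioned on short baselines (the
  correction is not); pool or weight by amplitude before interpreting τ maps.
* Ripley statistics assume a rectangular window; irregular synaptic ROIs
  would need a polygonal edge correction that is not implemented.
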