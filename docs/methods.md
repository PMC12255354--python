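# Methods

## Overview

`clusterecho` detects echoes of clustered microbubble contrast agents in
beamformed ultrasound RF data by one-class learning: an LSTM autoencoder is
trained to reconstruct the 160-sample RF segments of *individual* microbubble
events, and any test segment whose mean squared reconstruction error exceeds
a threshold set just above the worst training error is declared an anomaly.
Because the data this method targets are not publicly available, the package
ships a synthetic flow-phantom simulator that generates labelled frame stacks
with the relevant acoustic contrasts, and every end-to-end result in the test
suite is computed on that simulator.

## Synthetic data model

A frame is a 2-D grid of RF amplitudes over `n_elements × n_samples`
(defaults 64 × 512) at sampling rate `fs = 4 f0` (defaults
`f0 = 2.8 MHz`, `fs = 11.2 MHz`; 4× sampling keeps the second harmonic below
Nyquist). Each frame is the sum of three components:

* **Static wall clutter.** Two Gaussian-windowed reflection bands (width 8
  samples, offset 12 samples) bracketing the 160-sample lumen window,
  modulated at `f0` along depth, with a smooth deterministic per-element gain
  taper. The clutter is a pure function of the configuration — identical in
  every frame — so coherent mean-frame subtraction removes it exactly.
* **At most one bubble event** per frame (Bernoulli with `event_prob = 0.3`;
  the low-dilution protocol this emulates was designed to isolate single
  agent events). The event is a cluster with probability `cluster_frac`
  (default 0.25, the cluster yield of the crosslinked sample; 0 in control
  runs). Its waveform is a Gaussian-windowed burst
  `amp · g(t) · [sin(2π f0 τ) + h2 sin(2π 2f0 τ) + s sin(2π (f0/2) τ)]`
  with envelope width `pulse_sigma = 0.7 µs` (about two cycles at 2.8 MHz,
  typical of a resonant bubble echo). Individual events use
  `s = sub_ratio_ind = 0.05`; clusters use `s = sub_ratio_clu = 0.4` and are
  scaled by `cluster_gain = 3`, encoding the elevated amplitude and
  subharmonic content that distinguish cluster acoustics. Peak amplitude is
  log-normal: `amp = amp_mean · exp(amp_sd · N(0,1))` with `amp_mean = 1`
  (median) and `amp_sd = 0.15` (log-scale sd), a modest size dispersion for
  a sorted agent population. The event lands on a random element within the
  lateral tunnel span (default 3 elements at the array centre) at a uniform
  depth inside the lumen, and spreads to neighbouring elements with a
  Gaussian lateral profile of `lateral_sigma = 1.75` elements — a beam a few
  elements wide, as expected for a 2.8 MHz phased array; a much narrower
  value would make the centre-element RF extraction blind to off-centre
  events in a way the physical acquisition is not.
* **White Gaussian noise**, `noise_sd = 0.02 · amp_mean`.

One seeded generator drives a run; a `(specs, seed)` pair reproduces every
sample bitwise.

What the simulator does **not** model: bubble dynamics (no Rayleigh–Plesset
oscillation, no resonance-size dependence), beamforming from channel data,
flow between frames, multiple simultaneous events, coalescence mechanics,
depth-dependent attenuation, and speckle from diffuse tissue scatterers.
Passing tests therefore demonstrate that the pipeline isolates events whose
amplitude and band energy are elevated in the configured way — not that it
would meet the same sensitivity on hardware data, where event morphology and
clutter are richer.

## Preprocessing

1. **Background subtraction** is applied coherently to the RF frames (the
   stack mean is subtracted from each frame) before envelope formation.
   Coherent subtraction cancels a strictly static clutter component exactly;
   subtracting envelope images instead would leave a speckle-dependent
   residual. Each tunnel/stack gets its own mean frame.
2. **Envelope images** are the magnitude of the analytic signal along depth
   (Hilbert transform), without log compression — log display compression
   would add a dynamic-range parameter with no counterpart in the detection
   chain.
3. **ROI cropping** uses half-open, 0-based element and depth spans; the
   depth span is exactly 160 samples so the final extraction needs no further
   windowing. The ROI centre element is the midpoint of the element span,
   ties broken low.
4. **Thresholding and frame selection.** Pixels at or below `level` are
   zeroed; a frame is retained iff at least `min_pixels = 3` pixels survive.
   `level` defaults to `8 × 1.4826 × MAD` of the pooled subtracted-envelope
   pixels in the ROI. The envelope of Gaussian RF noise is Rayleigh
   distributed, for which `1.4826 × MAD ≈ 0.66 σ`; the multiplier 8 places
   the threshold near `5.3 σ`, where an empty 3 × 160 ROI essentially never
   yields three suprathreshold pixels while a bubble echo (tens of σ) always
   does. A multiplier of 4 (≈ `2.7 σ`) would retain roughly a third of empty
   frames and was rejected for violating the selection-soundness requirement
   that empty frames be retained at under 1 %.
5. **Extraction.** The 160 depth samples at the ROI centre element of the
   background-subtracted RF frame become one `RFVector`. Training vectors
   come from the individual-agent stack only; test vectors from the sample
   stack, with simulator truth labels carried through. Test frame indices
   are offset by the training-stack length so the two splits never share an
   index.

## Anomaly detector

Vectors are scaled to [0, 1] by a *global* min–max transform fitted on the
training set only (a single `(lo, hi)` pair for all 160 positions, preserving
waveform shape); test values outside the training range are clipped. The
autoencoder is three LSTM layers of widths 32/16/8, the last hidden state
repeated along time as the bottleneck code, three mirrored decoder layers
(8/16/32), and a time-distributed one-unit sigmoid readout, trained with
mini-batch Adam (learning rate 3e-3, batch 256, 20 epochs, MSE loss) in
float32 with a single seeded generator; fixed seeds reproduce training
bitwise on one machine (single-threaded BLAS recommended for cross-machine
reproducibility). The widths and schedule were sized for single-CPU training
of ~2,000 vectors in about a minute.

The anomaly threshold is `margin × max(training errors)` with
`margin = 1.05`, and the anomaly decision uses a strict inequality, so an
error exactly at the threshold is not an anomaly. A multiplicative margin
(rather than an additive one) keeps the rule scale-free in the normalized
error units.

### What the autoencoder actually learns

On phase-random oscillatory RF bursts, the reconstruction converges to the
conditional mean of the training data — a near-constant trace at the scaled
baseline — rather than a faithful copy of each burst. This was verified
directly: training loss plateaus at the variance of the data around its mean
within a few epochs, gradient checking (float64 finite differences) confirms
the backpropagation is exact, and heavily over-training a small subset does
not escape this solution; a sequence-preserving bottleneck variant behaves
the same way. The reconstruction error therefore acts as a (model-mediated)
measure of how far a vector deviates from the learned baseline — in effect an
energy-novelty statistic. That is sufficient for the task: cluster echoes
carry roughly `cluster_gain²` times the energy of individual echoes (and are
clipped by the normalization when they exceed the training amplitude range),
so their errors sit far above the training maximum, while test vectors from
the training distribution essentially never cross `1.05 ×` the maximum of
~2,000 training errors. The method's own headline numbers on real data —
training errors of order 1e-1 on [0, 1]-scaled signals — are consistent with
this regime.

## Spectral comparison

Spectra are one-sided DFT magnitudes of the *unnormalized* 160-sample RF
vectors (bins `k · fs/160`, k = 0…80), with no apodization window — the
segment is analyzed exactly as extracted. Band amplitudes are the mean
magnitude over bins within `±0.15 f0` of the band centre (`f0` for the
fundamental, `f0/2` for the subharmonic); the statistic is configurable
(`mean` or `max`) and defaults to mean. Group comparisons report per-group
mean band amplitudes, the bin-wise mean spectrum with its trapezoidal area
under the curve, and the OLS fit of subharmonic on fundamental amplitude per
group; the anomaly group's slope is compared against every other group. For
a constant-`y` degenerate fit the r² is reported as 1 (the horizontal line
is exact); fits require at least two distinct `x` values.

## Pipeline, seeds, determinism

A run is configured by one `RunConfig` (YAML-loadable). `mode="control"`
forces `cluster_frac = 0` in both stacks; `mode="experiment"` uses the
configured cluster fraction in the sample stack only. The top-level seed
derives per-stage seeds by stage-name hashing (CRC32), so stages can be
re-run in isolation and two runs with identical config and seed produce
identical reports and results files. Default stack sizes are 6,700 training
and 1,700 testing frames, retaining roughly 2,000 and 500 vectors at the
default event probability — a scale chosen so a full run (simulation through
spectral comparison) completes in about 1–2 minutes on one CPU. The pipeline
persists the vector datasets (HDF5), truth/retention/results/spectra tables
(CSV) and the report (JSON); raw frame stacks (~1 GB at defaults) are written
only on request (`save_frames=True`) or via the `simulate` CLI stage, and the
report can be regenerated from the persisted intermediates alone.

## Degenerate inputs and numerical choices

* Empty frame stacks, empty retained sets, empty training sets, and empty
  spectral groups raise explicit errors rather than producing empty outputs.
* Global min–max normalization refuses degenerate (constant) training data.
* The detector validates vector length (exactly 160) everywhere.
* Envelope, MSE, DFT, band means, trapezoidal areas and OLS fits are each
  tested against independent brute-force oracles (scalar loops, direct DFT
  sums, normal equations) at tolerances of 1e-9 relative or better.
* Training runs in float32 for speed; reported errors are accumulated in
  float64.

## Known limitations

* The autoencoder's constant-reconstruction regime (above) means detection
  rests on amplitude/energy novelty, not on waveform-shape novelty; a cluster
  echo with individual-like energy would be missed.
* The simulator's event model is phenomenological; its parameters set the
  difficulty of the task, and the reported sensitivity/specificity are
  properties of those settings.
* Thresholding operates on the linear envelope with a single global level per
  stack; depth-dependent gain is not modelled or compensated.
* Bit-level determinism is guaranteed within one machine/BLAS configuration;
  across BLAS builds, floating-point reduction order may differ.
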