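# Methods

This note documents the models behind `eegfmri`: what the synthetic data
generator emulates, how each correction and evaluation stage is defined, the
parameters that matter and their defaults, the numerically delicate choices,
and the known limitations.

## 1. The synthetic session model

The generator produces EEG and fMRI data with the statistical structure that
the downstream analyses assume, with exact bookkeeping: every artifact array
added to the data is stored, and `clean + Σ components` reproduces the
contaminated data bit for bit (components are accumulated with a single
in-place addition each, in a fixed order, so floating-point associativity
cannot break the identity).

### Clean EEG

* **1/f background** — per-channel noise with 1/√f amplitude shaping
  (flattened below 0.5 Hz), default 8 µV RMS per channel.
* **Occipital alpha** — a narrowband (8.5–11.5 Hz) noise carrier (a pure
  tone would be both unrealistic and spectrally indistinguishable from a
  narrowband interference peak) with a slow random envelope, weighted by a
  smooth occipital topography; default 6 µV.  During eyes-closed blocks of
  the paradigm (5 blocks of 32 s open + 32 s closed) the amplitude doubles.
* **Microstates** — a 4-state Markov sequence (geometric dwell, default mean
  80 ms) of four smooth, mutually orthogonal, average-referenced
  topographies (built analytically from the montage coordinates by
  Gram–Schmidt over the diagonal, anterior–posterior and vertex seed
  patterns; these also serve as the canonical A–D templates and are
  synthetic idealized stand-ins for the normative maps of the literature),
  driven by a broadband 1–30 Hz source, default 7 µV.

The electrode montage is generated analytically: a golden-angle spiral over
the upper spherical cap, giving 10-20-like coverage for any channel count
without external montage files.

### Artifacts

* **Gradient artifact (GA)** — a fixed multi-lobed waveform (constant lobe
  table: one broad lobe that keeps the fundamental dominant plus narrow
  lobes that extend the harmonics to the kHz range) repeated every
  TR/excitations seconds, plus a distinct three-lobe pattern at each volume
  boundary.  Per-channel gains are drawn once.  The artifact is exactly
  periodic — deliberately, so AAS residuals measure the implementation, not
  artifact drift.  Phases are evaluated at a quarter-sample offset so no
  sample sits on the floating-point modulo boundary.  Default amplitude
  5000 µV (≈3 orders of magnitude above the neural background).  The
  spectral contract — fundamental at excitations/TR, volume component at
  1/TR — is what the acceptance script measures (20 and 12.5 Hz slice
  fundamentals, 0.95 and 0.28 Hz volume fundamentals for the two protocol
  geometries).
* **Pulse artifact (PA)** — beat-locked templates at R-peak times
  (60/HR ± Gaussian jitter), with `pa_n_shape_clusters` distinct shapes
  (perturbed lobe tables), zero-mean over the beat window (AC-coupled
  recording), applied through a smooth channel-loading pattern; default
  150 µV.  A synthetic ECG channel with sharp R-peaks is appended.
* **Motion artifact (MA)** — a small set of <8 Hz processes mixed into the
  scalp through a static or slowly time-varying mixing (sinusoidal gain
  modulation, configurable period).  The appended reference-sensor channels
  carry well-conditioned mixtures of the same processes, plus sensor noise
  and a scaled copy of the mean scalp PA.  The number of independent motion
  processes defaults to `n_sensors − 1`: with as many independent processes
  as sensors *plus* a PA copy, the artifact subspace would exceed the sensor
  span and no regression could remove the PA — physically this encodes the
  assumption that a few rigid-body motion modes dominate.
* **Environment artifact (EA)** — pure sinusoids (default 33 and 47 Hz,
  3 µV) with random per-channel amplitude and phase, on every channel.

### Synthetic fMRI

A small box-parcellated grid (default 24×24×14): three network ROIs with
shared band-limited (0.01–0.08 Hz) latent timecourses, white voxel noise, a
common drift course with per-voxel gains, six motion-coupled nuisance
courses, and a visual ROI that adds −β times the HRF-convolved, standardized
alpha-power envelope (negative alpha–BOLD coupling).  The background is
Rician magnitude noise — |N(0,σ) + iN(0,σ)| — of known σ.  A single-frame
quality volume with piecewise-constant ROI means and Gaussian within-ROI
spread supports the quality metrics.

## 2. The correction cascade

Stage order is enforced (a stage applied after a later one raises unless
forced): triggers → AAS → OBS → R-peaks → k-means PA → downsample →
reference regression → bandpass → interpolation → average reference → ICA.

Per-stage definitions and the design choices that were genuinely open:

* **Trigger estimation** — triggers are fitted to `t_k = a + b·k` by
  iterated least squares; jittered triggers snap to the grid, missing ones
  are inserted; >10 % missing without a supplied period is an error.
* **AAS** — volume-level epochs by default (volume triggers are what the
  recording provides); sliding template of the `window_k` nearest epochs
  (default 25, self excluded), slice-level optional.  `window_k=None` uses
  all epochs — the optimal template for a drift-free artifact, and the
  setting the pipeline uses on synthetic sessions.  `template_rank`
  optionally projects each template onto its top spatial components before
  subtraction: the GA is driven by a handful of gradient axes and is
  spatially low-rank, so the projection strips the background noise frozen
  into the average without touching the artifact (the pipeline uses rank 6).
  Two subtleties worth knowing: a short sliding window behaves as a comb
  filter whose sidelobes modulate in-band oscillations by several percent,
  and the non-GA content frozen into the template is re-injected into every
  epoch at `content/√window_k` — both vanish with the all-epoch template.
* **OBS** — per channel, PCA of the mean-removed epoch matrix; the top
  `n_basis` (default 4) components fitted and subtracted per epoch.  With
  `artifact_gate=True` (pipeline default) only basis components that look
  like GA residuals — spectra concentrated on the slice-frequency harmonic
  comb, or sharply lobe-concentrated waveforms — are subtracted.  The gate
  exists because ungated PCA of post-AAS epochs is dominated by whatever is
  largest (usually the pulse artifact): measured on the synthetic session it
  removed 64 % of the PA and 10 % of the neural signal, incoherently across
  channels, which destroys the spatial structure the later reference
  regression relies on.
* **R-peak detection** — 5–30 Hz bandpass, squared derivative, 150 ms
  integration, adaptive threshold at a quantile of the detection function,
  300 ms refractory, refinement to the ECG extremum.
* **k-means PA** — epochs in a (−0.25, +0.75) s window around R-peaks,
  per-channel baseline removal; clustering (default k = 5) and amplitude
  fitting both use >8 Hz content so slow drifts neither drive the beat-shape
  assignment nor bias the scale; the scale is fitted jointly across channels
  (beat-strength variation is global, and a common scale keeps the
  subtraction spatially coherent) with empirical-Bayes shrinkage toward the
  cluster mean (fit noise estimated by split-half); templates are reduced to
  rank 3 across channels and weighted by their split-half reliability, so a
  "template" estimated from noise alone subtracts nothing.  Scalp *and*
  reference channels are corrected — the sensors carry the
  ballistocardiogram too, and leaving it in the regressors would re-inject
  it later.  `k = 1` reduces to plain beat-averaged subtraction.
* **Downsampling** — zero-phase low-pass at 0.4 × target rate, then
  decimation (polyphase for non-integer ratios); events re-indexed.
* **Adaptive reference regression** — overlapping 10 s Hann-weighted
  windows, ridge least squares of each scalp channel on the reference
  channels plus ramp-modulated copies (`drift_order`, pipeline default 2)
  that track within-window changes of the mixing; the raw-reference fit is
  subtracted so the artifact's in-window mean goes too.  Narrowband peaks
  are detected on the reference channels and projected out of the
  *regressors* before fitting (coherent sinusoids in the regressors bias the
  motion fit; the scalp EA itself is left for the ICA stage).
* **Bandpass** — order-4 zero-phase Butterworth, 0.75–70 Hz.  Note the
  honest response: an order-4 zero-phase filter attenuates 100 Hz by ~25 dB;
  order 8 is available where ≥40 dB stopband is wanted.
* **Interpolation** — spherical splines (order m = 4, regularization 1e-5,
  50 Legendre terms); refuses if more than 20 % of scalp channels are bad.
* **ICA** — PCA to `n_scalp − 1` components (average-reference rank
  deficit), extended Infomax unmixing estimated on an even subsample of at
  most 6000 samples (the algorithm's cost grows steeply with sample count;
  sources are computed in full), criteria: GA-residual = harmonic-comb power
  ratio at slice-frequency multiples > 0.5; EA = single-bin concentration
  against the ±2 Hz neighborhood > 0.8; PA-residual = R-peak-locked epoch
  consistency > 0.5; eye = frontal loading > 0.4 and sub-4 Hz fraction
  > 0.55; muscle = >20 Hz fraction > 0.7 and edge loading > 0.6.  Flags are
  mutually exclusive (GA > EA > PA > eye > muscle).  Flagged components are
  zeroed **except** EA components: those identify the interference
  frequencies (refined to sub-bin precision by quadratic interpolation on
  the full-length periodogram), and the exact sine/cosine pair at each
  frequency is projected out of every scalp channel — 2 degrees of freedom
  per frequency over the whole recording, which removes the coherent peak
  without the neural content riding the same component.  All criterion
  scores are reported for audit.

## 3. Evaluation metrics

EEG spectra use Welch's method (10 s Hann, 50 % overlap) reported as
amplitude: `sqrt(2·P)` with spectrum scaling, which returns a sinusoid's
amplitude at its peak bin.  Band magnitudes are means over fixed edges
(lower inclusive, upper exclusive).  Microstate fitting normalizes each
recording by its mean GFP, clusters the maps at GFP peaks (minimum 10 ms
separation) with polarity-invariant modified k-means (distance
1 − squared spatial correlation; centroids are dominant eigenvectors), best
of 20 seeded restarts by global explained variance; canonical labeling is
exhaustive over the 4! assignments by total absolute spatial correlation;
back-fitting is per-sample argmax |correlation| with no temporal smoothing —
which means measured durations shorten wherever noise wins at source zero
crossings, so dwell-time recovery is validated where the topographic signal
dominates.  The alpha block score is (mean closed − mean open)/pooled SD of
the squared-bandpass (7–13 Hz) envelope smoothed over 2 s.

MRI: FWHM = 2√(2 ln 2)·SD of the ROI values; the background σ estimator
slides a 5³ window over the background, accepts windows whose mean/RMS ratio
is within ±0.1 of the Rayleigh value √(π/4), and takes the modal histogram
bin of local RMS/√2 (median fallback for few windows; global RMS/√2 with a
warning when nothing passes).  Spatial SNR is frame-wise ROI mean over σ,
time-averaged; temporal SNR excludes zero-variance voxels and reports their
count.

fMRI: fALFF uses the plain FFT amplitude of demeaned voxel timecourses; when
the Nyquist frequency is below the 0.25 Hz denominator bound (the TR 3.52 s
protocol) the bound becomes Nyquist, with a warning.  INC includes the voxel
in the ROI mean, matching its definition.  Connectivity regresses cosine
drift, motion + derivatives and the mean of each available tissue ROI from
the ROI timecourses before the 0.009–0.08 Hz bandpass (linear operations
commute with spatial averaging, so this equals voxelwise confound removal).
The GLM's single-gamma HRF is parameterized by peak 5.4 s and FWHM 5.2 s
(shape/scale solved numerically); sticks are convolved on a 0.1 s grid; the
alpha column is the HRF-convolved TR-averaged power, residualized against
the four stick columns and demeaned; t→Z uses tail-accurate CDF mapping.
Surrogates randomize the raw alpha column's spectral phases (conjugate
symmetric, DC and Nyquist real), re-orthogonalize and refit; the magnitude
spectrum is asserted equal per trial, which also fixes the surrogate's
autocorrelation function.

## 4. Problem sizes and what the tests show

The test suite and examples run at a reduced scale chosen as this package's
validation conditions: 1 kHz EEG sampling (5 kHz in a real session), 24
scalp channels (vs 63), a 360-volume TR 1.05 s protocol, and a 24×24×14
fMRI grid at 300 volumes.  At this scale the complete cascade recovers the
clean EEG with median channel correlation ≈0.95 (seed 0; 0.92–0.95 across
seeds 0–3, one weaker seed at 0.87 driven by an unfavorable draw of motion
mixing and pulse loadings), and the planted eyes-closed alpha doubling is
detected with block contrast >1.

What passing does *not* show about real data: the synthetic GA neither
drifts nor jitters (real AAS windows trade template noise against drift
tracking, and the all-epoch template used here would be wrong there); the PA
is exactly spatially rank-1 with stable shapes; the motion mixing varies
smoothly; environment peaks are stationary single frequencies (real coldhead
interference wanders); the clean EEG model has no eye or muscle activity by
default, so those ICA criteria are exercised on dedicated planted sources;
and the fMRI model has white thermal noise rather than physiological noise
structure.

## 5. Known limitations

* The automatic ICA criteria replace the visual component review a human
  would do; thresholds are configurable and all scores are reported, but on
  real data they would need tuning against inspection.
* Epochs at the R-peak window length overlap when the heart rate exceeds
  1/window; overlapping subtraction is approximately, not exactly, additive.
* The volume-level AAS default (`window_k=25`) follows common practice for
  drifting artifacts; on the drift-free synthetic artifact it is strictly
  dominated by the all-epoch template, which the pipeline therefore uses.
* No k-space/MR physics, no head-model forward solutions, no respiratory
  noise model; image registration, segmentation and motion correction are
  out of scope (motion parameters and parcellations are inputs).
* The pipeline report is JSON only.
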