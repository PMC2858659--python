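# Methods

This note documents the models, parameter choices and numerical details of
the `wmfusion` pipeline, in the order data flows through it.

## Paradigm and schedule generator

One session is 554 usable scans at TR 1.815 s (≈1006 s). Each of 80 trials
(40 per set size, ss2/ss5, randomly interleaved) is a 2.5 s stimulus, a
3.5 s retention period and a 2 s probe, separated by a jittered
inter-stimulus interval; six 24.5 s baseline blocks occupy evenly spaced
slots among the trials. The ISI must lie in [1800, 2500] ms with mean
2000 ms. No distribution with both properties is uniform, and no
triangular distribution on that support can have that mean (its mode would
fall below the lower bound), so the generator draws a Beta(2, b) variate
scaled onto the range, with b solved so the mean is exact — Beta(2, 5) for
the defaults, giving mean 1800 + 700·(2/7) = 2000 ms exactly. Trial order
and baseline placement are not constrained by the paradigm description;
randomized interleaving and even spacing are the package's choices.

## Trial band power and load effects

Ground-truth retention-window band power for trial *i* and band *b* is

  p_ib = m_b · (1 + δ_b·[load_i = ss5]) · L_ib,

with L lognormal, E[L] = 1, CV = 0.3 for every band. Default mean powers
m_b (µV²/Hz): theta 2.0, alpha1 3.0, alpha2 2.5, beta1 1.0, beta2 0.5,
gamma 0.2 — a typical 1/f-shaped resting spectrum sampled at the band
centres. Default load effects δ_b: theta +0.30, alpha1 −0.20, alpha2 0,
beta1 +0.10, beta2 +0.10, gamma +0.15. The signs follow the observed
load-effect pattern (theta positive, alpha1 negative, upper bands mostly
positive); alpha2 is set to zero because the contrast-estimate load
analysis shows no alpha2 effect even though scalp power does change —
one δ per band drives both phenomena in the simulator, and the ROI-level
pattern is the one the recovery harness scores.

## EEG synthesis and measurement

Each band contributes a random-phase sinusoid at its centre frequency
during every retention period, weighted across 62 channels by a band
topography (frontal peak for theta, parieto-occipital for alpha/beta1,
frontal for beta2/gamma). Topography vectors are normalized so that
mean(w⁴) = 1, which makes the RMS-over-channels of per-channel band power
equal the scalar trial target. Amplitudes are calibrated *through the
package's own spectral chain*: the 6×6 cross-band leakage matrix of the
unit-amplitude oscillations is solved, then refined by four fixed-point
iterations against the superposed multi-channel window, so the measured
RMS band power of the analysis window matches the ground-truth table to
~1e-6 relative in the noise-free case. 1/f-power background noise
(exponent 1.0, default 2 µV RMS) is added per channel. Synthesis is at
256 Hz (the post-downsample analysis rate); raw-rate synthesis is only
needed when exercising template subtraction, for which explicit artifact
event times are provided.

What the generator does *not* emulate: ocular/muscle artifacts and their
ICA cleanup, head motion, volume conduction from realistic sources,
non-sinusoidal band structure, and between-subject topography variability.
Passing tests therefore demonstrate correctness of the analysis chain
under the stated generative model, not robustness to every property of
real in-scanner EEG.

## EEG conditioning

Template (average-artifact) subtraction estimates the per-channel mean
waveform over *all* epochs at the given event times and subtracts it from
each occurrence — the simplest reproducible variant; a sliding-window
template is deliberately not the default. The bandpass is a 4th-order
Butterworth (24 dB/octave design slope) applied forward–backward
(zero phase; effective roll-off twice the design slope), followed by
polyphase resampling to 256 Hz. Segments are half-open sample windows
[floor(start·fs), start+window); the ±150 µV rejection uses strict
inequality ("exceeding") and only flips flags, never values. Rejected
trials keep a placeholder row (per-load mean of retained trials) so the
GLM modulators stay aligned with the schedule while contributing nothing
after mean-centring.

## Spectral estimation

"10 % Hanning" is implemented as a Tukey taper: cosine ramps over the
first and last 10 % of the 640-sample window (total taper fraction 0.2);
a full Hann window is available via `taper_fraction=0.5`. The tapered
segment is zero-padded to 1024 points (0.25 Hz grid) and converted to
one-sided power density normalized by fs·Σw², so that without taper and
padding the density integrates to the mean squared amplitude (Parseval,
verified to 1e-9). Band power averages the bins with lo ≤ f ≤ hi, edges
inclusive on both sides — the 10.0 Hz bin belongs to both alpha1 and
alpha2, exactly as the band list is printed; disjointness was deliberately
not enforced.

## Fusion GLM

* **HRF**: canonical double-gamma (peak delay 6 s, undershoot delay 16 s,
  dispersions 1, ratio 6, length 32 s), scaled to peak 1; no derivatives.
* **Design**: regressors built at 16 microtime bins per TR with continuous
  onsets, convolved at microtime resolution, sampled at the middle bin of
  each scan. Per load: encoding/retention/retrieval boxcars plus six
  retention modulators weighted by mean-centred per-trial RMS band power —
  mean-centred per band per load and *not* serially orthogonalized
  (order-independence; serial orthogonalization is a flag). A constant
  modulator is dropped with a warning. Drift: orthonormal DCT basis with
  periods ≥ 128 s (15 columns at the default length) plus an intercept.
  Identifiability note: six centred modulators per load require at least
  seven trials of that load.
* **AR(1)**: one global ρ̂ pooled over in-mask voxels, as in packages that
  use a global approximate autocorrelation model, rather than voxelwise.
  The raw pooled lag-1 autocorrelation of OLS residuals is attenuated by
  the residual-forming projection (for the default design, true ρ = 0.4
  yields ≈0.31 raw); the estimate is therefore debiased by moment
  matching — the expected raw value under AR(1) noise is a ratio of two
  polynomials in ρ whose coefficients are diagonal sums of projected
  operators, and the moment equation is inverted by bisection. Whitening
  uses the exact AR(1) inverse square root (first row scaled by
  √(1−ρ²), then first differences with weight ρ).
* **Inference**: t = c'β̂ / √(σ̂² c'(X'X)⁻¹c) on the whitened design with
  df = scans − rank(X); zero-variance voxels get signed-infinity
  sentinels rather than NaNs. Group maps are voxelwise one-sample t
  across subjects (df = n−1). FWE is Bonferroni (exact and
  distribution-free under independence; random-field theory is out of
  scope), FDR is Benjamini–Hochberg step-up, and cluster extent comes
  from a Monte-Carlo simulation of smoothed Gaussian noise.

## Cluster-extent Monte Carlo

Per iteration: a Gaussian white-noise volume (generated with a
stationarity pad of 4σ that is cropped after smoothing), smoothed with a
Gaussian kernel of the stated FWHM, standardized to unit variance,
thresholded one-tailed at the voxel-p quantile; clusters are
18-connected, and the returned k is the smallest extent whose
max-cluster exceedance frequency across iterations falls below the
cluster-level alpha (i.e. family-wise control). The implementation was
checked two ways: with FWHM 0 it matches a brute-force Bernoulli
enumeration oracle, and with smoothing its supra-threshold fraction and
cluster counts agree with random-field-theory expectations.

A caveat worth stating plainly: for the full acquisition geometry
(73×73×42 at 3 mm, 9 mm FWHM, p<0.001, alpha 0.01, 1000 iterations) this
family-wise procedure yields k ≈ 50. Legacy cluster-simulation scripts in
wide use at the time the field adopted these thresholds often applied
truncated smoothing kernels and/or per-cluster (rather than max-cluster)
probability criteria, both of which produce substantially smaller k
(in-package experiments: truncated 3³ kernels give k≈9–20, a per-cluster
survival criterion gives k≈23, acquisition-grid simulation k≈30). The
package keeps the statistically well-defined max-cluster FWE version and
documents the discrepancy rather than emulating any particular legacy
behaviour.

## BOLD synthesis and the default signal-to-noise condition

Voxel time courses are a baseline (100) plus task betas times the
HRF-convolved phase boxcars, plus signed per-band couplings times the
*same* modulator columns the analysis builds (so the zero-noise pipeline
recovers couplings to ≤1e-6), plus stationary AR(1) noise (ρ = 0.3,
marginal sd 1). Default coupling magnitudes are set per band as
c_b = 3/(m_b·CV·K), where K = 21.5 is the whitened-design column norm of
a unit-sd retention modulator at the default timing (measured once on the
default design and frozen); this realizes the default SNR condition of
single-subject modulator |t| ≈ 3 at truth voxels (measured mean 3.01).
Coupling signs: negative blobs for theta/alpha1/alpha2, positive for
beta1/beta2/gamma, each a 36-voxel box on the 20×20×10 desk grid. The
load-responsive region (30 voxels) carries a retention beta difference of
1.5 (ss5 3.0 vs ss2 1.5) and an additional ss5-only coupling increment of
sign(δ_b)·0.5·c_b — the generative mechanism behind the ROI sign table:
with per-load mean-centred modulators, a band-power load effect alone
cannot move the per-load coupling betas, so the load dependence of the
coupling itself is explicit ground truth.

## Pipeline, seeds, problem sizes

A root seed spawns one `SeedSequence` child per subject plus one for the
group stage; identical configurations reproduce results bit for bit. The
EEG arm can be run in full (`eeg="synthesize"`) or bypassed
(`eeg="truth-power"`, feeding ground-truth band power into the design);
the repeated-run recovery harnesses use the bypass, which isolates the
GLM/inference path — EEG measurement fidelity is validated separately
(noise-free calibration error ~1e-6; with default background noise the
measured power adds a small positive bias that mean-centring absorbs).
Desk-scale runs use the 20×20×10 grid (4000 voxels) with 16 subjects; the
full 73×73×42 geometry appears only in the cluster-threshold simulation.
The two 50-run harnesses (recovery and null calibration) and the
full-geometry cluster simulation dominate the test suite's runtime
(roughly ten minutes on one CPU).

## Known limitations

* The load-independent EEG power index is implemented as raw
  retention-window band power (log-transform before the one-sample test
  is an option); the original index formula was not recoverable.
* Alpha2 is 10–13 Hz throughout (the methods definition; a 10–12 Hz
  variant appears elsewhere in the source description).
* Bonferroni FWE is conservative for smooth maps; on the unsmoothed
  synthetic grids voxels are independent, where it is essentially exact.
* The EDF writer emits plain EDF with 1 s records and 16-bit scaling per
  channel; recordings are zero-padded to whole records.
* No spatial preprocessing of acquired volumes (motion correction,
  normalization, smoothing) is implemented; the simulator emits data in
  analysis space directly.
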