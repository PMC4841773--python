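# Methods

## Generative model of the stimulus

The stimulus is a chain of `n_segments` segments of fixed duration
(default 0.3 s). A hidden *population* is a Gaussian over log-frequency:
log₂ f ~ N(log₂ μ_pop, σ_pop²), with μ_pop ~ U(120, 140) Hz and
σ_pop ~ U(1/128, 1/16) octaves. At every segment after the first the
population is replaced with probability `p_change` (default 1/8) by a
fresh, independent draw of (μ_pop, σ_pop); the segment's f value is then
drawn from the population in effect. The first segment always starts a
fresh population.

The population lives in log-frequency (octave) space because σ_pop is an
octave quantity and every derived difference (Δf, ξ, Δμ) is measured in
octaves; a Hz-space Gaussian parameterised by an octave SD would be
incoherent. A Hz-space variant is deliberately not offered: all
downstream mathematics assumes the octave-space process. Draws are not
clipped to any bound — the observer's grid instead extends beyond the μ
range by `pad_sigmas` (default 4) × max σ.

### Audio rendering

Instantaneous fundamental frequency is defined sample-wise, its
cumulative sum gives the phase, and each harmonic h is
sin(2πr_h + 2πh·Σf/s) with one fixed random phase offset r_h per
harmonic, so the waveform is phase-continuous across segment boundaries
by construction. Harmonics are instantiated for every integer h with
h·min(f) below the generation Nyquist; a zero-phase FIR high-pass at
1.8 kHz (Kaiser design, default 70 dB stopband, 200 Hz transition) then
keeps only unresolved harmonics. A sharp FIR edge is used rather than a
low-order IIR because the highest sub-cutoff harmonic sits only ~100–250
Hz below the cutoff and must be driven ≥ 40 dB down. Audio is generated
at 88.2 kHz and polyphase-resampled 2:1 to 44.1 kHz (the resampler's
anti-aliasing filter removes components above the output Nyquist), then
peak-normalised and written as 16-bit PCM WAV.

## Ideal-observer inversion

The observer knows the generative rules exactly (no learning of
`p_change` or the parameter ranges). Inference runs on a discretised
model space: 41 μ bins × 29 σ bins × 513 f bins (f uniform in octaves).
Each column holds the Gaussian probability mass between f-bin edges,
renormalised to sum to one exactly. These resolutions keep a full
8000-segment inversion to a few seconds while doubling every resolution
changes the headline surprise/prediction-error correlation by < 0.01
(tested).

Sequentially, for segment t:

1. The parameter posterior is the normalised product of the inverse-model
   planes of all observations since the last accepted change (accumulated
   in log space; an all-zero product raises a diagnostic error).
2. The prior prediction is the mixture
   (1 − p)·(posterior-weighted average of forward columns) +
   p·(unweighted average). Its mean μ_t, variance σ²_t and precision
   Π_t = 1/σ²_t are computed in octave space from the full mixture —
   the mixture *is* the prediction, so its precision is the predictive
   precision (the no-change component alone would overstate certainty).
3. Regressors at f_t: surprise S_t = −log(prior bin mass, floored at
   1e−12 to guard zero-mass tail bins); prediction error
   ξ_t = |log₂ f_t − μ_t|; precision Π_t; pitch change
   Δf_t = |log₂(f_t/f_{t−1})| (undefined, emitted as NaN, for the first
   segment). Prediction change Δμ_t = |μ_{t+1} − μ_t| uses the prior
   mean after the update below, so the run computes one extra prior after
   the final segment.
4. Change inference: for candidate change times k ∈ {t, t−1, t−2, t−3}
   (never earlier than the last accepted change),
   P(c_k|f_t) = 1/(1 + ((1−p)/p)·L_stay/L_k), where L_stay is the
   no-change predictive (all observations since the last accepted change)
   at f_t, and L_k is the predictive of a posterior rooted at the uniform
   parameter plane and updated with observations k..t−1 — at k = t this
   is exactly the uniform-average change predictive, giving the canonical
   single-segment rule: equal likelihoods return the prior 1/8, and the
   0.5 decision boundary sits at likelihood ratio 1/7. The candidate with
   the largest P(c|f) is accepted iff it exceeds 0.5, ties broken toward
   the most recent candidate (minimal history revision). Four candidates
   are used because longer memories do not change the estimates
   appreciably. A retrospectively accepted change re-roots the posterior
   but never alters priors already emitted.

Observations are binned by clipping to the f grid; the standalone
posterior-update operation additionally rejects observations more than
0.1 octaves outside the grid as degenerate (a clipped far-outlier would
silently masquerade as an edge observation).

Note on S versus Π·ξ: for a Gaussian prior, S = ½log(2π/Π) + Π·ξ²/2, so
surprise is *not* exactly proportional to precision × prediction error;
the implementation keeps the exact −log p and the test suite checks the
Gaussian closed form only in the sharply-peaked limit. Predictive
variance is floored at (bin width)²/12 — the quantisation variance of a
single bin — so a degenerate single-bin prior still has finite
precision, with Π·σ² = 1 holding exactly for the stored values.

## Partialisation

All series are z-scored, then each regressor is replaced by its residual
after least-squares projection (intercept included) onto the other
regressors at lags −2..+2 and its own values at lags ±1, ±2 — never its
own lag 0. Z-scoring first makes correlation and regression coefficients
coincide; the intercept is included because the lag-trimmed slices are
not exactly centred. Edge segments lacking the full lag window (and the
first segment's undefined Δf) are dropped symmetrically; downstream
analyses use the trimmed index set. Rank-deficient designs fall back to
the pseudo-inverse with a warning. Two alternative presets are provided
as configuration, not separate code paths: `df-only-partial` (the three
perceptual regressors partialised only against contemporaneous Δf, Δf
itself left unpartialised) and `no-precision` (Π omitted entirely, as
target and as conditioning column).

Because each residual is exactly orthogonal, in sample, to every
conditioning column, a synthetic effect driven linearly by one raw
regressor cannot reach another regressor's residual through their shared
variance — the basis of the specificity checks below.

## Synthetic LFP

Each channel is independent 1/f^α background noise (FFT-shaped Gaussian
noise, default exponent 1, unit SD); effects are shared across channels,
scaled by per-channel gains (default 1). An effect adds, in a fixed
window relative to every segment onset, a Hanning-windowed sinusoidal
burst at its band's centre frequency with amplitude
baseline + gain·z(regressor) (defaults: baseline 1, gain 0.6 per
regressor SD). The amplitude is deliberately *signed*: a rare negative
value flips the carrier phase rather than clipping, keeping the
modulation exactly linear in the regressor (a hard clip at zero was
found to inject nonlinear regressor components that defeat the
orthogonality of the partialised residuals and produce spurious
cross-correlates). Induced effects draw a fresh uniform phase per
segment (shared across channels); evoked effects keep a fixed phase. The
default effects mirror the layout the analysis is intended to recover:
gamma (30–100 Hz, 90–500 ms) scaled by surprise, beta (12–30 Hz) at
300–500 ms — around the next segment onset — scaled by Δμ, alpha
(8–12 Hz, 0–300 ms) scaled by Π, and a phase-locked 2–12 Hz evoked
component (0–300 ms) scaled by Δf. The default gain of 0.6 yields
windowed induced correlations of roughly 0.1–0.3 against the partialised
residuals — strong but plausible for a well-placed intracranial contact,
and sufficient for reliable recovery at the problem sizes used.

What the generator does *not* emulate: biophysical mixing (dipoles,
volume conduction, reference effects), non-stationary background
spectra, epileptiform or movement artifacts, asymmetric burst shapes, or
any nonlinear coupling between variables and amplitude. Passing recovery
tests therefore demonstrate that the analysis chain is correct and
specific under its own assumptions, not that real cortical recordings
would behave this way.

Recordings round-trip losslessly through an HDF5 container
(`/signal`, `/onsets`, `/channel_gains`, a JSON-encoded ground-truth
block, and sample-rate/seed attributes, schema-versioned) with a sidecar
CSV channel table; a file with the ground truth removed reads back with
effects marked absent.

## Time-frequency regression

Morlet decomposition uses the fixed protocol: frequencies 2–100 Hz in
2 Hz steps, epoch times −300..600 ms in 10 ms steps, cycle count linear
from 1 at 2 Hz to 10 at 100 Hz, wavelet support ±3.5 temporal SDs,
amplitude-normalised so a unit sinusoid at the centre frequency yields
unit amplitude. Segments whose padded window would cross the recording
edge are dropped. Coefficients are stored complex64; regression
workspaces run in float32 (the permutation loop is pure BLAS/elementwise
passes), which bounds the residual-orthogonality error at ~1e−5 in r —
far below any threshold in use.

Artifact rejection z-scores amplitude per (channel, frequency) across
segments and times, then rejects trials whose mean or maximum normalised
amplitude exceeds an automated percentile threshold (default 99.5%) —
a reproducible stand-in for threshold-setting by eye; the keep/reject
decision is a pure function of the stored statistics and thresholds.

Channel selection keeps channels whose largest mean-across-segments
response anywhere in a 300 ms analysis window beats the (1 − α) quantile
of a null built by re-averaging with each segment's window independently
jittered by up to ±300 ms (on the 10 ms grid) per permutation.

The two-stage regression at every (channel, time, frequency) point:
real and imaginary parts are each regressed on the regressor; the
modulus of the two correlation coefficients is the *evoked* map
(reported unsigned, as a modulus must be). Both parts are residualised
jointly (slope and intercept, i.e. the across-trial mean — the ERP — is
removed too), the complex residual is converted to amplitude, and the
amplitude is regressed on the regressor again, giving the signed
*induced* map. Per-channel maps are averaged in Fisher-Z space (Z first,
then average; back-transformed r is available for display).

Significance uses max-statistic permutation correction: each permutation
shuffles the regressor across segments and recomputes the full two-stage
regression; the largest |Z| of the channel-averaged map within the
correction domain enters the null, and the corrected threshold is its
(1 − α) quantile (two-sided by construction since induced maps are
signed). The default correction domain is every time-frequency point of
the channel-averaged map; per-permutation channel-averaged maps are
retained so a region-of-interest threshold (e.g. the gamma 30–100 Hz
rows) can be recomputed from the same permutations. Canonical band
membership is half-open (lo, hi] so adjacent bands never share a bin.

The surprise-vs-prediction-error comparison computes, for both
regressors partialised against everything *except* each other and then
additionally against each other, the channel-mean windowed induced Z
(90–500 ms × 30–100 Hz); the stage-2 difference is tested by sign-flip
(label-swap) permutation across channels. With very few channels the
attainable p is limited by 2^(n_channels); tests use enough channels to
resolve the nominal level.

Variance explained regresses raw amplitude in the 0–300 ms window on the
four raw regressors of interest (intercept included) and averages R²
over channels. Pattern similarity scalar-multiplies each channel's
induced map with the channel-averaged map, averages over time-frequency,
and scales by the largest absolute score so values lie in [−1, 1].

### Specificity and wavelet bandwidth

The prescribed cycle counts make the wavelets spectrally broad at low
frequencies (spectral SD σ_f = f/cycles ≈ 6–8 Hz through the alpha–beta
range), so any narrowband effect of sufficient power is *necessarily*
significant in neighbouring bands: e.g. a 10 Hz burst is seen by the
14 Hz wavelet at ~80% amplitude. Demanding zero significance outside the
embedded band would therefore be physically unsatisfiable at any power
sufficient for reliable recovery. The recovery summary instead reports,
per regressor: which bands contain corrected-significant points, the
band holding the peak significant |Z|, whether the embedded
(band × window) was recovered, and whether any significance appears at
bins beyond 3σ_f of the embedded carrier — contamination that wavelet
bandwidth cannot explain and that the tests require to be absent.

## Problem sizes used by the test suite

The full-length inversion tests run the study-scale 8000 segments. The
synthetic-recording Monte-Carlo tests run at reduced scale, chosen as
the package's own trade-off between statistical resolution and suite
runtime: parameter recovery uses two seeded runs of 1500 segments ×
3 channels × 100 permutations; the family-wise-error calibration uses
120 corrected families from 30 null runs of 150 segments; the
evoked/induced dissociation uses 300 segments × 2 channels. Thresholds
(α = 0.05 corrected, the 0.5 change-inference boundary, the 0.89–0.95
acceptance band on r(S, ξ)) are never relaxed to compensate.

## Known limitations

- The observer is given the true generative rules; learning them, and
  non-Gaussian population models, are out of scope.
- Surprise is defined on discrete bin mass; densities differ by the
  constant log(bin width), which cancels in every correlation-based
  analysis but matters if absolute surprise values are compared across
  grids.
- The synthetic LFP's linear amplitude coding and perfectly segment-locked
  windows are idealisations; recovery rates reported here are upper
  bounds on what comparable real recordings could yield.
- The permutation null shuffles segments independently, which is exact
  for exchangeable regressors; the partialised residuals are close to
  white, but strongly autocorrelated custom regressors would need a
  block-permutation variant that is not implemented.
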