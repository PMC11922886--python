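# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data experiments do and do not
establish.

## Stimulus model

**Geometry.** A target is a disc of `n` concentric ring bands. Outer radii
form the arithmetic sequence `r_i = (2i−1) r_max / (2n)`, so consecutive
cell boundaries are evenly spaced and the outermost band edge
`(2n−1) r_max / (2n)` defines the *stimulus disc* used for all area
bookkeeping. Inner radii come from a per-cell rule: the band occupies the
fraction `C/(1+C)` of its annular cell's area
(`inner² = outer² − C/(1+C)·(outer² − prev_outer²)`), which makes the
global band/background ratio inside the disc exactly `C` in the continuum.
Rendering uses 4× supersampled coverage masks for anti-aliased edges;
verification counts pixels on the binary 1× mask, where the realized ratio
matches `C` within ~0.3% at a 512-px canvas (2% is the accepted bound,
dominated by discretization at small ring counts).

**Motion.** The motion model is a sinusoidal radial displacement applied
to every band boundary, with amplitude equal to half the mean band width:
phase 0→π expands, π→2π contracts, and the cycle-average geometry equals
the static geometry. Boundaries are clamped at zero radius. (A radial
*scaling* model was the alternative; displacement was chosen because it
keeps band widths, and hence local contrast, constant over the cycle.)

**Color and isoluminance.** The color sweep weight follows the raised
cosine `w(t) = (1 − cos 2πft)/2`, so each cycle runs black→red→black for
the rings and white→green→white for the background with no luminance step.
Perceived luminance is `L = C1 (0.2126 R + 0.7152 G + 0.0722 B)` with the
device constant `C1 = 0.7`; display gamma is not modelled (luminance is
treated as linear in channel values, consistent with this formula).
Because ring motion changes the band/background split within a frame, a
static endpoint match cannot hold the spatial mean constant while rings
move. The renderer therefore solves the *background* luminance each frame
from the realized band fraction so that the disc-mean luminance is
analytically constant, then realizes that luminance on the white→green
trajectory. When the pure green hue cannot reach the required luminance
(high brightness), the color is desaturated toward white; the
`match_luminance` API itself is strict and raises a gamut error with the
maximum achievable value. Pixel-measured ripple of the disc-mean luminance
is ~0.3% over a cycle (bound: 1%), the residual coming from anti-aliased
edges.

**Brightness levels.** The study names low/medium/high levels without RGB
values; the package defaults to peak channel values 85/170/255. These are
package defaults, not measured display values.

**Layout.** The four-target layout places targets at (0, ±240) px
vertically and (±360, 0) px horizontally from the canvas center, with a
bounding-box overlap check. The composed stream length is the least common
multiple of the per-target cycle lengths (2 s at 60 fps for
3/3.5/4/4.5 Hz).

## Synthetic EEG forward model

Each 5-s trial at 1,200 Hz over 6 channels is the sum of:

- **Evoked response:** phase-locked sinusoids at the stimulation frequency
  and its harmonics (default H = 2, amplitudes 1.0 and 0.4 µV), scaled by
  a paradigm gain (bimodal 1.0 > single-motion 0.75 > single-color 0.6),
  a brightness gain peaking at medium (0.85/1.0/0.92), per-channel gains
  peaking at Oz, and a per-subject lognormal factor (σ = 0.3).
- **1/f background:** spectrally shaped Gaussian noise with exponent
  γ = 1 (flat below 1 Hz), RMS 1.5 µV.
- **Rhythmic components:** Gaussian-profile spectral humps for θ (center
  6 Hz, σ 0.8), α (10 Hz, σ 1.2; default power 4 µV², the posterior alpha
  dominance) and β (20 Hz, σ 3; 0.6 µV²). Humps rather than flat bands are
  used both for realism (EEG rhythms are narrowband) and so that
  band-integrated power measurements track the injected powers without
  cross-band edge leakage under Welch smoothing. Per-task linear power
  drifts (`power × (1 + slope·(task−1))`) model workload/fatigue
  evolution.

Paradigm gains are calibrated **only to preserve orderings** (response
amplitude, SNR and accuracy: bimodal > single-motion > single-color); no
absolute human amplitudes are reproduced, and the printed human accuracies
(83.81% etc.) are not targets of this package. All randomness derives from
one master seed via SHA-256-keyed `SeedSequence`s per
(subject, paradigm, brightness, task, trial), so sessions are reproducible
to the bit.

What the generator does **not** model: eye blinks and EMG artifacts,
volume conduction / channel correlation (channels get independent noise),
latency jitter of the evoked response, and non-stationarity within a
trial. Passing tests therefore demonstrate correctness of the analysis
chain under idealized steady-state conditions, not performance on human
recordings.

## Preprocessing

The acquisition chain is an 8th-order Butterworth band-pass 2–100 Hz plus
a 4th-order band-stop 48–52 Hz (powerline); analysis presets are 1–30 Hz
(before averaging and bandpowers) and 2–40 Hz (before FFT spectra), both
4th order. All filters are applied zero-phase (`sosfiltfilt`) to preserve
evoked-response latency for averaging; this doubles the effective order,
which is accepted since only magnitude behaviour is asserted. Epochs cover
`[onset, onset + 5 s)`; cue (1 s) and gray (1 s) intervals fall outside by
construction. Averaging pools all trials of a condition after per-trial
filtering; with phase-locked responses this is equivalent to per-subject
averaging followed by pooling.

EDF export writes plain 16-bit EDF (1-s records, ±500 µV physical range,
~0.015 µV quantum); reading goes through MNE, which doubles as an
independent oracle for the writer in the round-trip test.

## Spectral estimation and SNR

Welch PSDs use 2-s Hann windows with 50% overlap (0.5 Hz resolution —
enough to separate 3 from 3.5 Hz) and density scaling, so band powers are
bin sums times the resolution and Parseval holds within estimation error.
The harmonic SNR uses up to 4 harmonics inside a 1–45 Hz analysis band
(harmonics above the band or Nyquist are dropped with a log note). Two
numerical choices depart from the naive single-bin ratio:

1. **Signal bins aggregate the nearest bin ±1 per harmonic.** The Hann
   main lobe spreads a bin-centered sinusoid over three bins (only 2/3 of
   its power sits in the peak bin, a −1.8 dB bias for a single-bin
   reading).
2. **Noise-baseline subtraction (default).** The raw ratio counts the
   noise beneath the harmonic bins as signal, biasing low-SNR estimates
   upward by ~4 dB at −10 dB true SNR. By default the noise density
   estimated from the non-signal bins is subtracted from the signal bins
   and the denominator is rescaled to the whole band — the standard
   debiased SSVEP SNR. `debias=False` restores the raw ratio.

With both, the estimator recovers analytic sinusoid-in-noise
constructions within ±0.3 dB across −10…+20 dB from 200-trial averaged
PSDs. Per-trial estimates at −10 dB are noise-floor limited (the signal
is not detectable in a single 5-s trial), which is why calibration is
stated for trial-averaged spectra. The absolute PSD scale is pinned only
up to a constant; the SNR, a ratio, is invariant to it.

FFT amplitude spectra of 5-s averages live on a 0.2 Hz grid: 3 and 4 Hz
(and all second harmonics 6/7/8/9 Hz) are on-grid and localized exactly;
3.5 and 4.5 Hz fall between bins and are localized to the neighbouring
bin.

## Workload and fatigue

Band edges are the conventional θ 4–8, α 8–13, β 13–30 Hz. Bandpowers are
Welch integrals per trial, averaged over channels and then over the trials
of each (subject, paradigm, task) cell. Load is θ/α, fatigue (θ+α)/β; a
least-squares line over task index 1..4 gives the variation extent
`100·(fit(4) − fit(1))/|fit(1)|`. Extents are computed on **raw** fitted
ratios; per-subject z-scoring is applied only for cross-subject
aggregation, because relative differences of z-scored values blow up near
zero. If the fitted task-1 value is numerically zero (below 1e−6 of the
subject's mean ratio), the extent is reported as NaN rather than a huge
number.

The injected-drift recovery oracle disables the evoked response: at the
study's stimulation frequencies the response harmonics (4–9 Hz) overlap
the θ and α bands and differ per task (task k presents frequency k), an
inherent confound of frequency-ordered tasks that would contaminate any
band-ratio trend — a caveat that applies to real data as well. With
rhythmic components isolated, a +10%/task θ-power drift yields an analytic
load-ratio extent of 24.1% (the 1/f floor's in-band share dilutes the
nominal 30%), recovered within ±5 points over 50 replicates.

## Classification

**CCA** references use 4 harmonics (matching the SNR harmonic count);
canonical correlations are computed via QR decompositions and the SVD of
`Qx^T Qy` with rank guarding, verified to 1e−8 against a generalized
eigenvalue oracle. Ties break to the lowest frequency, logged.

**Compact CNN.** The architecture follows compact EEG-network practice:
8 temporal filters of length fs/2 (600 samples at 1,200 Hz; the rule
rescales under decimation), a depthwise spatial stage spanning all 6
channels with depth multiplier 2, a separable temporal stage (16-tap
depthwise + 16 pointwise filters), batch normalization, ELU, average
pooling (4 then 8), dropout 0.25, and a dense softmax head; Adam at 1e−3,
batch 16, ≤120 epochs with loss-plateau early stopping. The implementation
is pure NumPy with hand-derived backward passes (finite-difference checked
to 1e−7); the long temporal convolution runs in the frequency domain for
speed. Max-norm weight constraints of the published architecture are
omitted — on the high-SNR synthetic task regularization beyond dropout
proved unnecessary. Inputs are z-scored per trial. Training is
bit-reproducible given the seed (seeded init, batch order and dropout).

Evaluation uses stratified k-fold cross-validation over trials; 4×
decimation (300 Hz, kernel 150) is enabled in the evaluation helpers by
default since the full-rate kernel is ~16× costlier for no accuracy gain
on synthetic data. Segment-length sweeps truncate trials from onset.

## Problem sizes

Sessions in tests and the acceptance script are scaled down from the full
study structure (which would be ~3.5 GB per paradigm block): typically
1–3 subjects × 6–20 trials at medium brightness, 50 replicates for drift
recovery, 200 trials per SNR calibration point, and a 60/20 train/test
split for the CNN check. These sizes were chosen so every stochastic
assertion has at least ~3σ of margin under its stated tolerance.

## Known limitations

- The luminance model ignores display gamma and assumes the Rec.-709 luma
  weights describe the presentation device.
- The forward model's independence across channels understates the
  spatial correlation of real EEG; cross-channel methods (CCA, the
  depthwise spatial stage) are therefore easier on synthetic data than on
  recordings.
- The band-ratio workload metrics inherit the harmonic-overlap confound
  described above whenever tasks are frequency-ordered.
- The EDF writer emits the plain 16-bit profile only (no EDF+ annotations;
  events travel in the sidecar CSV).
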