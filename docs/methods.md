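# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind `preictal`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic EEG generator

The generator emulates the *statistical regime* the analysis assumes, not
the biophysics of scalp EEG. Each channel is a sum of white-Gaussian-noise
components shaped by small IIR cascades:

* **Background**: ~1/f broadband noise (three pole/zero pairs per decade,
  ≈ −10 dB/decade from 0.25 to 79 Hz), RMS 12 µV. Typical resting scalp
  EEG amplitudes are tens of microvolts, so this is a realistic scale.
* **Alpha rhythm**: 8–13 Hz band-pass noise, RMS 8 µV per channel.
* **Preictal signature**: inside [onset − SPH − SOP, onset − SPH) a 5–7 Hz
  component with RMS `preictal_effect × 8 µV` is added and the alpha
  component is scaled by `1 − 0.5·preictal_effect`, with 5-s cosine ramps
  at the boundaries. Relative theta rises and relative alpha falls — a
  shift the feature set can detect. Real preictal dynamics are not
  characterised quantitatively in the literature this emulates; the shift
  is a planted, recoverable ground truth, and its magnitude is a config
  knob (`preictal_effect`, default 0.5, at which an oracle threshold on
  relative theta separates preictal from interictal windows with
  AUC > 0.9).

The shaping transfer functions are exported (`pink_sos`, `alpha_sos`,
`theta_sos`, `band_fraction`) so tests derive expected band powers by
integrating |H(f)|² rather than trusting any feature code.

**Artefacts.** Four parametric morphologies, with independent seed streams
per type so toggling one type never changes another:

* *Ocular events* alternate between rare dense "active" epochs (mean
  45 min, rate ×5) and long quiet stretches (mean 4 h, rate ×0.05) — a
  doubly stochastic Poisson process emulating waking/rest cycles. 60% of
  events are eyelid-flutter bursts (2–6 s sinusoids; frequency 4.5–7.5 Hz
  and amplitude scale drawn once per epoch, median 30 µV), the rest
  single biphasic blinks (~130 µV, 0.4 s); both are weighted toward the
  frontal channels. Flutter is the classic theta-band contaminant of
  scalp EEG and is deliberately confusable with the planted preictal
  shift.
* *Muscle bursts*: 0.5–2 s of 20–90 Hz band-limited noise, RMS 25 µV, on
  a random channel subset, at homogeneous Poisson times.
* *Flatlines* (2–8 s constant) and *saturation* (1–4 s clipped at
  ±550 µV), across all channels, homogeneous Poisson.

The ground truth records per-sample artefact masks, per-type event lists,
and the clean signal, so the denoiser and the error-removal stage can be
scored exactly. Default rates (blink 60/h, muscle 20/h, flatline and
saturation 1/h) are plausible for long-term scalp monitoring; they are
study conditions of the synthetic benchmark, not estimates of any
clinical dataset.

**Concept drift** scales the alpha-band component by
`max(1 − drift_rate·t_hours, 0.1)`, deterministically. Suppressing alpha
moves the interictal background *toward* the preictal signature (relative
theta up) — the adversarial direction that periodic retraining is meant to
absorb. The drift experiments use 0.05/h, i.e. roughly a halving of alpha
amplitude over 10 h, consistent with medication-taper-scale changes.

## Preprocessing

* Band-pass 0.5–100 Hz realised as a Butterworth with 4 poles
  (`butter(N=2, btype='band')`) and a second-order IIR notch at 50 Hz
  (Q = 30), both applied forward-backward (zero phase) so features see no
  phase distortion. Sampling rates ≤ 200 Hz are rejected (band edge at or
  above Nyquist).
* Experimental errors: flatline runs of identical samples ≥ 1 s; runs
  ≥ 0.1 s pinned above 99% of the per-channel observed rail; samples with
  |x| > 500 µV. All are masked on every channel. The thresholds are
  declared defaults — the source analyses do not quantify them.
* Postictal discard: [onset, onset + 30 min) for every onset.
* Denoising is a pluggable interface. The default
  `TemplateSubtractionDenoiser` is a deterministic signal-processing
  stand-in for a learned artefact-removal model: a frontal-average 0.5–8 Hz
  reference is regressed out of every channel wherever its smoothed RMS
  envelope exceeds 2× its median (ocular events), and 20–90 Hz bursts
  whose 0.25-s RMS exceeds 4× the channel median are scaled back to the
  median level (muscle). Thresholded activation keeps distortion on
  artefact-free data below 10% RMS (asserted in the tests). The
  `identity` denoiser is the "noisy" branch.
* Windowing: non-overlapping 10-s windows aligned to the record start on
  a fixed grid; any window overlapping an invalid sample is dropped
  entirely (the strict realisation of "segments with too many artefacts
  are removed"); trailing partials are dropped; contiguity flags feed the
  firing-power gap rule.

## Features (55 per channel)

5 moments (mean, sample variance with n−1, skewness, excess kurtosis,
normalised mean intensity mean|x|/max|x|) + 2 Hjorth (mobility,
complexity; activity coincides with the variance and is not duplicated) +
1 decorrelation time (first zero crossing of the sample ACF; the maximum
searched lag if none) + 7 absolute band powers (delta 0.5–4, theta 4–8,
alpha 8–13, beta 13–30, gamma1 30–47, gamma2 53–75, gamma3 75–90 Hz) + 6
relative powers (gamma3's is linearly redundant given the rest and is
omitted) + 21 pairwise band ratios (i < j) + 1 total power + 3 spectral
edge frequencies and 3 spectral edge powers (cumulative power at 50/75/90%
of the 0.5–90 Hz total) + 1 alpha peak frequency + 5 relative Daubechies-4
detail energies (5 levels) = 55. The composition is fixed and auditable in
`FEATURE_NAMES_PER_CHANNEL`; the enumeration in the source literature
over-determines the printed total, so the linearly redundant entries were
the ones dropped.

PSD estimation: Welch with 2-s Hann segments and 50% overlap (0.5 Hz
resolution; no estimator is named in the source description). Degenerate
windows (constant signal, zero power) return 0 rather than NaN so training
never sees missing values.

## Labeling, splits, standardisation

Window-to-label assignment is by window start time (unambiguous for 10-s
windows at minute-scale boundaries). The 60% train share is rounded half
up at the seizure level (minimum 2 train, 1 test; < 3 seizures is an
error). Each test seizure's segment runs from 30 min after the previous
onset to its own onset. The 80/20 holdout is sample-level and stratified
by default — plain random splitting risks starving the tiny preictal
class at desk scale; `stratify=False` restores it. Z-scores are always
computed on the training samples only (per feature, or per channel for
raw windows) and carry a provenance tag asserted in tests.

## Classifiers and training

The network kernels (`_nn.py`) are NumPy with hand-written backward
passes, verified against central finite differences to ~1e-9 relative
error. Training: balanced 64-sample batches (32 per class; an epoch is
⌈n_majority/32⌉ batches; the minority class cycles with replacement),
Adam at 3e-4, softmax cross-entropy (= binary cross-entropy for two
classes), early stopping with patience 50 against a validation set,
best-validation weights restored. Per-member seeds are
`seed_base + run`, covering initialisation, batch order and dropout, so
the full ensemble is bit-reproducible. Ensemble fusion is majority vote
on per-window *hard labels* (the fusion point is otherwise ambiguous);
this makes the ensemble a drop-in prediction source for the firing-power
stage. Conv blocks order operations conv → strided conv → spatial
dropout → swish → batch norm; the temporal axis is convolved with
channels as the feature axis.

## Alarms

The firing power over the τ most recent 10-s slots (τ = 180) divides by
τ, so fp ∈ [0, 1]; missing slots — preprocessing gaps or pre-stream
history — contribute zero, which makes decay-to-zero after a long gap
emergent rather than a special case. The printed formulation of the
regularisation sums τ+1 terms over divisor τ; the moving-window reading
("ratio of preictal instants in the window") is implemented. Triggering
is strictly fp > 0.5; each alarm suppresses further alarms for
SPH + SOP = 40 min of wall-clock time, after which eligibility resumes
unconditionally.

## Evaluation

True-alarm semantics, sensitivity and FPR/h are as in the README. The
interictal duration in FPR/h counts emitted test windows labelled
interictal (gaps and preictal/SPH windows excluded) — the time during
which a false alarm could actually occur.

Surrogate analysis relocates each test onset uniformly within its own
segment, leaving room for SPH + SOP before it (the full segment, with a
warning, if the segment is shorter); relocated onsets may overlap other
seizures' occurrence periods. The p-value is the Monte-Carlo rank
p = (#{surrogate > real} + u + 1)/(n + 1), with u drawn uniformly from
{0..#tied}: under the exchangeable null this p is exactly uniform on its
grid, so the test is calibrated — the property the acceptance suite
checks at 500 repetitions. 39 surrogates are used so the attainable
p-grid (k/40) contains the 0.05 level exactly, the classic 1/(n+1)
surrogate-count convention. A one-sample t-type alternative
(`method="ttest"`) is provided but is anti-conservative under
exchangeability and is not the default. Sensitivity must also exceed the
surrogate mean for an above-chance declaration.

Approach comparisons use one-tailed Mann-Whitney U tests with midrank
ties (p = 0.5 by convention when every value is identical): sensitivity
tested as "B greater", FPR/h as "B lower", except deep vs shallow where
the feature models' FPR/h is tested as greater, mirroring the reporting
convention of the study design this reproduces.

## Desk-scale profile and problem sizes

The default `ExperimentConfig` is a desk-scale profile chosen so the full
acceptance suite runs on one core: 5-member ensembles, 2-h training
windows, 200-epoch cap, the reduced CNN-BiLSTM (8 starting filters, 8
LSTM units — same topology), and synthetic patients with 1–2 channels and
3–4 seizures at the minimum legal 4 h 30 min spacing (12–17 h of signal).
`ExperimentConfig.paper_scale()` restores 31 members, 4-h windows, 500
epochs and the full network; the generator default remains 19 channels at
256 Hz. Ensemble size, training-window length and channel count scale the
compute, not the semantics; every contract tested at desk scale holds at
full scale by construction.

## What passing tests do and do not show

The synthetic benchmark plants a *stationary, linearly separable*
spectral signature and parametric artefacts. Passing recovery tests shows
the pipeline is correct and leak-free, not that real preictal EEG is
detectable; real preictal dynamics are nonstationary, patient-specific
and far weaker. The qualitative findings (denoising and retraining reduce
false alarms) are reproduced *directionally* on conditions constructed to
contain the corresponding failure modes — artefact-dense waking epochs
unseen in training, and alpha-suppressing drift; they quantify nothing
about clinical data. Ocular events are deliberately epoch-clustered
(modulated Poisson) rather than homogeneous, because uniformly spread
transients cannot sustain a 30-min firing-power window and would make the
denoising comparison vacuous.

## Known limitations

* The default denoiser is a signal-processing stand-in with thresholded
  activation; it removes the synthetic morphologies it was designed for
  and is not a learned artefact-removal model.
* Surrogate p-values are randomized at ties; two evaluations with
  different seeds can differ by one grid step when ties occur.
* With one test seizure, sensitivity is 0 or 1 and a single well-placed
  alarm often cannot reach p ≤ 0.05 against 39 surrogates (ties); this is
  a property of the evaluation design, visible in the null experiments.
* The EDF writer emits classic EDF (integer sampling rates, 1-s records);
  reading goes through mne.
* FPR/h is undefined when refractory periods exhaust the interictal time;
  the implementation raises rather than clamping.
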