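# preictal

Patient-specific seizure prediction from long-term scalp EEG, built as a
tested, reusable pipeline: preprocessing, handcrafted feature extraction,
preictal/interictal labeling, ensemble neural-network classification,
firing-power alarm generation, and surrogate-validated evaluation — plus a
ground-truthed synthetic-EEG generator so the whole chain runs end-to-end
without access to clinical recordings.

It is aimed at researchers studying two practical questions about seizure
prediction systems: whether removing physiological artefacts (eye blinks,
eyelid flutter, muscle bursts) from the EEG improves prediction, and
whether periodically retraining models as new seizures accrue mitigates
concept drift in multi-day recordings.

## The method

A recording (19 channels, 256 Hz in the full profile) is band-pass
filtered (0.5–100 Hz, fourth order) with a 50 Hz notch (second order),
stripped of experimental errors (flatlines, saturation, extreme
amplitudes) and of the 30 min after each seizure onset, optionally
denoised, and cut into non-overlapping 10-s windows. Each window yields 55
univariate features per channel (statistical moments, Hjorth mobility and
complexity, decorrelation time, absolute/relative band powers and their
ratios over delta through gamma-3, spectral edge frequencies/powers,
alpha peak frequency, Daubechies-4 wavelet detail energies).

Windows are labelled by the seizure occurrence period (SOP, 30 min) and
seizure prediction horizon (SPH, 10 min): windows starting in
[onset − SPH − SOP, onset − SPH) are preictal, windows inside the SPH are
discarded, everything earlier is interictal. The first 60% of seizures
train, the rest test; training uses only the 4 h before each training
onset (2 h in the desk profile). Two classifiers are provided as
scikit-learn style estimators: a shallow softmax network over the
1045-dimensional feature vector (input dropout 50%, two-neuron FC layer)
and a compact CNN-BiLSTM over the raw 2560×19 window (three conv blocks
with stride-2 learnable pooling, swish f(x) = x·σ(x), spatial dropout,
batch norm; filters 128 doubling per block, kernel 3; BiLSTM with 64
units). Training uses balanced 64-sample batches (32 per class, minority
oversampled), Adam at 3·10⁻⁴, binary cross-entropy, and early stopping
(patience 50, max 500 epochs) on a stratified 80/20 sample holdout, with
z-scores frozen on the training samples. An odd ensemble (31 runs in the
full profile) fuses per-window labels by majority vote.

Alarms come from the gap-aware firing power

    fp[n] = (1/τ) · Σ o[k]  over the τ most recent 10-s slots,

with τ = SOP/10 s = 180 and windows missing from the stream contributing
0. An alarm fires when fp exceeds 0.5 and is followed by a 40-min
refractory period (SPH + SOP). An alarm at time t is a true prediction iff
an onset falls in [t + SPH, t + SPH + SOP). Reported per patient:

    sensitivity = #true alarms / #test seizures
    FPR/h = #false alarms / (interictal hours − #false alarms · 2/3 h)

Chance level is assessed by surrogate analysis: test onsets are relocated
uniformly within their own test segments and the fixed alarms re-scored
(39 surrogates; exchangeable-rank p-value with randomized tie-breaking);
a model is above chance if its sensitivity beats the surrogate mean at
p ≤ 0.05. Approaches (noisy/denoised × features/EEG ×
standard/chronological retraining) are compared with one-tailed
Mann-Whitney U tests.

## Worked example

```python
from preictal import ExperimentConfig, make_patient, run_standard

# synthetic patient: 4 seizures 4.5 h apart, 2 channels, planted
# preictal signature (relative theta up, alpha down) of strength 0.5
record, truth_mask, cfg = make_patient(
    n_seizures=4, n_channels=2, preictal_effect=0.5, seed=1)

report = run_standard(record, ExperimentConfig(branch="noisy", seed_base=1))
print(f"sensitivity:       {report.sensitivity:.2f}")
print(f"FPR/h:             {report.fpr_per_h:.2f}")
print(f"surrogate p-value: {report.p_value:.3f}")
print(f"above chance:      {report.above_chance}")
```

prints

```
sensitivity:       1.00
FPR/h:             0.00
surrogate p-value: 0.025
above chance:      True
```

Both held-out seizures were predicted (a firing-power crossing inside each
pre-onset window), no false alarms fired in ~8 h of interictal test data,
and the alarms beat 39 random relocations of the onsets (p = 1/40), so the
model performs above chance for this patient.

The same flow is available from the shell:

```bash
preictal synth generate --config patient.yaml --out patient/ --seed 1
preictal run --patient-dir patient/ --approach denoised_features_standard \
    --out reports/p1.json
preictal compare --reports reports/
```

## Layout

```
src/preictal/
  synth.py           ground-truthed synthetic EEG generator
  preprocessing.py   filters, error masks, pluggable denoiser, windowing
  features.py        55 univariate features per channel per window
  dataset.py         SOP/SPH labeling, chronological splits, z-scoring
  models.py          shallow softmax net, CNN-BiLSTM, majority-vote ensemble
  _nn.py             NumPy layer kernels (conv, BiLSTM, batch norm, Adam)
  alarms.py          gap-aware firing power and refractory alarms
  evaluation.py      alarm scoring, FPR/h, surrogate analysis, rank tests
  pipeline.py        standard/chronological regimes, approach comparison
  io.py              EDF writer/reader, annotation and feature CSVs
  cli.py             `preictal` command-line front end
```

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
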