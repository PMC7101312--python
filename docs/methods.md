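# Methods

## The experiment being emulated

A 64-channel EEG session (extended 10-20 montage, 500 Hz) during
transcutaneous electrical nerve stimulation of a phantom limb under three
graded conditions — INNO (pulse width 1 ms, 45 Hz), MOD (5 ms, 4 Hz) and NOX
(20 ms, 20 Hz), all at 1.6 mA. Stimulation arrives as blocks of five 2 s
pulse trains separated by 4 s ± 25 % jittered delays; four blocks per
condition give 3 × 4 × 5 = 60 trials, 20 per condition. Block order is a
seeded random permutation, with a rest gap between blocks.

## The synthetic session generator

### Signal model

Each condition's evoked response is a sum of spatio-temporal components,
`component = spatial weights ⊗ temporal kernel`. Spatial weights fall off as
a Gaussian in squared scalp distance from a centre electrode and are zero
outside the component's named electrode group (central = {Cz, C4, C6},
parietal = {P2, P4, P6}); kernels are either Gaussian bumps (centre ±
sigma) or plateaus with raised-cosine edges, and are identically zero before
stimulus onset. Default templates (amplitudes in µV):

| condition | early parietal (54 ms, σ 12 ms) | parietal plateau (100–950 ms) | central component |
|-----------|--------------------------------|-------------------------------|-------------------|
| INNO      | 4.0                            | 0.6                           | —                 |
| MOD       | 7.0                            | 1.5                           | −9.0 Gaussian, 700 ms, σ 60 ms (depression) |
| NOX       | 4.5                            | —                             | +6.5 plateau 450–750 ms + 13.0 Gaussian, 700 ms, σ 30 ms |

The MOD *central depression* reflects the reported blue (negative) central
topography under moderate stimulation and is what makes the three classes
separable along a single central spatial mode (INNO ≈ 0, MOD < 0, NOX > 0)
— the property that lets a two-component PCA retain the class structure.
Its width matters: the decoding feature is a signed window *maximum*, so a
narrow depression would be sampled at its weak edges; at σ = 60 ms it stays
deeply negative across a 100 ms window. The NOX peak at 700 ms (σ 30 ms) is
deliberately sharp so that the discriminative structure is concentrated in
the [650, 750) window rather than smeared into its neighbours.

The kernel of each condition is defined over one 1 s cycle and rendered once
per second of the 2 s train: the response is modelled as steady-state over
sustained stimulation. This is the assumption that makes the 2 s → 2 × 1 s
augmentation label-preserving (both halves of a trial carry the condition's
signature); without it the augmented test set would be half noise.

### Noise model

Three seeded components, all configurable:

* **1/f background** (default 3.0 µV RMS per channel): white noise shaped in
  the frequency domain to power ∝ 1/f above a 1 Hz knee (flat below — real
  EEG spectra plateau at very low frequency, and unbounded drift would make
  the pre-train baseline meaningless for the second augmented segment). The
  field is smoothed across the scalp with a Gaussian mixing kernel
  (correlation length 0.25 of the unit-disc radius) to imitate volume
  conduction; rows of the mixing matrix are L2-normalised so the per-channel
  RMS is preserved.
* **white sensor noise** (1.0 µV RMS), independent per channel;
* **line interference** (1.0 µV at 60 Hz), common phase across channels.

Spectral shaping is exact in expectation; the log–log periodogram slope over
1.5–40 Hz is −1 within ±0.3 (asserted in tests).

### Calibration

The published study reports where the discriminative structure lies, not its
microvolt amplitudes, so the defaults above were calibrated once so that the
planted structure is *recoverable but not trivially so* under the pipeline's
own statistics: across 20 seeds the sweep's best window is the planted
[650, 750) interval with a large margin (pooled mean bACC ≈ 0.92 there
versus ≤ 0.52 elsewhere), the mean held-out test accuracy sits near 96–97 %
(above the 94.66 % reference), the post-stimulus GFP means order
NOX > MOD > INNO, and the 54 ms parietal peak is recovered within two
samples. Single-trial peak SNR is roughly 13–19 µV evoked over ~3 µV RMS
noise at the strongest channel, and ~4 µV over 3 µV for the weakest planted
component. After calibration the defaults are fixed; every number the tests
assert is recomputed from these defaults at run time.

### What the generator does not emulate

Ocular/muscle artifacts (rejection is exercised with planted amplitude
spikes instead), TENS artifact bleed-through, non-stationarity across the
two-hour session, inter-subject variability, and any biophysical forward
model (the spatial falloff is a smooth kernel on the electrode disc, not
volume conduction from dipoles). Passing tests therefore show that the
*pipeline* recovers what was planted under realistic noise — not that real
amputee EEG will decode at these accuracies.

## Pipeline choices

* **Filtering** is applied forward–backward (`sosfiltfilt`), squaring the
  magnitude response of the designed fourth-order Butterworth; the pass-band
  is unaffected at this band but phase is exactly zero, which the latency
  claims (54 ms, 450–750 ms) require. The notch is an IIR design with
  quality 30.
* **Epochs** are half-open `[t_start, t_end)` windows at 0-based sample
  indexing, which makes the 2 s → 2 × 1 s split exact and non-overlapping
  (re-concatenation is bit-identical, asserted).
* **Baseline** of both augmented segments is the trial's original pre-train
  mean; there is no pre-stimulus interval inside the second second of a
  train.
* **Artifact rejection** flags a trial when any channel's within-epoch
  peak-to-peak amplitude exceeds the (configurable, default 150 µV)
  threshold. The operation is idempotent and reports the worst channel and
  value per rejected trial.
* **Features** use the *signed* maximum (an `absmax` flag exists): red
  (positive) enhancements and blue (negative) depressions are distinct
  phenomena and a signed max keeps a depression from masquerading as
  activation.
* **The sweep** scores all five classifiers on all 64 features (no PCA) on
  the 60 original trials; the augmented 120 trials are used only for the
  split/PCA/test stage. The best window is the argmax of the
  classifier-pooled mean bACC, earlier windows winning ties.
* **QDA** is a pooled-per-class Gaussian discriminant written in-package
  with a relative covariance ridge (`reg_param`, default 1e-3), because the
  18-trials-per-fold × 64-features regime makes every class covariance
  singular; the singular case warns. LDA (SVD solver), KNN (k = 5,
  Euclidean), Gaussian NB and SVM are scikit-learn.
* **SVM grid**: {linear} × C ∈ {0.1, 1, 10, 100} plus {RBF} × the same C ×
  γ ∈ {scale, 0.01, 0.1, 1}; ties in mean CV bACC resolve to the first grid
  point. Multiclass is one-vs-one (libsvm's native scheme).
* **Sequential forward selection** scores candidate channel sets by mean
  stratified-CV balanced accuracy of an LDA discriminant, averaged over five
  fold-shuffle repetitions (greedy argmax over ~64 candidates is an extreme
  value — averaging repetitions keeps it tracking real gains rather than a
  single split's luck); ties resolve to the lower channel index. The scorer
  is a fold-vectorised pooled-covariance discriminant numerically identical
  to per-fold LDA (unit-tested) but ~50× faster than fitting estimators in a
  loop.
* **Selection-recovery benchmark** (`synth.central_selection_config`): the
  identifiability limit of greedy selection at 60 trials over 64 channels is
  the selection noise itself (~±4 % apparent gain for the luckiest of 61
  noise channels, larger than a third channel's true marginal gain), so the
  recovery property is checked on a construction where it is identifiable:
  signal confined to the central trio with near-uniform weights (±3 µV at
  700 ms; MOD negative, NOX positive, INNO silent), 24 blocks per condition
  (360 trials) of short 1 s trains, white sensor noise. The default-session
  selection is still computed and reported by the pipeline, it is just not a
  pass/fail property there.
* **Statistics**: the Kolmogorov–Smirnov normality check standardises the
  sample and uses the standard KS null (no Lilliefors correction — the
  plain one-sample test is the stated procedure); Mann–Whitney uses midrank
  ties with continuity-corrected normal approximation; Kruskal–Wallis uses
  the tie-corrected H with a chi-square null, returning H = 0, p = 1 on
  all-identical input; the post-hoc is Tukey HSD applied to the pooled
  rank-transformed data (respecting the nonparametric omnibus), with
  raw-scale Tukey behind `use_ranks=False`. The pipeline's group samples are
  per-trial window maxima at a chosen channel for the three conditions plus
  a pre-stimulus background window.
* **Peak detection** ties resolve to the earliest latency, then the lowest
  channel index, so reports are reproducible.

## Reproducibility

`GeneratorConfig.seed` fixes every random draw; schedule and noise use
separate streams spawned from the seed so the schedule is stable under noise
changes. Cross-validation, splits and the SVM grid derive their shuffles
from the pipeline seed. Re-running a `PipelineConfig` reproduces reports
byte-for-byte (asserted); the report manifest records a hash of the config.
EDF output quantises to 16 bits over the session's physical range
(quantisation ≤ range/65534, asserted on round-trip through MNE's reader).

## Problem sizes

The test suite and the acceptance script evaluate the decoding twin on 20
generator seeds of the default 60-trial session, the selection benchmark on
20 seeds of the 360-trial construction, chance level with 10,000 label
permutations, scheduler jitter with 10,000 delay draws, and the
Kruskal–Wallis type-I rate with 1,000 null replicates of n = 20 groups —
sizes at which every asserted margin is several standard errors wide.

## Known limitations

Greedy selection on realistically small sessions is noise-limited (see
above); the benchmark quantifies the property, not the 60-trial case. The
steady-state repetition assumption is the strongest modelling idealisation —
real sustained responses adapt. GFP comparisons are planted-amplitude
driven; with other template settings the NOX > MOD > INNO ordering need not
hold. The EDF writer covers the single-rate, single-record-duration case
used here, not the full format.
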