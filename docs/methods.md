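# Methods

This note documents the models, numerical conventions, and design choices
behind `thermoeeg`, and what the synthetic-data generator does and does not
emulate.

## Experimental design being modelled

Five thermal stimuli on the right hand, grouped by intensity: NOX (very
cold, very hot), MOD (cold, hot), INNO (warm). Two sessions per subject:
day 1 delivers very hot / hot / warm (10 trials each, 30 trials), day 2
very cold / cold (20 trials). Each trial is 10 s baseline + 30 s
stimulation at 512 Hz over 64 channels (5% 10-10 montage); trial order is a
seeded uniform shuffle. A supplementary 10-trial dual-stimulation block
exists in the design total (60 recorded trials) but is out of analysis
scope; the analyzed set is 50 trials. Subjective discomfort per condition
(0–9 scale, mean ± SD): very cold 6.6 ± 0.48, very hot 5.9 ± 0.83, cold
4.5 ± 0.5, hot 3.9 ± 0.3, warm 2.6 ± 0.48.

## Synthetic EEG generator

The generator produces continuous sessions with exactly the statistical
structure the analyses assume, so recovery of every injected parameter can
be asserted.

**Background.** Per-channel 1/f (pink) noise, default broadband RMS 5 µV,
exponent 1, built by spectral shaping of white noise. On top, an ongoing
8–12 Hz alpha rhythm (narrowband-filtered Gaussian noise) with a
posterior-dominant spatial weight map (occipital 1.0, parietal 0.8,
central/temporal 0.6, frontal 0.15) and RMS 15 µV at unit weight. These
amplitudes are realistic for scalp EEG and keep the noise floor well below
the 100 µV rejection threshold.

**ERD realization.** During each stimulation window the alpha component at
channel c is multiplied by `sqrt(1 − f·w_c)`, where `f` is the condition's
ERD fraction and `w_c` the ERD site weight (contralateral-central channels
C3/C5/C1/CP3/CP5 at 1.0, other central 0.4, posterior 0.2). The square
root is deliberate: the ground-truth fraction `f` is defined on the *power*
scale, so the measured index `(P_base − P_stim)/P_base` at a unit-weight
channel recovers `f` directly. Default fractions increase strictly with
discomfort — warm 0.05, hot 0.25, cold 0.35, very hot 0.55, very cold
0.65 — which makes the alpha-power-versus-discomfort correlation negative
by construction and gives the decoders a realistic effect to find. These
fractions are the generator's calibration; they are fixed, not tuned per
experiment.

**Evoked transients.** Each stimulus onset adds a Gaussian-windowed
(σ = 80 ms) cosine pulse (4 Hz carrier, hence biphasic side lobes) centred
at the condition's latency — 0.30 / 0.45 / 0.65 / 0.95 / 0.80 s for very
cold / very hot / hot / cold / warm — with peak amplitude at Cz ordered by
discomfort (2.5–8 µV) and a fixed spatial spread (peak channel 1.0, same
electrode row 0.45, elsewhere 0.15). Latencies are realized at the nearest
sample (0.30 s → sample 154 at 512 Hz, i.e. 0.3008 s); "exact recovery"
throughout the tests means agreement at sample precision.

**Artifacts.** Two kinds, Poisson-placed per trial (default 0.1/trial
each), with a complete ground-truth table: high-amplitude excursions
(Gaussian bump, 150–300 µV, σ = 20 ms — low-frequency, so it survives the
band-pass and trips the 100 µV rule) and EMG bursts (120–180 Hz carrier,
1.5–5 mV, σ = 50 ms — above the 70 Hz band-pass edge, so it is invisible
in the filtered data and must be caught by the raw-data EMG criterion).
The carrier floor of 120 Hz is chosen so that the band-pass residue of the
largest burst stays below the 100 µV amplitude threshold, keeping the two
rejection criteria synthetically disjoint.

**Ratings.** Truncated normal on [0, 9] with the condition's mean/SD,
rounded to integer scores (the sensation scale is discrete). With the
published SDs the rounding bias is < 0.01 rating units.

**What the generator does not emulate.** Real scalp topographies and volume
conduction (channels are spatially independent noise plus deterministic
weight maps), anticipatory pre-stimulus activity, source-space dynamics,
eye/movement artifacts beyond the two injected kinds, and between-subject
variability. Passing tests therefore demonstrate correctness of the
pipeline's computations and recoverability under the assumed effect model,
not claims about real recordings; the published human accuracies are not
reproduction targets.

## Preprocessing conventions

* Band-pass: order-4 Butterworth, 0.5–70 Hz, as second-order sections,
  applied forward-backward (zero phase) by default. Peak latencies are
  analyzed to tens of milliseconds, and a causal pass would bias them; the
  causal single-pass variant remains available via
  `FilterConfig(zero_phase=False)`. Normalized corner frequencies are
  reported as fractions of Nyquist, truncated to 4 (low) / 3 (high)
  decimals: (0.0019, 0.273) at 512 Hz.
* Notch: second-order IIR at 50 Hz, quality factor 30.
* Epochs: half-open windows relative to stimulus onset, 0-based sample
  indexing, length `round((end − start)·fs)`; the default analysis epoch is
  [0, 3) s and the baseline [−3, 0) s, extracted by the same operation.
* Baseline correction subtracts the per-trial, per-channel pre-stimulus
  mean.
* Rejection: an epoch is dropped if any absolute sample of the filtered
  data exceeds 100 µV ("beyond 100 µV" read as per-sample absolute
  amplitude, the common threshold semantics), else flagged as EMG and
  dropped if the 50–200 Hz band-limited component of the matching *raw*
  epoch has peak amplitude within 1–10 mV. The EMG check needs raw data
  because the EMG band lies above the band-pass edge. The criterion is
  automated here; interactive visual review is out of scope. Whether the
  amplitude rule applies before or after filtering is configurable; after
  is the default.

## Spectral and spatio-temporal analysis

* Band power: Welch PSD with 1-s Hann segments and 50% overlap (fixed in
  config for reproducibility), integrated over the band by the trapezoid
  rule, averaged over trials. Units µV².
* ERD index `(base − stim)/base`; a zero-power baseline yields a missing
  value rather than an error.
* GFP is implemented as the population standard deviation of the
  potentials across electrodes at each time point. (A literal reading of
  one common typesetting of the formula — the division by N placed outside
  the square root — contradicts that verbal definition; the verbal
  definition is what is computed here.)
* Peak detection maximizes *absolute* amplitude in the search window
  (polarity handling is otherwise ambiguous); ties break toward the
  earliest latency, then the channel order. Cross-checked in the tests
  against MNE's `get_peak`.
* Which contralateral-central subset enters the discomfort correlation is
  configurable; the default is the five-channel set above.

## Decoding chain

Order of operations: crop augmentation → CSP log-variance features →
PCA(2) → LDA.

* Crops: offsets 0, stride, 2·stride, … while the window fits; the default
  window = stride = 3 s tiles a 30-s trial into exactly 10 crops (500 from
  50 trials). The crop length is fixed at 3 s to match the augmented trial
  length used throughout.
* CSP: class covariances are per-crop spatial covariances, trace-normalized
  and averaged, shrunk by `(1−s)·C + s·(tr C/n)·I` (default s = 1e-4; the
  generalized eigenproblem is otherwise sensitive to rank deficiency).
  Filters solve `Ca w = λ (Ca+Cb) w`; the `n_pairs` filters with the
  largest and smallest eigenvalues are kept, extremes first. Default
  n_pairs = 2 (4 features) — the filter count is a free choice here.
* PCA uses a deterministic sign convention (largest-magnitude loading
  positive).
* Evaluation: 80/20 stratified split, then stratified k-fold CV (k = 10 by
  default) on the training side; LDA refitted per fold. Because crops of
  one trial are strongly dependent, splits are **group-aware by parent
  trial** by default — naive per-crop stratification leaks trial identity
  across the boundary and inflates accuracy; it remains available
  (`group_aware=False`) for comparison with the naive protocol. CSP and
  PCA are refitted inside every fold (`csp_per_fold=True`) so no spatial
  filter sees its validation or test crops; fitting once on the full
  training split is switchable. When the rarest class has fewer parent
  trials than the requested fold count, the fold count is capped so every
  fold retains both classes.
* Only binary contrasts are decoded (the five study pairs); multi-class
  decoding is explicitly not attempted.

## Statistics

Normality via one-sample KS against a normal with the sample's estimated
mean/SD. Estimating the parameters from the same sample makes the plain KS
p-value conservative; the Lilliefors-corrected variant is available and is
the more powerful choice, but the plain test is the default reported one.
Mann–Whitney U is two-sided with tie correction. Kruskal–Wallis refers H
to a chi-square distribution; with exactly two groups the call routes to
the U test. The post-hoc is a Dunn-style pairwise z-test on pooled ranks
with tie correction and **no** multiple-comparison adjustment; a
Tukey-HSD-on-ranks variant is switchable because the two descriptions of
the original procedure are mutually inconsistent, and neither variant is
claimed as canonical. Significance threshold 0.05 throughout.

## Robot skin

Contact profiles are modelled as exponential relaxation from ambient
(28 °C, the recording-room temperature) toward the object temperature,
with per-sensor time constants (0.8 s and 1.15× that) and 0.05 °C Gaussian
sensor noise at 250 Hz; a 3-s contact window gives 750 samples per sensor.
Features are computed per sensor channel and concatenated (2 × 7). SSC and
WA thresholds default to 0.01 °C, the sensor-noise scale. QLDA is
quadratic discriminant analysis with per-class covariance regularization
(`reg_param = 0.5`; with 14 features and few training profiles per class
the per-class covariances are otherwise singular). Temperatures falling in
the gaps between the printed bins map to the nearest bin boundary and are
flaggable (`in_gap`); an `unresolved` policy returns no label instead. The
drift option of the dataset generator (objects equilibrating toward
ambient over a session) reproduces the characteristic confusion of very
cold/very hot with cold/hot. The real-time robot loop is reduced to the
pure withdrawal-policy function (NOX → fast, MOD → slow, INNO → delayed);
hardware control is out of scope.

## I/O and reproducibility

EDF was chosen as the interchange format (the original acquisition format
is proprietary); the writer is a minimal in-package plain-EDF implementation
(16-bit, 1-s records, per-channel symmetric physical scaling, ~0.01%
quantization), read back via MNE. Events, ratings, and artifact ground
truth travel in CSV sidecars. A documented columnar text dialect is the
fallback format. The acquisition reference electrode label is stored but
no re-referencing is applied by default (the original reference handling
is ambiguous). All result JSON uses fixed 9-significant-digit float
formatting so determinism checks are byte-level, and every artifact
carries the configuration hash.

## Problem sizes

The verification suite uses the full study geometry (64 channels, 512 Hz,
40-s trials). Reduced trial counts appear where the quantity under test
does not depend on them: ERD recovery uses 5 trials per condition,
noise-free peak recovery 2 per condition, and the end-to-end NOX-vs-INNO
decoding uses two-condition sessions (very hot vs warm, 10 trials each —
the same contrast without simulating the unused third condition), averaged
over 10 seeds. The Kruskal–Wallis type-I calibration uses 5000 null
simulations with three groups of n = 10. The discomfort correlation uses
the full 50-trial two-session design.
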