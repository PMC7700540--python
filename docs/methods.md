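# Methods

## Problem and model

`harkit` classifies short windows of triaxial inertial data
(accelerometer, gyroscope or magnetometer, worn at the wrist, chest,
thigh, waist or pocket) into activity labels. The model has four
stages: signal denoising, windowed multi-fused feature extraction,
genetic-algorithm (GA) feature reweighting/selection, and nearest
weighted-template classification. The working assumptions are that
activities of interest are quasi-periodic over a window of a couple of
seconds (gait-band frequencies roughly 0.5–4 Hz), that impulsive
artifacts from abrupt movements are short (1–2 samples) and so are
removable by an order-3 median filter, and that a fixed per-class
feature centroid is an adequate class summary — i.e. classes are
unimodal in the selected feature space.

## Preprocessing

Order of operations: third-order median filter → moving average →
min–max normalization → framing. Both filters use edge replication, so
output length equals input length and neither filter can widen the
per-axis range. The moving average is centered by default, which has
zero group delay; the causal variant delays by (width−1)/2 samples and
`compensate_delay` advances by exactly that amount (with the centered
default, compensation is the identity, kept as an explicit pipeline
step). Signal normalization maps each axis affinely to [0, 1] using
stored training extremes, clamping out-of-range test values; a
constant axis maps to zeros with a warning rather than raising,
because dead channels occur in practice and should not abort a run.
Normalization is per-stream (each stream's own extremes on the
training pass); per-window normalization would destroy inter-window
amplitude information that the magnitude features rely on.

Framing: window length W = round(window_seconds · rate), step =
max(1, floor(W·(1−overlap))), trailing partial window discarded.
Default window 2.0 s (200 samples at the 100 Hz default rate): at
least one full period of every gait-band activity. Default overlap
0.6, the setting the sweep utilities treat as the operating point.

## Feature bank

Per axis: mean, median, 10-bin histogram mode (leftmost bin on ties;
the bin center is reported), sample standard deviation and variance
(n−1 denominator; length-1 input is an error), min, max, negative and
positive peaks, zero-crossing rate, signal energy (mean square),
fundamental frequency, phase angle, spectral entropy, and nine
Hilbert–Huang values. Per frame: mean vector magnitude
mean_i √(x_i²+y_i²+z_i²), signal magnitude area, and the three
pairwise Pearson correlations (0 with a warning when an axis is
constant). Total: 3·23 + 5 = 74 values, 22 distinct feature kinds.

Conventions that needed a decision:

- **Peaks** are gated by linear-interpolation ("type 7") quartiles:
  negative peak = min over samples strictly below Q1, positive peak =
  max over samples strictly above Q3, falling back to the global
  min/max when a subset is empty (constant windows).
- **ZCR** is computed on the mean-removed series. After min–max
  normalization every value is non-negative, so the raw crossing count
  would be identically zero; mean removal restores the
  negative-to-positive interchange the feature is meant to measure.
  Zero samples are skipped when pairing signs; the count is divided by
  W−1, so the value lies in [0, 1].
- **SMA** is kept as the literal signed triple sum divided by W (so
  the scale is window-length invariant); the common absolute-value
  variant is available via `sma_absolute`.
- **Fundamental frequency** is the Hann-periodogram argmax excluding
  the DC bin; **phase angle** is the argument of the raw FFT
  coefficient at that bin. A constant series returns 0 for both by
  convention.
- **Spectral entropy** is Shannon entropy of the PSD normalized over a
  band, divided by log of the band's bin count, hence in [0, 1] (0 =
  single-line spectrum, 1 = flat). The default band is (0, Nyquist],
  excluding DC. Zero-power bins contribute nothing; an all-zero
  series returns 0 with a warning.
- **EMD** uses standard sifting: cubic-spline envelopes through
  interior extrema with two extrema mirrored at each boundary,
  envelope-mean subtraction, Cauchy SD stopping criterion < 0.2 or 10
  sifts per IMF, at most 8 IMFs, decomposition stopping when the
  residue has fewer than two maxima or minima. The residue is the
  exact remainder, so IMFs + residue reconstruct the input to machine
  precision. These are the canonical published constants.
- **HHT descriptors**: for each of the first 3 IMFs (zero-filled when
  fewer exist) the energy fraction relative to the input signal, the
  mean analytic-signal amplitude, and the mean instantaneous frequency
  from the unwrapped phase difference, averaged over interior samples
  only (10% margin per side) to suppress Hilbert edge effects.
- Group tags: ZCR, spectral entropy and the HHT descriptors are tagged
  *acoustic*; fundamental frequency and phase *frequency*; the rest
  *time*. Tags affect only reporting, not computation.

Before selection, the feature table itself is min–max normalized with
per-column training extremes (clamped on test data). The feature bank
mixes units — Hz, radians, squared amplitudes — and both the GA
reweighting and cosine template matching presuppose commensurate
column scales; column-wise extremes normalization is the same
"normalize with extremes" device used on the raw signal, applied at
the feature level.

## GA feature selection

A chromosome is a continuous weight vector in [0, 1]ᵖ (not a
bitstring: the retained-weight reports are fractional, and the
classifier consumes weighted features). Fitness: reweight the table,
stratified 80/20 split of the training partition, train a linear SVM
(C = 1) and a random forest (100 trees, fixed seed) on the 80%, score
both on the 20%, average the two accuracies. All chromosomes in one
run share the same seeded split so fitnesses are comparable; fitness
evaluations are cached by genome.

Defaults: population 30, at most 50 generations, tournament size 3,
crossover probability 0.8, mutation rate 0.05, one elite, stop after
10 generations without improvement. Only the mutation rate is
method-inherent; the rest are standard GA practice. Selection after
evolution retains features whose weight is at or above the mean weight
(at least one feature is always retained).

`GAFeatureSelector` wraps this as a scikit-learn transformer
(`fit` evolves, `transform` reweights and restricts to the retained
columns), so the full method composes with sklearn pipelines and model
selection.

## Template matching

One template per class: the elementwise mean of the class's reweighted
retained training vectors. Prediction is argmax similarity; cosine by
default, with negative Euclidean distance substituted when either
vector is all-zero (cosine undefined), and a `euclidean` mode that
makes the classifier exactly nearest-centroid. Ties go to the earliest
class in training-label order. The chromosome evolved during feature
selection supplies the matching weights; no second GA run is performed
by default.

## Synthetic data

Each activity class is, per axis a: gravity offset g_a + amplitude
A_a · Σ_k r_k sin(2π k f t + φ_a) + Gaussian noise + Poisson-timed
±spikes, with fixed axis phases (0, 2π/3, 4π/3). The shipped 6-class
preset spans base frequencies 0.8–2.8 Hz in 0.4 Hz steps (sit-like,
stand-like, ascend-like, descend-like, walk-like, jog-like) with
distinct amplitudes and orientations but overlapping noise levels —
chosen to be learnable but not trivially separable. Spikes emulate the
impulsive artifacts the median filter exists to remove. Deterministic
given a seed; per-class sub-seeds are spawned from the dataset seed so
adding a class never perturbs another. The generator makes no attempt
at biomechanical realism: no orientation drift, no within-class
frequency variability, no sensor saturation. Passing tests therefore
demonstrate that the pipeline machinery recovers known structure under
controlled conditions, not field performance on real recordings.

## Evaluation

Per-class accuracy is recall (confusion diagonal over row sum), the
only reading under which a per-class "accuracy" column and its mean
are both well-defined. The macro mean is truncated toward zero to two
decimals; truncation (not rounding) is the convention the
report-arithmetic checks validate against the published tables bundled
in `harkit.refdata`. `truncate2` pre-rounds at the 6th decimal of the
shifted value to keep binary-float representations (90.16999…) from
losing a hundredth. Splits: stratified-by-windows at fraction 0.7 by
default; a leave-subjects-out protocol is provided for realistic
subject-independent evaluation. Window-level stratified splitting of
overlapped windows leaks correlated samples between train and test and
so flatters absolute accuracies; it is kept as the default because it
is the conventional desk-scale protocol, with the subject-level
alternative one flag away.

## Problem sizes in the checks

The test suite and the acceptance script run the full-scale synthetic
experiment (6 classes × 200 windows at 60% overlap, ≈ 16,000 samples
per class; GA at its package defaults) for the end-to-end recognition
check, and deliberately smaller configurations elsewhere: the
brute-force feature oracle uses 128-sample windows (the naive O(n²)
DFT oracle dominates the cost), and the GA-mechanics property checks
(elitism monotonicity, informative-column recovery) use reduced
populations, generation counts and forest sizes, since the properties
they assert are invariants of the algorithm rather than of a problem
size.

## Known limitations

- EMD is sensitive to its envelope and boundary conventions; this
  implementation fixes one canonical set and checks itself against an
  independently coded sifting loop, but other EMD codes will produce
  numerically different IMFs.
- The GA fitness can saturate on easily separable data (both
  classifiers at 100%), in which case evolution has no gradient and
  the returned chromosome is essentially the best of the initial
  random population. The template matcher tolerates this because the
  normalized feature table keeps random reweightings informative.
- Even unsaturated, the fitness is one stratified 80/20 split, so its
  resolution is 1/(validation size) and its value is noisy; on small
  tables the weight gap between genuinely informative and noise
  columns is weak and varies with the seed. The acceptance script
  therefore reports that gap as a mean over several trials.
- Cosine matching with one template per class cannot represent
  multi-modal classes; the sklearn baselines are the fallback there.
- Streams with non-uniform sampling are split at large timestamp gaps
  rather than resampled.
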