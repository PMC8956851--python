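# Methods

## Model

The learner is a stack of L Fisher discriminant layers with sigmoid
activations. For input vectors x_i ∈ R^d with class labels y_i ∈ {1..C}
(class j has m_j samples, mean μ_j; μ is the overall sample mean), each
layer computes

- within-class scatter Σ_intra = Σ_j Σ_{x_i∈C_j} (x_i−μ_j)(x_i−μ_j)ᵀ,
- between-class scatter Σ_inter = Σ_j m_j (μ_j−μ)(μ_j−μ)ᵀ,

and maximizes the Rayleigh coefficient J(φ) = φᵀΣ_inter φ / φᵀΣ_intra φ
via the symmetric-definite generalized eigenproblem
Σ_inter φ = λ (Σ_intra + εI) φ (solved with `scipy.linalg.eigh`). Σ_inter
has rank at most C−1, so a layer keeps the C−1 leading eigenvectors;
projections x̂ = Φᵀx pass through the logistic sigmoid. Layer l ≥ 2
receives the stacking vector z^l = [x ; x̌^{l−1}] (original input plus the
previous layer's activated output, width d + (C−1) — not the previous
stacked vector, so deep-layer width does not grow with depth). The final
feature concatenates every layer's activated output (length L(C−1)).
Fitting is greedy/feed-forward — no global refit — which gives the prefix
property: a depth-L model's first L−1 layers are bit-identical to the
depth-(L−1) fit.

Two conventions in the scatter definitions are genuinely open, and both
are exposed as options:

- **Between-class weighting.** The count-weighted form (default,
  `between_class_weighting="count"`) makes Σ_intra + Σ_inter equal the
  total scatter Σ_i (x_i−μ)(x_i−μ)ᵀ exactly — an identity the test suite
  checks at 1e−8 relative tolerance. An unweighted variant (`"uniform"`)
  drops the m_j factor.
- **Total mean.** μ is always the ordinary sample mean (1/N)Σx_i, the
  only choice consistent with the conservation identity for both
  weightings.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `depth` (L) | 3 | number of stacked layers; selectable by `select_depth` |
| `n_components` | C−1 | per-layer output width (rank bound of Σ_inter) |
| `ridge` (ε) | 1e−6 · tr(Σ_intra)/d | Tikhonov term keeping Σ_intra invertible when n < d (rank-deficient within-class scatter); negligible relative to the data scale otherwise |
| `between_class_weighting` | `count` | see above |
| NN `k` / metric | 1 / Euclidean | the classification stage; both configurable |

Depth selection grows the stack to `max_depth` (default cap 5), scores
each prefix with the full downstream 1-NN classifier on a
subject-disjoint validation split, and returns the smallest depth whose
accuracy the next depth does not exceed. The selection metric is
validation *accuracy* of the end classifier — the quantity the pipeline
ultimately reports. Validation must be subject-disjoint from training;
overlapping subject IDs raise a protocol error rather than silently
optimizing on seen users. On very easy data (large class separation)
depth 1 already saturates and the heuristic legitimately returns 1.

## Numerical choices

- Eigenvectors are unit-normalized, ordered by descending eigenvalue, and
  sign-fixed so each column's largest-magnitude entry is positive; exact
  eigenvalue ties are ordered lexicographically. This makes fitted models
  (and their serialized archives) deterministic across runs.
- The generalized eigensolve is checked by tests against a brute-force
  per-sample-loop implementation (eig of Σ_intra⁻¹Σ_inter), against the
  two-class closed form Σ_w⁻¹(μ₁−μ₂), and against a 0.1°-resolution grid
  search of the Rayleigh quotient.
- Scatter matrices are explicitly symmetrized (½(M+Mᵀ)) to remove
  accumulation round-off before the solver sees them.
- 1-NN distance ties break by smallest reference row index; k>1 vote ties
  by smallest class label.
- Feature files are written with 8 significant digits (`%.8g`), keeping
  write/read round-trip error below every tolerance used in the pipeline.
- No input standardization is applied by default: the expected inputs are
  feature vectors already normalized to [−1, 1]. Raw feature banks should
  be z-scored by the caller (the signal-pipeline test does exactly this).

## Evaluation protocol and metrics

`subject_independent_split` partitions *subjects* by a seeded shuffle
(round(0.7·S) train subjects by default; 30 subjects → 21/9) and raises a
protocol error if either side loses a class entirely. `evaluate` reports
the confusion matrix (rows = true), accuracy, and per-class one-vs-rest
TP rate (= recall), FP rate, precision, F-score and rank-based ROC AUC
(from the NN classifier's negated nearest-distance scores). Because
published HAR tables rarely state their averaging convention, macro
(unweighted), micro and support-weighted averages are all computed; the
macro values are the headline numbers. Metrics undefined for a class
(zero support or zero predictions) are NaN and excluded from macro
averages with a warning.

## Synthetic data

`generate_gaussian_features` draws C class means on a regular simplex
with edge length `separation` (in units of the identity within-class
standard deviation), embedded at a seeded random orientation, and adds a
per-subject offset vector of scale `subject_shift` — a covariate-shift
model of the observation that different people produce systematically
different signals for the same activity. Defaults (C=6, 30 subjects,
separation 10, subject_shift 0.1, 10 samples per subject per class,
d=20) define the study conditions used throughout the tests and the
acceptance script; d=20 keeps the default runs fast while the scale test
separately exercises the realistic 7,380×561 regime. Randomness flows
from one root seed through one child stream per subject, so enlarging
the cohort never perturbs existing subjects' data.

`generate_activity_signals` produces raw windows instead: each activity
is a per-axis sinusoid template (dynamic activities differ in gait
frequency and amplitude) or a constant orientation vector (static
postures load gravity on different axes), modulated by a subject-specific
gain and phase plus white noise. What these generators do *not* emulate:
real gait harmonics and transients, sensor drift and saturation,
activity-dependent noise, or label noise — so passing tests demonstrate
correctness and protocol behaviour of the pipeline, not field performance
on real recordings.

## Feature bank

`extract_window_features` computes, per axis and per axis-group magnitude
signal: mean, standard deviation, median absolute value, max, min,
energy (mean square), interquartile range, signal entropy, AR
coefficients, and spectral descriptors (dominant-frequency bin index,
power-weighted mean frequency in Hz, skewness/kurtosis of the magnitude
spectrum, band energies); per axis group: signal magnitude area, pairwise
Pearson correlations, and the angle between the mean window vector and a
reference gravity direction. Choices the field leaves open and this
implementation fixes (all configurable): entropy uses a 16-equal-width-bin
histogram of |x| with natural log; AR coefficients are least-squares fits
of order 4; band energies split [0, Nyquist] into 4 equal bins; the angle
reference is the unit z axis of each group. This bank is deliberately
approximate: it makes the pipeline runnable end-to-end from waveforms but
does not reproduce any specific public dataset's 561-feature expansion,
ordering or filtering (no Butterworth gravity separation, no jerk
signals).

## Limitations

- The stack is linear-then-sigmoid per layer; kernelized or sparse
  discriminant variants and any jointly optimized (backpropagated) stack
  are out of scope.
- Scatter matrices are d_l×d_l; very high-dimensional inputs (d ≫ 10⁴)
  would need a different formulation.
- AUC from 1-NN distances is a surrogate: nearest-distance scores are not
  calibrated probabilities.
- Published accuracies on real benchmark recordings depend on the exact
  official feature expansion and split; this package reproduces the
  method and protocol, and its acceptance script measures performance on
  its own generated conditions.
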