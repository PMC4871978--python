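# Methods

## Model and training

`wkelm` treats PD screening from voice measurements as binary classification
with an Extreme Learning Machine: the hidden representation is fixed (a
kernel or random features) and the output weights are the solution of one
regularised least-squares problem, so training is a single linear solve.

Labels are encoded +1 (PD, the declared positive class) and −1 (healthy);
prediction thresholds the real-valued score at 0, with ties going to the
positive class. Features are z-scored with statistics estimated **on the
training split only** — the 22 voice features span five orders of magnitude
(fundamental frequency ~10² Hz vs. absolute jitter ~10⁻⁵), and any
distance-based kernel would otherwise be dominated by the frequency columns.
Constant training columns get sd = 1 so they map to zeros rather than
dividing by zero.

Three variants:

- **full_kernel** — (I/E + D) S = C with D the training kernel matrix. The
  system is solved with a symmetric LAPACK solver; if it is singular or
  ill-conditioned the code falls back to least squares and logs a warning.
  No explicit matrix inverse is formed anywhere.
- **center_subset** — K centers drawn from the training rows by a seeded
  shuffle; S = Aᵀ(I/E + AAᵀ)⁻¹C with Aᵢₖ = b(xᵢ, cₖ). Note this is a
  genuinely different estimator from full_kernel even at K = N with all rows
  as centers (there A = D and the scores become k·D(I/E + D²)⁻¹C rather than
  k·(I/E + D)⁻¹C; equality would require D = I). We keep the printed
  regularised-ELM form rather than the RKHS-penalised variant that would
  coincide with full_kernel at K = N, because the neuron count K is exactly
  what the genetic algorithm tunes.
- **random_feature** — classic ELM baseline: input weights and biases drawn
  uniform(−1, 1) from a seeded generator, hidden matrix H = f(Xl + b),
  β = pinv(H) C. Activations: sigmoid = logistic, tangent sigmoid = tanh,
  triangular basis = max(0, 1 − |z|), radial basis = exp(−z²), hard limit =
  step at 0.

**Regulation coefficient E** (default 1.0, dimensionless, > 0): the ridge
constant; larger E means weaker regularisation and, on fixed training data, a
non-decreasing training accuracy (checked as a property test). E = 1 is a
neutral default on z-scored data; it is exposed everywhere.

## The wavelet kernel

The default kernel is the three-parameter translation-invariant wavelet
kernel b(r, g) = cos(w·d/x)·exp(−d²/y) with d = ‖r − g‖ (Euclidean; no other
metric is supported). It is bounded in [−1, 1], symmetric, and equals 1 at
d = 0, but it is **not guaranteed positive semidefinite** in this norm-based
form; the solvers therefore never assume PSD-ness (hence the least-squares
fallback). A per-dimension product form
∏ₖ cos(w·δₖ/x)·exp(−δₖ²/y) is available via `KernelSpec(form="product")` for
users who want a provably PSD tensor-product kernel; the norm form is the
default because it uses each of w, x, y exactly once and is the standard
three-parameter family.

Default parameters w=1, x=16, y=16 were chosen for z-scored inputs of ~22
features, where the typical squared distance between two random rows is
about twice the dimension (≈ 44): y = 16 keeps exp(−d²/y) informative rather
than numerically zero, and x = 16 makes the cosine factor slowly varying, so
the default behaves like a mildly oscillatory Gaussian kernel. The GA search
range [1, 16]³ contains these defaults.

## Genetic algorithm

Hyperparameters (w, x, y, K) are encoded in a 20-bit chromosome: three 4-bit
fields (offset binary, MSB first: 0000→1 … 1111→16) and one 8-bit field
(00000000→5 … 11111111→260). Fitness is the training accuracy of the
center-subset WK-ELM decoded from the chromosome (K capped at the number of
training rows); a failed fit scores 0 with a warning rather than aborting the
search. The loop is generational: fitness-proportionate roulette selection
(uniform fallback when all fitnesses are 0), single-point crossover at a
uniform cut in [1, 19] with probability 0.8, independent per-bit mutation
with probability 0.02, and one elite copied unchanged — which makes the
best-fitness history provably non-decreasing. Defaults: population 40,
50 generations, optional stall-based early stop. Fitness ties are broken
toward fewer neurons, then the lexicographically smaller bit string, keeping
the cheapest model. Fitness values are cached per bit string, so total model
fits never exceed population × (generations + 1). Crossover/mutation rates,
the generation budget and elitism are package choices: standard textbook
values for a 20-bit binary GA, exposed in `GAConfig`.

Training-set accuracy is used as the fitness literally; it can saturate at
1.0 on separable data, after which selection pressure comes only from the
tie-breaks. The leakage-safe way to *evaluate* a GA-tuned model is to rerun
the search inside every training split (`wkelm evaluate --ga`); optimizing
once and freezing the parameters is also available and mimics a two-stage
workflow, but its test rates are optimistically biased.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP) and overall accuracy
(TP+TN)/N are computed from an explicit 2×2 tally with a declared positive
class (PD). A zero denominator raises an error instead of silently returning
0. The ROC curve sweeps thresholds over the distinct score values from high
to low (predict positive iff score ≥ threshold); tied scores collapse to one
point and the endpoints (0,0), (1,1) are always present. AUC is the
trapezoidal area, which equals the Mann–Whitney rank statistic
P(s₊ > s₋) + ½P(s₊ = s₋); the identity is asserted in tests and the whole
curve is cross-checked against scikit-learn's `roc_auc_score`.

`SplitPlan` expresses repeated stratified holdout (default: train fraction
2/3, 3 repeats) and k-fold cross-validation, both built on scikit-learn's
splitters; stratification is on by default because the data are ~75% PD and
small unstratified test sets can lose a class. Group-aware splitting (all
recordings of one subject on the same side of every split) is available for
tables with multiple recordings per person; per-recording splitting remains
the default. Aggregation is the arithmetic mean of the per-repeat rates at
full precision; rounding to two decimals is display-only.

## Synthetic data generator

`simulate_dataset` emulates the 22-feature schema, not any particular
recording set: lognormal fundamental frequency around 150 Hz with
Flo ≤ Fo ≤ Fhi enforced row-wise; positive lognormal jitter (5 features,
percent/absolute scales) and shimmer (6 features, dB and ratio scales)
families with a shared within-family latent correlation (default 0.7 —
jitter variants are near-collinear in real recordings); NHR lognormal with
HNR built from the negated NHR latent so the two are anticorrelated;
RPDE/DFA clipped to (0, 1); spread1 negative; D2 around 2.4; PPE lognormal.
The PD class is shifted by `effect_size` latent standard deviations on the
jitter/shimmer/PPE subset (configurable). Defaults: 192 recordings,
prevalence 0.75, effect size 1.5 — a cohort whose difficulty is comparable to
published dysphonia tables, where reported accuracies run 80–97%.

What the generator does **not** emulate: repeated recordings per subject
(rows are independent), heavy-tailed measurement outliers, instrument- or
session-level batch effects, and the real (unknown) dependence structure
between the nonlinear measures and the perturbation families. Tests passing
on this generator therefore demonstrate correctness of the machinery and
learnability of a planted signal, not clinical performance on real cohorts.

## Numerical choices and degenerate inputs

- Linear systems: `scipy.linalg.solve(..., assume_a="sym")` with a
  least-squares fallback and warning; residual of the defining system is
  asserted to ≤ 1e−8 in tests.
- Decision ties (score exactly 0) go to the positive class.
- Prevalence rounding: the PD count is `round(n·prevalence)` exactly.
- Constant features: sd set to 1 (transform to zeros).
- Missing or non-numeric cells in input CSVs are hard errors naming the row
  and column; there is no imputation.
- A training split containing a single class is an error naming the repeat.

## Known limitations

- Binary classification only; no multiclass, regression, or online variants.
- The wavelet kernel's indefiniteness means the full-kernel system can in
  principle be singular; the fallback handles it but the model is then a
  least-squares compromise rather than the exact closed form.
- GA fitness on the training split rewards interpolation; with large E it
  will happily pick kernels that memorise. Use the protocol runner (or the
  `--ga` evaluation mode) for honest estimates.
- Serialized models store reference points verbatim; for the full-kernel
  variant that is the whole (standardized) training set.
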