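# Methods

This note records the models, algorithmic conventions and numerical
choices behind the package, and what its synthetic experiments do and do
not demonstrate.

## Data model and preprocessing

An `ExpressionDataset` is a samples × features matrix of nonnegative
expression values with one designated numeric target and a forward-only
provenance stage (`raw → filtered → denoised → scaled`). Missing values
are an error, not imputed.

**Presence filter.** Features with zero expression in every sample are
removed. Samples with a zero target are reported as warnings but never
dropped — sample removal is a study-design decision the pipeline should
not make silently.

**Low-information filter.** A feature is removed iff its third quartile
is below 2, or its mode is 0 and the mode covers more than 15% of
samples. Conventions the rule needs but that are genuinely open:

- *Quantile rule*: linear interpolation between order statistics
  (NumPy's default, "type 7"). Recorded in the filter report metadata.
- *Mode of real-valued data*: computed after rounding to 6 decimals, ties
  broken toward the smallest value. Expression tables contain exact
  zeros — the case the rule targets — so the rounding only collapses
  float round-trip noise.
- Rule precedence for reporting is Q3 first, zero-mode second.
- Both filters are idempotent, and their order is immaterial (an all-zero
  column violates both).

**Wavelet denoising.** Each feature's expression vector, in the dataset's
given row order, is denoised with a discrete Meyer wavelet: multilevel
DWT (default depth `min(4, floor(log2 n))`, periodized boundaries),
universal threshold `σ·sqrt(2 ln n)` with `σ` estimated from the median
absolute deviation of the finest detail level (MAD/0.6745), soft
thresholding of detail coefficients only.

A numerical point worth documenting: the 62-tap FIR approximation of the
Meyer wavelet that PyWavelets ships (`dmey`) violates the double-shift
orthonormality conditions by about 2·10⁻³, which caps multilevel
reconstruction accuracy near 3·10⁻³ relative error. Since a denoiser
should be exactly invertible when thresholding is off, the filter is
projected at import onto the perfect-reconstruction manifold (nearest
point by sequential quadratic programming, then a Newton polish of the
constraint residual). The projection moves no coefficient by more than
8·10⁻⁴ — the result is still a discrete Meyer FIR approximation — and
restores machine-precision round trips (~10⁻¹⁵ relative error).

**Scaling.** Features map to [−1, 1] (the logistic activation's sensitive
range), the target to [0, 1] by min–max. A mean/max variant
((x−μ)/(max−μ)), which centres the mean at 0 but does not bound the
minimum at −1 for asymmetric data, is selectable as
`method="eq2_as_printed"`; min–max is the default because the stated
[−1, 1] range is taken as the binding requirement. Scaling parameters are
stored per column for exact inversion (round trip to 10⁻¹²); constant
columns raise a named error rather than producing NaN.

**Collinearity report.** All feature pairs with |Pearson r| above a
threshold (default 0.95) are listed, advisory only — consistent with
fitting networks on the full selected subset and leaving redundancy to
the feature-mask search.

## Genome and decoding

Genomes are fixed maximum-length bit strings (`n_feature_bits + 1 + 6 +
64·10 = 746` at the defaults); decoding reads the feature mask, the
validation bit (0 = hold-out, 1 = k-fold), the hidden-layer count
(`int(6 bits)+1`) and the first L node fields (`int(10 bits)+1` each).
Numeric fields are most-significant-bit first; the choice is arbitrary
but cross-implementation reproducibility depends on it, so it is fixed
and tested. Variation operators act on the full string including the
inactive node-field tail — neutral genetic material that keeps the
operators closed over fixed-length strings — while decoding ignores it.
Randomly created genomes are repaired to a non-empty feature mask; if
variation later produces an empty mask the phenotype is marked infeasible
and assigned the worst-fitness sentinel (10⁹, far above any achievable
MSE on a [0, 1] target) rather than silently repaired.

## Networks and training

The MLP uses logistic (σ(t)=1/(1+e⁻ᵗ)) hidden layers and a single affine
output unit; weights are Glorot-uniform, biases zero. Gradients are exact
backpropagation of the mean squared error (validated against central
finite differences to 10⁻⁶ relative error up to 4 hidden layers).

- **RMSprop** (search-time trainer): per-parameter running mean of squared
  gradients with decay 0.9 and ε = 10⁻⁸ (standard values, configurable),
  batch 50, learning rate 0.01, up to 5000 epochs.
- **Early stopping**: validation MSE evaluated once per epoch; training
  stops after 10 consecutive evaluations without improvement and the
  best-validation snapshot is returned (never a worse one).
- **Dropout**: rate 0.5, applied only between the last hidden layer and
  the output, with inverted scaling at train time so inference needs no
  correction. At rate 0 the trainer is bit-identical to the no-dropout
  path.
- **Rprop+** (final-model trainer): full-batch resilient backpropagation
  with weight backtracking; step sizes multiply by η⁺ = 1.2 on gradient
  sign agreement and η⁻ = 0.5 on disagreement (clamped to
  [10⁻⁶, 50], initial 0.1), and on a sign change the previous update is
  reverted and the stored gradient zeroed. These are the canonical
  constants of the cited algorithm family.

**Fitness.** A phenotype's adaptation value is its mean *test* MSE: over
20 repetitions of a fresh random 50/25/25 train/validation/test split
(hold-out), or over k = 10 folds with 25% of each training portion held
out for early stopping (k-fold). Each repetition re-initializes and
retrains. Fitness evaluations are cached on the genome's active region,
so duplicate phenotypes never retrain; the cache key can be widened to
the full bit string for fitness functions that read raw bits (used by the
surrogate tests).

## Evolutionary loop

Generational GA: evaluate → log → copy elites → rank-select parents →
uniform crossover → mutate → replace non-elite slots.

- *Selection*: linear-rank with pressure SP = 2 (best rank probability
  2/N, worst 0). Tied fitnesses share the average probability of their
  tied ranks, so an all-equal population selects uniformly.
- *Elitism*: 10% of the population, minimum one elite whenever elitism is
  enabled — this is what makes the best-fitness trace provably
  non-increasing, which every run asserts.
- *Mutation*: the default reading of "10% mutation" is a per-individual
  trigger followed by per-bit flips at rate 1/length (expected one flip
  per mutated individual), which keeps disruption low for elitist
  convergence at full scale. A `per_bit` mode (every bit flips at the
  given rate) is selectable and is what the scaled-down experiments use,
  where the tiny budget needs more exploration per generation.
- *Stopping*: after 5 consecutive generations in which the best MSE
  improves by less than 10⁻⁴ (the "significant change" threshold is not
  externally specified; 10⁻⁴ is roughly the repetition standard error of
  the fitness at full scale), or at 100 generations, or at a hard
  evaluation budget (default 20 000 phenotype evaluations) which aborts
  gracefully with partial results.

`run_emdav` performs independent seeded executions (default 20) and
consolidates a top-10 phenotype table (generation, individual, feature
count, validation, architecture, MSE, R²) sorted ascending by MSE.

## Olden connection-weight importance

The importance of input *i* is the sum over all input→output paths of the
products of connection weights — the i-th entry of the chained product of
the weight matrices. Biases are excluded (they correspond to no input)
and activations are ignored, as in the original connection-weights idea;
the chained product is the natural multi-layer generalization of the
single-hidden-layer definition, and it is verified against brute-force
path enumeration to 10⁻¹². Signed importances from repeated Rprop+
trainings (dropout off, runs differing only by seed) are averaged per
feature first, then the features with positive mean are renormalized to
percentages summing to 100% — average-then-filter, not
filter-then-average.

## Synthetic data generator

Feature magnitudes are log-normal (meanlog 0, sdlog = `dispersion`,
default 1.5 → strongly right-skewed, as bulk small-RNA counts are),
multiplied by a Bernoulli mask of structural zeros whose per-feature rate
is drawn uniformly on [0, 2·`zero_inflation`] — so at the default mean of
0.2 some features stay nearly complete while others cross the filter's
15% zero-mode threshold, giving the filters a graded workload. A
configurable 5% of features are identically zero for the presence filter.
Informative features are kept free of structural zeros so the planted
signal is well defined. The target is
`link(Σ wᵢ·x̃ᵢ) + N(0, noise_sd)` with x̃ the informative features min–max
scaled to [−1, 1], weights alternating in sign (repression = negative)
with magnitude 1/√k by default, sigmoid link (the family the network
represents) and noise_sd = 0.05 on the ~[0, 1] response.

What this emulates: zero inflation, right skew, a sparse nonlinear signal
with mixed effect signs, filterable junk columns. What it does not:
count-specific mean–variance structure, correlated miRNA families, batch
effects, or any sequence/target-site biology. Passing the recovery
experiments therefore shows the *search and attribution machinery* work
when the generating assumptions hold — not that any particular biological
claim transfers to real tumour data.

## Scaled-down experiment sizes

The validation experiments run at desk scale; the reductions are the
package's own choices and are fixed:

- *Planted recovery*: 200 samples × 20 features, 4 informative;
  population 10, ≤10 generations, ≤2 hidden layers of ≤32 nodes, ≤200
  epochs, 3 hold-out repetitions per evaluation, per-bit mutation,
  dropout off, patience 20. Success = the best mask contains ≥3 of the 4
  planted features; expected in ≥7 of 10 seeded runs.
- *Surrogate GA check*: 12-bit genomes, fitness = number of set bits,
  compared with the exhaustive optimum over all 2¹² strings; the full
  cache is keyed on raw bits here since the surrogate reads the inactive
  tail.
- *Decoder check*: exhaustive over all 2¹⁹ genomes of a reduced layout
  (4 feature bits, 2 layer bits, 3-bit node fields) against an
  independent string-slicing decoder.
- *Filter counts*: a synthetic 1074 × 140 table with 99 features built to
  survive and 41 built to fail the low-information rules (25 by Q3, 16 by
  zero mode). This checks the decision rule at a published table shape on
  constructed data; it is not a reproduction of any real supplementary
  table.
- *Toy pipeline determinism*: 150 × 15, two executions of a population-8,
  5-generation search, 5 final Rprop+ runs; the full serialized output
  must be bit-identical across repeated runs with the same master seed.

## Known limitations

- The logistic-hidden/linear-output family and MSE loss are fixed; no
  classification heads, convolutional layers or GPU execution.
- Olden importance ignores activation nonlinearities by construction; for
  deep saturated networks the signed path products are a linearized
  attribution, best read comparatively across features.
- The "time-series" treatment of expression vectors for denoising uses
  the dataset's row order as given; with unordered samples the denoiser
  acts as a mild shrinkage whose effect depends on that arbitrary order.
- The printed mean/max feature scaling variant is kept selectable for
  fidelity but does not guarantee the [−1, 1] range; the CLI warns when
  it is chosen.
- Fitness uses test-set MSE as the adaptation value; the alternative
  (validation MSE) is a one-line change but is not the default reading.
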