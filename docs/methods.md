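# Methods

## Problem and model

A polypharmacy side effect is an adverse event attributable to a drug
*pair*. For each side effect *s* the task is binary classification of
unordered drug pairs: does (dᵢ, dⱼ) exhibit *s*? Pairs are unordered
throughout; every table and example store a pair once, with the
lexicographically smaller drug identifier first.

Each drug carries two binary profiles: mono side effects and protein
interaction partners. Both drug × feature matrices are reduced
independently and concatenated:

* **PCA reducer (default).** Columns are mean-centred but not scaled;
  the retained component count k is minimal such that the cumulative
  explained-variance fraction reaches `variance_threshold` (default 0.95).
  The decomposition is a full, deterministic SVD of the centred matrix
  (desk-scale inputs need no randomized solver), and each component's sign
  is fixed by making its largest-magnitude loading positive, so scores are
  reproducible across runs and platforms. Centring-only is the standard
  treatment of binary presence/absence data; unit-variance scaling would
  inflate near-constant columns.
* **Low-variance reducer (alternative).** Keeps the k columns of highest
  sample variance, uncentred, ties broken toward the lower column index.

PCA is fit once on the full drug matrix before any train/test split.
Features are drug-level, not pair-level, so this is the natural order of
operations, but it is a known (mild) leakage trade-off: test *pairs* share
drug representations with training pairs.

A pair's feature vector is the **sum** of the two drug rows (default),
which is symmetric in the pair by construction; concatenation ordered by
ascending drug index is available for comparison and doubles the input
width.

## Classifier

One independent feedforward network per side effect: input width =
pair-feature width, hidden layers 300/200/100 with ReLU, one sigmoid
output. Weights are Glorot-normal (σ = √(2/(fan_in+fan_out))), biases
zero. Training minimizes binary cross-entropy with mini-batch SGD
(learning rate 0.01, momentum 0.9, batch 1024, 50 epochs by default, no
early stopping, no weight decay or schedule). Choices the defaults leave
open are resolved as the common conventions: inverted dropout (rate 0.1)
after each hidden activation, active only during training; plain (not
Nesterov) momentum; the last incomplete mini-batch is used, not dropped.
Per-epoch shuffling and dropout masks come from generators keyed on
(seed, epoch), so a run is bit-reproducible from its seed.

The implementation is explicit numpy forward/backward passes. Gradients
are exact and checked against central finite differences in the tests; the
check is run at a generic point (biases nudged off zero) because an exactly
zero pre-activation sits on the ReLU kink where the two-sided difference
quotient and the one-sided derivative legitimately disagree.

## Examples, splits, threshold, metrics

Only positive pairs are observed, so negative construction is a design
choice of this package: we sample
negatives uniformly without replacement from the canonical non-self pairs
not listed for that side effect, at a 1:1 ratio by default (the convention
of the graph-based baselines this method is compared against). Examples
are shuffled once per run and partitioned into 5 near-equal parts; for
each fold the held-out part is halved into validation and test, which
realizes "80/10/10 with 5-fold cross-validation" exactly (at 100 examples:
80/10/10). With an odd held-out part, validation gets the smaller half.
Repetitions (default 10) rerun the whole procedure with fresh seeds, giving
the 50 fold-runs of the full protocol; every (side effect, repetition) is
seeded independently via `SeedSequence`, so results are independent of
execution order and of the parallelism degree (`n_jobs`).

θᵢ is selected on the *validation* split as the candidate maximizing the
F-score over {0} ∪ {observed scores}; since prediction is the strict rule
p > θ, this grid realizes every achievable prediction set, so the selected
F-score is never below the default-0.5 cutoff's. Ties go to the larger
threshold. An all-positive validation split returns θ = 0 (everything
positive, F = 1); a split with no positives has F ≡ 0, and the selection
falls back to 0.5 with a warning. Test metrics use the strict p > θ rule;
every 0/0 ratio (precision with no positive calls, MCC with a zero row or
column) is defined as 0. AUROC is the rank statistic with ties counted
half; AUPRC is step-wise average precision, not trapezoidal interpolation,
avoiding that estimator's known optimistic bias. AUROC/AUPRC/ROC curves are
computed by scikit-learn behind this module's surface and are cross-checked
in the tests against O(n²) pair-counting and explicit-summation oracles.

MLoss and MAUROC are unweighted per-epoch means over side effects of the
training loss and validation AUROC respectively. All aggregate metric
averages are likewise unweighted over side-effect reports; confusion counts
are additionally pooled (summed) and labelled separately, since averaged
metrics and pooled counts answer different questions. The reported SD of
θᵢ is the sample standard deviation (ddof = 1).

## Synthetic data

The generator emulates the *structure* of the real inputs, not their
pharmacology. Each drug gets a latent vector zᵢ ~ N(0, I) of dimension
`latent_dim` (default 8 — small against the 120 mono-effect and 60 protein
columns, as a low-rank biological signal would be). Each feature column
gets a Gaussian loading scaled so the pre-intercept logits have SD ≈ 2
(columns individually noisy but informative); the intercept is solved by
Brent's method so the realized Bernoulli density matches `feature_density`
(default 0.05, sparse like real pharmacovigilance profiles). For each side
effect a direction w is drawn and pair (i, j) is positive with probability
logistic(signal_strength · w·(zᵢ+zⱼ) + intercept): the label law acts on
the *sum* of latent vectors, so the pipeline's summation aggregation is
correctly specified for this data. The intercept targets 1.1× the
requested positive count and the draw is thinned uniformly to exactly
`positive_pairs_per_effect` (default 1,000), making dataset sizes
deterministic while each pair's inclusion stays logistic in the planted
score. `signal_strength` 0 makes labels independent of all features
(pipeline AUROC ≈ 0.5); the default 3 yields mean test AUROC ≈ 0.93 under
the default pipeline at 20 epochs.

What passing these tests shows: the implementation recovers a planted
low-rank signal through the full ingest → PCA → sum → MLP → threshold
chain, at the power the generative law predicts, and degrades to chance at
the null. What it does not show: performance on real pharmacovigilance
data, whose feature matrices are not low-rank-logistic, whose positives are
confounded and reporting-biased, and whose marginal distributions
(per-drug degree, side-effect frequencies) the generator does not imitate.

One stated surrogate was adjusted after analysis: a binary Bernoulli
matrix cannot concentrate ≥ 80% of its variance in 2 components even when
a 2-d latent fully determines the probabilities (in the noise-free limit,
halfspace-indicator columns at 5% density put ~46% of variance in the top
2 components). The parameter-recovery test instead regresses the true 2-d
latent on the top-2 PCA scores and requires R² ≥ 0.8 per dimension, which
is the recovery claim actually meant.

## Numerical choices and scale

* Loss is computed from logits via log(1+eᶻ) − yz (stable for large |z|);
  probability-side evaluation clips p to [1e-12, 1−1e-12].
* Model files store float64 at 17 significant digits, which round-trips
  bit-exactly through text.
* Negative sampling enumerates the complement of the positive set in the
  linearized upper-triangular pair index — exact uniformity without
  rejection loops; fine up to ~10⁴ drugs.
* Tests and the acceptance script run the pipeline at 200 drugs, 5 side
  effects, 2,000 examples per side effect and 20 epochs — sizes chosen so
  the planted-signal power study completes in minutes on one CPU while the
  training dynamics (few large mini-batches per epoch) mirror the
  full-scale protocol.

## Known limitations

* One network per side effect; no parameter sharing or multi-task variant.
* The hyperparameter grid is expressible through `RunConfig`, but no sweep
  driver is included.
* No identifier normalization across chemical databases, and synonym
  merging of mono side effects requires a user-supplied map; inference of
  synonyms is out of scope.
* An autoencoder reducer is not provided; the reducer interface accepts
  only `pca` and `low_variance`.
* CPU only; at real-data scale (≈10⁵ examples × 964 side effects × 50
  fold-runs) training takes hours, as expected for the full protocol.
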