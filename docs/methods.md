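# Methods

## The prediction problem

A spontaneous-report system yields, after joining case tables, a count
matrix `C` (m drugs × n side effects) of primary-suspect reports.
Thresholding at `t` turns counts into binary associations. The task is
ranking: for each side effect, order the drugs whose association status
is unknown so that true-but-unreported associations surface early. The
headline metric is the area under the precision–recall curve (PR-AUC),
averaged over a designated set of severe side effects — PR-AUC because
positives are rare and false alarms are the practical cost.

Two properties of the data shape the model. First, it is *implicit
feedback*: a zero means "no reports", not "no association", so zeros are
soft evidence. Second, association strength is graded: a pair with 500
reports is more certainly real than one with 3.

## Models

All families share `score(i,j) = d_iᵀ s_j + b_i + b_j` with factors
`D ∈ R^{m×k}`, `S ∈ R^{n×k}` and per-entity biases.

* **mf** — squared error against the binary matrix; zeros are learned as
  true zeros; all pairs weigh equally. The classic explicit-feedback
  baseline and its known weakness here.
* **logistic_mf** — sigmoid predictions, weighted log loss. The weight
  function `w = 1 + α·log(1 + c)` for `c ≥ t`, else `β ∈ (0,1]`,
  implements both data properties: log-growth in the count (each extra
  report adds less certainty) and a uniform down-weight for unobserved
  pairs. `α = 0, β = 1` recovers the unweighted log loss exactly.
  The logarithm is natural (configurable); defaults `t=3, α=10, β=0.8,
  λ=0.005` are the grid-search optima for this model class on
  FAERS-derived data.
* **fgrmf** — squared error plus `μ Σ_{i,i'} sim_{ii'}‖d_i−d_{i'}‖²`
  (ordered pairs; equivalently `2μ·tr(DᵀLD)` with the graph Laplacian L
  of the drug–drug similarity). Similarity defaults to Tanimoto on
  binary fingerprints. Bias terms are included for comparability with
  the other families.

### Penalty accounting

The L2 term is accumulated *per pair*, exactly as the loss is written:
`Σ_{(i,j)∈pairs} [err_ij + λ(‖d_i‖² + ‖s_j‖²)]`. A drug appearing in
many training pairs is therefore regularized proportionally harder
(effective per-drug strength ≈ λ·n). A conventional per-parameter
variant is available via `penalty="per_param"`; both have exact analytic
gradients (verified against central differences to 1e-5 relative error).

### Training

Full-batch Adam (β₁=0.9, β₂=0.999, ε=1e-8) on all m×n pairs per epoch —
no negative sampling; unobserved pairs are down-weighted by β instead.
Held-out positives (validation/test roles) are masked out of the loss
entirely. Initialization: factors ~ N(0, init_sd²) with `init_sd=0.1` default,
biases 0, seeded.

Early stopping and the learning-rate schedule both key off the mean
severe-set PR-AUC on validation pairs, computed each epoch. The schedule
is a plateau rule: after every `decay_patience` (default 5) consecutive
epochs without a new validation best, the rate is multiplied by
`lr_decay` (default 0.1); training stops `patience + 1` epochs after the
last improvement and the best-epoch parameters are returned. Earlier
iterations of this schedule ("decay on any epoch below the running
best", then "below the previous epoch") were measured to collapse the
rate geometrically during the noisy early transient — the validation
metric fluctuates before the factors organize — freezing training near
the initialization; the plateau form keeps the intended ×0.1-on-dip
behaviour while surviving that transient. The learning-rate sequence is
nonincreasing and every decrement is exactly ×`lr_decay`.

If a split has no validation pairs, training runs to `max_epochs` and
returns the final parameters (used for fit-to-everything diagnostics).

## Data splitting and evaluation

Drugs are split 50/50 into training and test drugs. Positive pairs of
training drugs go 80/20 into train/validation roles; positive pairs of
test drugs go 60/40 into train/test roles. In expectation 70/10/20 of
all positive pairs land in train/validation/test — exactly so when every
drug has the same number of positives. The point of the drug-level
design: cold-start deletion can remove a *test* drug's training history
without touching the training drugs.

Evaluation per side effect ranks the **test drugs** against test-role
labels; a test drug's training/validation-role positives (and any
cold-start-deleted pairs) are excluded from the candidate set — the
standard recommender holdout, toggleable via `exclude_known=False`.
Repeats re-randomize the drug split; the severe-set mean is computed per
repeat and then aggregated (mean and sample SD across repeats).

### PR-AUC estimator

Step-wise interpolation over distinct score thresholds
(average-precision style): tied scores collapse to one curve point and
the area is `Σ_k (R_k − R_{k−1}) P_k`. Constant scores therefore give
exactly the positive prevalence. The estimator is verified exhaustively
against an independent threshold-enumeration loop and scikit-learn's
average precision on all short tied vectors. Note the finite-sample
property of this estimator family: a random ranking scores slightly
*above* prevalence at small candidate counts.

### Cold-start simulation

`apply_cold_start(split, ratio, seed)` deletes `round(ratio · eligible)`
of the test drugs' training-role pairs, with per-pair probability
proportional to the drug's training-role positive count (rich histories
lose more), sampled without replacement. Two design choices worth
flagging:

* **Deleted pairs become unreported.** Their counts drop to zero in the
  training view, so they re-enter the loss as β-weighted negatives — a
  genuinely cold drug, not a masked one.
* **Deletions nest across ratios.** For a fixed seed one weighted
  deletion order is drawn and each ratio removes a prefix, so sweeping
  the ratio monotonically shrinks the surviving history instead of
  re-rolling it. This is a variance-reduction choice for the sweep; the
  marginal distribution at any single ratio is unchanged.

### Future-label validation

Candidates are the pairs negative at a past cutoff; labels come from a
later snapshot. Side effects with no newly emerged positives are flagged
and excluded from the mean. Chance level is the emergence rate among
past-negatives, so these PR-AUCs are not comparable to random-split test
values.

## Cold-start mapping (Map-LMF)

A linear map `d̂_i = Mᵀ desc_i` is fitted by ridge regression from the
training drugs' attributes onto their converged latent factors (closed
form; minimum-norm least squares at ridge 0). The reference logistic
model is trained on **training drugs only**, which makes the mapped
scorer provably independent of test-drug deletion — fitting the map
against the full deletion-affected model instead was measured to leak
the degradation into the mapped scores (its side-effect factors absorb
the false negatives), contradicting the flat deletion profile this
scorer exists to provide. Cold drugs get the mean training drug bias as
`b̄`; the hybrid scorer switches per drug between learned and mapped
factors at a known-side-effect-count threshold. A metric-optimized
(rather than squared-error) mapping is a documented extension point, not
the default: the closed form is deterministic and testable.

## Attribute computation

Circular (Morgan) fingerprints, radius 2, 2048 bits (radius is
configurable; the 4-equivalent diameter is the common default). Kernel
PCA (RBF default, gamma tunable by validation grid search) reduces them
to 100 dimensions, fitted on training drugs only and the fitted
projector stored with its training-drug list so test drugs are never
refit. The RDKit descriptor panel is standardized over training drugs;
constant or non-finite descriptors are dropped and logged. Drugs whose
structures fail to parse are reported by label and excluded.

## The synthetic world

The generator draws a ground-truth logistic factor model, samples
associations `z_ij ~ Bernoulli(σ(d_iᵀs_j + b_i + b_j))`, and emits
counts as a reporting system would: a true association accrues
`t − 1 + Poisson(report_intensity)` reports (default intensity 5, so it
almost always clears the threshold), a non-association gets a
`Poisson(0.1)` noise floor. Attributes are `D·G` plus optional Gaussian
noise — an exactly recoverable mapping target at `attr_noise_sd = 0`.
The severe set is the `n_severe` most prevalent side effects.

Default priors: factor coordinates ~ N(0, 2²), biases ~ N(−5, 0.5²) per
side. This places most true probabilities near 0 or 1 with ~10–15%
positive pairs: a drug either does or does not cause a side effect, and
the latent structure decides which — the regime the thresholded
association model assumes, and the regime in which "recovery" is a
meaningful notion (weak-factor worlds leave mid-range probabilities
whose single Bernoulli realization carries too little information for
any estimator to reconstruct them at desk scale; we measured a MAP
ceiling of r ≈ 0.85 there). Sparser, FAERS-like worlds (~1%) are
reachable through `bias_mean`.

What the generator does **not** emulate: reporting biases (stimulated
reporting, the Weber effect), drug-name synonymy, case-version
resubmission, MedDRA term granularity, or correlated side-effect
vocabularies. Passing tests on synthetic worlds therefore demonstrate
the *mechanics* of the method — losses, splits, weighting, mapping — not
its field performance on real FAERS extracts.

## Problem sizes used in tests

Module tests run on 20–100-drug worlds. The end-to-end suite uses
200×300 (k=5) for probability recovery and 300×400 with 60 severe side
effects × 5 repeats for the cold-start sweep — the smallest sizes at
which the per-side-effect PR curves are stable enough for the
monotonicity and flatness patterns to be read off the means. The
acceptance script's split-fraction simulation uses 100 drugs × 10
positives each over 200 seeds.

## Known limitations

* FAERS ingestion normalizes drug names only by case/whitespace; mapping
  trade names to ingredients is out of scope (a synonym-table hook
  exists). Multi-quarter case versioning is not reconciled.
* The per-pair penalty accounting couples regularization strength to
  matrix width; λ values are not transferable between matrix sizes.
* The default hyperparameter grids are the original search ranges for
  FAERS-scale data; on small
  synthetic worlds the selected optimum is usually interior but need
  not match the FAERS-scale optimum (t=3, α=10, β=0.8, λ=0.005).
* The FGRMF formula follows the common graph-regularized form; the
  similarity kernel is configurable because the comparison method's
  exact choice is not restated in the source describing it.
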