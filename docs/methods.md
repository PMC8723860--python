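# Methods

This note documents the models, the defaults and the numerical choices
behind `edlcdss`, and what the synthetic-data experiments do and do not
establish about real clinical data.

## Problem setting

The target task is binary CKD screening from a small tabular cohort:
~400 records, 24 mixed predictors, a 250:150 disease/healthy imbalance,
and pervasive missingness. Three design pressures follow: (i) missing
values and mixed types must be handled before any model sees the data;
(ii) the minority (healthy) class must be rebalanced or sensitivity and
specificity trade off poorly; (iii) with so few rows, leakage between
training and evaluation dominates any modelling gain, so every fitted
statistic is computed on training rows only.

## Preprocessing

Numeric columns: impute (median by default — robust to the skewed
laboratory values typical of renal panels; mean available), then min–max
scale to [0, 1] with the observed training min/max. Held-out values
outside the training range are clipped; a constant column maps to all
zeros (documented convention — the column carries no information either
way). Categorical columns: mode imputation (ties broken by schema level
order), binary levels to {0, 1}, k > 2 levels to one-hot. An unseen
level at transform time takes the all-zero "other" code (0 for binary
columns) and is logged. The [0, 1] range is not cosmetic: the DBN treats
inputs as Bernoulli visible probabilities.

Preprocessing is idempotent: re-fitting on already-transformed data
yields the identity map, which the suite asserts.

## ADASYN

Standard adaptive synthetic sampling: the minority class receives
G = round(β·(m_l − m_s)) synthetic points, allocated over minority
samples proportionally to the majority share of each sample's k = 5
nearest neighbours (Euclidean, over both classes), with largest-remainder
rounding so the allocation is integral and exact. Donors are drawn from
the k nearest *minority* neighbours and each synthetic point is a convex
combination x_i + λ(x_z − x_i). Determinism: distance ties break by row
index, λ and donor draws come from one seeded generator. When no
minority point has majority neighbours (well-separated classes) the
allocation falls back to uniform with a log notice. One-hot coordinates
are interpolated like numerics and left fractional — the downstream
models consume them as continuous features, and snapping would distort
the density-adaptive placement; β = 1 (full balance) is the default.
By default ADASYN runs on training folds only; a `before_split` variant
(oversample first, then split, so synthetic rows can be evaluated) exists
because some published protocols evidently do this — its metrics are
optimistic and the report metadata always records which variant ran.

## KELM

With a kernel K and regularisation λ > 0, training solves
(I/λ + Ω)A = T, Ω_ij = K(x_i, x_j), T one-hot; prediction scores are
K(X_new, X_train)·A. The system matrix is symmetric positive definite
for any λ > 0, so it is solved by Cholesky factorisation — an explicit
inverse or pseudo-inverse is never formed. Defaults: RBF kernel with
γ = 1/d and λ = 1. Larger λ weakens the ridge and tightens the training
fit (the suite checks training error is monotone in λ). Targets are kept
one-hot rather than ±1 so the same code covers C > 2 classes. Class
scores are the model's fusion contribution; posteriors for soft voting
are clipped-and-renormalised scores.

## DBN

Binary-unit RBMs with energy E(v,h) = −aᵀv − bᵀh − vᵀWh and sigmoid
conditionals. Pretraining is greedy CD-1 per layer (k configurable),
with visible reconstructions kept as probabilities and hidden states
sampled — the standard low-variance recipe; hidden *probabilities*, not
samples, feed the next layer. Weight init N(0, 0.1): small enough to
keep sigmoids responsive, large enough that hidden units differentiate
on low-dimensional inputs (with N(0, 0.01) the stack can collapse to
near-constant activations that neither the head nor fine-tuning
recovers from at practical learning rates). After pretraining a softmax
head is trained on the frozen top-layer features (so `epochs_finetune=0`
still yields a working classifier), then the whole stack is fine-tuned
by plain SGD on the cross-entropy. Defaults: hidden sizes (32, 16),
lr 0.1 for both phases, 15/30 pretrain/fine-tune epochs, batch 16. The
fusion vector is the top hidden activations concatenated with the head
posterior.

Correctness is anchored by exhaustive enumeration: for every RBM shape
with n_v + n_h ≤ 6 the sigmoid conditionals are compared with Bayes
conditionals of the exact joint exp(−E)/Z at 1e-10, and the mean CD-1
update direction is checked against the exact log-likelihood gradient.

## CNN-GRU

Valid 1-D cross-correlation (kernel width 5) with sigmoid activation and
width-2 average pooling extract feature maps from the flat predictor
vector. The published formulation pools 2×2 with a 1/4 factor — an
image-era leftover; inputs here are 1-D, so pooling is width-K with
factor 1/K and the discrepancy is noted rather than reproduced. Pooled
maps are distributed round-robin over a bank of GRU networks (12 by
default, capped at the map count); each unit's maps are flattened,
chunked into 25-wide slices (zero-padded tail) and consumed stepwise by
a 50-unit GRU without gate biases, exactly per the gate equations. Each
unit ends in a 10-neuron tanh penultimate layer and a class softmax; the
bank's posteriors are averaged (a soft per-unit vote), and the
concatenated penultimate activations form the fusion vector. The
10-neuron layer feeding a 2-class softmax reconciles the published
per-unit output width with a binary label.

Training is mini-batch SGD (lr 0.5, 40 epochs, batch 16) on the
cross-entropy of the *mean* posterior, with every gradient derived by
hand — conv, pool, chunking, GRU recursion, tanh head, softmax mean —
and verified against central differences at 1e-4 relative on a
40-parameter model (observed agreement ~1e-7). A trailing pooled
remainder shorter than the pool width is discarded; a configuration
whose pooling would consume the whole map is rejected at fit time.

## QOBOA

Butterfly optimization with quasi-opposition. Ambiguities in the printed
recurrences were resolved toward the standard BOA reading:
moves are x + (α²g* − x)f (global) and x + (α²x_j − x_k)f (local) with
α ~ U(0,1) per move; the parenthesisation matches the BOA literature the
method builds on. The stimulus intensity I is unspecified in print; here
I = normalised fitness rank in [0, 1] (best = 1), which is scale-free
across objectives. Moves are accepted greedily and g* is elitist —
additions implied by "optimal solution" semantics and necessary for a
non-increasing convergence curve. Quasi-opposite points are drawn
uniformly between the space midpoint and the candidate's mirror point;
at initialisation the best pop_size of the 2·pop_size union are kept
(an optional per-iteration "jumping" variant exists). Defaults follow
the BOA reference values: c = 0.01, a = 0.1, p = 0.8, pop 20, 50
iterations. Integer dimensions are rounded after clipping; learning-rate
dimensions are searched in log10 space.

Hyperparameter tuning minimises 1 − validation accuracy on a fixed
stratified holdout with a fixed per-candidate training seed, so the
search is deterministic given its seed. Default search spaces cover DBN
layer widths/rates/epochs and CNN-GRU kernel count, GRU width, rate and
epochs.

## Ensemble and metrics

Soft voting (weighted mean of the three posteriors, uniform by default)
is the production decision rule; a logistic head on the concatenated
fusion vector is provided as the alternative that uses the fused
representation literally. Exact posterior ties go to the disease class —
a deliberate sensitivity-first clinical convention. Metrics are computed
from confusion counts (disease = positive): sensitivity, specificity,
accuracy, F-score, Cohen's kappa, and rank-based AUC (mid-rank tie
handling, equal to the trapezoidal ROC area). Kappa is Cohen's
definition; the published five-run table's kappa values are not
reproducible from its printed confusion counts (run 1 implies ≈0.932
against a printed 0.9545), so the formula, not the table, is treated as
authoritative. Reports use the five-run + Average layout at 4 decimals,
round-half-even.

## Synthetic data: what it shows and what it does not

The generator emulates the UCI CKD table's *shape*: 250:150 imbalance,
11 numeric + 13 categorical predictors, ~10% missingness, and a
configurable standardized mean shift (default 2.5) between
class-conditional unit-variance Gaussians, with class-dependent level
probabilities for categoricals. It does not emulate real CKD data's
inter-feature correlations, informative missingness, measurement noise
structure, or label noise. Passing the end-to-end suite therefore
demonstrates that the pipeline recovers a known signal under realistic
size/imbalance/missingness conditions without leakage — not that it
attains any particular accuracy on clinical records. The published
headline numbers were obtained on the real UCI table under an unstated
split and are not bit-reproducible; they are used only as worked-example
arithmetic (sensitivities from printed confusion counts, Average-row
means), which the suite reproduces exactly.

## Problem sizes and degenerate inputs

The default experiment uses the 400-row cohort with a 25% stratified
holdout, five runs, and the model defaults above; the acceptance script
completes in well under a minute on one CPU. Degenerate inputs are
handled explicitly: all-missing columns are refused (never silently
dropped), single-class inputs to ADASYN are errors, a lone minority
point duplicates itself as its own donor, kernel matrices with
non-finite entries are rejected, and out-of-[0,1] DBN inputs raise
immediately with a pointer to preprocessing.
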