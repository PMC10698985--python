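# Methods

## The prediction problem

A protein–protein interaction (PPI) site is a residue that lies in an
interaction interface. Given only a protein's amino-acid sequence (and
optionally an evolutionary profile), the task is to decide for every
residue whether it is an interaction site. Two properties dominate the
design space: the signal is *local but contextual* — a residue's role
depends on a window of neighbours — and the labels are *highly imbalanced*
(interaction sites are typically 10–18% of residues in curated
benchmarks).

## Hybrid residue features

Classical sliding-window encodings concatenate the features of all window
residues into one long vector, which dilutes the residue actually being
classified. This package instead builds a **hybrid** feature per residue:

* the **targeted-residue feature** `f_tr` — the feature vector of the
  residue under classification, kept on its own untransformed path, and
* the **context feature** `f_ctx` — the ordered `(2W+1) × dim(f_tr)`
  matrix of the same per-residue features over the window `i−W … i+W`,
  zero-padded beyond the sequence ends with an explicit pad mask.

Six per-residue encoders are provided, combined in three fixed pairs
("feature-forming modules", ffmods):

| ffmod | encoders | dim |
|---|---|---|
| 0 | one-hot (20) + entropy density (20) | 40 |
| 1 | physicochemical properties (21) + hydropathy indices (2) | 23 |
| 2 | logistic-squashed PSSM row (20) + K-PseAA (30) | 50 |

Entropy density attaches `−p_u log2 p_u` of each residue type's
whole-sequence frequency to every position. The physicochemical and
hydropathy tables are bundled data files of standard published scales
(Kyte–Doolittle, Hopp–Woods, Grantham, Chou–Fasman, Zimmerman, Tien
SASA, …), z-scored per column at load; the exact 21-property multivariate
summary used in the original feature's source is not reproducible from
its citation, so a curated table of equivalent standard scales stands in
for it — the values are configuration, validated structurally only.

**K-PseAA** computes Chou-type pseudo amino acid composition on the
subsequence `sequence[i−K … i+K]` (K = 10 by default, so up to 21
residues): 20 normalized composition terms plus λ = 10 sequence-order
correlation terms `θ_j`, each the average over positions of the mean
squared difference of three standardized property scales (hydrophobicity,
hydrophilicity, side-chain mass) between residues j apart, weighted by
w = 0.05. `θ_j` is clamped to 0 when the subsequence is shorter than
j + 1; all 20 + λ components are non-negative and sum to 1. λ = 10 fixes
the 30-dimensional output; K = 10 is chosen so the subsequence (2K+1 = 21)
supports all ten correlation levels at interior positions; w = 0.05 is
the conventional PseAAC weight. Unknown residues (`X`) are encoded as
zeros by every encoder and dropped from composition counts.

The window half-width defaults to W = 32 (context segment 2W+1 = 65),
the best-performing of {8, 16, 32, 64}; the mechanism-recovery
experiments use W = 8 to keep single-CPU runtimes small.

## The base network

The context path: three stages of (1-D convolution, kernel 5, stride 1,
same-length zero padding → ReLU → max pooling, size 3, stride 1,
same-length padding), 8 kernels per stage, giving `Z ∈ R^{(2W+1)×8}`;
then masked multi-head self-attention with 4 heads of dimension 16: per
head, queries/keys/values are learned projections of the conv features,
energies `K Qᵀ/√16` receive a −10⁹ penalty at padded key positions, and a
softmax over keys makes each output position's weights sum to 1. Head
outputs are concatenated without an output projection (`A`, 64 dims per
position), `S = [Z | A]` rowwise (72 dims), and `f_agg` is the arithmetic
mean of `S` over non-padded positions. Restricting both the attention and
the pooling to non-padded positions — and zeroing padded rows at entry —
makes the output provably invariant to padded-row content, which the test
suite asserts under random perturbations.

The predictor head on `f_prot = [f_agg | f_tr]`: FC 1024 → batch norm →
ReLU → dropout 0.5 → FC 256 → batch norm → ReLU → dropout → FC 1 →
sigmoid. Batch normalization is placed between affine map and activation;
inference uses running moments. Two ablations are configurable: a
single-head model (`n_heads=1`) and a no-attention model
(`use_attention=False`, aggregation over `Z` alone).

The network and its gradients are implemented directly in NumPy
(`ppistack/_nn.py`): convolution, pooling, batch norm, dropout, attention
and the affine layers each carry an explicit backward pass, verified
against central finite differences in the test suite (median relative
error below 1e−7; isolated mismatches at ReLU/max-pool kinks are expected
for finite differences and tolerated). Parameters are initialized with
fan-in-scaled normal draws from a recorded seed; the final affine layer
uses a small scale (0.01) so initial outputs sit near 0.5. Training
minimizes mean binary cross-entropy (predictions clipped to
[1e−7, 1−1e−7]) with Adam at its default moments, learning rate 0.001,
batch size 64, at most 50 epochs.

## Imbalance handling

With `n_neg` negative and `n_pos` positive residues, the negatives are
shuffled and split into `M = max(1, floor(n_neg/n_pos))` near-equal parts;
each part plus *all* positives forms one training subset. Flooring (never
rounding up) keeps every subset's negative/positive ratio strictly below
2. Training visits the subsets round-robin, one per epoch, and each epoch
further subsamples the subset's negatives (without replacement) down to
the positive count, so one cycle through the M subsets exposes every
negative once while positives are learned M times. Negatives are shuffled
before partitioning (seeded), since file order carries no meaning here.

## Early stopping

Validation loss is monitored after every epoch. Training stops when the
trailing-3-epoch mean has **strictly** increased for 5 consecutive epochs
(ties do not count), or at the 50-epoch cap. The rule is evaluated on
validation loss when a validation split is supplied, otherwise on
training loss.

## Stacking

Three base networks — one per ffmod — are trained independently on the
same training split. Their per-residue probabilities form a 3-column
meta-feature matrix; the meta rule is fitted on the *validation* split's
meta-features (the held-out split that also drives model selection;
out-of-fold stacking would need per-fold base retraining and is out of
scope). Rules: logistic regression (default, and the best-performing
rule), decision tree, random forest, nearest neighbor, plain averaging,
majority voting (no probability emitted, ties broken positive —
unreachable with 3 models), and a least-squares linear rule
(`linear_mse`) honoring the mean-squared-error formulation of the
ensemble objective. Trainable rules are scikit-learn classifiers behind
this module's interface; the logistic rule is cross-checked in tests
against an independent scipy re-minimization of the same convex
objective. Final calls threshold the ensemble probability at 0.5 (scores
exactly at the threshold are positive calls).

## Metrics

Accuracy, precision, recall, F1 and Matthews correlation follow the
standard confusion-count formulas; any metric with a zero denominator is
reported as 0 rather than NaN so degenerate runs stay comparable. AUROC
uses the rank (Mann–Whitney) formulation with ties counted half; AUPRC is
average precision — stepwise integration of the precision–recall curve
with no interpolation, the convention that never overstates performance
on imbalanced data. Both are cross-checked against scikit-learn and
against independent formulations (trapezoidal ROC integration) in the
tests.

## Synthetic data: what it does and does not show

The generator plants a fixed 5-residue motif (`WCHKR` by default) into
background sequences (uniform residue composition by default, 60–120
residues, 200 sequences) at a rate tuned to a target positive prevalence
(default 15%, matching the 10–18% of curated benchmarks); motif-covered
residues are labeled 1, labels are optionally flipped with a noise rate,
and mock PSSMs add an integer signal (+8 by default) in the motif
residue's column at motif positions over a noisy near-zero background.
With label-flip noise ρ and prevalence p, the best achievable test AUROC
is bounded (≈ 0.88 at ρ = 0.05, p = 0.15, counting ties at half), so the
learnability check's 0.85 bar asks the network to approach the Bayes
ceiling, not to reach 1.

`decoy_motif_ratio` optionally plants additional *unlabeled* motif
occurrences. This exists because a fully separable planted signal cannot
demonstrate what class rebalancing does at convergence: with symmetric
flip noise the motif posterior lies on the same side of the 0.5 threshold
under the natural and the rebalanced prior, so balanced and unbalanced
training end at the same recall. With 1.5 decoys per labeled occurrence
the natural-prior posterior of a motif residue falls to ≈ 0.4 (suppressed
by a model trained on the raw 10:1 data) while the rebalanced posterior
is ≈ 0.87 — the regime, as in real interface data, where the balancing
strategy visibly recovers positive-class recall.

Passing these checks shows the pipeline recovers a planted, localized,
imbalanced sequence signal end to end; it says nothing about structural
context, evolutionary couplings, or the spatial label correlations of
real interfaces, and benchmark-level performance is out of scope.

## Problem sizes of the shipped experiments

Chosen so the full suite runs on one CPU in minutes, and stated here as
the package's own experiment design: the single-network learnability and
permuted-label runs use 200 sequences, W = 8, noise 0.05, up to 50
epochs; the stacking run uses 100 sequences and 12 epochs per base
network; the balanced-vs-unbalanced comparison uses 100 sequences at 10:1
imbalance, decoy ratio 1.5, 6 epochs per run. The permuted-label control
shuffles training- and validation-split labels and evaluates against the
untouched test labels, separating genuine signal from leakage.

## Numerical and policy choices

* Mask penalty 10⁹ subtracted from attention energies at padded keys.
* Average pooling over non-padded positions only.
* Softmax is computed with max-subtraction for stability.
* Non-standard residue letters other than `X` are rejected at read time;
  silent coercion hides data bugs.
* Sequence-level splitting (ratio 3:1:1 by default): floor-sized buckets
  filled train → validation → test from a seeded shuffle, remainders to
  train first; no residue of one sequence ever crosses splits.
* Mock PSSM scores are integers so the PSI-BLAST ASCII round trip is
  exact.
* Checkpoints are `.npz` archives with the architecture config embedded;
  an ensemble bundle is a directory of three checkpoints, pickled meta
  parameters, and a JSON manifest.

## Known limitations

* Batch statistics make training-mode outputs depend on batch
  composition; only evaluation mode is deterministic per sample.
* The meta rule sees only three probabilities; with near-identical base
  models stacking cannot improve much over averaging (the tests assert
  it does not hurt).
* The NumPy implementation targets clarity and single-CPU scale; wide FC
  layers dominate runtime, and no GPU path exists.
* K-PseAA near sequence ends operates on clamped subsequences; the
  zero-clamp of high-order correlation terms is a choice, not a
  published convention.
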