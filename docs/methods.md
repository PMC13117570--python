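# Methods

## Problem setting

Driver gene prediction is cast as transductive binary node
classification on a fixed PPI graph: every gene has features and a
network position during training, but only the labeled subset (known
drivers vs curated non-drivers, roughly 5% positive) contributes to the
loss.  Scores are read out for all genes, and the top of the ranking is
the candidate list.

## Graph operator

The propagation operator is `S = D̂^(−1/2)(A+I)D̂^(−1/2)` with
`D̂ᵢᵢ = Σⱼ(A+I)ᵢⱼ`.  Self-loops guarantee isolated nodes a well-defined
row (a single entry of 1); symmetric scaling balances hub and leaf
influence.  The operator is stored sparsely and verified against dense
brute-force algebra to 1e-10 in the tests.

## Encoders

Every residual layer adds a node-wise linear path to a neighborhood
convolution path, both ReLU-activated before the merge.  The additive
shortcut keeps gradients alive through the deep (6-layer) classifier
head — the suite checks that the first layer still receives gradient
after 50 training steps.  Encoder depth is two (widths 96 then 256),
with one layer normalization (ε = 1e-5) after each encoder's output.

The expression block is encoded by three structurally identical,
parameter-independent "interaction" encoders, whose outputs pass through
per-view MLPs (one hidden layer, width 256) and a fusing linear map.
The three views consume the expression block alone by default; setting
`encoder.expression_pair_input` concatenates the paired omics block
(mutation/methylation/CNV respectively) to each view's input, so both
readings of "interaction" are available.  Cross-omics interaction under
the default arises from the independent per-view parameters and the
downstream attention fusion.

During training each feature entry is zeroed with probability 0.1 and
each undirected edge dropped with probability 0.1 (both configurable);
the operator is re-normalized from the augmented adjacency at every
epoch.  Augmentation is disabled at evaluation.

## Attention fusion

Scores are standard additive attention, `vᵀ σ(W_a s + b_a)` with
σ = tanh (ReLU selectable) and attention width d_a = 64; softmax over
the omics axis yields one scalar weight per (node, omics), and fusion is
the weighted sum of embeddings.  Weights are exposed as an N×4
diagnostic table (`predict --dump-attention`).  The ablation variant
replaces attention with a plain sum.

## Feature enhancement

Three label-free-at-build-time sources concatenate into `X_extra`:

- **Structural metrics** (computed once on the full graph): degree,
  normalized betweenness, Wasserman–Faust closeness, eigenvector
  centrality (principal eigenvector via Lanczos, unit L2, largest entry
  positive), local clustering, PageRank (damping 0.85), core number.
  The registry is pluggable; all seven are validated against brute-force
  enumeration/power-iteration/peeling oracles.
- **Walk embeddings**: second-order biased walks (return parameter p,
  in-out parameter q; p = q = 1 walks are generated fully vectorized)
  feeding a skip-gram model with negative sampling (unigram^0.75 noise,
  linearly decaying learning rate), implemented in numpy and
  deterministic under the seed.  Defaults p = q = 1, walk length 80,
  10 walks per node, window 10, 32 dimensions.
- **Teacher logits**: the ensemble-mean soft label, entered raw as one
  extra column (not sigmoid-squashed).

Structural and walk features are unsupervised and computed once per
graph; *standardization* of all extras, like that of the omics matrix,
is refitted inside every training fold.  Teacher logits are
label-derived and therefore retrained per fold (below).  `MLP_extra`
(one hidden layer at the hidden width) projects `X_extra`, added
residually to the fused representation; zeroing it recovers the fused
representation exactly, which is the "no enhancement" ablation.

## Heads and output

A residual-GCN projection to 128 dimensions feeds both heads.  The GCN
head stacks six residual layers of width 200 (constant width; the paper
trail gives no taper) with dropout 0.2 after each merge and ends in a
linear map to one logit.  The MLP head layer-normalizes its input, runs
256 → 128 → 64 with ReLU (dropout on the third transform) and maps to
one logit.  The final logit is the exact sum of the two; probabilities
use an overflow-free sigmoid.

## Losses

- Task loss: class-balanced BCE over labeled training nodes, computed
  via log-sigmoid/softplus identities (finite for |logit| ≫ 100).
  "auto" weights are inverse-frequency and mean-preserving:
  `w_p = N/(2N_pos)`, `w_n = N/(2N_neg)`.
- Focal option: `−w(1−p_t)^γ log p_t`, γ default 2; γ = 0 reduces to the
  balanced BCE to machine precision.
- Distillation: mean soft-target cross-entropy between the student's
  sigmoid and the teacher's probability over the distillation node set
  (training-fold nodes, plus unlabeled nodes by default); no temperature
  by default (parameter available).  Total `L = L_B + λ·L_K`, λ = 0.5.

## Teachers

Teachers share the multi-encoder architecture with higher-capacity
classifier layers (6 layers; 128 then 512 wide), dropout 0.15, AdamW at
lr 3e-4 / weight decay 5e-5, up to 1200 epochs with early stopping
(patience 200) on validation AUPRC, and a parameter EMA (decay 0.995)
that supplies the final logits.  The stopping-validation subset is a
stratified 10% of the training-fold labels; the loss sees the remaining
90%.  Teachers consume structural and walk extras but never teacher
features, and are trained without distillation.  By default teachers are
retrained inside each cross-validation fold so their soft labels never
encode held-out labels; a single-global-teacher mode exists for
comparison but is not the default because it leaks test labels into the
student's inputs.

## Evaluation protocol

Repeated stratified k-fold cross-validation (default 10×5) over labeled
nodes; a one-shot 75%/25% stratified holdout is also provided.  Within a
fold: fit standardizers on training rows, retrain teachers, train the
student ensemble, score the untouched test fold.  AUROC is the midrank
Mann–Whitney statistic; AUPRC is step-integral average precision with
tied scores collapsed onto one threshold — both validated to 1e-9
against all-pairs and curve-walk oracles (and scikit-learn).  Student
ensembles combine member logits with weights
`softmax(val_AUPRC / T)`, T = 0.08 (the combination rule behind the
stated integration temperature is not pinned down; a plain-mean mode is
selectable).  Negative-sampling experiments subsample training negatives
to a given ratio, leaving test folds intact.

A 15-entry ablation registry covers omics-block subsets, a shared
GraphSAGE encoder, GAT encoders, sum fusion, the GCN-only head,
per-source enhancement toggles and the teacher variants (features only,
distillation loss only, neither).

## Synthetic benchmark

The generator emulates the data shape of the real task: a
Barabási–Albert graph (m = 3) for PPI-like degree heavy tails (a
stochastic-block-model option adds community structure), positives drawn
with probability ∝ degree^topo_signal (default 0.5) to plant a
label–centrality correlation, and Gaussian features where each column of
a signal-carrying block shifts by `signal` SD for positives.  Defaults:
1000 nodes, prevalence 0.05, signal (1, 1, 1, 0) — the CNV block stays
pure noise — noise SD 1, no label flips (a `label_noise` knob simulates
negative-set contamination).  What it does not emulate: correlated
features within and across omics blocks, cancer-type structure among the
16 columns, realistic TCGA rate distributions, assortativity and
community structure of curated PPIs, and literature-biased labeling.
Passing tests therefore demonstrate the correctness and leak-freeness of
the machinery and its capacity to exploit planted feature/topology
signal — not clinical performance.

## Numerical choices

- The network stack runs in float32 (float64 selectable per model); the
  autodiff core preserves input dtype and is gradient-checked in
  float64.
- Softmax is max-shifted; all loss terms use softplus/log-sigmoid forms;
  sigmoid is branch-stable for |x| up to overflow.
- Zero-variance feature columns standardize to 0 (std clamped to 1);
  population (ddof = 0) convention.
- One master seed fans out through `numpy` seed sequences to folds,
  teachers, students, dropout, augmentation and walks; two runs with the
  same master seed produce byte-identical prediction files on one
  platform (single-threaded BLAS).
- The `amp` config flag is accepted for configuration compatibility and
  is a documented no-op: all computation is full precision for its
  width.

## Benchmark sizes used by the suite and acceptance script

The suite runs the full-width architecture with scaled-down study sizes:
single teacher (vs an ensemble of 10) trained for 120–300 epochs (vs
1200), single student (vs 6) for 150 epochs (vs 900), walk corpus of 4
walks × length 40 per node with window 5, benchmark graphs of 300–1000
nodes, and 1×5-fold cross-validation in the acceptance script.  The
monotonicity and null-instance controls use a width-reduced student
(hidden 16/32, 2 classifier layers of 24) since they probe the generator
and the leak-freeness of the protocol, not model capacity.

## Known limitations

- Real TCGA-derived feature tables and curated PPI networks are out of
  scope; rate definitions are documented in the README's data-format
  terms and features are treated as opaque columns.
- Gene-symbol harmonization is uppercase-and-strip only; no alias
  database.
- The exact seven structural metrics and walk hyperparameters of the
  original study are not published in its main text; the standard
  centrality battery and canonical node2vec defaults are used, and the
  metric registry is pluggable.
- Single-head attention over omics; no pairwise cross-omics attention.
- Eigenvector centrality on a graph whose components tie in spectral
  radius is ill-determined; ties do not occur in the benchmark graphs.
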