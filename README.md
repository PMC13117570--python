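# mgnn — multi-modal graph neural network for cancer driver gene prediction

Cancer driver genes — the genes whose somatic alterations push a cell
toward malignancy — are hard to separate from passenger genes by any
single data type.  `mgnn` predicts drivers by combining two complementary
signals on a protein–protein interaction (PPI) network: per-gene
multi-omics profiles and the gene's topological position in the network.

Each gene *i* carries a 64-dimensional feature vector split into four
16-dimensional omics blocks (one scalar per cancer type per omics):
somatic mutation rate, differential expression, differential DNA
methylation, and copy-number alteration (CNV) rate.  The model is a
transductive node classifier built from:

1. **Independent omics encoders.**  Each block passes through its own
   two-layer residual GCN (widths 96 → 256).  A layer computes
   `H' = ReLU(H·W_L) + ReLU(S·H·W_c)` with
   `S = D̂^(−1/2)(A+I)D̂^(−1/2)` the self-looped, symmetrically
   normalized adjacency; layer normalization follows each encoder.  The
   expression block additionally runs through three interaction encoders
   (independent parameters) whose per-view MLP outputs are concatenated
   and fused linearly, targeting expression–mutation,
   expression–methylation and expression–CNV interaction patterns.
2. **Attention fusion.**  For node *i* and omics *m*, the score
   `vᵀ tanh(W_a s_i^(m) + b_a)` is softmax-normalized over the four omics
   and the embeddings are combined as `Σ_m a_i^(m) s_i^(m)`.
3. **Topological feature enhancement.**  Seven structural metrics
   (degree, betweenness, closeness, eigenvector centrality, clustering,
   PageRank, core number), node2vec walk embeddings, and soft-label
   logits from a distilled teacher ensemble are projected by an MLP and
   added residually: `H_enhanced = H_fused + MLP_extra(X_extra)`.
4. **Dual prediction heads.**  A projection layer (residual GCN, 128-d)
   feeds a 6-layer residual GCN head (width 200, dropout 0.2) and a
   3-layer MLP head in parallel; the final logit is the exact sum
   `ŷ = ŷ_G + ŷ_m` and `P(y=1) = σ(ŷ)`.

Training minimizes `L = L_B + λ·L_K`, a class-balanced binary
cross-entropy on the labeled training nodes plus (λ = 0.5) a distillation
cross-entropy against the teacher's soft labels; focal loss is available
as an option.  Feature masking and edge dropping augment each training
epoch.  Evaluation is repeated stratified k-fold cross-validation scored
by AUROC and AUPRC (average precision), the metric of choice at ~5%
positive prevalence.  The whole network stack — autodiff, AdamW,
parameter EMA, GCN/GAT/SAGE layers — is implemented in numpy and
gradient-checked against finite differences.

## Worked example

Generate a synthetic benchmark (1000 genes on a scale-free graph, 5%
drivers attached preferentially to hubs, 1-SD planted signal in three of
the four omics blocks), then cross-validate the full pipeline:

```bash
mgnn synth --n 1000 --prevalence 0.05 --seed 7 --out bench/
mgnn cv bench/ --repeats 1 --folds 5 --seed 7 \
    --student-epochs 150 --teacher-epochs 120 --out cv_metrics.json
```

A run of the equivalent library calls (seed 1, single teacher and single
student per fold) prints:

```
cv_auprc_mean: 0.9967 (n=1000)
cv_auprc_std: 0.0067 (n=1000)
cv_auroc_mean: 0.9998 (n=1000)
cv_auroc_std: 0.0004 (n=1000)
null_test_auprc: 0.0876 (n=400)
random_baseline_auprc: 0.0720 (n=400)
```

Read: on the planted-signal benchmark the model ranks essentially every
held-out driver above the non-drivers (AUPRC ≈ 1, twenty times the 0.05
chance level), while on a *null* instance with no planted signal its test
AUPRC (0.088) is indistinguishable from the permutation baseline (0.072)
— the pipeline finds signal only where signal exists, so the
cross-validation machinery is leak-free.

Ranked candidate lists and per-gene attention weights come from:

```bash
mgnn predict bench/ --top-k 100 --dump-attention attention.tsv
mgnn ablation bench/ --variant without_attention_layer
```

## Data formats

- **Edge list** (`edges.tsv`): `geneA<TAB>geneB[<TAB>score]`, `#`
  comments; optional confidence thresholding at read time.
- **Feature table** (`features.tsv`): first column `gene`, then 64
  numeric columns ordered mutation, expression, methylation, CNV
  (16 cancer types each).
- **Labels**: one gene symbol per line, separate files for positives
  (known drivers) and negatives.

## Layout

- `src/mgnn/graph_io.py` — parsing, symbol harmonization, the normalized
  operator, fold-aware Z-score standardization
- `src/mgnn/nn.py` — numpy reverse-mode autodiff, AdamW, EMA
- `src/mgnn/encoders.py`, `fusion.py`, `enhancement.py`, `heads.py` —
  the model blocks
- `src/mgnn/objectives.py` — balanced BCE, focal, distillation losses
- `src/mgnn/distillation.py` — teacher ensemble and soft labels
- `src/mgnn/pipeline.py` — CV protocol, metrics, ensembling, ablations
- `src/mgnn/synthetic.py` — benchmark generator
- `docs/methods.md` — modeling assumptions, defaults, limitations
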