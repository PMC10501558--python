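# Methods

## Problem and model

`rnaloc` predicts the subcellular localization of an mRNA from its
nucleotide sequence, optionally augmented with protein–protein
interaction (PPI) information. Two target regimes are supported:

- **continuous**: each mRNA carries a probability vector over
  compartments (as produced by fractionation expression profiling,
  e.g. four compartments cytosol / insoluble / membrane / nuclear);
- **discrete**: each mRNA carries a single compartment label (as in
  curated localization databases, e.g. five compartments cytoplasm /
  ER / extracellular / mitochondria / nucleus).

Both regimes share one model and one loss: a feed-forward network with
a softmax output trained to minimise the mean Kullback–Leibler
divergence KL(Q‖P) between observed (Q) and predicted (P) compartment
distributions. Discrete labels are one-hot encoded, for which the KL
loss is exactly cross-entropy, so a single training path serves both.

The model deliberately stays shallow — one 200-unit ReLU hidden layer —
on the premise that composition-style features do not benefit from deep
hierarchies and that a small model trains quickly on CPU.

## Feature encodings

**Sanitization.** All input sequences are folded to {A,C,G,T,N}: case
is normalised, U→T (RNA and DNA FASTA are both accepted), and any other
character (IUPAC ambiguity codes, gaps) becomes the sentinel N. Every
counting operation skips windows or pairs touching an N rather than
dropping the record, so ambiguous positions cost only their own
windows. Sanitization is idempotent.

**k-mer profile.** Counts of all 4^k lexicographically ordered width-k
windows (sliding, step 1), divided by the sequence length L when
normalised. Note the divisor is L, not the window count L−k+1; the two
differ by a per-record scalar and the choice follows the convention of
dividing composition counts by sequence length. A sequence shorter
than k yields a zero vector rather than an error, so corpora with very
short records run to completion. Dense 4^k storage is guarded at
k ≤ 12; the default k = 5 uses 1,024 columns.

**Distance (gapped-pair) profile.** For gap size k, cell (a, b) counts
positions i with S[i] = a and S[i+k+1] = b — first and last nucleotide
separated by exactly k intervening characters. "Distance k" therefore
means *gap length*, not index difference: adjacent pairs are k = 0.
The deployed feature concatenates the 16-cell blocks for k = 0…8
(144 columns). The aggregate over all admissible gaps (all ordered
position pairs i < j) is kept as a separate diagnostic operation,
`aggregate_pair_counts`, because it is what hand-counting on a short
sequence naturally produces; a consistency test asserts it equals the
sum of the per-gap blocks. Gap-pair normalisation (divide by L) is off
by default — the natural reading of the feature is raw counts — but the
pipeline configuration enables it so the block is on the same scale as
the normalised k-mer block during training.

**PPI embedding.** The corpus adjacency matrix has one row per mRNA;
an edge weight is the interaction strength of the proteins the two
mRNAs encode. Matrix rows are column-mean-centred (no variance
scaling) and projected onto the top principal components (default
500). mRNAs absent from the network participate as all-zero rows — a
zero row embeds as the projection of the negative column means, which
is tested. Component signs are fixed by making each component's
largest-magnitude loading positive, so results are reproducible across
BLAS builds. The default fits PCA once on the whole corpus before
cross-validation; because that lets held-out rows influence the
rotation, a `train_fold_only` scope is provided that fits centring and
rotation on training rows only and projects held-out rows with them.

## Network and training

Defaults: 300 epochs, batch size 512, one hidden layer of 200 fully
connected ReLU units, dropout rate 0.2, validation fraction 0.1.
Setting `hidden_layers=0` gives plain softmax regression; the k-mer
baseline variant uses two hidden layers as wide as its 1,364-dim
input. An alternative dropout of 0.5 can be set through the config;
0.2 is the default selected value. The optimizer is Adam with Nesterov
momentum (Nadam; β₁ = 0.9, β₂ = 0.999) at learning rate 0.001 — the
conventional default for this optimizer family, since no single value
is canonical. The KL loss guards log(0) with ε = 1e-7 added inside
both logarithms.

Weight initialisation is He-scaled Gaussian for hidden layers from a
seeded generator; the output layer starts at zero, so an untrained
model predicts the uniform distribution (a useful calibration check).
No early stopping is applied — validation loss is only recorded, and
the per-epoch history is stored on the model so overfitting can be
inspected. Backpropagation is analytic and hand-derived (including the
ε term of the loss); a finite-difference gradient check on a toy
network asserts relative agreement below 1e-4. All stochastic elements
(init, shuffling, dropout masks, validation split) draw from one
seeded generator, making training bit-reproducible for a given
(seed, data, config) triple. A non-finite loss aborts with a
diagnostic rather than silently producing NaN weights.

## Evaluation protocol

Repeated k-fold cross-validation (default 30 repeats × 10 folds),
stratified by label in discrete mode (class imbalance in curated
databases is severe), plain shuffled folds in continuous mode. Within
each repeat, held-out predictions are **pooled across folds before
metrics are computed**, then metric values are averaged across repeats
(standard deviations reported). Pooling was chosen over per-fold
averaging because one-vs-rest metrics for rare compartments are
unstable on single folds; per-repeat values are retained on the report
for anyone wanting the other aggregation.

Continuous mode: per-compartment Pearson correlation between predicted
and observed columns (a zero-variance column is reported as missing
with a warning) and per-mRNA Spearman rank correlation across
compartments with average-rank tie handling, reporting the count of
mRNAs with coefficient exactly 1. Discrete mode: one-vs-rest
confusion-table metrics applied exactly as the standard formulas read
— precision TP/(TP+FP), recall TP/(TP+FN), F = 2PR/(P+R),
ACC = (TP+TN)/total, MCC = (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))
— with any 0/0 reported as 0 with a warning, so compartments that
never receive a prediction yield 0 rows rather than crashes. Macro
averages summarise across compartments; overall accuracy is the
fraction of argmax-correct mRNAs. AUC-ROC uses the rank-based
(Mann–Whitney) statistic with tie averaging; AUC-PR is the step-wise
precision-recall summary. A threshold-based multi-label assignment
mode and an exhaustive grid scan for the F-maximising threshold
(ties toward the lower threshold) are provided.

## Synthetic corpora

The generator produces corpora with the statistical structure the
method assumes, so the pipeline is testable end-to-end without any
external data:

- **Sequences**: per-record compartment drawn from configurable class
  proportions (default cytoplasm-heavy with a 3% mitochondrial class,
  mirroring the imbalance of curated databases and exercising the
  degenerate-metric paths); sequence drawn i.i.d. from a
  compartment-specific base distribution — uniform mixed with a
  compartment-designated nucleotide at effect size δ (δ = 0 is the
  null corpus) — with an optional planted motif inserted at a
  per-compartment rate. Default lengths are uniform in 150–400 nt,
  chosen to keep toy corpora fast while giving every gap size 0–8
  thousands of counting positions per record.
- **PPI graph**: planted-partition (stochastic block) edges — each
  unordered pair is an independent Bernoulli edge with within-class
  probability 0.15 vs between-class 0.01 by default, weights uniform
  in (0,1] — emulating the assumption that proteins interacting
  strongly tend to share a compartment.
- **Continuous targets**: Dirichlet draws with concentration mass
  (default 20) on the true compartment — the simplest simplex family
  that interpolates from uninformative (mass 1) to one-hot (mass → ∞).

What the generator does **not** emulate: UTR/codon structure, zipcode
motifs with positional preference, transcript-length/compartment
correlations, isoform ambiguity, or realistic PPI degree
distributions. Passing the end-to-end recovery tests therefore shows
the pipeline is correctly wired and can extract planted compositional
and network signal; it does not certify accuracy on real transcript
corpora.

## Problem sizes used in the checks

The end-to-end recovery checks run a 4-class, 800-record corpus with
δ = 0.3 and a single repeat of 5-fold CV at 50 epochs with a
150-component PPI embedding, and a 400-record weak-signal corpus
(δ = 0.05) for the PPI-ablation direction check — sizes at which the
planted signal is comfortably recoverable and the whole suite runs on
one CPU in a few minutes. The acceptance script measures encoder
dimensionalities on a 520-record corpus, the smallest round size that
supports a 500-component PCA.

## Known limitations

- The whole-corpus PCA scope leaks fold information by construction;
  use `train_fold_only` for leakage-free estimates (at extra cost,
  since the embedding is refit per fold).
- The multiclass MCC reported is the macro-average of per-class binary
  MCCs, not the single-formula multiclass generalisation.
- KL with ε is not exactly cross-entropy for soft targets; the
  difference is bounded by ε·C and irrelevant at ε = 1e-7.
- Training is dense-matrix CPU numpy; corpora beyond ~10⁵ records or
  k > 8 k-mer spaces would need a sparse or batched encoder.
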