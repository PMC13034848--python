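# Methods

## Problem setting

A CRISPR/Cas9 guide RNA (sgRNA) directs the nuclease to a 20-nt protospacer
adjacent to an NGG PAM. Sites that are imperfectly complementary to the
guide can still be cleaved; predicting which candidate sites are true
off-targets from the aligned guide/site sequence pair is a heavily
imbalanced binary ranking problem (genome-wide screens report on the order
of 2% or fewer positives among candidate sites).

Each aligned position of a guide/site pair is one of 16 base-pair tokens
(guide base first, T standing for U): four Watson-Crick matches (AA, CC,
GG, TT) and twelve mismatches, grouped by guide base into rA, rG, rC, rT
(TC is the rU-dG wobble, GA the rG-dT wobble). A pair is therefore a
sequence of (position, token) indices into an L x 16 matrix.

## Hybrid model

The core idea is to initialize the first layer of a small sequence model
with a literature-derived prior matrix and let backpropagation update the
prior jointly with the network ("synchronous update"). Two prior families
give two sub-models:

* **MTP** (mismatch tolerance profile), M^init in R^(L x 16): per-position
  tolerance of each mismatch type. Rules: PAM rows are 1 for all tokens;
  match tokens are 1 everywhere; known mismatch tolerances are copied from
  the table; mismatch entries absent from the table default to 1
  ("missing" is treated as fully tolerated).
* **DRICS** (DNA-RNA interaction contribution scores), D^init: scores for
  all 16 tokens at each guide position; PAM rows are 0. Raw scores span an
  asymmetric range (matches roughly in (0, 0.6], mismatches in [-5.5, 0)),
  so the matrix is normalized piecewise: entries >= 0 are divided by
  v_max, entries < 0 by |v_min|, mapping the two sign classes onto [0, 1]
  and [-1, 0] while preserving signs and within-class order. Normalization
  is global across positions, not per-position: the extrema are scanned
  over all guide-row entries at once (the published phrasing speaks of
  "the values in the positive and negative intervals", a global reading);
  v_max/v_min are recorded, and PAM/pad constants are excluded from the
  scan because they are fill-ins, not scores. Re-normalizing an already
  normalized matrix is an error rather than a silent re-scale.

Each sub-model is: scalar embedding lookup (each position contributes
exactly its L x 16 matrix cell — this is what makes the learned update per
(position, pair-type) directly interpretable) -> Inception block of
parallel same-padded 1-D convolutions (kernel sizes 3 and 5, 20 kernels
each, ReLU) plus an identity residual branch, concatenated along channels
-> bidirectional LSTM stack (M-model: 2 layers, hidden 25; D-model: 1
layer, hidden 20) -> flattened over all L steps -> dense head 80 -> 20 ->
1 with ReLU on the hidden layers and a sigmoid output probability.
The ensemble prediction is the arithmetic mean of the two sub-model
probabilities.

Design choices made where the published architecture leaves details open:
same-length zero padding in the conv branches (so branch outputs
concatenate at length L), ReLU activations, and flattening the full
recurrent output sequence before the head. These are declared defaults,
all configurable.

## Position convention

The embedding has L = 24 rows but 20 guide + 3 PAM positions account for
only 23. The 24th row is placed as a single 5' pad row (row 1), followed
by the 20 guide rows (5'->3') and the 3 PAM rows; the layout is
configurable because the original placement of the extra position is not
documented. The pad row of a full 24-nt input takes the self-pair of the
observed base (matched, information-free context); 23-nt inputs are
left-padded with a configured match token (default AA). An N in the PAM
(the N of NGG) is encoded as the self-pair of the partner base — PAM rows
carry constant prior values, so the token choice there cannot change the
prior lookup, only the learned update. An N inside the guide region is an
error.

Matrix rows run 5'->3'; all *reported* coordinates are biological
positions with 1 = PAM-proximal, 1-10 the seed region and 11-20 the
non-seed region, via the row<->position bijection.

## Training

Binary cross-entropy (optional positive-class weighting, default off,
since AUPRC-based early stopping already targets ranking), Adam
(default learning rate 1e-3, batch 256, both configurable). The prior
embedding is an ordinary trainable parameter updated in the same
backward pass as the downstream weights; freezing it yields the
"no-update" ablation, and the Inception/BiLSTM blocks can be dropped for
the architecture ablations. After each epoch the model is scored by AUPRC
on a validation split; training stops when the metric fails to improve
for `patience` epochs and the best-epoch parameters are restored. A
validation split without both classes is rejected (the stopping metric
would be undefined).

Runs are repeated across seeds (default 5). The seed drives both weight
initialization and the per-epoch shuffling order, so each seed sees a
distinct data order while any single run is bit-reproducible.

### Compute engine

The layers, backward passes and Adam are implemented directly in NumPy
(`otpred/nn.py`); gradients are exact (verified against central finite
differences in the test suite). Downstream weights and activations are
float32 — the workload is memory-bound, so single precision roughly
halves step time — while the embedding parameter is float64 so that its
initialization equals the prior matrix bit-for-bit and frozen runs return
it unchanged bit-for-bit.

## Evaluation

Off-target validation is per-guide in practice, so metrics are computed
per sgRNA and averaged without weighting: for every sgRNA with at least
one true off-target in the evaluation set, AUPRC (step-function
precision-recall summary, ties grouped; identical to scikit-learn's
average precision) and AUROC (midrank tie convention) are computed over
its candidate sites; the dataset score is the mean over those sgRNAs.
sgRNAs with no positive — or no negative, where the curves are equally
undefined — are excluded. Precision, recall, F1 and MCC at a fixed
threshold (default 0.5, configurable and flagged in reports) follow the
same per-sgRNA aggregation; division-by-zero cases return 0 with a
degeneracy flag rather than raising.

Seed-wise method comparisons use the one-sided exact Wilcoxon signed-rank
test: zero differences dropped, midranks for tied magnitudes, and
p = P(W+ >= observed) by enumeration of all 2^n sign assignments for
n <= 20 (normal approximation beyond). Under this standard convention
five uniformly favorable differences give exactly 1/32 (~.031), and five
uniformly unfavorable ones give 1.0.

## Update-pattern analysis

Per-seed updates are differenced against the shared initial matrix
(Delta_s = M_s^update - M^init) and fused by majority vote: a strictly
positive delta votes +1, otherwise -1 (an exact zero counts as the
non-increase branch; exact zeros only arise in frozen or degenerate
runs). The primary direction T is the sign of the vote sum; the fused
delta is the mean over agreeing seeds only, and M^Fusion = M^init +
Delta^Fusion. With an even seed count a tied vote yields no consensus
(T = 0, fused delta 0); with the default odd n this never triggers.

Distribution summaries (violin data, per-position mean and population
variance of the 12 mismatch values) are computed from the fused embedding.
Mismatch-pair similarity over a region (seed = positions 1-10, non-seed =
11-20, or all) is
Phi = (1 - alpha) * P + alpha * (1 - Norm(E)), alpha = 0.5 by default,
where P is the Pearson correlation and E the Euclidean distance of the
two tokens' per-position value vectors; Norm() is min-max over the 66
unordered distinct token pairs of the region, chosen so that
1 - Norm(E) spans [0, 1] symmetrically with Pearson's scale. A constant
profile makes Pearson undefined; such entries are flagged NaN. Group
summaries average Phi within each guide-base group (3 pairs) and between
group pairs (9 pairs).

For cross-dataset comparison, a dataset's "update distribution" is its
vote-fused delta over the 240 guide-row mismatch cells (a declared choice;
the published analysis does not pin down whether per-seed or fused deltas
were used). Pairwise Pearson correlations between datasets and a
mean-similarity ranking (descending) are reported; constant vectors are
flagged NaN.

## Synthetic data

`otpred.simdata` generates everything the tests need:

* Prior-table fixtures with the literature value ranges: MTP tolerances
  uniform over (0, 1] at the 240 mismatch cells; DRICS scores over all 320
  guide-row cells with matches in (0, 0.6] and mismatches in [-5.5, 0),
  the reported raw range of the source scores.
* Labelled pair datasets with a planted 20 x 16 effect matrix `w`:
  penalties at mismatch cells are the product of a positional severity
  (linearly decreasing from 2.5 at PAM-proximal position 1 to 0.5 at
  position 20, echoing seed-region sensitivity) and a fixed per-token
  factor in [0.4, 1.6] (the wobble pairs TC and GA mildest); match cells
  are 0. Sites carry 1-6 mismatches (uniform count, positions sampled
  without replacement, substitute bases uniform). Labels are Bernoulli
  with logit p = intercept + sum of penalties (default link) or
  p = sigmoid(intercept) * exp(sum) (product-of-tolerances link); the
  intercept is calibrated by bisection on the realized penalty sums so the
  expected prevalence hits the target (default 2%, emulating the extreme
  imbalance of genome-wide screens). Splits are guide-disjoint
  (default 60/20/20 by guide).

What the generator does **not** emulate: detection-technology biases and
cross-assay discordance, genomic sequence composition (guides are uniform
20-mers), bulges/indels, position-position interaction effects, and any
relationship between the prior tables and the planted effects (fixture
priors are independent noise). Passing the recovery tests therefore shows
that the machinery can pull a planted position-by-token structure out of
labelled pairs and expose it through the fused embedding update — not
that the priors or the learned updates are biologically correct on real
data.

## Desk-scale study sizes

The heavier checks run at deliberately small scale so the whole suite
completes on one CPU: the recovery study uses the generator defaults
(20 guides x 2000 sites, ~2% prevalence, guide-disjoint splits), 5 seeds
for each of the trainable M-model, frozen M-model and D-model, with
6 epochs maximum, patience 3, batch 256 and learning rate 3e-3 (a desk-
scale setting chosen for fast convergence of the small engine; the
package default remains 1e-3). Under those conditions the vote-fused
mismatch-cell deltas rank-correlate with the planted penalties
(|Spearman rho| >= 0.4), trainable runs beat frozen runs on held-out
per-sgRNA AUPRC in at least 4 of 5 seeds, and the mean-fused ensemble
stays within 0.02 of the better sub-model. Smoke tests use smaller
generators still (hundreds of sites).

## Known limitations

* The alphabet has no bulge/indel tokens; pairs must arrive pre-aligned
  and equal-length.
* Guide-similarity filtering uses ungapped positional identity over the
  20-mer, a declared stand-in for the (undocumented) published similarity
  measure.
* The NumPy engine targets clarity and desk-scale reproducibility, not
  GPU-scale throughput; training on millions of pairs is supported but
  slow.
* Threshold metrics at sgRNA level inherit the degenerate-case policy
  above; alternative aggregations are possible and would change F1/MCC
  summaries on sparse guides.
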