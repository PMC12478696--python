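# Methods

## Model

`epiattend` classifies a paired enhancer (3000 bp) and promoter (2000 bp)
DNA window as interacting or not, from sequence alone. The architecture is
a two-branch 1-D CNN feeding a single transformer block and a hierarchical
attention readout:

1. **Encoding.** Default "embed-OneHot": every base indexes a frozen 5 × 4
   lookup (A, C, G, T → standard basis vectors; N → the zero row). Freezing
   makes the encoding a pure lookup — datasets live on disk as raw strings
   and the matrix is materialized per batch. N encodes as all-zero rather
   than 0.25-uniform so undetermined bases contribute nothing to
   convolution sums. Lowercase input (soft-masked genome FASTA) is folded
   to uppercase. The alternative DNA2Vec mode tokenizes overlapping 6-mers
   (stride 1; tokens containing N map to a zero-vector unknown token) and
   looks them up in a width-100 pretrained table (word2vec text format); a
   deterministic random-frozen table stands in when no vector file is
   given. The exact tokenization used by upstream distributed-embedding
   work is not standardized; k = 6 with stride 1 is that lineage's
   convention and both k and the width are configurable.
2. **Branch feature extraction.** Per branch: valid-padding stride-1
   convolution (128 filters, width 40, ReLU — the convolution activation is
   a design choice; ReLU is the CNN-genomics default), then max pooling
   20/20. Pooled length is `floor(((L − 40 + 1) − 20)/20) + 1`: 148
   positions for the enhancer, 98 for the promoter.
3. **Merge.** Concatenation along the position axis, enhancer rows first,
   giving 246 × 128. (The published geometry — 148 enhancer parts followed
   by 98 promoter parts — fixes this order.) Dropout p = 0.5 follows the
   merge.
4. **Transformer block.** 16-head scaled dot-product self-attention
   (head dim 128/16 = 8; per head a row-stochastic 246 × 246 matrix with
   queries on rows), dropout, residual add, layer norm; then a 255 → 128
   feed-forward (ReLU then linear), dropout, residual add, layer norm.
   There is a single block and no positional encoding: the source design
   describes one block and never mentions positional encodings, and the
   conv/pool stage already encodes locality; treated as an open choice and
   kept minimal.
5. **Hierarchical attention readout.** `S = Σᵢ softmaxᵢ(tanh(W hᵢ + b)ᵀ u) hᵢ`
   with hidden width 246 (reading the published "attention layer dim" as
   the tanh hidden width; the alternative reading — that it merely restates
   the 246 positions — would leave the width unspecified, and 246 is a
   reasonable hidden size either way). The `tanh` here follows the design's
   prose description of the scoring function.
6. **Output.** One sigmoid unit on `S`.

The network, including backpropagation and Adam, is implemented in NumPy
(single precision) so it trains on a CPU-only scientific stack. Gradients
of every layer were verified against central finite differences in double
precision (relative error ~3e-6 across all parameter groups).

## Training protocol

* Split: 10% test, then 5% of the remaining pool for validation (the
  "5% further set aside from the training set" is read as 5% of the 90%
  pool), stratified by label, deterministic per seed.
* Imbalance handling, selectable per fit: **augment** creates shifted
  copies (|shift| in 10–50 bp) of each positive — after splitting and in
  the training split only, so no augmented copy of a positive can sit in a
  different split from its source; vacated ends fill with N because
  synthetic windows carry no flanking genome (a flank-aware variant would
  slice true context where available). **class_weight** multiplies each
  sample's cross-entropy term by the balanced inverse-frequency weight
  `w_c = N/(2 N_c)`, so w_pos/w_neg equals the negative:positive ratio.
* Optimizer: Adam, learning rate 1e-3 (configurable; the source design
  does not state one), batch 64, binary cross-entropy.
* Early stopping on validation AUPR (patience 10, max 100 epochs,
  configurable), restoring the best weights. A `monitor="loss"` option
  tracks validation loss instead: ranking metrics saturate early on easy
  tasks while the loss — and the sharpness of the attention maps — keeps
  improving, so loss-monitored stopping is used for interpretability
  studies.
* Two-stage ("pooled-then-finetune") protocol: stage 1 trains one model on
  the concatenated training splits of all cell lines; stage 2 clones the
  stage-1 weights and fine-tunes per cell line.
* Metrics: AUROC (rank/trapezoid) and AUPR (precision-recall step
  interpolation), the pair appropriate for 1:20 imbalance, via
  scikit-learn.

## Interpretability pipeline

Run on positive test samples of a trained model:

* **Region geometry.** Merged position r < 148 is an enhancer region with
  receptive field `[20r, 20r + 59)` (pool window of 20 conv positions, each
  conv window 40 bp); r ≥ 148 maps to the promoter analogously. The
  general formula is the union of conv windows under the pool window,
  clipped to the sequence.
* **Attention capture.** Per-sample, per-head 246 × 246 maps taken from
  the multi-head attention; rows are softmax distributions.
* **Pair ranking.** Candidates are restricted to the enhancer × promoter
  cross blocks; since attention is directional and the design does not say
  which direction was read, a candidate's score averages its two
  directional entries. Top 5–8 by default; ties break row-major; an
  exhaustive mode returns all 148 × 98 candidates ranked (used for
  CTCF-style scans beyond the top scores).
* **PWM extraction.** Per sample, within a region's pool window, the conv
  position maximizing the per-position maximum over filters selects a
  40-bp window; base counts accumulate into a 4 × 40 PWM with pseudocount
  0.25 per base (avoids zero probabilities that break motif comparison).
  Taking the max over filters (rather than per-filter extraction) is a
  design choice; pooling semantics in the source are not pinned down.
* **Interchange.** PWMs export as minimal MEME motif files; TOMTOM result
  TSVs are filtered at e-value < 0.07 and p < 1e-4; BioGRID TAB exports
  are joined order-insensitively on official gene symbols, with system
  types beyond physical/genetic mapped to "indirect". External tools are
  never invoked — only their formats are produced and consumed.
* **PWM comparison.** Two PWMs are compared by the best over relative
  shifts (minimum overlap: half the narrower motif, as motif-comparison
  tools allow) of the mean per-column Pearson correlation between 4-base
  frequency columns; zero-variance columns contribute 0. Partial-shift
  alignment matters because a convolution filter's preferred phase need
  not center the motif in its window.

## Synthetic data

The generator emulates the *shape* of Hi-C-derived EPI benchmarks:
fixed-length pairs (3000/2000 bp by default), a 1:20
positive:negative ratio, and uniform 50% GC background (configurable; the
benchmarks' composition is not modeled). Every positive carries exactly one
enhancer-motif and one promoter-motif plant at uniformly random admissible
positions, recorded in a ground-truth manifest; a planted base mutates with
probability `mutation_rate` to one of the other three bases, so the
expected match fraction to the consensus is 1 − μ. Negatives are pure
background by default; `negative_mode="single_motif"` plants exactly one of
the two motifs in a random half of negatives so that single-motif presence
is uninformative and only the *pairing* separates the classes.

What the generator does **not** emulate: genomic coordinates and
enhancer–promoter distance distributions (real benchmarks match them
between classes), repeat structure, GC heterogeneity, multiple or
cooperative motif occurrences, and cell-type-specific chromatin context.
Passing the recovery tests therefore shows the architecture and pipeline
can learn and localize a planted pairwise signal under heavy imbalance —
not that it attains any particular accuracy on real Hi-C-labeled data.

## Scaled study configurations

CPU-sized experiments use 300/200-bp windows, 16 filters of width 8,
pooling 4/4, 4 heads, feed-forward 32 → 16, attention hidden width 32 and
dropout 0.1 (`scaled_test_config()`); geometry then pools to 73 + 48 = 121
merged positions. The end-to-end recovery study trains on 500 positives +
2500 negatives with planted 8-mers mutated at rate 0.05, class-weighted
loss, learning rate 2e-3, and a fixed 30 epochs without best-weight
restore (the ranking metrics saturate within ~10 epochs while the
attention maps keep sharpening, so early stopping would measure the model
before it has localized the pairing), over five seeds. Recovery is scored per positive test sample: the sample's
own head-averaged attention matrix is ranked into top-8 cross-block pairs,
and the sample counts as recovered when one pair's receptive fields
overlap both of its planted windows (plants sit at random positions, so a
sample-averaged matrix would have no privileged region pair); a run
succeeds when the majority of samples recover, and the enhancer/promoter
PWMs aggregate each supporting sample's extracted window at its own
overlapping region.

## Numerical choices and degenerate inputs

* Forward arithmetic in float32; losses and metrics accumulate in float64.
* Softmax is max-shifted; sigmoid is computed in its numerically stable
  split form; cross-entropy clips probabilities at 1e-12.
* Glorot-uniform initialization throughout, seeded; dropout and batch
  shuffling draw from a separate seeded generator, so identical
  (config, seed) runs reproduce split membership and first-batch loss
  exactly.
* Max-pool backward routes the gradient to the first arg-max on ties.
* Splits use largest-remainder stratified allocation; when a split ends up
  single-class at tiny N a warning is emitted (validation-based early
  stopping then falls back to validation loss).
* `pooled_length` rejects inputs shorter than the kernel or pool window
  rather than returning zero-length maps.

## Known limitations

* No positional encoding and a single transformer block: positions are
  distinguishable only through content and the conv/pool locality, which
  is faithful to the source design but limits long-range order awareness.
* The NumPy engine is single-threaded per operation and intended for the
  scaled configurations; full-size (3000/2000, 128-filter) training works
  but is slow compared to GPU frameworks.
* DNA2Vec mode shifts the pooled geometry (tokens number L − k + 1), so
  its region receptive fields include the k − 1 token overhang; PWM
  extraction in that mode still counts kernel-width windows.
* Attention-derived region pairs are correlational; the BioGRID evidence
  join annotates, it does not validate.
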