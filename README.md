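# epiattend

Interpretable, sequence-only prediction of enhancer–promoter interactions
(EPIs), with motif and transcription-factor (TF) interaction extraction from
multi-head attention.

## The problem

Enhancers amplify the transcription of target genes by contacting their
promoters, often over large genomic distances; mapping which enhancer talks
to which promoter is central to understanding gene regulation and disease
variants. Experimental maps (Hi-C, ChIA-PET) are expensive, so classifiers
that score an (enhancer, promoter) pair of raw DNA windows — 3000 bp and
2000 bp respectively — are a practical substitute. Beyond the score itself,
biologists want to know *which* sequence elements drive a predicted
interaction: candidate TF binding motifs in the enhancer paired with motifs
in the promoter.

`epiattend` is for computational biologists who want such a classifier that
runs and trains on a plain CPU scientific Python stack, plus the
interpretability pipeline to go from attention weights back to motifs and
TF–TF interaction tables.

## The model

Each branch one-hot encodes its sequence through a **frozen embedding
lookup** (A,C,G,T → basis vectors, N → 0; the table is never trained, so
datasets stay on disk as raw strings at ~1 byte/base), then extracts local
features:

    Eo = MaxPool(ReLU(Conv(Embed(E))))      # 3000 bp → 148 × 128
    Po = MaxPool(ReLU(Conv(Embed(P))))      # 2000 bp →  98 × 128
    M  = [Eo ; Po]                          # 246 positions × 128 features

with 128 valid-padding convolution filters of width 40 and non-overlapping
max pooling 20/20. A single transformer block refines `M`:

    H = LayerNorm(FFN(X) + X),   X = LayerNorm(MHA(M) + M)

where MHA is 16-head scaled dot-product self-attention (each head a
row-stochastic 246 × 246 matrix; queries on rows) and the FFN is a
255 → 128 two-layer perceptron. A hierarchical attention readout

    S = Σᵢ softmaxᵢ( tanh(W hᵢ + b)ᵀ u ) · hᵢ

pools the 246 positions into one vector, and a single sigmoid unit outputs
the interaction probability. Training uses Adam on binary cross-entropy
with either shift augmentation of positives (whole-window shifts of
10–50 bp) or a balanced inverse-frequency class-weighted loss to handle the
1:20 positive:negative imbalance; model selection is by validation AUPR. A
DNA2Vec mode (overlapping 6-mers mapped to pretrained 100-d vectors in
word2vec text format) is available behind the same interface.

For interpretation, each of the 246 merged positions maps back to a 59-bp
receptive field (`[20r, 20r+59)`); enhancer-region × promoter-region pairs
are ranked by averaged cross-block attention; per region, the
strongest-activation 40-bp convolution windows of positive test sequences
are stacked into position weight matrices (PWMs), exported in MEME motif
format for comparison against motif databases (e.g. via TOMTOM, retaining
hits with e-value < 0.07 and p < 1e-4), and TF pairs are annotated with
physical/genetic evidence from a BioGRID TAB export. The network itself
(convolution, pooling, attention, layer norm, Adam, backpropagation) is
implemented in NumPy inside the package — no deep-learning framework is
required.

## Worked example

Because the benchmark Hi-C-labeled datasets require large downloads and
GPU-scale training, the package ships a first-class synthetic generator
that emulates their shape — fixed-length pairs, 1:20 imbalance — while
planting a known interacting motif pair as ground truth:

```python
import epiattend as ea

enh_motif = ea.PlantedMotif("enh8", "TGACGTCA", mutation_rate=0.05)
prom_motif = ea.PlantedMotif("prom8", "CCGGAAGT", mutation_rate=0.05)
records, manifest = ea.generate_dataset(
    500, 5, enh_motif, prom_motif, seed=11, enh_len=300, prom_len=200)

model = ea.EPIModel(records, config=ea.scaled_test_config())
res = model.fit(mode="class_weight", seed=11, max_epochs=12, patience=5)
print(res.summary())
```

```
Enhancer-Promoter Interaction Model Results
===============================================
Records (pos/neg)             500/2500
Splits (train/val/test)       2565/135/300
Imbalance mode                class_weight
Encoding                      onehot
Geometry (enh+prom=merged)    73+48=121
Heads x head dim              4 x 4
Epochs run (best)             12 (10)
Final train loss              0.2569
Test AUROC                    0.9690
Test AUPR                     0.9112
```

The test AUROC/AUPR say the model ranks held-out interacting pairs far
above non-interacting ones despite the 1:5 imbalance used here. Recovery of
the planted ground truth closes the loop:

```python
positives = [r for r in res.test_records if r.label == 1]
report = ea.evaluate_motif_recovery(res, positives, manifest, k=8)
print(round(report.overlap_fraction, 2), round(report.enh_pwm_correlation, 3))
```

`overlap_fraction` is the fraction of positive test pairs whose top-8
attention region pairs point at both planted windows, and the PWM
correlation compares the motif rebuilt from convolution activations with
the planted one; the short run above prints `0.58 0.997` — the extracted
PWM already reads `TGACGTCA`, and training to convergence (~30 epochs)
pushes the overlap fraction above 0.9 for most seeds.

The same pipeline is scriptable from the shell:

```bash
epiattend gen-data --n-pos 500 --neg-per-pos 5 --seed 11 --out data/
epiattend train --data data/dataset.tsv --mode class_weight --seed 11 --out run/
epiattend evaluate --model run/ --data data/dataset.tsv --split test --out run/
epiattend interpret --model run/ --data data/dataset.tsv --top-k 8 \
    --meme-out run/regions.meme --out run/
```

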