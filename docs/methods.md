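# Methods

## The prediction problem

A transcription factor (TF) binds short, degenerate sequence patterns
(motifs), and chromatin immunoprecipitation sequencing (ChIP-seq) reports
where in a genome a given TF was bound in a given cell type. The package
frames genome-wide binding-site prediction the standard way: tile the
genome into fixed 200 bp bins, call a bin positive for an experiment when
at least 50% of the bin is covered by that experiment's peaks, and predict
the whole label vector (one bit per TF-cell-type experiment) from the
bin's 1000 bp sequence context. What distinguishes this architecture from
sequence-only predictors is that each TF is also represented by a
fixed-length protein embedding (mean-pooled output of a protein language
model adapted to DNA-binding proteins, dimension d2 = 1280, consumed here
as a precomputed table), and prediction couples the two modalities through
cross-attention.

## Model

**DNA encoder.** The one-hot (L_in x 4) window passes through a valid
(unpadded) 1-D convolution — 320 filters, kernel width 26, ReLU — then
non-overlapping max-pooling with window 13. "Valid" convolution and
stride-13 pooling are forced by the arithmetic: the pooled length is
L = floor((L_in − 26 + 1) / 13), which gives exactly L = 75 for the
1000 bp default. A two-layer bidirectional LSTM (160 units per direction)
produces d1 = 320 features per position, and one pre-norm transformer
encoder layer (16-head self-attention, 1024-unit feed-forward) globalizes
them into H (L x d1). The pooled vector x1 is the position-mean of H. No
positional encoding is added in the transformer or fusion stages: the
BiLSTM already injects order, and the fusion summary is mean-pooled anyway
(a design choice; the attention itself is permutation-invariant over its
key/value rows).

**Protein projection.** Each TF embedding e_p (d2) is mapped by a
learnable affine x2 = W_p e_p + b_p into the d1-dimensional DNA feature
space. Embeddings are consumed unnormalized; the projection absorbs scale.

**Cross-attention fusion.** Projected TF vectors are queries; keys and
values derive from H. Attention is softmax(q K^T / sqrt(d_head)) V per
head with 16 heads, head concatenation followed by a learned output
projection (the standard multi-head completion of the single-head
formula). Attention dimensionality d equals d1, keeping [x1; z] symmetric.
In the multilabel model all E experiment queries (each experiment using
its TF's embedding, duplicated across cell types) run in one attention
pass; the attended rows are mean-pooled into a single summary z. Per-label
affine heads score [x1; z] — the minimal reading of label-specific
classifier weights. Mean-pooling all attended rows before the heads
discards TF-specific attended detail; it is implemented as specified, and
the pooled-z design is part of the architecture being reproduced.

**Variants.** `fusion_mode` selects plain concatenation (z is the mean of
the projected TF vectors; no attention), unidirectional cross-attention
(default), or bidirectional (an extra pass where DNA positions query the
TF set; its mean-pooled result is concatenated to the head input).
`encoder_mode` drops the transformer (`lstm_only`), the BiLSTM
(`transformer_only`; a linear adapter restores the d1 width when the
filter count differs), or both (`sequence_only`).

**Pairwise (label-zero-shot) variant.** The same stack with a single
query and one shared affine head maps an arbitrary (DNA window, TF
embedding) pair to one logit. During training, whole embeddings are masked
to zero with probability 0.05 and element-wise Gaussian noise
(sigma = 0.01) is added to unmasked ones, discouraging memorization of TF
identity. Because the head is shared, a TF never seen in the label matrix
can be scored by supplying its embedding.

## Training and evaluation

Loss is binary cross-entropy on logits (computed via the stable
softplus form); the optimizer is AdamW (default learning rate 3.28e-4,
weight decay 0.028) with cosine annealing over the epoch budget (default
60) at batch size 256. Checkpoint selection uses validation macro-AUPR,
the informative metric under severe class imbalance; class imbalance is
otherwise handled only by the loss. AUROC is the rank statistic
(ties half credit) and AUPR is average precision (step-wise PR integral,
the non-optimistic estimator) — both computed per label via scikit-learn,
with labels lacking either class excluded from macro means and listed.
Paired model comparison uses a two-sided paired t-test plus paired
Cohen's d = mean(diff)/sd(diff, ddof=1); zero-variance differences are
flagged degenerate rather than producing an undefined p-value. The
leave-three-out harness deals disjoint held-out TF triples from a seeded
shuffle; pairs involving held-out TFs are removed from training and
validation, and the no-leakage property is asserted at construction.

The whole network stack — autodiff, layers, AdamW — is implemented on
numpy inside `transbind.nn` and gradient-checked against central finite
differences; training is exactly reproducible given the config seeds
(single-threaded deterministic BLAS ops, `numpy.random.Generator`
streams for batching, dropout and masking).

## Data pipeline conventions

Coordinates are 0-based half-open (BED convention) throughout. Trailing
partial bins are dropped. The 50% overlap threshold is inclusive and uses
union coverage (merged peak intervals), so abutting peaks are not double
counted. Duplicate bins are OR-merged (positive in any duplicate record
means positive). Windows whose flank extension leaves the chromosome, or
that contain any non-ACGT character, are rejected and counted — rejection
rather than padding, consistent with discarding ambiguous sequence; the
counts appear in the build log and dataset metadata. Reverse-complement
augmentation doubles every partition and inherits labels unchanged
(binding is double-stranded); augmentation is applied within partitions,
after the chromosome split, so a window and its reverse complement can
never cross partitions. The 8-mer Jaccard audit samples sequences without
replacement, uppercases, skips k-mers containing N, and evaluates all
cross pairs of the sampled sets on k-mer presence (not multiplicity).

## Protein identity analysis

Global pairwise alignment uses BLOSUM62 with affine gaps (open 10, extend
0.5 — EMBOSS-needle-style defaults) and identity = identical aligned
residue pairs / alignment length, gaps included. The alignment scheme of
the original diversity analysis is not recorded anywhere authoritative,
so published summary identities may differ slightly under this pinned
scheme; the scheme is echoed in every report.

## Interpretability

Two routes recover motifs from a trained model. (1) Kernel motifs: each
first-layer filter becomes a PWM either by per-column softmax of its
weights or — the default for MEME export, following DeepBind-style
practice — by scanning sequences and counting the bases of k-length
subsequences whose activation reaches a fraction (default 0.5; the
recovery study uses 0.7) of the global maximum. (2) Attribution motifs:
integrated gradients of one label's logit with respect to the input,
conditioned on that TF's embedding, evaluated at midpoint Riemann nodes
(default 128 steps) from an all-zeros baseline (the "absent sequence");
the completeness gap |sum(attributions) − (F(x) − F(baseline))| is always
reported. Only positive attributions of the observed base count toward
window scores (binding evidence, not repulsion); each sequence contributes
its best window of the chosen width, windows in the top quantile are
stacked into a position frequency matrix, and a few deterministic EM
rounds flip each window to the strand the consensus prefers (seeded from a
single window so an exact 50/50 strand mixture cannot stall). MEME output
quantizes each row to the 6-decimal grid with largest-remainder rounding
so serialized motifs re-parse as exactly normalized PWMs; background
defaults to uniform 0.25 unless a genome-derived background is supplied.

Recovered and planted PWMs are compared by sliding the shorter matrix
along the longer on both strands and taking the alignment minimizing the
mean per-column total-variation distance (0 identical, 1 disjoint).

## Synthetic data: what it does and does not emulate

The generator produces (i) a random genome with adjustable GC content
(default 0.41, the human genome-wide fraction); (ii) per-experiment peak
sets — peaks placed uniformly without overlap within an experiment
(rejection sampling, 1000 retries) but freely across experiments,
mirroring multi-TF co-binding — where with probability `motif_insert_prob`
a peak receives one motif instance sampled column-wise from the
experiment's PWM, on a uniformly chosen strand, written into the genome so
sequence and labels agree; and (iii) TF embeddings as unit-norm family
centroids plus Gaussian noise, with experiments of one motif family
sharing an embedding family. Everything is a pure function of the spec
including its seed.

Deliberately not emulated: read-level signal, peak-calling artifacts,
antibody effects, chromatin accessibility, and genomic sequence
composition (repeats, CpG islands). One consequence of uniform peak
placement is intrinsic label noise: a peak overlapping a bin just below
50% leaves its motif inside a *negative* bin's window, so even a perfect
motif detector cannot reach AUROC 1 on this data — a degraded analogue of
real ChIP-seq boundary ambiguity. Passing tests therefore demonstrate that
the implementation learns and recovers planted signal under controlled
conditions, not that it reproduces benchmark performance on real
ENCODE-scale data, which requires the original dataset, real protein
embeddings, and GPU-scale training.

## Study problem sizes and settings

The reference studies in `transbind.studies` use 100 bp bins with 50 bp
flanks (200 bp windows; a peak overlapping a bin by >= 50% always lies
inside the window), motifs of width 10 with consensus probability 0.95,
`motif_insert_prob` 1, and a scaled architecture: 32 filters, kernel 12,
pool 10 (L = 18), one BiLSTM layer of 16 units per direction (d1 = 32),
4 transformer and cross-attention heads, embedding dimension 64.
Optimization for these small problems uses a higher learning rate than
the full-scale default (2e-3 to 3e-3) because the loss surface is far
smaller. Motif width matters at this scale: de-novo discovery by a
randomly initialized convolution is only reliable when the motif carries
enough information content (~20 bits at width 10) to stand out from a
0.41-GC background within a few thousand training windows; narrower or
highly AT-rich motifs can stay undiscovered within this epoch budget,
which is a property of desk-scale motif learning, not of the
architecture.

* **Memorization study** — 64 bins x 4 labels, regularization off
  (dropout 0, weight decay 0): a pure capacity check that the full stack
  can drive training loss near zero and rank its own training bins almost
  perfectly within 200 epochs.
* **Motif recovery study** — 2000 bins over four chromosomes (one held
  out for validation, one for testing), 2 experiments with one motif
  family each, 350 peaks per experiment (positive prevalence ~18%, enough
  motif instances for discovery); dropout 0.1 and weight decay 0.028, 60
  epochs, best-validation checkpoint. Interpretation conditions on the
  experiment with the highest validation AUROC — interpretability is
  applied to signal the model demonstrably acquired — and both routes
  (kernel activation counting over the full training set at 0.7 of the
  maximum activation; integrated-gradients attribution at 24 path steps,
  top half of per-sequence best windows) are compared against that
  experiment's planted motif.
* **Zero-shot family study** — 1000 bins, 9 TFs in 3 embedding families
  (3 TFs each), 150 peaks per TF with 90% of each TF's peaks drawn from
  its family's shared repertoire and tight embedding families (noise
  0.02), one TF held out; the pairwise model (dropout 0.05, 40 epochs)
  trains on the other 8 TFs' (window, embedding, label) triples and the
  held-out TF's never-seen labels are scored against a 1000-draw
  label-permutation null (95th percentile). This probes *label*-zero-shot
  transfer — the mechanism the pairwise model is designed for: binding
  knowledge learned for paralogous training TFs reaches the unseen TF
  through embedding proximity. Training loss certifies the mechanism: a
  model blind to the embedding cannot fit windows whose labels conflict
  across families, so a low loss implies family-conditional predictions.

## Known limitations

* The numpy network is CPU-only and orders of magnitude slower than a GPU
  framework; full-scale (690-label, 1000 bp, millions of bins) training is
  out of reach by design.
* The exact output-head internals of the original architecture are
  under-determined by its published parameter counts; the per-label affine
  head here is the minimal consistent reading, so parameter counts are not
  expected to match published totals.
* The multilabel model's single pooled summary vector z limits how much
  TF-specific attended signal survives to the heads; this mirrors the
  specified architecture rather than an optimized alternative.
* Synthetic zero-shot transfer operates through embedding-family
  proximity; it cannot probe transfer to genuinely novel structural
  families, which requires real protein embeddings.
* At desk scale the pairwise model does not additionally generalize its
  TF-conditioned predictions to chromosomes absent from training: the
  single-TF pairwise fit generalizes across chromosomes as well as the
  multilabel model does, but with many TFs per window the embedding
  pathway (which enters only through attention weights) is too weak for
  joint motif-plus-TF learning at a few thousand windows. The zero-shot
  study therefore evaluates unseen labels on the binding landscape the
  model was trained on, mirroring a fixed-genome, new-TF use case;
  simultaneous new-TF/new-locus generalization is a full-scale property
  the synthetic studies do not establish.
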