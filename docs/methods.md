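# Methods

## Problem setting

Given a genome and a set of annotated lncRNA loci, the task is binary: decide
whether a genomic stretch (an annotated locus plus fixed-length flanking
context) is a lncRNA locus or a random stretch of the same genome and length.
The contrast deliberately contains no transcriptome signal — the claim under
test is that genomic sequence context alone carries enough information, and
that the informative sequence features can be recovered and localized by
attribution analysis.

Coordinates are 0-based half-open internally; GTF I/O converts to/from
1-based inclusive at the boundary, and BLAST-style alignment records keep
their native 1-based inclusive query coordinates until consumed.

## Dataset construction

* **Flanks.** Each locus is extended by `flank` bases (default 500) on both
  sides, clamped at chromosome boundaries: `start' = max(0, start − flank)`,
  `end' = min(L, end + flank)`. The flank length is configuration, not a
  constant, because regulatory context widths are study-dependent.
* **Similarity filter.** Queries whose merged alignment coverage against an
  mRNA database exceeds 90% of their length are removed as likely
  protein-coding contamination. HSP query intervals are union-merged before
  computing the covered fraction, so overlapping hits are not double
  counted; "over 90%" is a strict inequality (a query at exactly 0.90 is
  retained). Queries with no alignments are retained; records naming unknown
  queries are skipped with a warning.
* **Controls.** For every flanked lncRNA a random genomic interval of exactly
  the same length is drawn (uniform over chromosomes weighted by length,
  rejection sampling) with zero overlap against the flanked lncRNA
  intervals. Controls may overlap one another (mirroring `bedtools shuffle`
  defaults); such events are logged. The control's nominal core is its
  sequence minus `flank` on each side, giving both classes the same
  coordinate scheme for positional profiling.
* **Split.** Stratified train/test split (scikit-learn) with a fixed seed;
  class proportions are preserved to within one item.
* **Tokenization.** Overlapping k-mers, stride 1, k ∈ [3, 6]; a sequence of
  length L yields L − k + 1 tokens. K-mers containing N map to the unknown
  token at encoding time so that N runs never shift coordinates.
* **Strand.** Sequences are taken from the stored (forward) strand;
  strandedness of extraction is a known limitation.

## Classifier

A deliberately small encoder trained from random initialization:

* token + learned absolute position embeddings (64 dims);
* a residual width-7 1-D convolution stem over the embeddings. The
  convolution makes short motifs (up to ~9 bp at k=3) visible to single
  learned filters; learning strict k-mer adjacency through attention alone
  is unreliable within the few hundred gradient steps of a desk-scale run;
* two pre-norm transformer blocks (4 heads, feed-forward 256, ReLU);
* a final LayerNorm and a two-part pooled representation feeding a 2-way
  linear head: the PAD-masked **mean** over the attention-stack output
  (context summary) concatenated with the PAD-masked **max** over the
  conv-stem ReLU activations (motif-detector summary, in the style of
  classic convolutional motif models). The max is taken *before* any
  LayerNorm deliberately: normalization equalizes per-position magnitudes
  and would erase the single-position contrast that motif presence
  detection relies on. `[CLS]`/`[SEP]` are emitted by the encoder but the
  pooled representation is used for classification — attention-pooling
  through a CLS query is noisy at this scale, and masked pooling preserves
  exact invariance to padding length. A mean-only pooling mode is kept for
  ablation.

**Long sequences.** Token streams longer than `max_seq_length` are processed
as non-overlapping windows, each encoded as `[CLS] … [SEP]`. Each window
yields a scalar evidence score d = logit(lncRNA) − logit(other); the
sequence score is the log-mean-exp of its window scores and
p(lncRNA) = sigmoid(score). Log-mean-exp is a smooth maximum: one strongly
informative window suffices to call a sequence positive, which matches the
biology (boundary motifs occupy one or two of ~6 windows of a flanked
locus) and is the standard multiple-instance aggregation. A plain average
provably fails here: the informative window's gradient is diluted 6-fold
and training collapses to the majority logit. For single-window sequences
the formulation reduces exactly to the 2-way softmax. Training
backpropagates through the aggregation, so optimization is end-to-end at
the sequence level. The single-window `encode` path (truncation from the
end) is retained for short-input use.

**Optimization.** AdamW (decoupled weight decay 0.01 on matrix-shaped
parameters), cross-entropy, linear warmup over the first 10% of steps then
linear decay to zero, dropout 0.1. The configuration defaults follow the
standard fine-tuning recipe for pre-trained DNA language models (learning
rate 2e-5, 4.0 epochs, batch 4, `max_seq_length` 2048). The **tiny reference
configuration** used throughout the tests overrides what the from-scratch
setting requires: `max_seq_length` 256, learning rate 2e-3, batch 8,
3 epochs. Training is bit-reproducible given (data, seed) on a single
worker; gradients are verified against central finite differences in the
test suite. The network is pure NumPy — no deep-learning framework is
required at install or run time.

## Attribution and motif extraction

Attribution targets the lncRNA class probability p:

* **occlusion** (default): `score_i = p(full) − p(token i → [MASK])`.
  Deterministic and model-agnostic; cost is one forward pass per token, so
  it is the method of choice for small inputs and spot checks.
* **gradient×input**: ∂p/∂(embedding of token i) · embedding(token i); one
  forward/backward pass per sequence. This is the practical method when
  attributing hundreds of multi-window sequences, and is what the pipeline
  harness uses for motif discovery.

Runs of **≥ 8 successive strictly positive** scores ("more than 7") are
merged into one motif occurrence: the k-mers reconstruct the underlying
substring (length = run + k − 1) and the run's scores are summed. A score of
exactly zero is non-positive and terminates a run; the threshold is exposed
as `min_run` so the ≥ 7 reading can also be tested. Motif identity for
frequency counting is exact string equality, and the ranking key is
frequency × summed attribution; the top 50 are reported.

## Motif statistics

* **Enrichment.** Presence counts (a sequence counts once regardless of
  occurrence multiplicity, mirroring line-wise `grep`; an occurrences mode
  exists but is not default) feed a Pearson chi-square on the 2×2 table,
  df = 1, no continuity correction; p from the chi-square survival function.
  Motifs with raw p < 0.05 are kept. No multiple-testing correction by
  default, matching the raw-threshold convention; Benjamini–Hochberg is
  available as an option. Tables with a zero marginal are flagged and
  reported as p = 1.
* **Sharing.** Exact-match sharing across species is always computed;
  optional clustering links two motifs iff one is a substring of the other
  (single linkage over the containment graph), which merges homopolymer
  length variants (AAAAAAA / AAAAAAAA) into one cluster. The containment
  rule is the package's operationalization of "sequence similarity" —
  deliberately minimal and auditable.
* **Positional profile.** Occurrence start positions are assigned to 60
  bins: 1–20 tile the upstream flank at flank/20 bp (25 bp for 500 bp
  flanks), 21–40 tile the lncRNA body in 5% intervals, 41–60 tile the
  downstream flank. Because the body length varies while flanks are fixed,
  each sequence's body-bin contribution is rescaled by (flank bin width /
  body bin width) before accumulation, putting body counts on the flanks'
  per-width scale; a doubling of body length at constant per-base motif
  density then leaves the normalized body mass unchanged in expectation.
  Zero-length cores are skipped with a warning.

## Synthetic data

The generator emulates exactly the statistical structure the pipeline
assumes and nothing more: i.i.d. background with P(G)=P(C)=gc/2 (default GC
0.40, a typical plant genome value), uniformly placed non-overlapping loci
(rejection sampling with a retry cap; the reserved span includes the motif
windows so plantings never invade a neighbouring locus), and motif strings
overwritten into the 100 bp windows immediately up- and downstream of each
locus boundary with probability 0.9 per side. Planting overwrites bases in
place, so coordinates never shift and the GTF stays valid. The default
grammar is the 8-mer `TGACGTCA` (the ACGT-box core of many plant
cis-regulatory elements); transfer experiments use `CTTAGGCC` as an
unrelated grammar. All outputs are byte-identical under a fixed
(config, seed).

What this does **not** emulate: gene models, splicing, repeats, GC
heterogeneity, chromatin context, or any sequence signal intrinsic to real
lncRNA bodies. Passing tests therefore demonstrate that the pipeline
recovers boundary-localized sequence signal when it exists — they say
nothing about how much such signal real genomes carry.

## Problem sizes and numerical choices

The study-condition runs use 1000 planted loci (201–400 bp, 500 bp flanks,
matched controls; 80/20 split) for the single-species analysis, 250-locus
species for transfer checks, and the tiny reference classifier; the
acceptance script defaults to 500/200 loci, chosen as the package's
reference desk-scale problem, and trains at batch 4 so the smaller dataset
still yields the same ~600-step optimization budget. Attribution for motif
discovery uses up to 150 held-out lncRNA sequences with gradient×input.

Ties in motif ranking break lexicographically. Degenerate metric
denominators (e.g. no predicted positives) report 0 with a warning rather
than raising, so model sweeps keep running. The AUROC estimator averages
tied ranks. Softmax uses max-subtraction; attention masks PAD keys with an
additive −1e9 bias; float32 is used for training with float64 accumulation
in losses and probabilities.

## Known limitations

* The classifier is a desk-scale stand-in trained from scratch: it shares
  the tokenization, optimization schedule, interfaces and interpretation
  contract of large pre-trained DNA language models, not their capacity.
* Strand is ignored at extraction.
* Exact-string motif identity fragments context-dependent attribution runs;
  the clustering option only partially compensates.
* Occlusion attribution is quadratic in sequence length for multi-window
  inputs; use gradient×input at scale.
* The similarity filter consumes alignment tables; it does not run an
  aligner.
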