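# lncmotif

Identify long non-coding RNAs (lncRNAs) directly from **genomic DNA** with a
k-mer token sequence classifier, and explain the predictions by extracting,
ranking, significance-testing and positionally profiling the genomic motifs
that drive them.

Most lncRNA predictors work from transcriptome assemblies and hand-crafted
coding-potential features. This package implements the alternative route: the
input is a genome FASTA plus lncRNA annotations (GTF); each annotated locus is
extracted with 500 bp flanking context, contrasted against length-matched
random genomic controls, tokenized into overlapping k-mers (k = 3..6), and
classified by a small self-attention encoder with a convolutional
motif-detector stem. An explainability stack then
asks *why* a sequence was called lncRNA: per-k-mer attribution scores are
computed, runs of 8 or more successive positively-attributed k-mers are merged
into candidate motifs, motifs are ranked by

    importance = frequency × Σ attribution,

chi-square tested against the control class (p < 0.05), and localized on a
60-bin coordinate system (20 bins upstream flank / 20 bins lncRNA body,
length-normalized / 20 bins downstream flank).

Because assembling real training sets requires genome downloads, the package
ships a first-class synthetic-data module: multi-chromosome i.i.d. background
genomes with planted lncRNA loci whose boundary regions carry a configurable
motif grammar, emitted as FASTA + GTF + ground-truth tables. Every stage of
the pipeline is testable against this ground truth, end to end.

## The model and metrics

Sequences are tokenized into overlapping k-mers (stride 1) and encoded as
`[CLS] t₁ … tₙ [SEP]` windows over a vocabulary of 4^k k-mers plus five
special tokens. The classifier is a from-scratch desk-scale encoder: token +
learned position embeddings, a residual width-7 convolution stem, two
pre-norm transformer blocks (4 heads, 64 dims), pooling that concatenates
the masked mean of the attention stack with the masked max of the conv-stem
activations, and a 2-way softmax head. Sequences longer than one window are processed in
non-overlapping windows whose evidence scores are combined by a smooth
maximum (log-mean-exp), trained end-to-end. Training uses AdamW with linear
warmup (10%) and linear decay, cross-entropy loss, and is bit-reproducible
under a fixed seed on one worker.

Evaluation reports the six standard metrics with lncRNA as the positive
class:

    accuracy  = (TP+TN) / (TP+TN+FP+FN)          F1  = TP / (TP + (FP+FN)/2)
    precision = TP / (TP+FP)                     recall = TP / (TP+FN)
    MCC       = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

and AUROC via the tie-averaged Mann–Whitney estimator. A cross-species
harness evaluates one species' model on other species' test sets and
aggregates accuracies by lineage group (monocot/dicot).

## Worked example

```python
from lncmotif import pipeline
from lncmotif.model import tiny_reference_config

res = pipeline.run_species(
    seed=1009, species="species1", n_loci=500, n_attribution=120,
    config=tiny_reference_config(k=3, seed=1012, batch_size=4),
)
print(f"held-out accuracy {res.metrics.accuracy:.3f}  "
      f"AUROC {res.metrics.auroc:.3f}  MCC {res.metrics.mcc:.3f}")
print("top motif:", res.ranked_motifs[0].motif_sequence)
print(f"planted motif {res.planted_motif}: chi2={res.planted_chi2[0]:.1f} "
      f"p={res.planted_chi2[1]:.2e}, flank mass {res.planted_flank_mass:.2f}")
```

This simulates one species (500 lncRNA loci of 201–400 bp, 500 bp flanks, the
8-mer `TGACGTCA` planted near both locus boundaries with probability 0.9),
trains the tiny reference classifier, and prints:

```
held-out accuracy 0.970  AUROC 0.983  MCC 0.940
top motif: ATGACGTCAA
planted motif TGACGTCA: chi2=937.1 p=8.52e-206, flank mass 1.00
```

i.e. the classifier separates lncRNA loci from random genomic stretches, the
highest-ranked attribution motif contains the planted 8-mer, the motif is
overwhelmingly enriched in the lncRNA class, and essentially all of its
positional profile mass falls in the flank bins — the boundary localization
the method is designed to reveal. The run takes a few minutes on one CPU.

The same steps are available from the shell:

```bash
lncmotif simulate --config cfg.yaml --outdir sim/
lncmotif build-dataset --genome sim/genome.fa --gtf sim/loci.gtf --outdir data/
lncmotif train --dataset data/train.tsv --k 3 --outdir model/
lncmotif evaluate --model model/ --dataset data/test.tsv --out metrics.tsv
lncmotif interpret --model model/ --dataset data/test.tsv --out motifs.tsv
lncmotif motif-stats --motifs motifs.tsv --lnc data/test.tsv --ctrl data/test.tsv --outdir stats/
```

## Layout

| module | contents |
| --- | --- |
| `lncmotif.simulate` | synthetic genomes, planted loci, motif grammars, alignment tables |
| `lncmotif.datasets` | FASTA/GTF/BLAST-table readers, flanks, similarity filter, controls, splits, k-mers |
| `lncmotif.model` | vocabulary, encoding, the classifier, training, persistence |
| `lncmotif.nn` | the NumPy encoder: forward, backprop, AdamW, schedules |
| `lncmotif.evaluate` | six metrics, confusion counts, cross-species harness |
| `lncmotif.attribution` | occlusion / gradient×input attribution, run merging, motif ranking |
| `lncmotif.motifstats` | chi-square enrichment, motif sharing/clustering, 60-bin profiles |
| `lncmotif.pipeline` | end-to-end runs used by the tests and `scripts/acceptance.py` |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
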