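"""Shared fixtures: small separable training fixtures and the full-scale
single-species pipeline run reused by the acceptance tests."""
from __future__ import annotations

import numpy as np
import pytest

from lncmotif import datasets, model, pipeline
from lncmotif.types import LNCRNA, NON_LNCRNA

BASES = np.array(list("ACGT"))
PLANTED = pipeline.PRIMARY_MOTIF  # TGACGTCA


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


def make_separable_sequences(
    rng: np.random.Generator,
    n_per_class: int = 80,
    length: int = 120,
    motif: str = PLANTED,
):
    """Fully separable fixture: positives carry the motif once, negatives never."""
    positives, negatives = [], []
    for _ in range(n_per_class):
        s = random_dna(rng, length)
        pos = int(rng.integers(0, length - len(motif)))
        positives.append(s[:pos] + motif + s[pos + len(motif):])
        neg = random_dna(rng, length)
        while motif in neg:
            neg = neg.replace(motif, random_dna(rng, len(motif)))
        negatives.append(neg)
    return positives, negatives


def tokenized_pairs(positives, negatives, k=3):
    docs = [
        (datasets.seq_to_kmers(s, k, source_id=f"pos{i}"), 1)
        for i, s in enumerate(positives)
    ] + [
        (datasets.seq_to_kmers(s, k, source_id=f"neg{i}"), 0)
        for i, s in enumerate(negatives)
    ]
    return docs


@pytest.fixture(scope="session")
def separable_data():
    rng = np.random.default_rng(1234)
    positives, negatives = make_separable_sequences(rng, n_per_class=80)
    docs = tokenized_pairs(positives, negatives)
    order = rng.permutation(len(docs))
    docs = [docs[i] for i in order]
    split = 120
    return {
        "train": docs[:split],
        "test": docs[split:],
        "positives": positives,
        "negatives": negatives,
    }


@pytest.fixture(scope="session")
def separable_model(separable_data):
    """Tiny classifier trained on the separable fixture (single-window inputs)."""
    cfg = model.tiny_reference_config(
        k=3, seed=7, batch_size=4, learning_rate=2e-3, epochs=6.0,
        logging_steps=50,
    )
    return model.train(separable_data["train"], None, cfg)


@pytest.fixture(scope="session")
def species1_result():
    """Full-scale single-species pipeline run under the study conditions:
    1000 planted loci (201-400 bp, 500 bp flanks, boundary 8-mer planted with
    probability 0.9), matched controls, tiny reference classifier."""
    return pipeline.run_species(
        seed=101, species="species1", n_loci=1000, n_attribution=150
    )
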