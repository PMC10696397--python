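"""End-to-end desk-scale pipeline runs shared by the test harness and scripts.

A "species" here is a simulated genome with planted lncRNA loci whose flanks
carry a short motif grammar.  ``run_species`` takes such a species through
dataset construction, training, evaluation, attribution-based motif discovery,
significance testing, and positional profiling — the same sequence of steps a
real-genome analysis would follow.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import attribution, datasets, evaluate, model, motifstats, simulate
from .types import KmerDocument, LabeledSequence, LNCRNA, MetricsReport, RankedMotif

#: The default "grammar" planted at locus boundaries of the primary species:
#: the TGACGT/ACGT-box core found in many plant cis-regulatory elements.
PRIMARY_MOTIF = simulate.DEFAULT_FLANK_MOTIF
#: An unrelated grammar for negative-transfer species.
UNRELATED_MOTIF = "CTTAGGCC"


def species_config(
    seed: int,
    n_loci: int = 1000,
    motifs: Tuple[str, ...] = (PRIMARY_MOTIF,),
    bases_per_locus: int = 4000,
) -> simulate.SyntheticConfig:
    """Study-condition generator config: loci of 201-400 bp, 500 bp flanks
    downstream, boundary motifs planted with probability 0.9 within 100 bp
    of each locus edge."""
    n_chrom = 4
    chrom_len = max(50_000, int(np.ceil(n_loci * bases_per_locus / n_chrom)))
    return simulate.SyntheticConfig(
        n_chromosomes=n_chrom,
        chromosome_length=chrom_len,
        gc_content=0.40,
        n_loci=n_loci,
        locus_length_range=(201, 400),
        flank_motifs=motifs,
        motif_insert_probability=0.9,
        motif_window=100,
        seed=seed,
    )


def tokenize_dataset(
    sequences: Sequence[LabeledSequence], k: int
) -> List[Tuple[KmerDocument, str]]:
    return [
        (datasets.seq_to_kmers(s.sequence, k, source_id=s.id), s.label)
        for s in sequences
    ]


@dataclass
class SpeciesData:
    species: str
    config: simulate.SyntheticConfig
    truth: simulate.GroundTruth
    train_seqs: List[LabeledSequence]
    test_seqs: List[LabeledSequence]

    @property
    def all_seqs(self) -> List[LabeledSequence]:
        return self.train_seqs + self.test_seqs


def make_species(
    seed: int,
    species: str,
    n_loci: int = 1000,
    motifs: Tuple[str, ...] = (PRIMARY_MOTIF,),
    flank: int = datasets.DEFAULT_FLANK,
    test_fraction: float = 0.2,
) -> SpeciesData:
    """Simulate one species and build its labelled, flanked, split dataset."""
    cfg = species_config(seed, n_loci=n_loci, motifs=motifs)
    genome, truth, annotations = simulate.simulate_species(cfg, species=species)
    labelled = datasets.build_dataset(
        genome, annotations, flank=flank, species=species, seed=seed + 1
    )
    train_seqs, test_seqs = datasets.split_dataset(
        labelled, test_fraction=test_fraction, seed=seed + 2
    )
    return SpeciesData(species, cfg, truth, train_seqs, test_seqs)


@dataclass
class SpeciesRunResult:
    data: SpeciesData
    classifier: model.TrainedClassifier
    metrics: MetricsReport
    ranked_motifs: List[RankedMotif]
    planted_motif: str
    planted_chi2: Tuple[float, float]
    planted_flank_mass: float
    motif_tests: List


def run_species(
    seed: int,
    species: str = "species1",
    n_loci: int = 1000,
    k: int = 3,
    motifs: Tuple[str, ...] = (PRIMARY_MOTIF,),
    n_attribution: int = 200,
    attribution_method: str = "gradient_input",
    config: Optional[model.ClassifierConfig] = None,
) -> SpeciesRunResult:
    """Full single-species run: simulate, train, evaluate, interpret, test."""
    data = make_species(seed, species, n_loci=n_loci, motifs=motifs)
    cfg = config or model.tiny_reference_config(k=k, seed=seed + 3)
    train_set = tokenize_dataset(data.train_seqs, cfg.k)
    test_set = tokenize_dataset(data.test_seqs, cfg.k)
    classifier = model.train(train_set, None, cfg)
    metrics = evaluate.evaluate_model(classifier, test_set)

    lnc_test = [s for s in data.test_seqs if s.label == LNCRNA][:n_attribution]
    lnc_docs = [datasets.seq_to_kmers(s.sequence, cfg.k, source_id=s.id) for s in lnc_test]
    _, ranked = attribution.attribute_dataset(
        classifier, lnc_docs, method=attribution_method
    )

    lnc_all = [s for s in data.all_seqs if s.label == LNCRNA]
    ctrl_all = [s for s in data.all_seqs if s.label != LNCRNA]
    planted = motifs[0]
    lnc_with, lnc_total = motifstats.count_motif_presence(planted, lnc_all)
    ctrl_with, ctrl_total = motifstats.count_motif_presence(planted, ctrl_all)
    chi2_stat, chi2_p = motifstats.chi_square_motif(
        lnc_with, lnc_total, ctrl_with, ctrl_total
    )
    motif_tests = motifstats.significant_motifs(ranked, lnc_all, ctrl_all) if ranked else []

    profile = motifstats.positional_profile([planted], lnc_all)[0]
    return SpeciesRunResult(
        data=data,
        classifier=classifier,
        metrics=metrics,
        ranked_motifs=ranked,
        planted_motif=planted,
        planted_chi2=(chi2_stat, chi2_p),
        planted_flank_mass=motifstats.flank_mass_fraction(profile),
        motif_tests=motif_tests,
    )


def planted_motif_in_top(
    ranked: Sequence[RankedMotif], planted: str, top_n: int = 10
) -> bool:
    """Is the planted motif contained (as a substring) in a top-n ranked motif?"""
    return any(planted in m.motif_sequence for m in ranked[:top_n])


def cross_species_transfer(
    classifier: model.TrainedClassifier,
    trained_species: str,
    others: Dict[str, SpeciesData],
    group_map: Dict[str, str],
):
    """Evaluate one species' model on the test sets of other species."""
    test_sets = {
        name: tokenize_dataset(data.test_seqs, classifier.config.k)
        for name, data in others.items()
    }
    return evaluate.cross_species_evaluate(
        classifier, trained_species, test_sets, group_map
    )
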