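"""Synthetic genomes with planted lncRNA loci and boundary-motif grammars.

The generator emulates the statistical structure the downstream pipeline
assumes: multi-chromosome genomes of i.i.d. background composition, a set of
non-overlapping "lncRNA" loci recorded as GTF intervals, and short motifs
written into the flanking windows immediately up- and downstream of each
locus boundary.  The planted motifs are the only signal separating the
lncRNA class from length-matched random controls, so recovering them is a
well-posed parameter-recovery problem for the classifier and the
explainability stack.

Everything is deterministic under (config, seed): the same ``SyntheticConfig``
always yields byte-identical FASTA/GTF/TSV outputs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .types import (
    ALIGNMENT_COLUMNS,
    AlignmentRecord,
    AnnotationRecord,
    AnnotationSet,
    GenomeSet,
    GenomicInterval,
    LabeledSequence,
)

_BASES = np.array(["A", "C", "G", "T"])

#: Default flank motif: the TGACGT/ACGT-box core found in many plant
#: cis-regulatory elements; any string over {A,C,G,T} works.
DEFAULT_FLANK_MOTIF = "TGACGTCA"


class PlacementError(RuntimeError):
    """Raised when loci or controls cannot be placed without overlap."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one simulated species.

    ``motif_window`` is the number of bases from each locus boundary within
    which flank motifs are planted (always outside the locus body, inside
    what later becomes the added flank).
    """

    n_chromosomes: int = 2
    chromosome_length: int = 200_000
    gc_content: float = 0.40
    n_loci: int = 50
    locus_length_range: Tuple[int, int] = (201, 400)
    flank_motifs: Tuple[str, ...] = (DEFAULT_FLANK_MOTIF,)
    motif_insert_probability: float = 0.9
    motif_window: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be positive")
        if self.chromosome_length < 1:
            raise ValueError("chromosome_length must be positive")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must lie in [0, 1]")
        if self.n_loci < 1:
            raise ValueError("n_loci must be positive")
        lo, hi = self.locus_length_range
        if lo < 201:
            raise ValueError(
                "locus_length_range.min must be >= 201 (lncRNAs are transcripts "
                "longer than 200 nucleotides)"
            )
        if hi < lo:
            raise ValueError("locus_length_range must be (min, max) with min <= max")
        if not (0.0 <= self.motif_insert_probability <= 1.0):
            raise ValueError("motif_insert_probability must lie in [0, 1]")
        if self.motif_window < 1:
            raise ValueError("motif_window must be positive")
        for motif in self.flank_motifs:
            if not motif or set(motif) - set("ACGT"):
                raise ValueError(f"motif {motif!r} must be a non-empty string over ACGT")
            if len(motif) > self.motif_window:
                raise ValueError(
                    f"motif {motif!r} longer than motif_window {self.motif_window}"
                )
        # Loci plus their motif windows must plausibly fit.
        per_locus = hi + 2 * self.motif_window
        if self.n_loci * per_locus > self.n_chromosomes * self.chromosome_length:
            raise ValueError(
                "total planted locus length plus spacing exceeds genome size"
            )

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Exact planted structure of one simulated species."""

    loci: List[GenomicInterval]
    #: (motif string, chromosome, 0-based position, locus_id)
    planted_motif_positions: List[Tuple[str, str, int, str]]
    species_label: str = "synthetic"


def generate_genome(config: SyntheticConfig) -> GenomeSet:
    """Draw an i.i.d. background genome with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences: Dict[str, str] = {}
    for i in range(config.n_chromosomes):
        draws = rng.choice(4, size=config.chromosome_length, p=probs)
        sequences[f"chr{i + 1}"] = "".join(_BASES[draws])
    return GenomeSet(sequences)


def plant_loci(
    genome: GenomeSet,
    config: SyntheticConfig,
    species: str = "synthetic",
    max_tries_per_locus: int = 2000,
) -> Tuple[GenomeSet, GroundTruth, AnnotationSet]:
    """Select non-overlapping loci and plant boundary motifs in their windows.

    Loci are placed uniformly at random with rejection; the rejected region
    around each accepted locus includes its two motif windows, so plantings
    never fall inside a neighbouring locus.  Motif planting overwrites the
    background bases in place (no coordinate shifts).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    w = config.motif_window
    lo, hi = config.locus_length_range
    chroms = sorted(genome.sequences)
    lengths = genome.lengths
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    loci: List[GenomicInterval] = []
    for _ in range(config.n_loci):
        for attempt in range(max_tries_per_locus):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            length = int(rng.integers(lo, hi + 1))
            max_start = lengths[chrom] - length - w
            if max_start < w:
                continue
            start = int(rng.integers(w, max_start + 1))
            end = start + length
            # reserve the motif windows too, so windows never overlap a locus
            lo_r, hi_r = start - w, end + w
            if all(hi_r <= s or e <= lo_r for s, e in placed[chrom]):
                placed[chrom].append((lo_r, hi_r))
                loci.append(GenomicInterval(chrom, start, end, "+"))
                break
        else:
            raise PlacementError(
                f"could not place locus {len(loci) + 1}/{config.n_loci} "
                f"after {max_tries_per_locus} tries"
            )
    loci.sort(key=lambda iv: (iv.chrom, iv.start))

    mutable = {c: np.array(list(genome.sequences[c])) for c in chroms}
    plantings: List[Tuple[str, str, int, str]] = []
    records: List[AnnotationRecord] = []
    for idx, locus in enumerate(loci):
        locus_id = f"{species}_lnc{idx + 1}"
        for motif in config.flank_motifs:
            m = len(motif)
            # upstream window [start - w, start)
            if rng.random() < config.motif_insert_probability:
                pos = int(rng.integers(locus.start - w, locus.start - m + 1))
                mutable[locus.chrom][pos : pos + m] = list(motif)
                plantings.append((motif, locus.chrom, pos, locus_id))
            # downstream window [end, end + w)
            if rng.random() < config.motif_insert_probability:
                pos = int(rng.integers(locus.end, locus.end + w - m + 1))
                mutable[locus.chrom][pos : pos + m] = list(motif)
                plantings.append((motif, locus.chrom, pos, locus_id))
        records.append(
            AnnotationRecord(
                locus,
                locus_id,
                {"gene_id": locus_id, "transcript_id": f"{locus_id}.1"},
            )
        )
    planted_genome = GenomeSet({c: "".join(mutable[c]) for c in chroms})
    truth = GroundTruth(loci, plantings, species_label=species)
    return planted_genome, truth, AnnotationSet(records)


def simulate_species(
    config: SyntheticConfig, species: str = "synthetic"
) -> Tuple[GenomeSet, GroundTruth, AnnotationSet]:
    """Generate a background genome and plant loci in one call."""
    genome = generate_genome(config)
    return plant_loci(genome, config, species=species)


def emit_alignment_table(
    lncRNAs: Sequence[LabeledSequence],
    contaminate_fraction: float,
    seed: int,
) -> List[AlignmentRecord]:
    """Fabricate 12-column alignment records for the similarity filter.

    A ``contaminate_fraction`` of the query sequences receives two overlapping
    HSPs whose merged query coverage exceeds 0.9 (mimicking lncRNA candidates
    that are really mRNA fragments); every other query gets one HSP covering
    at most half its length.
    """
    if not lncRNAs:
        raise ValueError("need at least one query sequence")
    if not (0.0 <= contaminate_fraction <= 1.0):
        raise ValueError("contaminate_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(lncRNAs)
    n_contam = int(round(n * contaminate_fraction))
    contaminated = set(rng.choice(n, size=n_contam, replace=False).tolist())

    records: List[AlignmentRecord] = []

    def _rec(q: LabeledSequence, q_start: int, q_end: int) -> AlignmentRecord:
        length = q_end - q_start + 1
        identity = float(rng.uniform(92.0, 99.5))
        mism = int(round(length * (1 - identity / 100)))
        return AlignmentRecord(
            query_id=q.id,
            subject_id=f"mrna_{rng.integers(1, 1000)}",
            percent_identity=round(identity, 2),
            alignment_length=length,
            mismatches=mism,
            gap_opens=0,
            q_start=q_start,
            q_end=q_end,
            s_start=1,
            s_end=length,
            e_value=1e-30,
            bit_score=round(length * 1.8, 1),
        )

    for i, q in enumerate(lncRNAs):
        L = len(q.sequence)
        if i in contaminated:
            # two HSPs whose union covers ~95% of the query
            covered = max(int(np.ceil(0.95 * L)), int(0.9 * L) + 1)
            split = covered // 2
            overlap = max(1, min(split - 1, int(rng.integers(1, 30))))
            records.append(_rec(q, 1, split))
            records.append(_rec(q, split - overlap + 1, covered))
        else:
            covered = max(1, int(0.4 * L))
            records.append(_rec(q, 1, covered))
    return records


# ---------------------------------------------------------------------------
# Serialization


def write_fasta(genome: GenomeSet, path: Path | str, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name in sorted(genome.sequences):
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(annotations: AnnotationSet, path: Path | str, source: str = "lncmotif") -> None:
    """Write loci as GTF (1-based, inclusive coordinates; feature 'lncRNA')."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in annotations.records:
            iv = rec.interval
            attrs = dict(rec.attributes)
            attrs.setdefault("gene_id", rec.feature_id)
            attrs.setdefault("transcript_id", rec.feature_id)
            attr_str = " ".join(f'{k} "{v}";' for k, v in attrs.items())
            fh.write(
                f"{iv.chrom}\t{source}\tlncRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attr_str}\n"
            )


def write_ground_truth(truth: GroundTruth, path: Path | str) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("motif\tchrom\tposition\tlocus_id\n")
        for motif, chrom, pos, locus_id in truth.planted_motif_positions:
            fh.write(f"{motif}\t{chrom}\t{pos}\t{locus_id}\n")


def write_alignment_table(records: Sequence[AlignmentRecord], path: Path | str) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for r in records:
            fields = [str(getattr(r, col)) for col in ALIGNMENT_COLUMNS]
            fh.write("\t".join(fields) + "\n")
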