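"""Dataset construction: genome + GTF (+ alignment table) -> labelled sequences.

The pipeline mirrors the standard genomic workflow: lncRNA intervals are
extracted with fixed-length flanks clamped at chromosome boundaries, queries
with high merged alignment coverage against mRNA are discarded, length-matched
random controls are drawn from the genome excluding the lncRNA loci, and the
result is split into stratified train/test partitions and tokenized into
overlapping k-mers.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree
from sklearn.model_selection import train_test_split

from .types import (
    ALIGNMENT_COLUMNS,
    AlignmentRecord,
    AnnotationRecord,
    AnnotationSet,
    GenomeSet,
    GenomicInterval,
    KmerDocument,
    LabeledSequence,
    LNCRNA,
    NON_LNCRNA,
)
from .simulate import PlacementError

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 500  # bp added upstream and downstream of each locus


# ---------------------------------------------------------------------------
# Readers


def load_genome(path: Path | str) -> GenomeSet:
    """Load a FASTA file into memory, uppercasing bases.

    Raises ``ValueError`` for an empty file, duplicate record ids, or
    characters outside {A,C,G,T,N}.
    """
    path = Path(path)
    sequences: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA record id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"record {record.id!r}: unexpected characters {sorted(bad)}"
            )
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSet(sequences)


def load_gtf(path: Path | str, feature_type: Optional[str] = None) -> AnnotationSet:
    """Read a GTF file into an AnnotationSet (converting to 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records: List[AnnotationRecord] = []
    for feature in db.all_features(order_by=("seqid", "start")):
        if feature_type is not None and feature.featuretype != feature_type:
            continue
        attrs = {k: v[0] for k, v in feature.attributes.items() if v}
        feature_id = attrs.get("gene_id") or feature.id
        records.append(
            AnnotationRecord(
                GenomicInterval(
                    feature.seqid,
                    feature.start - 1,  # GTF is 1-based inclusive
                    feature.end,
                    feature.strand if feature.strand in "+-" else ".",
                ),
                feature_id,
                attrs,
            )
        )
    return AnnotationSet(records)


def load_alignment_table(path: Path | str) -> List[AlignmentRecord]:
    """Read a 12-column tabular (BLAST outfmt 6 style) alignment file."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=ALIGNMENT_COLUMNS,
        float_precision="round_trip",
    )
    return [
        AlignmentRecord(
            query_id=str(row.query_id),
            subject_id=str(row.subject_id),
            percent_identity=float(row.percent_identity),
            alignment_length=int(row.alignment_length),
            mismatches=int(row.mismatches),
            gap_opens=int(row.gap_opens),
            q_start=int(row.q_start),
            q_end=int(row.q_end),
            s_start=int(row.s_start),
            s_end=int(row.s_end),
            e_value=float(row.e_value),
            bit_score=float(row.bit_score),
        )
        for row in df.itertuples(index=False)
    ]


def load_exclusion_bed(path: Path | str) -> List[GenomicInterval]:
    """Read 0-based half-open intervals from a BED file."""
    intervals: List[GenomicInterval] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.append(GenomicInterval(chrom, int(start), int(end)))
    return intervals


# ---------------------------------------------------------------------------
# Construction


def add_flanks(interval: GenomicInterval, flank: int, chrom_length: int) -> GenomicInterval:
    """Extend an interval by ``flank`` bases each side, clamped to the chromosome."""
    return GenomicInterval(
        interval.chrom,
        max(0, interval.start - flank),
        min(chrom_length, interval.end + flank),
        interval.strand,
    )


def merged_query_coverage(
    hsps: Sequence[Tuple[int, int]], query_length: int
) -> float:
    """Fraction of the query covered by the union of 1-based inclusive HSP spans."""
    if query_length <= 0:
        raise ValueError("query length must be positive")
    spans = sorted((min(s, e), max(s, e)) for s, e in hsps)
    covered = 0
    cur_start: Optional[int] = None
    cur_end = 0
    for s, e in spans:
        if cur_start is None:
            cur_start, cur_end = s, e
        elif s <= cur_end + 1:
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
    if cur_start is not None:
        covered += cur_end - cur_start + 1
    return covered / query_length


def filter_by_similarity(
    queries: Sequence[LabeledSequence],
    alignments: Sequence[AlignmentRecord],
    coverage_threshold: float = 0.9,
) -> Tuple[List[LabeledSequence], List[LabeledSequence]]:
    """Remove queries whose merged alignment coverage exceeds the threshold.

    A query is removed iff the union of its HSP query spans covers strictly
    more than ``coverage_threshold`` of its length ("over 90%").  Queries
    without alignment records are retained.  Records naming unknown queries
    are skipped with a warning.
    """
    by_query: Dict[str, List[Tuple[int, int]]] = {}
    known = {q.id for q in queries}
    for rec in alignments:
        if rec.query_id not in known:
            warnings.warn(
                f"alignment record references unknown query {rec.query_id!r}; skipped",
                stacklevel=2,
            )
            continue
        by_query.setdefault(rec.query_id, []).append((rec.q_start, rec.q_end))

    retained: List[LabeledSequence] = []
    removed: List[LabeledSequence] = []
    for q in queries:
        hsps = by_query.get(q.id)
        if hsps and merged_query_coverage(hsps, len(q.sequence)) > coverage_threshold:
            removed.append(q)
        else:
            retained.append(q)
    return retained, removed


def extract_sequences(
    genome: GenomeSet,
    annotations: AnnotationSet,
    flank: int = DEFAULT_FLANK,
    species: str = "unknown",
) -> List[LabeledSequence]:
    """Extract one flanked, positively-labelled sequence per annotation record."""
    annotations.validate_against(genome)
    lengths = genome.lengths
    out: List[LabeledSequence] = []
    for rec in annotations.records:
        iv = rec.interval
        flanked = add_flanks(iv, flank, lengths[iv.chrom])
        seq = genome.fetch(flanked)
        core_start = iv.start - flanked.start
        out.append(
            LabeledSequence(
                id=rec.feature_id,
                species=species,
                sequence=seq,
                label=LNCRNA,
                flank_length=flank,
                core_span=(core_start, core_start + len(iv)),
            )
        )
    return out


def generate_controls(
    genome: GenomeSet,
    excluded: Sequence[GenomicInterval],
    lengths: Sequence[int],
    seed: int,
    flank: int = DEFAULT_FLANK,
    species: str = "unknown",
    max_tries: int = 20_000,
) -> List[LabeledSequence]:
    """Draw random genomic stretches of the requested lengths, avoiding exclusions.

    One control per requested length (exact multiset match), each disjoint
    from every excluded interval; controls may overlap each other (logged).
    The nominal core of a control is the sequence minus ``flank`` on each side.
    """
    rng = np.random.default_rng(seed)
    trees: Dict[str, IntervalTree] = {}
    for iv in excluded:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    chrom_lengths = genome.lengths
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    controls: List[LabeledSequence] = []
    seen: List[GenomicInterval] = []
    for idx, length in enumerate(lengths):
        placed = None
        for _ in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            max_start = chrom_lengths[chrom] - length
            if max_start < 0:
                continue
            start = int(rng.integers(0, max_start + 1))
            end = start + length
            tree = trees.get(chrom)
            if tree is not None and tree.overlap(start, end):
                continue
            placed = GenomicInterval(chrom, start, end)
            break
        if placed is None:
            raise PlacementError(
                f"could not place control of length {length} after {max_tries} tries"
            )
        if any(placed.overlaps(prev) for prev in seen):
            logger.info("control %d overlaps a previously placed control", idx)
        seen.append(placed)
        seq = genome.fetch(placed)
        core = (min(flank, length // 2), max(length - flank, length - length // 2))
        controls.append(
            LabeledSequence(
                # id carries the source coordinates, bedtools-style
                id=f"{species}_ctrl{idx + 1}|{placed.chrom}:{placed.start}-{placed.end}",
                species=species,
                sequence=seq,
                label=NON_LNCRNA,
                flank_length=flank,
                core_span=(core[0], max(core[0], core[1])),
            )
        )
    return controls


def split_dataset(
    sequences: Sequence[LabeledSequence],
    test_fraction: float,
    seed: int,
) -> Tuple[List[LabeledSequence], List[LabeledSequence]]:
    """Stratified, seeded train/test split."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    labels = [s.label for s in sequences]
    for cls in {LNCRNA, NON_LNCRNA}:
        if labels.count(cls) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
    train, test = train_test_split(
        list(sequences),
        test_size=test_fraction,
        random_state=seed,
        stratify=labels,
    )
    return list(train), list(test)


def seq_to_kmers(sequence: str, k: int, source_id: str = "") -> KmerDocument:
    """Tokenize into overlapping k-mers of width k, stride 1."""
    if not (3 <= k <= 6):
        raise ValueError("k must lie in [3, 6]")
    if len(sequence) < k:
        raise ValueError(
            f"sequence of length {len(sequence)} shorter than k={k}"
        )
    tokens = [sequence[i : i + k] for i in range(len(sequence) - k + 1)]
    return KmerDocument(tokens=tokens, k=k, source_id=source_id)


# ---------------------------------------------------------------------------
# Dataset (de)serialization

_DATASET_COLUMNS = [
    "id",
    "species",
    "label",
    "sequence",
    "core_start",
    "core_end",
    "flank_length",
]


def write_dataset(sequences: Sequence[LabeledSequence], path: Path | str) -> None:
    rows = [
        {
            "id": s.id,
            "species": s.species,
            "label": s.label,
            "sequence": s.sequence,
            "core_start": s.core_span[0],
            "core_end": s.core_span[1],
            "flank_length": s.flank_length,
        }
        for s in sequences
    ]
    pd.DataFrame(rows, columns=_DATASET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dataset(path: Path | str) -> List[LabeledSequence]:
    df = pd.read_csv(path, sep="\t")
    return [
        LabeledSequence(
            id=str(row.id),
            species=str(row.species),
            sequence=str(row.sequence),
            label=str(row.label),
            flank_length=int(row.flank_length),
            core_span=(int(row.core_start), int(row.core_end)),
        )
        for row in df.itertuples(index=False)
    ]


def write_sequences_fasta(sequences: Sequence[LabeledSequence], path: Path | str) -> None:
    with Path(path).open("w") as fh:
        for s in sequences:
            fh.write(f">{s.id} label={s.label} species={s.species}\n{s.sequence}\n")


def build_dataset(
    genome: GenomeSet,
    annotations: AnnotationSet,
    flank: int = DEFAULT_FLANK,
    alignments: Optional[Sequence[AlignmentRecord]] = None,
    species: str = "unknown",
    seed: int = 0,
) -> List[LabeledSequence]:
    """Full construction: extract flanked lncRNAs, filter, add matched controls."""
    lnc = extract_sequences(genome, annotations, flank=flank, species=species)
    if alignments:
        lnc, removed = filter_by_similarity(lnc, alignments)
        logger.info("similarity filter removed %d/%d queries", len(removed), len(lnc) + len(removed))
    chrom_lengths = genome.lengths
    excluded = [
        add_flanks(rec.interval, flank, chrom_lengths[rec.interval.chrom])
        for rec in annotations.records
    ]
    controls = generate_controls(
        genome,
        excluded,
        [len(s.sequence) for s in lnc],
        seed=seed,
        flank=flank,
        species=species,
    )
    return lnc + controls
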