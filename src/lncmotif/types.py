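"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open everywhere in memory; GTF readers/writers
convert to and from the 1-based inclusive convention at the boundary, and
BLAST-style alignment records keep their native 1-based inclusive query
coordinates until they are consumed by the coverage filter.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

LNCRNA = "lncRNA"
NON_LNCRNA = "non-lncRNA"


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome or scaffold."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeSet:
    """A set of chromosome/scaffold sequences over {A,C,G,T,N}."""

    sequences: Dict[str, str]

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self.sequences[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval} exceeds chromosome length {len(seq)}"
            )
        return seq[interval.start : interval.end]


@dataclass
class AnnotationRecord:
    interval: GenomicInterval
    feature_id: str
    attributes: Dict[str, str] = field(default_factory=dict)


@dataclass
class AnnotationSet:
    records: List[AnnotationRecord]

    def validate_against(self, genome: GenomeSet) -> None:
        lengths = genome.lengths
        for rec in self.records:
            iv = rec.interval
            if iv.chrom not in lengths:
                raise ValueError(f"record {rec.feature_id}: unknown chromosome {iv.chrom}")
            if iv.end > lengths[iv.chrom]:
                raise ValueError(
                    f"record {rec.feature_id}: interval {iv.start}-{iv.end} outside "
                    f"{iv.chrom} (length {lengths[iv.chrom]})"
                )


# Standard 12-column tabular alignment layout (BLAST outfmt 6).
ALIGNMENT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
]


@dataclass
class AlignmentRecord:
    """One HSP in 12-column tabular layout; query coordinates 1-based inclusive."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end):
            raise ValueError(
                f"{self.query_id}: invalid query coordinates {self.q_start}-{self.q_end}"
            )


@dataclass
class LabeledSequence:
    """A flanked genomic sequence with its class label.

    ``core_span`` locates the unflanked locus within ``sequence`` (0-based,
    half-open).  For controls the core is the whole sequence minus nominal
    flanks of ``flank_length`` on each side.
    """

    id: str
    species: str
    sequence: str
    label: str
    flank_length: int
    core_span: Tuple[int, int]

    def __post_init__(self) -> None:
        if self.label not in {LNCRNA, NON_LNCRNA}:
            raise ValueError(f"invalid label {self.label!r}")
        cs, ce = self.core_span
        if not (0 <= cs <= ce <= len(self.sequence)):
            raise ValueError(
                f"{self.id}: core_span {self.core_span} outside sequence of "
                f"length {len(self.sequence)}"
            )

    @property
    def is_positive(self) -> bool:
        return self.label == LNCRNA


@dataclass
class KmerDocument:
    """A sequence tokenized into overlapping k-mers (stride 1)."""

    tokens: List[str]
    k: int
    source_id: str

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class ClassScore:
    sequence_id: str
    p_lncRNA: float
    predicted_label: str

    @classmethod
    def from_probability(cls, sequence_id: str, p: float) -> "ClassScore":
        return cls(sequence_id, float(p), LNCRNA if p >= 0.5 else NON_LNCRNA)


@dataclass
class AttributionTrack:
    """Signed per-k-mer importance scores for the lncRNA class."""

    sequence_id: str
    k: int
    scores: List[float]
    target_class: str = LNCRNA


@dataclass
class MotifOccurrence:
    sequence_id: str
    motif_sequence: str
    token_span: Tuple[int, int]  # inclusive first and last token index
    attribution_sum: float


@dataclass
class RankedMotif:
    motif_sequence: str
    frequency: int
    total_attribution: float
    importance: float
    rank: int


@dataclass
class MotifTestResult:
    motif_sequence: str
    lnc_with_motif: int
    lnc_total: int
    ctrl_with_motif: int
    ctrl_total: int
    chi_square_statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False


@dataclass
class PositionalProfile:
    """Counts of motif occurrences over the 60-bin flank/body/flank scheme.

    Bins 1-20 cover the upstream flank, 21-40 the lncRNA body (length
    normalized when ``normalized``), 41-60 the downstream flank.  ``bins`` is
    stored 0-indexed (bins[0] is bin 1).
    """

    motif_sequence: str
    bins: List[float]
    normalized: bool
    flank_length: int

    def __post_init__(self) -> None:
        if len(self.bins) != 60:
            raise ValueError("a positional profile has exactly 60 bins")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    accuracy: float
    auroc: Optional[float]
    f1: float
    mcc: float
    precision: float
    recall: float
    counts: ConfusionCounts
    n: int


@dataclass
class CrossSpeciesResult:
    trained_species: str
    test_species: str
    group_pair: str
    metrics: MetricsReport
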