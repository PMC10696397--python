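"""Motif significance testing, cross-species sharing, and positional profiles.

Significance: a Pearson chi-square (df=1, no continuity correction) on the
2x2 presence table of a motif in lncRNA versus control sequences; motifs
with raw p < alpha are kept (a Benjamini-Hochberg option is available but
off by default, matching the raw-threshold convention).

Positional profile: each motif occurrence start is assigned to one of 60
bins — bins 1-20 tile the upstream flank in flank/20-bp intervals (25 bp for
a 500 bp flank), bins 21-40 tile the variable-length lncRNA body in 5%
intervals, bins 41-60 tile the downstream flank.  Body-bin contributions are
rescaled by (flank bin width / body bin width) per sequence, putting body
counts on the same per-width scale as the flanks so long lncRNAs do not
dominate the body bins.
"""
from __future__ import annotations

import itertools
import warnings
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import networkx as nx
import numpy as np
from scipy.stats import chi2

from .types import (
    LabeledSequence,
    MotifTestResult,
    PositionalProfile,
    RankedMotif,
)


# ---------------------------------------------------------------------------
# Counting and chi-square


def find_occurrences(motif: str, sequence: str) -> List[int]:
    """Start positions of every (possibly overlapping) exact occurrence."""
    if not motif:
        raise ValueError("motif must be non-empty")
    out: List[int] = []
    start = sequence.find(motif)
    while start != -1:
        out.append(start)
        start = sequence.find(motif, start + 1)
    return out


def count_motif_presence(
    motif: str, sequences: Sequence[LabeledSequence], mode: str = "presence"
) -> Tuple[int, int]:
    """(#sequences containing the motif, #sequences) — grep-style line counts.

    ``mode='occurrences'`` counts every overlapping occurrence instead.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if mode == "presence":
        with_motif = sum(1 for s in sequences if motif in s.sequence)
    elif mode == "occurrences":
        with_motif = sum(len(find_occurrences(motif, s.sequence)) for s in sequences)
    else:
        raise ValueError(f"unknown counting mode {mode!r}")
    return with_motif, len(sequences)


def chi_square_motif(
    lnc_with: int, lnc_total: int, ctrl_with: int, ctrl_total: int
) -> Tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on the 2x2 table
    [[lnc_with, lnc_without], [ctrl_with, ctrl_without]].

    A zero marginal leaves the statistic undefined; such tables are reported
    as (0, p=1) with a warning.
    """
    if lnc_total <= 0 or ctrl_total <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= lnc_with <= lnc_total and 0 <= ctrl_with <= ctrl_total):
        raise ValueError("with-motif counts must not exceed group totals")
    obs = np.array(
        [
            [lnc_with, lnc_total - lnc_with],
            [ctrl_with, ctrl_total - ctrl_with],
        ],
        dtype=np.float64,
    )
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        warnings.warn(
            "zero marginal in 2x2 table; chi-square undefined, reporting p=1",
            stacklevel=2,
        )
        return 0.0, 1.0
    expected = row @ col / total
    statistic = float(((obs - expected) ** 2 / expected).sum())
    p_value = float(chi2.sf(statistic, df=1))
    return statistic, p_value


def significant_motifs(
    ranked: Sequence[Union[RankedMotif, str]],
    lnc_seqs: Sequence[LabeledSequence],
    ctrl_seqs: Sequence[LabeledSequence],
    alpha: float = 0.05,
    mode: str = "presence",
    correction: Optional[str] = None,
) -> List[MotifTestResult]:
    """Chi-square test each motif's presence in lncRNA vs control sequences.

    ``correction='bh'`` applies Benjamini-Hochberg to the raw p-values before
    thresholding; the default keeps the raw p < alpha rule.
    """
    if not lnc_seqs or not ctrl_seqs:
        raise ValueError("both sequence sets must be non-empty")
    motifs = [m.motif_sequence if isinstance(m, RankedMotif) else m for m in ranked]
    results: List[MotifTestResult] = []
    for motif in motifs:
        lnc_with, lnc_total = count_motif_presence(motif, lnc_seqs, mode=mode)
        ctrl_with, ctrl_total = count_motif_presence(motif, ctrl_seqs, mode=mode)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            stat, p = chi_square_motif(lnc_with, lnc_total, ctrl_with, ctrl_total)
            degenerate = any("zero marginal" in str(w.message) for w in caught)
        results.append(
            MotifTestResult(
                motif_sequence=motif,
                lnc_with_motif=lnc_with,
                lnc_total=lnc_total,
                ctrl_with_motif=ctrl_with,
                ctrl_total=ctrl_total,
                chi_square_statistic=stat,
                p_value=p,
                significant=False,
                degenerate=degenerate,
            )
        )
    if correction is None:
        for r in results:
            r.significant = r.p_value < alpha
    elif correction == "bh":
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="fdr_bh"
        )
        for r, rej in zip(results, reject):
            r.significant = bool(rej)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return results


# ---------------------------------------------------------------------------
# Cross-species sharing


class SharingTable:
    """Exact-match (and optionally cluster-level) motif sharing across species."""

    def __init__(
        self,
        per_species_sets: Mapping[str, Set[str]],
        clustered: bool = False,
        clusters: Optional[Dict[str, FrozenSet[str]]] = None,
    ):
        self.per_species_sets = {sp: set(s) for sp, s in per_species_sets.items()}
        self.clustered = clustered
        #: motif -> the cluster (frozenset of motifs) it belongs to
        self.clusters = clusters or {}
        units = (
            {sp: {self.clusters[m] for m in s} for sp, s in self.per_species_sets.items()}
            if clustered
            else {sp: set(s) for sp, s in self.per_species_sets.items()}
        )
        self._units = units
        species = sorted(units)
        self.pairwise_shared: Dict[Tuple[str, str], int] = {}
        for a, b in itertools.combinations(species, 2):
            n = len(units[a] & units[b])
            self.pairwise_shared[(a, b)] = n
            self.pairwise_shared[(b, a)] = n
        # upset-style per-combination counts: membership pattern -> count
        self.combination_counts: Dict[FrozenSet[str], int] = {}
        all_units = set().union(*units.values()) if units else set()
        for unit in all_units:
            members = frozenset(sp for sp in species if unit in units[sp])
            self.combination_counts[members] = self.combination_counts.get(members, 0) + 1
        self.n_unique = len(all_units)


def cluster_motifs(motifs: Iterable[str]) -> Dict[str, FrozenSet[str]]:
    """Single-linkage clusters where two motifs link iff one contains the other.

    This merges homopolymer length variants (e.g. AAAAAAA and AAAAAAAA) into
    one cluster, the behaviour needed to reproduce cross-species sharing of
    poly-A motifs of slightly different lengths.
    """
    motifs = sorted(set(motifs))
    graph = nx.Graph()
    graph.add_nodes_from(motifs)
    for a, b in itertools.combinations(motifs, 2):
        if a in b or b in a:
            graph.add_edge(a, b)
    assignment: Dict[str, FrozenSet[str]] = {}
    for component in nx.connected_components(graph):
        cluster = frozenset(component)
        for m in component:
            assignment[m] = cluster
    return assignment


def shared_motifs(
    per_species: Mapping[str, Iterable[str]], cluster: bool = False
) -> SharingTable:
    """Build the sharing table; ``cluster=True`` additionally merges motifs
    related by substring containment before counting."""
    sets = {sp: set(motifs) for sp, motifs in per_species.items()}
    if len(sets) < 2:
        raise ValueError("sharing requires at least two species")
    if not cluster:
        return SharingTable(sets, clustered=False)
    clusters = cluster_motifs(itertools.chain.from_iterable(sets.values()))
    return SharingTable(sets, clustered=True, clusters=clusters)


# ---------------------------------------------------------------------------
# Positional profiles


def normalize_bins(
    contribution: np.ndarray, core_bin_length: float, flank_bin_length: float
) -> np.ndarray:
    """Rescale one sequence's body-bin counts to the flank-bin width scale."""
    out = np.asarray(contribution, dtype=np.float64).copy()
    if core_bin_length <= 0:
        raise ValueError("core bin length must be positive")
    out[20:40] *= flank_bin_length / core_bin_length
    return out


def _sequence_contribution(
    motif: str, seq: LabeledSequence, normalize: bool
) -> Optional[np.ndarray]:
    cs, ce = seq.core_span
    core_len = ce - cs
    flank = seq.flank_length
    if core_len <= 0:
        warnings.warn(
            f"sequence {seq.id} has zero-length core; skipped from profile",
            stacklevel=3,
        )
        return None
    flank_bin = flank / 20.0
    core_bin = core_len / 20.0
    bins = np.zeros(60, dtype=np.float64)
    for start in find_occurrences(motif, seq.sequence):
        if start < cs:
            b = min(int(start // flank_bin), 19)
        elif start < ce:
            b = 20 + min(int((start - cs) // core_bin), 19)
        else:
            b = 40 + min(int((start - ce) // flank_bin), 19)
        bins[b] += 1.0
    if normalize:
        bins = normalize_bins(bins, core_bin, flank_bin)
    return bins


def positional_profile(
    motifs: Sequence[str],
    sequences: Sequence[LabeledSequence],
    normalize: bool = True,
) -> List[PositionalProfile]:
    """Accumulate 60-bin occurrence profiles for each motif over all sequences."""
    if not sequences:
        raise ValueError("no sequences supplied")
    flank = sequences[0].flank_length
    profiles: List[PositionalProfile] = []
    for motif in motifs:
        total = np.zeros(60, dtype=np.float64)
        for seq in sequences:
            contribution = _sequence_contribution(motif, seq, normalize)
            if contribution is not None:
                total += contribution
        profiles.append(
            PositionalProfile(
                motif_sequence=motif,
                bins=total.tolist(),
                normalized=normalize,
                flank_length=flank,
            )
        )
    return profiles


def flank_mass_fraction(profile: PositionalProfile) -> float:
    """Fraction of profile mass in the flank bins (1-20 and 41-60)."""
    bins = np.asarray(profile.bins)
    total = bins.sum()
    if total == 0:
        return 0.0
    return float((bins[:20].sum() + bins[40:].sum()) / total)
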