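"""Chi-square enrichment, motif sharing, and 60-bin positional profiles."""
import itertools

import numpy as np
import pytest

from lncmotif import motifstats
from lncmotif.types import LabeledSequence, LNCRNA, NON_LNCRNA


def seq(sequence, core_span=None, flank=500, label=LNCRNA, sid="s"):
    if core_span is None:
        core_span = (0, len(sequence))
    return LabeledSequence(
        id=sid, species="x", sequence=sequence, label=label,
        flank_length=flank, core_span=core_span,
    )


class TestCounting:
    def test_presence_semantics(self):
        seqs = [seq("AAATG"), seq("CCCC")]
        assert motifstats.count_motif_presence("AAT", seqs) == (1, 2)

    def test_overlapping_occurrences_count_once_in_presence_mode(self):
        assert motifstats.count_motif_presence("AAA", [seq("AAAA")]) == (1, 1)

    def test_occurrence_mode_counts_overlaps(self):
        assert motifstats.count_motif_presence("AAA", [seq("AAAA")], mode="occurrences") == (2, 1)

    def test_absent_motif(self):
        assert motifstats.count_motif_presence("GGG", [seq("AAAA"), seq("CCCC")]) == (0, 2)


class TestChiSquare:
    def test_worked_table(self):
        stat, p = motifstats.chi_square_motif(30, 100, 10, 100)
        assert stat == pytest.approx(12.5)
        assert p < 0.001

    def test_null_table(self):
        stat, p = motifstats.chi_square_motif(20, 100, 20, 100)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_flagged(self):
        with pytest.warns(UserWarning, match="zero marginal"):
            stat, p = motifstats.chi_square_motif(0, 100, 0, 100)
        assert (stat, p) == (0.0, 1.0)

    def test_against_textbook_oracle_on_random_tables(self):
        # brute-force expected-counts formula, plus scipy as a second opinion
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(23)
        for _ in range(500):
            n1, n2 = int(rng.integers(5, 200)), int(rng.integers(5, 200))
            a = int(rng.integers(1, n1))
            b = int(rng.integers(1, n2))
            stat, p = motifstats.chi_square_motif(a, n1, b, n2)
            obs = [[a, n1 - a], [b, n2 - b]]
            total = n1 + n2
            expected_stat = 0.0
            for i, j in itertools.product(range(2), range(2)):
                row = sum(obs[i])
                col = obs[0][j] + obs[1][j]
                e = row * col / total
                expected_stat += (obs[i][j] - e) ** 2 / e
            assert stat == pytest.approx(expected_stat, abs=1e-10)
            sp_stat, sp_p, _, _ = chi2_contingency(obs, correction=False)
            assert stat == pytest.approx(sp_stat, abs=1e-10)
            assert p == pytest.approx(sp_p, abs=1e-10)

    def test_p_monotone_decreasing_in_statistic(self):
        stats_ps = [motifstats.chi_square_motif(10 + d, 100, 10, 100) for d in (5, 15, 30)]
        stats, ps = zip(*stats_ps)
        assert list(stats) == sorted(stats)
        assert list(ps) == sorted(ps, reverse=True)


class TestSignificantMotifs:
    def test_threshold_behaviour(self):
        lnc = [seq("TGACGTCA" + "A" * 20, sid=f"l{i}") for i in range(30)]
        lnc += [seq("C" * 28, sid=f"l{30+i}") for i in range(10)]
        ctrl = [seq("G" * 28, label=NON_LNCRNA, sid=f"c{i}") for i in range(40)]
        results = motifstats.significant_motifs(["TGACGTCA"], lnc, ctrl)
        assert results[0].significant  # enriched in lnc
        # a motif equally frequent in both groups is dropped
        equal = motifstats.significant_motifs(
            ["AAAA"],
            [seq("AAAA", sid="l")] * 20,
            [seq("AAAA", label=NON_LNCRNA, sid="c")] * 20,
        )
        assert not equal[0].significant

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            motifstats.significant_motifs(["AAAA"], [], [seq("AAAA")])


class TestSharing:
    def test_pairwise_exact_count(self):
        table = motifstats.shared_motifs(
            {"a": {"AAAA", "CCGG"}, "b": {"AAAA", "TTTT"}}
        )
        assert table.pairwise_shared[("a", "b")] == 1
        assert table.pairwise_shared[("b", "a")] == 1

    def test_homopolymer_variants_cluster_together(self):
        clusters = motifstats.cluster_motifs(["AAAAAAA", "AAAAAAAA", "CCCC"])
        assert clusters["AAAAAAA"] == clusters["AAAAAAAA"]
        assert clusters["CCCC"] != clusters["AAAAAAA"]

    def test_cluster_level_sharing(self):
        table = motifstats.shared_motifs(
            {"a": {"AAAAAAA"}, "b": {"AAAAAAAA"}}, cluster=True
        )
        assert table.pairwise_shared[("a", "b")] == 1

    def test_combination_counts_partition_unique_motifs(self):
        sets = {"a": {"AAAA", "CCCC"}, "b": {"AAAA", "GGGG"}, "c": {"TTTT"}}
        table = motifstats.shared_motifs(sets)
        assert sum(table.combination_counts.values()) == table.n_unique == 4

    def test_pairwise_bounded_by_set_sizes(self):
        rng = np.random.default_rng(2)
        motifs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 6)]) for _ in range(30)]
        sets = {
            sp: set(rng.choice(motifs, size=10, replace=False))
            for sp in ("a", "b", "c")
        }
        table = motifstats.shared_motifs(sets)
        for (x, y), n in table.pairwise_shared.items():
            assert n <= min(len(sets[x]), len(sets[y]))
            assert n == table.pairwise_shared[(y, x)]

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            motifstats.shared_motifs({"a": {"AAAA"}})


def synthetic_flanked(motif_positions, core_len=1000, flank=500):
    """A flanked sequence of A's with motif 'TGCA' written at given positions."""
    total = core_len + 2 * flank
    s = list("A" * total)
    for p in motif_positions:
        s[p : p + 4] = "TGCA"
    return seq("".join(s), core_span=(flank, flank + core_len), flank=flank)


class TestPositionalProfile:
    def test_upstream_bin_assignment(self):
        sq = synthetic_flanked([10, 30])
        (profile,) = motifstats.positional_profile(["TGCA"], [sq], normalize=False)
        assert profile.bins[0] == 1  # offset 10 -> bin 1
        assert profile.bins[1] == 1  # offset 30 -> bin 2

    def test_core_bin_assignment(self):
        sq = synthetic_flanked([500 + 990])  # core offset 990, 50 bp core bins
        (profile,) = motifstats.positional_profile(["TGCA"], [sq], normalize=False)
        assert profile.bins[39] == 1  # bin 40

    def test_downstream_terminal_bin(self):
        sq = synthetic_flanked([500 + 1000 + 496])  # downstream offset 496 -> bin 60
        (profile,) = motifstats.positional_profile(["TGCA"], [sq], normalize=False)
        assert profile.bins[59] == 1

    def test_against_per_position_scan_oracle(self):
        rng = np.random.default_rng(31)
        bases = np.array(list("ACGT"))
        for _ in range(30):
            core_len = int(rng.integers(100, 800))
            flank = 500
            s = "".join(bases[rng.integers(0, 4, core_len + 2 * flank)])
            sq = seq(s, core_span=(flank, flank + core_len), flank=flank)
            motif = "".join(bases[rng.integers(0, 4, 3)])
            (profile,) = motifstats.positional_profile([motif], [sq], normalize=False)
            oracle = np.zeros(60)
            for p in range(len(s) - len(motif) + 1):
                if s[p : p + len(motif)] == motif:
                    if p < flank:
                        oracle[min(int(p / (flank / 20)), 19)] += 1
                    elif p < flank + core_len:
                        oracle[20 + min(int((p - flank) / (core_len / 20)), 19)] += 1
                    else:
                        oracle[40 + min(int((p - flank - core_len) / (flank / 20)), 19)] += 1
            assert profile.bins == pytest.approx(oracle.tolist())

    def test_normalization_scaling(self):
        # core bins 50 bp vs flank bins 25 bp: core counts halve
        contribution = np.zeros(60)
        contribution[25] = 4.0
        out = motifstats.normalize_bins(contribution, core_bin_length=50, flank_bin_length=25)
        assert out[25] == pytest.approx(2.0)

    def test_normalization_identity_when_widths_equal(self):
        contribution = np.zeros(60)
        contribution[30] = 3.0
        out = motifstats.normalize_bins(contribution, core_bin_length=25, flank_bin_length=25)
        assert out[30] == pytest.approx(3.0)

    def test_density_invariance_under_core_doubling(self):
        # constant per-base motif density: normalized core mass is length-invariant
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))

        def mass(core_len, n_rep=60):
            total = 0.0
            for _ in range(n_rep):
                s = "".join(bases[rng.integers(0, 4, core_len + 1000)])
                sq = seq(s, core_span=(500, 500 + core_len))
                (profile,) = motifstats.positional_profile(["ACG"], [sq])
                total += sum(profile.bins[20:40])
            return total / n_rep

        m1, m2 = mass(500), mass(1000)
        assert m2 == pytest.approx(m1, rel=0.25)  # stochastic, wide tolerance

    def test_flank_planted_mass_in_flank_bins(self):
        seqs = [synthetic_flanked([50 + i, 2100 + i]) for i in range(0, 400, 40)]
        (profile,) = motifstats.positional_profile(["TGCA"], seqs)
        assert motifstats.flank_mass_fraction(profile) >= 0.7

    def test_zero_core_skipped_with_warning(self):
        sq = seq("A" * 1000, core_span=(500, 500))
        with pytest.warns(UserWarning, match="zero-length core"):
            (profile,) = motifstats.positional_profile(["AAAA"], [sq])
        assert sum(profile.bins) == 0.0
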