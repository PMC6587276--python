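"""Ping-pong statistics, nucleotide biases, density profiles, composition."""

import math
import statistics

import numpy as np
import pytest

from pirnakit import (
    Interval,
    IntervalSet,
    OverlapHistogram,
    cluster_composition,
    density_profile,
    map_reads,
    nucleotide_bias,
    overlap_histogram,
    pingpong_zscore,
    ppp_stats,
)
from pirnakit.mapper import MappingResult, Alignment
from pirnakit.signatures import WINDOW_PRESETS
from pirnakit.simulate import LibrarySimConfig, simulate_pirna_library
from conftest import (
    make_alignment,
    oracle_overlap_histogram,
    oracle_ppp_percent,
)


class TestOverlapHistogram:
    def test_single_exact_pair(self):
        alns = [make_alignment("+", 100), make_alignment("-", 109)]
        h = overlap_histogram(alns)
        assert h.p(10) == 1.0
        assert all(h.p(k) == 0.0 for k in range(1, 29) if k != 10)

    def test_only_sense_reads(self):
        h = overlap_histogram([make_alignment("+", 100), make_alignment("+", 160)])
        assert h.pair_mass == 0

    def test_count_product_weighting(self):
        alns = [
            make_alignment("+", 100, count=3),
            make_alignment("-", 109, count=2),  # overlap 10, weight 6
            make_alignment("-", 104, count=1),  # overlap 5, weight 3
        ]
        h = overlap_histogram(alns)
        assert h.p(10) == pytest.approx(6 / 9)
        assert h.p(5) == pytest.approx(3 / 9)

    def test_matches_all_pairs_enumeration(self):
        """Histogram equals the O(n^2) pair-enumeration oracle on a library."""
        sim = simulate_pirna_library(
            LibrarySimConfig(seed=42, n_antisense_primary=400, f_pp=0.4,
                             n_background_sense=150, n_background_antisense=150)
        )
        alns = sim.truth_alignments().alignments
        h = overlap_histogram(alns)
        expected = oracle_overlap_histogram(alns)
        assert set(h.proportions) == set(expected)
        for k, v in expected.items():
            assert h.p(k) == pytest.approx(v)
        assert sum(h.proportions.values()) == pytest.approx(1.0)
        assert max(h.proportions, key=h.proportions.get) == 10


class TestZScore:
    def test_degenerate_background_undefined(self):
        h = overlap_histogram([make_alignment("+", 100), make_alignment("-", 109)])
        z, sig = pingpong_zscore(h)
        assert z is None and sig is False

    def test_uniform_background_undefined(self):
        props = {k: 1 / 23 for k in range(1, 24)}
        h = OverlapHistogram(props, pair_mass=23.0)
        z, sig = pingpong_zscore(h)
        assert z is None and sig is False

    def test_hand_computed_fixture(self):
        """c_k = k (k != 10), c_10 = 100: z matches direct formula evaluation."""
        counts = {k: float(k) for k in range(1, 24) if k != 10}
        counts[10] = 100.0
        total = sum(counts.values())
        h = OverlapHistogram({k: c / total for k, c in counts.items()}, pair_mass=total)
        z, sig = pingpong_zscore(h)
        b = [counts[k] / total for k in range(1, 24) if k != 10]
        expected = (counts[10] / total - statistics.mean(b)) / statistics.stdev(b)
        assert z == pytest.approx(expected)
        assert z == pytest.approx(12.68972883282082)
        assert sig is True

    def test_include_self_flag_changes_background(self):
        counts = {k: float(k) for k in range(1, 24)}
        counts[10] = 50.0
        total = sum(counts.values())
        h = OverlapHistogram({k: c / total for k, c in counts.items()}, pair_mass=total)
        z_excl, _ = pingpong_zscore(h)
        z_incl, _ = pingpong_zscore(h, include_self=True)
        assert z_incl < z_excl  # including the tested value deflates z


class TestPPP:
    def test_single_pair_is_100_percent(self):
        alns = [make_alignment("+", 100), make_alignment("-", 109)]
        assert ppp_stats(alns).percent_total == 100.0

    def test_no_opposite_strand_reads(self):
        alns = [make_alignment("+", p) for p in (10, 60, 90)]
        s = ppp_stats(alns)
        assert s.percent_total == 0.0 and s.percent_sense == 0.0

    def test_per_strand_percentages(self):
        alns = [
            make_alignment("+", 100, count=1),   # partnered
            make_alignment("-", 109, count=3),   # partnered
            make_alignment("+", 300, count=2),   # unpartnered sense
        ]
        s = ppp_stats(alns)
        assert s.percent_sense == pytest.approx(100 * 1 / 3)
        assert s.percent_antisense == 100.0
        assert s.percent_total == pytest.approx(100 * 4 / 6)

    def test_matches_all_pairs_enumeration(self):
        sim = simulate_pirna_library(
            LibrarySimConfig(seed=77, n_antisense_primary=300, f_pp=0.3,
                             n_background_sense=100, n_background_antisense=100)
        )
        alns = sim.truth_alignments().alignments
        assert ppp_stats(alns).percent_total == pytest.approx(oracle_ppp_percent(alns))

    def test_distinct_weighting_ignores_counts(self):
        alns = [
            make_alignment("+", 100, count=100),
            make_alignment("-", 109, count=1),
            make_alignment("+", 300, count=1, sequence="T" + "G" * 25),
        ]
        assert ppp_stats(alns, weighting="distinct").percent_total == pytest.approx(
            100 * 2 / 3
        )


class TestNucleotideBias:
    def test_all_reads_start_with_t(self):
        alns = [make_alignment("+", p, sequence="T" + "C" * 25) for p in (5, 50)]
        m = nucleotide_bias(alns)
        assert m.bias_1U == 100.0

    def test_symmetric_first_position(self):
        alns = [
            make_alignment("+", 10 * i, sequence=b + "C" * 25)
            for i, b in enumerate("ACGT")
        ]
        m = nucleotide_bias(alns)
        assert np.allclose(m.frequencies.loc[1].to_numpy(), 0.25)

    def test_columns_sum_to_one(self):
        sim = simulate_pirna_library(
            LibrarySimConfig(seed=9, n_antisense_primary=200, f_pp=0.5)
        )
        m = nucleotide_bias(sim.truth_alignments().alignments)
        assert np.allclose(m.frequencies.sum(axis=1).to_numpy(), 1.0)

    def test_primary_bias_recovered_at_scale(self):
        """p1U = 0.9 at n = 10,000 antisense primaries: 1U within 3 points of 90."""
        sim = simulate_pirna_library(
            LibrarySimConfig(seed=123, n_antisense_primary=10_000, p1U=0.9)
        )
        m = nucleotide_bias(sim.truth_alignments().alignments)
        assert abs(m.bias_1U - 90.0) < 3.0

    def test_ppp_subsets(self):
        alns = [
            make_alignment("+", 100, sequence="G" + "C" * 8 + "A" + "C" * 16),
            make_alignment("-", 109, sequence="T" + "C" * 25),
            make_alignment("+", 300, sequence="C" * 26),  # unpartnered
        ]
        assert nucleotide_bias(alns, subset="ppp_sense").bias_10A == 100.0
        assert nucleotide_bias(alns, subset="ppp_antisense").bias_1U == 100.0


class TestDensityProfile:
    def test_single_read_single_window(self):
        alns = [make_alignment("+", 150)]
        prof = density_profile(alns, target_length=1000, window_size=100,
                               normalization_total=10**6)
        assert prof.sense_rpm[1] == pytest.approx(1.0)
        assert prof.sense_rpm.sum() == pytest.approx(1.0)
        assert prof.antisense_rpm.sum() == 0.0

    def test_window_equals_target_length(self):
        alns = [make_alignment("+", 10, count=3), make_alignment("-", 500, count=2)]
        prof = density_profile(alns, 1000, 1000, 1000)
        assert prof.n_windows == 1
        assert prof.sense_rpm[0] + prof.antisense_rpm[0] == pytest.approx(5e6 / 1000)

    def test_preset_window_count_and_tally(self):
        """An 8.4 kb element at the 91-nt preset yields 93 windows; sums match a direct tally."""
        rng = np.random.default_rng(4)
        alns = [
            make_alignment("+-"[int(rng.integers(0, 2))], int(rng.integers(28, 8350)),
                           count=int(rng.integers(1, 5)))
            for _ in range(500)
        ]
        ws = WINDOW_PRESETS["ZAM"]
        prof = density_profile(alns, 8400, ws, 2_000_000)
        assert ws == 91 and prof.n_windows == math.ceil(8400 / 91) == 93
        for w in range(prof.n_windows):
            tally_s = sum(a.count for a in alns
                          if a.strand == "+" and a.five_prime // ws == w)
            assert prof.sense_rpm[w] == pytest.approx(1e6 * tally_s / 2_000_000)

    def test_mass_conservation(self):
        rng = np.random.default_rng(8)
        alns = [
            make_alignment("+-"[int(rng.integers(0, 2))], int(rng.integers(28, 970)),
                           count=int(rng.integers(1, 6)))
            for _ in range(200)
        ]
        prof = density_profile(alns, 1000, 91, 123_457)
        mass = sum(a.count for a in alns)
        recon = (prof.sense_rpm.sum() + prof.antisense_rpm.sum()) * 123_457 / 1e6
        assert abs(recon - mass) / mass < 1e-6


def _unique_result(alns):
    status = {a.read_sequence: "unique" for a in alns}
    counts = {a.read_sequence: a.count for a in alns}
    return MappingResult(list(alns), status, 0, counts)


class TestClusterComposition:
    def _aln(self, seq, start, count=1):
        return Alignment(seq, "chr1", start, start + len(seq), "+", 0, count)

    def test_all_reads_in_one_interval(self):
        alns = [self._aln("A" * 25, 120), self._aln("C" * 25, 150)]
        clusters = IntervalSet([Interval("chr1", 100, 300, "c1")])
        comp = cluster_composition(_unique_result(alns), clusters)
        assert comp.shares == {"c1": 1.0}

    def test_three_to_one_split(self):
        alns = [self._aln("A" * 25, 120, count=3), self._aln("C" * 25, 520, count=1)]
        clusters = IntervalSet(
            [Interval("chr1", 100, 300, "c1"), Interval("chr1", 500, 700, "c2")]
        )
        comp = cluster_composition(_unique_result(alns), clusters)
        assert comp.shares["c1"] == pytest.approx(0.75)
        assert comp.shares["c2"] == pytest.approx(0.25)

    def test_larger_overlap_wins_tie_first_in_bed_order(self):
        a = self._aln("A" * 20, 95)  # 5 bp in c0, 15 bp in c1
        clusters = IntervalSet(
            [Interval("chr1", 0, 100, "c0"), Interval("chr1", 100, 200, "c1")]
        )
        comp = cluster_composition(_unique_result([a]), clusters)
        assert comp.shares == {"c1": 1.0}
        b = self._aln("C" * 20, 90)  # 10 bp in each: first interval wins
        comp2 = cluster_composition(_unique_result([b]), clusters)
        assert comp2.shares == {"c0": 1.0}

    def test_empty_clusters_is_error(self):
        with pytest.raises(ValueError):
            cluster_composition(_unique_result([self._aln("A" * 25, 0)]), IntervalSet())

    def test_simulated_dominant_cluster_share(self):
        """A cluster emitting 78% of unique reads is recovered near 0.78."""
        from pirnakit import genome_unique_status
        from pirnakit.simulate import LibraryGenomeContext

        cfg = LibrarySimConfig(
            seed=31, n_antisense_primary=0,
            genome_context=LibraryGenomeContext(
                n_cluster_reads=2000, cluster_shares=(0.78, 0.10, 0.07, 0.05)
            ),
        )
        sim = simulate_pirna_library(cfg)
        res = genome_unique_status(sim.reads, sim.genome)
        comp = cluster_composition(res, sim.clusters)
        assert abs(comp.shares["cluster1"] - 0.78) < 0.04
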