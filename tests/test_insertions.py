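"""Chimeric-read isolation, discordant pairs, and insertion calling."""

import numpy as np
import pytest

from pirnakit import (
    Interval,
    IntervalSet,
    JunctionParams,
    ReferenceSet,
    annotate_candidates,
    call_insertions,
    find_discordant_pairs,
    find_junction_reads,
    revcomp,
)
from pirnakit.insertions import InsertionCandidate
from pirnakit.simulate import GenomeSimConfig, RepeatFamily, simulate_insertion_readset


def _random_dna(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


@pytest.fixture
def scene(rng):
    genome = ReferenceSet({"chr1": _random_dna(rng, 12_000)})
    te = ReferenceSet({"TE": _random_dna(rng, 2_000)})
    return genome, te


def _pair(pid, s1, s2):
    return (pid, s1, s2)


class TestJunctionReads:
    def test_constructed_five_prime_junction(self, scene):
        genome, te = scene
        read = genome["chr1"][5000:5030] + te["TE"][:71]
        mate = genome["chr1"][8000:8101]  # concordant mate, uniquely mappable
        jrs = find_junction_reads([_pair("p1", read, mate)], te, genome)
        assert len(jrs) == 1
        jr = jrs[0]
        assert jr.te_side == "5prime"
        assert jr.breakpoint_offset == 30
        assert jr.te_match_len == 71
        assert jr.flank_placements == [("chr1", 5000, "+", 0)]
        assert jr.implied_breakpoints == [("chr1", 5030)]

    def test_read_entirely_within_te_rejected(self, scene):
        genome, te = scene
        read = te["TE"][50:151]  # no genomic flank at all
        jrs = find_junction_reads([_pair("p1", read, read)], te, genome)
        assert jrs == []

    def test_uniquely_mapped_read_skipped(self, scene):
        genome, te = scene
        # genomic read that also happens to carry no TE sequence
        read = genome["chr1"][2000:2101]
        assert find_junction_reads([_pair("p1", read, read)], te, genome) == []

    def test_three_prime_junction_reverse_strand_read(self, scene):
        genome, te = scene
        # donor: ...TE 3' end | genomic flank...; read sequenced from the minus strand
        forward = te["TE"][-60:] + genome["chr1"][7000:7041]
        read = revcomp(forward)
        jrs = find_junction_reads([_pair("p1", read, genome["chr1"][1000:1101])], te, genome)
        assert len(jrs) == 1
        jr = jrs[0]
        assert jr.te_side == "3prime"
        assert jr.implied_breakpoints == [("chr1", 7000)]

    def test_te_shorter_than_min_match_is_error(self, scene):
        genome, _ = scene
        tiny = ReferenceSet({"TE": "ACGTACGTAC"})
        with pytest.raises(ValueError):
            find_junction_reads([_pair("p", "A" * 101, "C" * 101)], tiny, genome)

    def test_simulated_junction_reads_match_truth(self):
        """With error-free reads the detected set equals the simulator's truth."""
        sim = simulate_insertion_readset(GenomeSimConfig(seed=21, error_rate=0.0))
        jrs = find_junction_reads(sim.pairs, sim.te, sim.genome)
        assert {j.read_id for j in jrs} == set(sim.truth.junction_read_ids)


class TestDiscordantPairs:
    def test_constructed_discordant_pair(self, scene):
        genome, te = scene
        m1 = te["TE"][1000:1101]
        m2 = genome["chr1"][4700:4801]
        pairs = find_discordant_pairs([_pair("p1", m1, m2)], te, genome)
        assert len(pairs) == 1
        d = pairs[0]
        assert d.genome_interval == (4700, 4801)
        lo, hi = d.implied_window
        assert lo == 4801 and hi > 4801  # insertion implied downstream of the + mate

    def test_concordant_pair_not_reported(self, scene):
        genome, te = scene
        m1 = genome["chr1"][4000:4101]
        m2 = revcomp(genome["chr1"][4250:4351])
        assert find_discordant_pairs([_pair("p1", m1, m2)], te, genome) == []

    def test_simulated_discordant_count_matches_truth(self):
        sim = simulate_insertion_readset(GenomeSimConfig(seed=13, error_rate=0.0))
        pairs = find_discordant_pairs(sim.pairs, sim.te, sim.genome)
        assert {d.pair_id for d in pairs} == set(sim.truth.discordant_pair_ids)


class TestCalling:
    def test_two_sided_cluster_reports_tsd(self, scene):
        genome, te = scene
        d = 4
        site = 6000
        # left-junction read (flank | TE start) and right-junction read (TE end | flank)
        left = genome["chr1"][site + d - 40 : site + d] + te["TE"][:61]
        right = te["TE"][-55:] + genome["chr1"][site : site + 46]
        pairs = [
            _pair("L1", left, genome["chr1"][1000:1101]),
            _pair("L2", left, genome["chr1"][1200:1301]),
            _pair("R1", right, genome["chr1"][1400:1501]),
            _pair("R2", right, genome["chr1"][1600:1701]),
        ]
        jrs = find_junction_reads(pairs, te, genome)
        cands = call_insertions(jrs, [], genome)
        assert len(cands) == 1
        c = cands[0]
        assert (c.lo, c.hi) == (site, site + d)
        assert c.tsd == genome["chr1"][site : site + d]
        assert len(c.tsd) == 4

    def test_single_read_below_min_support(self, scene):
        genome, te = scene
        left = genome["chr1"][5960:6000] + te["TE"][:61]
        jrs = find_junction_reads([_pair("L1", left, genome["chr1"][1000:1101])], te, genome)
        assert call_insertions(jrs, [], genome, min_support=2) == []

    def test_repeat_ambiguity_group_of_three(self):
        """Insertion into a 3-copy repeat yields 3 candidates in one group."""
        sim = simulate_insertion_readset(
            GenomeSimConfig(
                seed=8, repeat_family=RepeatFamily(copy_number=3, divergence=0.02),
                insertion_in_repeat_copy=1, coverage=25.0,
            )
        )
        jrs = find_junction_reads(sim.pairs, sim.te, sim.genome)
        cands = call_insertions(jrs, [], sim.genome)
        groups = {c.ambiguity_group for c in cands if c.ambiguity_group}
        assert len(groups) == 1
        grouped = [c for c in cands if c.ambiguity_group]
        assert len(grouped) == 3
        # one alternative matches the true site; all carry identical evidence
        assert any(abs(c.lo - sim.truth.insertion_site) <= 5 for c in grouped)
        assert len({c.junction_read_ids for c in grouped}) == 1

    def test_determinism_of_candidate_tables(self, tmp_path):
        from pirnakit.insertions import write_candidates_tsv

        outs = []
        for rep in range(2):
            sim = simulate_insertion_readset(GenomeSimConfig(seed=99))
            jrs = find_junction_reads(sim.pairs, sim.te, sim.genome)
            disc = find_discordant_pairs(sim.pairs, sim.te, sim.genome)
            cands = call_insertions(jrs, disc, sim.genome)
            p = tmp_path / f"cand{rep}.tsv"
            write_candidates_tsv(cands, str(p))
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]


class TestAnnotation:
    def _cand(self, lo, hi):
        return InsertionCandidate("chr1", lo, hi, 2, 2, 0, ("a", "b"))

    def test_inside_interval(self):
        ann = IntervalSet([Interval("chr1", 5000, 7000, "cluster9")])
        out = annotate_candidates([self._cand(6000, 6004)], ann)
        assert out[0].annotations == ("cluster9",)

    def test_outside_all_intervals(self):
        ann = IntervalSet([Interval("chr1", 5000, 7000, "cluster9")])
        assert annotate_candidates([self._cand(100, 104)], ann)[0].annotations == ()

    def test_spanning_two_intervals(self):
        ann = IntervalSet(
            [Interval("chr1", 0, 6002, "left"), Interval("chr1", 6002, 9000, "right")]
        )
        out = annotate_candidates([self._cand(6000, 6004)], ann)
        assert out[0].annotations == ("left", "right")
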