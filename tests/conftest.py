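"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own algorithms: the
mapping oracle is an exhaustive per-offset Hamming scan with no seeding
or indexing, and the pair-statistics oracles enumerate all read pairs in
O(n^2).
"""

from __future__ import annotations

import numpy as np
import pytest

from pirnakit import Alignment, ReadSet, revcomp


# ---------------------------------------------------------------------------
# exhaustive mapping oracle
# ---------------------------------------------------------------------------

def oracle_scan(seq: str, refs: dict[str, str], max_mm: int) -> list[tuple]:
    """All full-length gap-free placements of ``seq`` by exhaustive scan.

    Returns sorted (reference, start, end, strand, mismatches) tuples for
    every offset on both strands with Hamming distance <= max_mm.  N never
    matches, not even against N.
    """
    hits = []
    n_byte = ord("N")
    for name, ref in refs.items():
        ref_a = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            m = len(oriented)
            if m > len(ref_a):
                continue
            win = np.lib.stride_tricks.sliding_window_view(ref_a, m)
            r = np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)
            mm = (win != r).sum(axis=1) + ((win == n_byte) & (r == n_byte)).sum(axis=1)
            for p in np.nonzero(mm <= max_mm)[0]:
                hits.append((name, int(p), int(p) + m, strand, int(mm[p])))
    return sorted(hits)


def oracle_map_readset(reads: ReadSet, refs: dict[str, str], max_mm: int) -> set[tuple]:
    """Alignment-tuple set for a whole ReadSet (sequence included)."""
    out = set()
    for read in reads:
        if "N" in read.sequence:
            continue
        for hit in oracle_scan(read.sequence, refs, max_mm):
            out.add((read.sequence,) + hit)
    return out


# ---------------------------------------------------------------------------
# O(n^2) pair-statistics oracles
# ---------------------------------------------------------------------------

def oracle_overlap_histogram(alignments: list[Alignment], k_max: int = 28) -> dict[int, float]:
    """All-pairs enumeration of 5'-overlap proportions."""
    weights: dict[int, float] = {}
    sense = [a for a in alignments if a.strand == "+"]
    anti = [a for a in alignments if a.strand == "-"]
    for s in sense:
        for a in anti:
            k = a.five_prime - s.five_prime + 1
            if 1 <= k <= k_max:
                weights[k] = weights.get(k, 0.0) + s.count * a.count
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()} if total else {}


def oracle_ppp_percent(alignments: list[Alignment]) -> float:
    """All-pairs count-weighted ping-pong-partner percentage."""
    sense = [a for a in alignments if a.strand == "+"]
    anti = [a for a in alignments if a.strand == "-"]
    member = 0
    total = 0
    for s in sense:
        total += s.count
        if any(a.five_prime - s.five_prime + 1 == 10 for a in anti):
            member += s.count
    for a in anti:
        total += a.count
        if any(a.five_prime - s.five_prime + 1 == 10 for s in sense):
            member += a.count
    return 100.0 * member / total if total else 0.0


# ---------------------------------------------------------------------------
# small constructed fixtures
# ---------------------------------------------------------------------------

def make_alignment(strand: str, five_prime: int, count: int = 1, length: int = 26,
                   reference: str = "TE", sequence: str | None = None) -> Alignment:
    if sequence is None:
        sequence = "T" + "C" * (length - 1)
    if strand == "+":
        start, end = five_prime, five_prime + length
    else:
        start, end = five_prime - length + 1, five_prime + 1
    return Alignment(sequence, reference, start, end, strand, 0, count)


def random_reads_from_ref(
    rng: np.random.Generator,
    ref: str,
    n: int,
    mutate_up_to: int = 3,
    len_range: tuple[int, int] = (18, 30),
) -> ReadSet:
    """Reads drawn from a reference with up to a few substitutions planted."""
    bases = "ACGT"
    rs = ReadSet("random")
    for i in range(n):
        m = int(rng.integers(len_range[0], len_range[1] + 1))
        if rng.random() < 0.1:  # pure random read, likely unmappable
            seq = "".join(bases[b] for b in rng.integers(0, 4, m))
        else:
            start = int(rng.integers(0, len(ref) - m + 1))
            seq = ref[start : start + m]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            for _ in range(int(rng.integers(0, mutate_up_to + 1))):
                pos = int(rng.integers(0, m))
                seq = seq[:pos] + bases[int(rng.integers(0, 4))] + seq[pos + 1 :]
        rs.add(seq, int(rng.integers(1, 4)))
    return rs


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230901)
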