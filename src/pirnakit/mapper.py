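"""Gap-free k-mismatch short-read mapping.

Maps 18-30 nt small-RNA reads (and DNA-seq mates) full-length onto
reference sequences on either strand, tolerating up to ``max_mismatches``
substitutions (no indels).  The search is exact (lossless) via pigeonhole
seeding: a read is split into ``k + 1`` non-overlapping seeds, each seed
is looked up exactly in a reference k-mer index, and every candidate
offset is verified by a full Hamming comparison.  Any placement with at
most k mismatches leaves at least one seed exact, so no hit is missed.

Two mapping regimes are used downstream: transposon-consensus mapping at
up to 3 mismatches (per-TE statistics) and genome mapping at 0 mismatches
(uniqueness calls and the reads-per-million denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import ReadSet, ReferenceSet, revcomp

logger = logging.getLogger("pirnakit")

UNMAPPED = "unmapped"
UNIQUE = "unique"
MULTI = "multi"


@dataclass(frozen=True)
class Alignment:
    """A full-length, gap-free placement of a read on a reference.

    ``five_prime`` is the genomic coordinate of the read's 5' end: the
    start on the + strand, ``end - 1`` on the - strand.  ``count`` carries
    the copy number of the collapsed read.
    """

    read_sequence: str
    reference: str
    start: int
    end: int
    strand: str
    mismatches: int
    count: int = 1

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


class MappingResult:
    """Alignments plus per-read mapping status at a mismatch threshold."""

    def __init__(
        self,
        alignments: list[Alignment],
        status: dict[str, str],
        max_mismatches: int,
        read_counts: dict[str, int],
    ) -> None:
        self.alignments = alignments
        self.status = status
        self.max_mismatches = max_mismatches
        self._read_counts = read_counts

    @property
    def mapped_total(self) -> int:
        """Sum of copy numbers of reads with at least one alignment."""
        return sum(
            n for seq, n in self._read_counts.items()
            if self.status.get(seq, UNMAPPED) != UNMAPPED
        )

    def unique_sequences(self) -> set[str]:
        return {s for s, st in self.status.items() if st == UNIQUE}

    def alignments_for(self, reference: str) -> list[Alignment]:
        return [a for a in self.alignments if a.reference == reference]


class ReferenceIndex:
    """Per-reference byte arrays plus lazily built seed k-mer indexes.

    Building the index once and reusing it across read sets amortises the
    reference scan; seed tables are keyed by (reference, seed length).
    """

    def __init__(self, refs: ReferenceSet) -> None:
        if len(refs) == 0:
            raise ValueError("empty ReferenceSet")
        self.refs = refs
        self.arrays: dict[str, np.ndarray] = {
            name: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            for name, seq in refs.items()
        }
        self._seed_tables: dict[tuple[str, int], dict[str, list[int]]] = {}

    def seed_table(self, name: str, seed_len: int) -> dict[str, list[int]]:
        key = (name, seed_len)
        table = self._seed_tables.get(key)
        if table is None:
            seq = self.refs[name]
            table = {}
            for pos in range(len(seq) - seed_len + 1):
                kmer = seq[pos : pos + seed_len]
                table.setdefault(kmer, []).append(pos)
            self._seed_tables[key] = table
        return table

    def candidate_starts(self, name: str, oriented: str, max_mm: int) -> np.ndarray:
        """Candidate start offsets for one read orientation on one reference."""
        m = len(oriented)
        ref_len = len(self.refs[name])
        if m > ref_len:
            return np.empty(0, dtype=np.int64)
        n_seeds = max_mm + 1
        seed_len = m // n_seeds
        table = self.seed_table(name, seed_len)
        starts: set[int] = set()
        for i in range(n_seeds):
            off = i * seed_len
            for pos in table.get(oriented[off : off + seed_len], ()):
                p = pos - off
                if 0 <= p <= ref_len - m:
                    starts.add(p)
        return np.fromiter(sorted(starts), dtype=np.int64, count=len(starts))

    def hamming_at(self, name: str, oriented: str, starts: np.ndarray) -> np.ndarray:
        """Vectorised mismatch counts of one read orientation at given offsets."""
        if starts.size == 0:
            return np.empty(0, dtype=np.int64)
        ref = self.arrays[name]
        read = np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)
        windows = ref[starts[:, None] + np.arange(len(read))[None, :]]
        mm = (windows != read[None, :]).sum(axis=1)
        # N never matches, not even N-vs-N
        n_byte = ord("N")
        if n_byte in ref or n_byte in read:
            mm = mm + ((windows == n_byte) & (read[None, :] == n_byte)).sum(axis=1)
        return mm.astype(np.int64)


def _align_one(
    index: ReferenceIndex, seq: str, count: int, max_mm: int
) -> list[Alignment]:
    m = len(seq)
    hits: list[Alignment] = []
    rc = revcomp(seq)
    for name in index.refs.names():
        for strand, oriented in (("+", seq), ("-", rc)):
            starts = index.candidate_starts(name, oriented, max_mm)
            mm = index.hamming_at(name, oriented, starts)
            for p, d in zip(starts.tolist(), mm.tolist()):
                if d <= max_mm:
                    hits.append(
                        Alignment(seq, name, p, p + m, strand, d, count)
                    )
    hits.sort(key=lambda a: (a.reference, a.start, a.strand))
    return hits


def map_reads(
    reads: ReadSet,
    refs: ReferenceSet | ReferenceIndex,
    max_mismatches: int = 0,
    report: str = "all",
) -> MappingResult:
    """Map every read full-length to every reference, both strands.

    ``report='all'`` keeps every placement with at most ``max_mismatches``
    substitutions; ``report='best'`` keeps only placements at the read's
    minimal observed distance.  Reads containing N are left unmapped (an N
    never matches).  Alignment order is (reference, start, strand) and is
    deterministic.
    """
    if report not in ("all", "best"):
        raise ValueError(f"report must be 'all' or 'best', got {report!r}")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    index = refs if isinstance(refs, ReferenceIndex) else ReferenceIndex(refs)
    alignments: list[Alignment] = []
    status: dict[str, str] = {}
    read_counts: dict[str, int] = {}
    for read in reads:
        seq, count = read.sequence, read.count
        read_counts[seq] = count
        if "N" in seq:
            status[seq] = UNMAPPED
            continue
        hits = _align_one(index, seq, count, max_mismatches)
        if not hits:
            status[seq] = UNMAPPED
            continue
        status[seq] = UNIQUE if len(hits) == 1 else MULTI
        if report == "best":
            best = min(h.mismatches for h in hits)
            hits = [h for h in hits if h.mismatches == best]
        alignments.extend(hits)
    return MappingResult(alignments, status, max_mismatches, read_counts)


def genome_unique_status(
    reads: ReadSet, genome: ReferenceSet | ReferenceIndex
) -> MappingResult:
    """Zero-mismatch genome mapping with uniqueness calls.

    ``mapped_total`` of the result is the total genome-mapped read mass at
    0 mismatches — the denominator used for reads-per-million
    normalisation of every profile.
    """
    return map_reads(reads, genome, max_mismatches=0, report="all")


def best_placements(result: MappingResult) -> list[Alignment]:
    """One alignment per read: its best placement.

    For per-TE statistics each read contributes its full copy number
    exactly once.  Among a read's minimal-mismatch placements, ties break
    by lowest start, then + strand — deterministic and documented.
    """
    by_read: dict[str, Alignment] = {}
    for aln in result.alignments:
        cur = by_read.get(aln.read_sequence)
        if cur is None or _placement_key(aln) < _placement_key(cur):
            by_read[aln.read_sequence] = aln
    return sorted(by_read.values(), key=lambda a: (a.reference, a.start, a.strand))


def _placement_key(a: Alignment) -> tuple[int, str, int, int]:
    return (a.mismatches, a.reference, a.start, 0 if a.strand == "+" else 1)


def write_alignments_tsv(alignments: Iterable[Alignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# gap-free alignments; start/end 0-based half-open\n"
            "read_sequence\treference\tstart\tend\tstrand\tmismatches\tfive_prime\tcount\n"
        )
        for a in alignments:
            fh.write(
                f"{a.read_sequence}\t{a.reference}\t{a.start}\t{a.end}\t"
                f"{a.strand}\t{a.mismatches}\t{a.five_prime}\t{a.count}\n"
            )


def write_alignments_bed(alignments: Iterable[Alignment], path: str) -> None:
    """BED6 export: name = read sequence, score = copy number."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                f"{a.reference}\t{a.start}\t{a.end}\t{a.read_sequence}\t"
                f"{a.count}\t{a.strand}\n"
            )
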