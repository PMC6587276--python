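"""Reading, collapsing, filtering and writing of small-RNA pipeline inputs.

Small-RNA libraries arrive as FASTA or FASTQ; identical sequences are
collapsed into :class:`CollapsedRead` records carrying a copy number, the
unit on which every downstream statistic is count-weighted.  References
(genome contigs, transposon consensus sequences) are plain FASTA; piRNA
cluster and TE annotations are BED3/BED6 with 0-based half-open
coordinates, preserved verbatim.

All sequences are normalised to the uppercase DNA alphabet at load time
(U -> T), so downstream modules work on a single alphabet.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger("pirnakit")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CollapsedRead:
    """A distinct small-RNA sequence with its copy number."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")

    @property
    def length(self) -> int:
        return len(self.sequence)


class ReadSet:
    """Collection of collapsed reads keyed by sequence.

    Iteration order is insertion order, which makes outputs deterministic
    for a given input stream.
    """

    def __init__(self, provenance: str = "") -> None:
        self._counts: dict[str, int] = {}
        self.provenance = provenance

    def add(self, sequence: str, count: int = 1) -> None:
        if count < 1:
            raise ValueError("count must be >= 1")
        self._counts[sequence] = self._counts.get(sequence, 0) + count

    def count_of(self, sequence: str) -> int:
        return self._counts.get(sequence, 0)

    @property
    def total_count(self) -> int:
        return sum(self._counts.values())

    def sequences(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self._counts

    def __iter__(self) -> Iterator[CollapsedRead]:
        for seq, n in self._counts.items():
            yield CollapsedRead(seq, n)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadSet):
            return NotImplemented
        return self._counts == other._counts

    def length_histogram(self) -> dict[int, int]:
        """Copy-number-weighted tally of read lengths."""
        hist: dict[int, int] = {}
        for seq, n in self._counts.items():
            hist[len(seq)] = hist.get(len(seq), 0) + n
        return hist

    def filter_lengths(self, min_len: int, max_len: int) -> "ReadSet":
        out = ReadSet(self.provenance)
        for seq, n in self._counts.items():
            if min_len <= len(seq) <= max_len:
                out.add(seq, n)
        return out


class ReferenceSet:
    """Named uppercase DNA reference sequences (genome contigs or TE consensus)."""

    def __init__(self, sequences: dict[str, str] | None = None) -> None:
        self._seqs: dict[str, str] = {}
        if sequences:
            for name, seq in sequences.items():
                self.add(name, seq)

    def add(self, name: str, sequence: str) -> None:
        if name in self._seqs:
            raise ValueError(f"duplicate reference name: {name}")
        seq = _normalize(sequence)
        if not seq:
            raise ValueError(f"empty reference sequence: {name}")
        self._seqs[name] = seq

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def names(self) -> list[str]:
        return list(self._seqs)

    def items(self) -> Iterable[tuple[str, str]]:
        return self._seqs.items()


@dataclass(frozen=True)
class Interval:
    contig: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end: {self.contig}:{self.start}-{self.end}"
            )

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


class IntervalSet:
    """Ordered BED-style annotation records, 0-based half-open."""

    def __init__(self, intervals: Iterable[Interval] = ()) -> None:
        self.intervals: list[Interval] = list(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def overlapping(self, contig: str, start: int, end: int) -> list[Interval]:
        return [
            iv
            for iv in self.intervals
            if iv.contig == contig and iv.overlap(start, end) > 0
        ]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".fq", ".fastq"):
        return "fastq"
    if ext in (".fa", ".fasta", ".fna"):
        return "fasta"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    return "fasta"


def load_reads(
    path: str,
    min_len: int = 1,
    max_len: int = 10**9,
    counts_in_header: bool = False,
) -> ReadSet:
    """Load a FASTA/FASTQ small-RNA library, collapse and size-select.

    Identical sequences are collapsed with summed counts; reads outside
    ``[min_len, max_len]`` are dropped; sequences are uppercased with
    U -> T.  With ``counts_in_header`` a collapsed-FASTA dialect is
    assumed in which a header of the form ``id_N`` carries copy number N;
    otherwise every record counts 1.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError(f"require 1 <= min_len <= max_len, got {min_len}, {max_len}")
    fmt = _sniff_format(path)
    out = ReadSet(provenance=os.path.basename(path))
    n_records = 0
    for record in SeqIO.parse(path, fmt):
        seq = _normalize(str(record.seq))
        count = 1
        if counts_in_header:
            tail = record.id.rsplit("_", 1)
            if len(tail) == 2 and tail[1].isdigit() and int(tail[1]) > 0:
                count = int(tail[1])
        n_records += count
        if min_len <= len(seq) <= max_len:
            out.add(seq, count)
    if len(out) == 0:
        logger.warning("no reads retained from %s (of %d records)", path, n_records)
    logger.info(
        "loaded %s: %d records, %d retained (%d distinct) in [%d, %d] nt",
        path, n_records, out.total_count, len(out), min_len, max_len,
    )
    return out


def load_references(path: str) -> ReferenceSet:
    """Load a FASTA file of reference sequences (genome or TE consensus)."""
    refs = ReferenceSet()
    for record in SeqIO.parse(path, "fasta"):
        refs.add(record.id, str(record.seq))
    if len(refs) == 0:
        raise ValueError(f"no sequences found in {path}")
    return refs


def load_intervals(path: str) -> IntervalSet:
    """Load BED3+ annotations; coordinates are kept 0-based half-open."""
    intervals: list[Interval] = []
    seen_names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            if name != "." and name in seen_names:
                logger.warning("%s:%d: duplicate interval name %r", path, lineno, name)
            seen_names.add(name)
            intervals.append(Interval(fields[0], start, end, name, strand))
    return IntervalSet(intervals)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_exact_contaminant(reads: ReadSet, contaminant: str) -> ReadSet:
    """Remove reads that are exact substrings of a contaminant sequence.

    Used for 2S rRNA depletion: a read is dropped when its sequence occurs
    verbatim in the contaminant or its reverse complement.  No mismatches
    are tolerated.
    """
    if not contaminant:
        raise ValueError("contaminant sequence must be non-empty")
    cont = _normalize(contaminant)
    cont_rc = revcomp(cont)
    out = ReadSet(reads.provenance)
    removed_distinct = 0
    removed_mass = 0
    for read in reads:
        if read.sequence in cont or read.sequence in cont_rc:
            removed_distinct += 1
            removed_mass += read.count
        else:
            out.add(read.sequence, read.count)
    logger.info(
        "contaminant depletion removed %d distinct reads (%d copies)",
        removed_distinct, removed_mass,
    )
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_reads(reads: ReadSet, path: str, counts_in_header: bool = True) -> None:
    """Write a ReadSet as FASTA.

    With ``counts_in_header`` (default) the collapsed dialect ``>readK_N``
    is emitted; otherwise each sequence is repeated once per copy.
    """
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            if counts_in_header:
                fh.write(f">read{i}_{read.count}\n{read.sequence}\n")
            else:
                for j in range(read.count):
                    fh.write(f">read{i}.{j}\n{read.sequence}\n")


def write_references(refs: ReferenceSet, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in refs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_intervals(intervals: IntervalSet, path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def write_fastq(records: Iterable[tuple[str, str]], path: str) -> None:
    """Write (id, sequence) records as FASTQ with constant quality 'I'."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def load_fastq_pairs(path1: str, path2: str) -> list[tuple[str, str, str]]:
    """Load mate-paired FASTQ files as (pair id, mate1 seq, mate2 seq)."""
    r1 = list(SeqIO.parse(path1, "fastq"))
    r2 = list(SeqIO.parse(path2, "fastq"))
    if len(r1) != len(r2):
        raise ValueError(
            f"mate files differ in record count: {len(r1)} vs {len(r2)}"
        )
    pairs = []
    for a, b in zip(r1, r2):
        pid = a.id.split("/")[0]
        pairs.append((pid, _normalize(str(a.seq)), _normalize(str(b.seq))))
    return pairs
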