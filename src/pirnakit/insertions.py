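"""Chimeric-read and discordant-pair detection of non-reference TE insertions.

Component TE callers built on concordant mapping miss insertions inside
repetitive regions such as piRNA clusters.  This module implements the
complementary strategy: from the reads that are *not uniquely mappable*
full-length on the reference genome, isolate chimeric (junction) reads
that join transposon terminus sequence to genomic flank, strip the TE
portion, and map the remaining flank back to the genome — reporting every
placement, so that an insertion into a multi-copy repeat surfaces as an
ambiguity group of alternative sites.  Discordant mate pairs (one mate on
the TE consensus, one on the genome) add orthogonal support, and
overlapping 5'/3' junction coordinates recover the target-site
duplication (TSD).

Coordinates are 0-based half-open internally; report writers emit
1-based inclusive columns alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .io import IntervalSet, ReadSet, ReferenceSet, revcomp
from .mapper import (
    MappingResult,
    ReferenceIndex,
    UNIQUE,
    UNMAPPED,
    map_reads,
)

logger = logging.getLogger("pirnakit")


@dataclass(frozen=True)
class JunctionParams:
    """Tunables of the chimeric-read scan.

    ``min_te_match`` / ``min_flank`` are the minimal lengths (nt) of the
    transposon-derived and genome-derived read segments; each segment
    tolerates up to one substitution by default.  ``terminus_length``
    bounds how far from a TE end the TE-derived segment may extend
    (covers LTR ends).  With ``require_fully_unmapped`` only reads with
    zero full-length genomic placements are scanned; by default any read
    that is not *uniquely* mappable qualifies, so multi-mappers from
    repeats are kept.
    """

    min_te_match: int = 20
    min_flank: int = 20
    max_mismatches_te: int = 1
    max_mismatches_flank: int = 1
    terminus_length: int = 200
    require_fully_unmapped: bool = False


@dataclass(frozen=True)
class InsertSizePrior:
    mean: float = 350.0
    sd: float = 50.0

    @property
    def max_span(self) -> int:
        return int(self.mean + 3 * self.sd)


@dataclass
class JunctionRead:
    """A read spanning a TE-genome junction, decomposed into TE part + flank."""

    read_id: str
    te_side: str  # '5prime' or '3prime': which TE terminus the read contains
    te_match_len: int
    flank_sequence: str
    breakpoint_offset: int  # position in the read where TE sequence ends/begins
    flank_placements: list[tuple[str, int, str, int]]  # (contig, start, strand, mm)
    implied_breakpoints: list[tuple[str, int]]  # (contig, breakpoint coordinate)


@dataclass
class DiscordantPair:
    """A mate pair with one mate on the TE consensus and one on the genome."""

    pair_id: str
    te_reference: str
    te_interval: tuple[int, int]
    te_strand: str
    genome_contig: str
    genome_interval: tuple[int, int]
    genome_strand: str
    implied_window: tuple[int, int]  # genomic interval expected to hold the insertion


@dataclass
class InsertionCandidate:
    """A clustered set of junction/discordant evidence localising an insertion."""

    contig: str
    lo: int
    hi: int  # breakpoint interval, 0-based half-open
    support_junction_5p: int
    support_junction_3p: int
    support_discordant: int
    junction_read_ids: tuple[str, ...]
    tsd: str | None = None
    ambiguity_group: str | None = None
    annotations: tuple[str, ...] = ()

    @property
    def total_support(self) -> int:
        return (
            self.support_junction_5p
            + self.support_junction_3p
            + self.support_discordant
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _mates(pairs: Sequence[tuple[str, str, str]]) -> Iterable[tuple[str, str]]:
    for pid, s1, s2 in pairs:
        yield f"{pid}/1", s1
        yield f"{pid}/2", s2


def _mate_readset(pairs: Sequence[tuple[str, str, str]]) -> tuple[ReadSet, dict[str, list[str]]]:
    """Collapse mate sequences; keep sequence -> mate-id mapping."""
    rs = ReadSet("mates")
    ids: dict[str, list[str]] = {}
    for mid, seq in _mates(pairs):
        rs.add(seq, 1)
        ids.setdefault(seq, []).append(mid)
    return rs, ids


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# junction reads
# ---------------------------------------------------------------------------

def _decompose_read(
    seq_arr: np.ndarray,
    te_fwd: np.ndarray,
    te_rc: np.ndarray,
    params: JunctionParams,
) -> tuple[str, int, str] | None:
    """Find the longest TE-terminus segment at either read end.

    Returns (te_side, te_match_len, te_end) where te_end is 'left' or
    'right' — which end of the read the TE segment occupies — or None.
    Four configurations cover both insertion orientations and both
    sequencing strands: a read suffix matching a TE 5' start (forward or
    reverse-complemented consensus) or a read prefix matching a TE 3'
    end.
    """
    m = len(seq_arr)
    t_max = min(params.terminus_length, m - params.min_flank)
    if t_max < params.min_te_match:
        return None
    L = len(te_fwd)
    best: tuple[str, int, str] | None = None
    for te_arr, side_suffix, side_prefix in (
        (te_fwd, "5prime", "3prime"),
        (te_rc, "3prime", "5prime"),
    ):
        for t in range(t_max, params.min_te_match - 1, -1):
            # read suffix vs TE start: read[-t:] == te[:t]
            if best is not None and t <= best[1]:
                break
            if _hamming(seq_arr[m - t :], te_arr[:t]) <= params.max_mismatches_te:
                best = (side_suffix, t, "right")
                break
        for t in range(t_max, params.min_te_match - 1, -1):
            # read prefix vs TE end: read[:t] == te[-t:]
            if best is not None and t <= best[1]:
                break
            if _hamming(seq_arr[:t], te_arr[L - t :]) <= params.max_mismatches_te:
                best = (side_prefix, t, "left")
                break
    return best


def find_junction_reads(
    pairs: Sequence[tuple[str, str, str]],
    te: ReferenceSet,
    genome: ReferenceSet | ReferenceIndex,
    params: JunctionParams = JunctionParams(),
) -> list[JunctionRead]:
    """Isolate TE-genome chimeric reads from the non-uniquely-mappable reads.

    Each mate that lacks a unique full-length 0-mismatch genomic placement
    is tested for a TE-terminus segment of at least ``min_te_match`` nt at
    either end; the TE portion is stripped and the remaining flank
    (>= ``min_flank`` nt) is mapped back to the genome, reporting *all*
    placements (repeat copies included).  The implied breakpoint of each
    placement is the genomic coordinate adjacent to the TE side of the
    flank.
    """
    te_names = te.names()
    if len(te_names) != 1:
        raise ValueError("expected exactly one TE consensus sequence")
    te_seq = te[te_names[0]]
    if len(te_seq) < params.min_te_match:
        raise ValueError("TE consensus shorter than min_te_match")
    te_fwd = _encode(te_seq)
    te_rc = _encode(revcomp(te_seq))

    index = genome if isinstance(genome, ReferenceIndex) else ReferenceIndex(genome)
    mates_rs, mate_ids = _mate_readset(pairs)
    genome_status = map_reads(mates_rs, index, max_mismatches=0, report="all").status

    out: list[JunctionRead] = []
    for seq in mates_rs.sequences():
        st = genome_status.get(seq, UNMAPPED)
        if st == UNIQUE:
            continue
        if params.require_fully_unmapped and st != UNMAPPED:
            continue
        if "N" in seq:
            continue
        dec = _decompose_read(_encode(seq), te_fwd, te_rc, params)
        if dec is None:
            continue
        te_side, t, te_end = dec
        if te_end == "right":
            flank = seq[: len(seq) - t]
            breakpoint_offset = len(seq) - t
        else:
            flank = seq[t:]
            breakpoint_offset = t
        if len(flank) < params.min_flank:
            continue
        flank_rs = ReadSet()
        flank_rs.add(flank, 1)
        flank_map = map_reads(
            flank_rs, index, max_mismatches=params.max_mismatches_flank, report="all"
        )
        if not flank_map.alignments:
            continue
        placements = [
            (a.reference, a.start, a.strand, a.mismatches)
            for a in flank_map.alignments
        ]
        breakpoints = []
        for a in flank_map.alignments:
            te_at_right_of_flank = te_end == "right"
            if a.strand == "+":
                bp = a.end if te_at_right_of_flank else a.start
            else:
                bp = a.start if te_at_right_of_flank else a.end
            breakpoints.append((a.reference, bp))
        for mid in mate_ids[seq]:
            out.append(
                JunctionRead(
                    read_id=mid,
                    te_side=te_side,
                    te_match_len=t,
                    flank_sequence=flank,
                    breakpoint_offset=breakpoint_offset,
                    flank_placements=placements,
                    implied_breakpoints=breakpoints,
                )
            )
    logger.info("junction scan: %d chimeric reads", len(out))
    return out


# ---------------------------------------------------------------------------
# discordant pairs
# ---------------------------------------------------------------------------

def find_discordant_pairs(
    pairs: Sequence[tuple[str, str, str]],
    te: ReferenceSet,
    genome: ReferenceSet | ReferenceIndex,
    insert_prior: InsertSizePrior = InsertSizePrior(),
    max_mismatches_te: int = 3,
) -> list[DiscordantPair]:
    """Mate pairs with one mate on the TE consensus and one on the genome.

    The genome mate's placement extended by the insert-size prior in the
    direction of its missing mate gives the window expected to contain
    the insertion breakpoint.
    """
    index = genome if isinstance(genome, ReferenceIndex) else ReferenceIndex(genome)
    te_index = ReferenceIndex(te) if isinstance(te, ReferenceSet) else te
    mates_rs, _ = _mate_readset(pairs)
    genome_map = map_reads(mates_rs, index, max_mismatches=0, report="all")
    te_map = map_reads(mates_rs, te_index, max_mismatches=max_mismatches_te, report="best")
    te_hits = {a.read_sequence: a for a in te_map.alignments}
    genome_unique = {
        a.read_sequence: a
        for a in genome_map.alignments
        if genome_map.status.get(a.read_sequence) == UNIQUE
    }

    out: list[DiscordantPair] = []
    span = insert_prior.max_span
    for pid, s1, s2 in pairs:
        for te_seq, g_seq in ((s1, s2), (s2, s1)):
            if te_seq in te_hits and te_seq not in genome_unique and g_seq in genome_unique:
                t = te_hits[te_seq]
                g = genome_unique[g_seq]
                if g.strand == "+":
                    window = (g.end, g.start + span)
                else:
                    window = (max(0, g.end - span), g.start)
                out.append(
                    DiscordantPair(
                        pair_id=pid,
                        te_reference=t.reference,
                        te_interval=(t.start, t.end),
                        te_strand=t.strand,
                        genome_contig=g.reference,
                        genome_interval=(g.start, g.end),
                        genome_strand=g.strand,
                        implied_window=window,
                    )
                )
                break
    logger.info("discordant scan: %d pairs", len(out))
    return out


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def _modal_position(positions: list[int]) -> int:
    from collections import Counter

    counts = Counter(positions)
    best_n = max(counts.values())
    return min(p for p, n in counts.items() if n == best_n)


def call_insertions(
    junctions: Sequence[JunctionRead],
    discordants: Sequence[DiscordantPair],
    genome: ReferenceSet,
    cluster_distance: int = 500,
    min_support: int = 2,
) -> list[InsertionCandidate]:
    """Cluster junction and discordant evidence into insertion candidates.

    Junction-implied breakpoints on one contig are single-linkage
    clustered within ``cluster_distance``; per cluster the modal position
    of each junction side is taken, and when both sides are present their
    positions bound the breakpoint interval — an overlap of 1-20 bp is
    reported as the target-site duplication, read off the reference.
    Reads whose flanks multi-map produce one candidate per alternative
    placement; candidates connected by shared junction reads form one
    ambiguity group and carry the identical (union) junction evidence.
    Candidates are ranked by total support.
    """
    # flatten junction evidence: (contig, pos, side, read_id)
    events: list[tuple[str, int, str, str]] = []
    for jr in junctions:
        for contig, bp in jr.implied_breakpoints:
            events.append((contig, bp, jr.te_side, jr.read_id))

    clusters: list[list[tuple[str, int, str, str]]] = []
    for contig in sorted({e[0] for e in events}):
        ce = sorted((e for e in events if e[0] == contig), key=lambda e: e[1])
        current: list[tuple[str, int, str, str]] = []
        for ev in ce:
            if current and ev[1] - current[-1][1] > cluster_distance:
                clusters.append(current)
                current = []
            current.append(ev)
        if current:
            clusters.append(current)

    raw: list[InsertionCandidate] = []
    cluster_reads: list[set[str]] = []
    for cl in clusters:
        contig = cl[0][0]
        by_side: dict[str, list[int]] = {"5prime": [], "3prime": []}
        reads_by_side: dict[str, set[str]] = {"5prime": set(), "3prime": set()}
        for _, pos, side, rid in cl:
            by_side[side].append(pos)
            reads_by_side[side].add(rid)
        positions = []
        for side in ("5prime", "3prime"):
            if by_side[side]:
                positions.append(_modal_position(by_side[side]))
        lo, hi = min(positions), max(positions)
        tsd: str | None = None
        if len(positions) == 2 and 1 <= hi - lo <= 20:
            tsd = genome[contig][lo:hi]
        if hi == lo:
            hi = lo + 1
        n_disc = sum(
            1
            for d in discordants
            if d.genome_contig == contig
            and d.implied_window[0] - cluster_distance <= hi
            and d.implied_window[1] + cluster_distance >= lo
        )
        cand = InsertionCandidate(
            contig=contig,
            lo=lo,
            hi=hi,
            support_junction_5p=len(reads_by_side["5prime"]),
            support_junction_3p=len(reads_by_side["3prime"]),
            support_discordant=n_disc,
            junction_read_ids=tuple(sorted(reads_by_side["5prime"] | reads_by_side["3prime"])),
            tsd=tsd,
        )
        raw.append(cand)
        cluster_reads.append(set(cand.junction_read_ids))

    # ambiguity groups: connected components over shared junction reads.
    # Alternative placements of the same evidence are indistinguishable, so
    # candidates within a group carry the identical (union) junction
    # evidence and support, and min_support applies to that shared evidence.
    read_side = {rid: side for _, _, side, rid in events}
    n = len(raw)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if cluster_reads[i] & cluster_reads[j]:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    group_counter = 0
    out: list[InsertionCandidate] = []
    for root, members in sorted(
        groups.items(), key=lambda kv: (raw[kv[1][0]].contig, raw[kv[1][0]].lo)
    ):
        union: set[str] = set()
        for i in members:
            union |= cluster_reads[i]
        gid: str | None = None
        if len(members) > 1:
            group_counter += 1
            gid = f"amb{group_counter}"
        n_5p = sum(1 for rid in union if read_side[rid] == "5prime")
        n_3p = len(union) - n_5p
        for i in members:
            cand = raw[i]
            if gid is not None:
                cand = replace(
                    cand,
                    support_junction_5p=n_5p,
                    support_junction_3p=n_3p,
                    junction_read_ids=tuple(sorted(union)),
                    ambiguity_group=gid,
                )
            if cand.total_support >= min_support:
                out.append(cand)
    out.sort(key=lambda c: (-c.total_support, c.contig, c.lo))
    return out


def annotate_candidates(
    candidates: Sequence[InsertionCandidate], annotation: IntervalSet
) -> list[InsertionCandidate]:
    """Label each candidate with every annotation interval its breakpoint overlaps."""
    out = []
    for c in candidates:
        hits = annotation.overlapping(c.contig, c.lo, c.hi)
        out.append(replace(c, annotations=tuple(iv.name for iv in hits)))
    return out


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def write_candidates_tsv(candidates: Sequence[InsertionCandidate], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# insertion candidates; lo/hi 0-based half-open, pos1/pos1_end 1-based inclusive\n"
            "contig\tlo\thi\tpos1\tpos1_end\tsupport_junction_5p\tsupport_junction_3p\t"
            "support_discordant\ttsd\tambiguity_group\tannotations\n"
        )
        for c in candidates:
            fh.write(
                f"{c.contig}\t{c.lo}\t{c.hi}\t{c.lo + 1}\t{c.hi}\t"
                f"{c.support_junction_5p}\t{c.support_junction_3p}\t{c.support_discordant}\t"
                f"{c.tsd or '.'}\t{c.ambiguity_group or '.'}\t"
                f"{','.join(c.annotations) or '.'}\n"
            )


def write_candidates_bed(candidates: Sequence[InsertionCandidate], path: str) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(candidates):
            fh.write(
                f"{c.contig}\t{c.lo}\t{c.hi}\tinsertion{i + 1}\t{c.total_support}\t.\t"
                f"{c.tsd or '.'}\t{c.ambiguity_group or '.'}\t"
                f"{','.join(c.annotations) or '.'}\n"
            )
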