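"""piRNA signature statistics.

Implements the count-weighted statistics used to characterise a
transposon's piRNA population:

* 5'-overlap histogram between sense and antisense reads (overlap lengths
  1-28 nt) and the ping-pong Z-score on the 1-23 nt proportions, with the
  conventional significance cut-off of 1.96;
* ping-pong partner (PPP) percentages — the fraction of read mass having
  at least one opposite-strand read whose 5' end overlaps its own by
  exactly 10 nt;
* positional nucleotide-frequency matrices and the 1U / 10A biases;
* sense/antisense density profiles in reads per million (RPM), where the
  million refers to the 0-mismatch genome-mapped mass of the library;
* piRNA-cluster composition of genome-unique 0-mismatch mappers.

The 5'-overlap between a sense read at 5' coordinate s and an antisense
read at 5' coordinate a is ``a - s + 1``; an exact ping-pong pair has
overlap 10.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntervalSet
from .mapper import Alignment, MappingResult, UNIQUE, best_placements

logger = logging.getLogger("pirnakit")

PINGPONG_OVERLAP = 10
ZSCORE_BACKGROUND_MAX = 23
ZSCORE_SIGNIFICANCE = 1.96

#: Density-profile window sizes (nt) used for the study's transposons,
#: scaled to each element's consensus length.
WINDOW_PRESETS: dict[str, int] = {
    "flamenco": 428,
    "ZAM": 91,
    "Burdock": 80,
    "Pifo": 87,
    "Phidippo": 85,
}


def _as_alignments(alignments) -> list[Alignment]:
    if isinstance(alignments, MappingResult):
        return best_placements(alignments)
    return list(alignments)


def _single_reference(alignments: list[Alignment]) -> str | None:
    refs = {a.reference for a in alignments}
    if len(refs) > 1:
        raise ValueError(f"alignments span multiple references: {sorted(refs)}")
    return next(iter(refs)) if refs else None


def _strand_masses(alignments: list[Alignment]) -> tuple[Counter, Counter]:
    """Count-weighted mass of 5' positions, per strand."""
    sense: Counter = Counter()
    anti: Counter = Counter()
    for a in alignments:
        (sense if a.strand == "+" else anti)[a.five_prime] += a.count
    return sense, anti


# ---------------------------------------------------------------------------
# Overlap histogram and Z-score
# ---------------------------------------------------------------------------

@dataclass
class OverlapHistogram:
    """Proportions of sense/antisense 5'-overlap lengths 1..k_max."""

    proportions: dict[int, float]
    pair_mass: float
    k_max: int = 28

    def p(self, k: int) -> float:
        return self.proportions.get(k, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "overlap_nt": list(range(1, self.k_max + 1)),
                "proportion": [self.p(k) for k in range(1, self.k_max + 1)],
            }
        )


def overlap_histogram(alignments, k_max: int = 28) -> OverlapHistogram:
    """Histogram of 5'-overlap lengths between sense and antisense reads.

    Every (sense, antisense) pair with overlap length in 1..k_max
    contributes the product of the two copy numbers; proportions are
    normalised by the total contributing mass.
    """
    alns = _as_alignments(alignments)
    _single_reference(alns)
    sense, anti = _strand_masses(alns)
    weights: dict[int, float] = {}
    for s_pos, s_mass in sense.items():
        for k in range(1, k_max + 1):
            a_mass = anti.get(s_pos + k - 1)
            if a_mass:
                weights[k] = weights.get(k, 0.0) + s_mass * a_mass
    pair_mass = sum(weights.values())
    if pair_mass == 0:
        logger.warning("no overlapping sense/antisense pair found")
        return OverlapHistogram({}, 0.0, k_max)
    props = {k: w / pair_mass for k, w in weights.items()}
    assert abs(sum(props.values()) - 1.0) < 1e-9
    return OverlapHistogram(props, pair_mass, k_max)


def pingpong_zscore(
    h: OverlapHistogram, include_self: bool = False
) -> tuple[float | None, bool]:
    """Z-score of the 10-nt overlap proportion against 1-23 nt background.

    z = (p10 - mean(B)) / sd(B) with B the proportions at overlap lengths
    1..23 (excluding 10 unless ``include_self``) and sd the sample
    standard deviation (n-1 denominator).  Returns (None, False) when the
    background is degenerate (sd = 0) or no pair exists.
    """
    if h.k_max < ZSCORE_BACKGROUND_MAX:
        raise ValueError("histogram must cover overlap lengths up to 23")
    if h.pair_mass == 0:
        return None, False
    ks = [
        k
        for k in range(1, ZSCORE_BACKGROUND_MAX + 1)
        if include_self or k != PINGPONG_OVERLAP
    ]
    background = np.array([h.p(k) for k in ks], dtype=float)
    sd = background.std(ddof=1)
    # proportions are O(1); sd below ~1e-12 is numerically zero
    if sd <= 1e-12:
        return None, False
    z = float((h.p(PINGPONG_OVERLAP) - background.mean()) / sd)
    return z, bool(z > ZSCORE_SIGNIFICANCE)


# ---------------------------------------------------------------------------
# Ping-pong partners
# ---------------------------------------------------------------------------

@dataclass
class PPPStats:
    percent_total: float
    percent_sense: float
    percent_antisense: float
    member_mass: float
    total_mass: float


def _ppp_positions(sense: Counter, anti: Counter) -> tuple[set, set]:
    ppp_sense = {p for p in sense if (p + PINGPONG_OVERLAP - 1) in anti}
    ppp_anti = {p for p in anti if (p - PINGPONG_OVERLAP + 1) in sense}
    return ppp_sense, ppp_anti


def ppp_stats(alignments, weighting: str = "count") -> PPPStats:
    """Percentages of reads with a ping-pong partner.

    A read is a PPP member iff at least one opposite-strand read overlaps
    its 5' end by exactly 10 nt.  ``weighting='count'`` weights by copy
    number (the default); ``'distinct'`` counts each distinct sequence
    once.
    """
    if weighting not in ("count", "distinct"):
        raise ValueError("weighting must be 'count' or 'distinct'")
    alns = _as_alignments(alignments)
    _single_reference(alns)
    if weighting == "distinct":
        alns = [
            Alignment(a.read_sequence, a.reference, a.start, a.end, a.strand,
                      a.mismatches, 1)
            for a in alns
        ]
    sense, anti = _strand_masses(alns)
    ppp_sense, ppp_anti = _ppp_positions(sense, anti)
    sense_total = sum(sense.values())
    anti_total = sum(anti.values())
    sense_member = sum(sense[p] for p in ppp_sense)
    anti_member = sum(anti[p] for p in ppp_anti)
    total = sense_total + anti_total
    member = sense_member + anti_member

    def pct(num: float, den: float) -> float:
        return 100.0 * num / den if den else 0.0

    return PPPStats(
        percent_total=pct(member, total),
        percent_sense=pct(sense_member, sense_total),
        percent_antisense=pct(anti_member, anti_total),
        member_mass=member,
        total_mass=total,
    )


# ---------------------------------------------------------------------------
# Nucleotide bias
# ---------------------------------------------------------------------------

BASES = ("A", "C", "G", "T")


@dataclass
class NucleotideMatrix:
    """Count-weighted base frequencies for read positions 1..P (5'->3')."""

    frequencies: pd.DataFrame  # index: position 1..P, columns A/C/G/T
    weight: float

    @property
    def bias_1U(self) -> float:
        """Percent of read mass with U (stored as T) at position 1."""
        return float(self.frequencies.loc[1, "T"] * 100.0)

    @property
    def bias_10A(self) -> float:
        """Percent of read mass with A at position 10."""
        return float(self.frequencies.loc[10, "A"] * 100.0)


def nucleotide_bias(
    alignments, positions: int = 10, subset: str = "all"
) -> NucleotideMatrix:
    """Positional base frequencies of mapped reads in sequenced orientation.

    ``subset`` restricts to ping-pong partners on one strand
    (``'ppp_sense'`` / ``'ppp_antisense'``) or uses every read
    (``'all'``).  Frequencies are weighted by copy number; every read must
    be at least ``positions`` nt long.
    """
    if subset not in ("all", "ppp_sense", "ppp_antisense"):
        raise ValueError(f"unknown subset {subset!r}")
    alns = _as_alignments(alignments)
    _single_reference(alns)
    if subset != "all":
        sense, anti = _strand_masses(alns)
        ppp_sense, ppp_anti = _ppp_positions(sense, anti)
        if subset == "ppp_sense":
            alns = [a for a in alns if a.strand == "+" and a.five_prime in ppp_sense]
        else:
            alns = [a for a in alns if a.strand == "-" and a.five_prime in ppp_anti]
    counts = np.zeros((positions, len(BASES)), dtype=float)
    weight = 0.0
    for a in alns:
        if len(a.read_sequence) < positions:
            raise ValueError(
                f"read shorter than {positions} nt: {a.read_sequence}"
            )
        weight += a.count
        for i in range(positions):
            base = a.read_sequence[i]
            if base in BASES:
                counts[i, BASES.index(base)] += a.count
    if weight == 0:
        logger.warning("empty subset %r for nucleotide bias", subset)
        freq = np.full((positions, len(BASES)), np.nan)
    else:
        col_tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            freq = np.where(col_tot > 0, counts / col_tot, np.nan)
    frame = pd.DataFrame(
        freq, index=pd.RangeIndex(1, positions + 1, name="position"),
        columns=list(BASES),
    )
    return NucleotideMatrix(frame, weight)


# ---------------------------------------------------------------------------
# Density profiles
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Windowed sense/antisense read density in RPM along one reference."""

    target: str
    target_length: int
    window_size: int
    normalization_total: int
    sense_rpm: np.ndarray
    antisense_rpm: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.sense_rpm)

    @property
    def window_starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.window_size

    def to_frame(self) -> pd.DataFrame:
        starts = self.window_starts
        ends = np.minimum(starts + self.window_size, self.target_length)
        return pd.DataFrame(
            {
                "window_start": starts,
                "window_end": ends,
                "sense_rpm": self.sense_rpm,
                "antisense_rpm": self.antisense_rpm,
            }
        )


def density_profile(
    alignments,
    target_length: int,
    window_size: int,
    normalization_total: int,
    target: str = "",
) -> DensityProfile:
    """Windowed read density, normalised to reads per million.

    Each read is assigned to exactly one window by its 5' coordinate; the
    window value is ``1e6 * mass / normalization_total`` split by strand.
    The last window may be short.  Mass is conserved: summed window RPM
    times the denominator recovers the profiled read mass exactly.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if normalization_total < 1:
        raise ValueError("normalization_total must be >= 1")
    alns = _as_alignments(alignments)
    ref = _single_reference(alns)
    if not target and ref:
        target = ref
    n_windows = math.ceil(target_length / window_size)
    sense = np.zeros(n_windows, dtype=float)
    anti = np.zeros(n_windows, dtype=float)
    for a in alns:
        w = a.five_prime // window_size
        if not (0 <= w < n_windows):
            raise ValueError(
                f"5' coordinate {a.five_prime} outside target of length {target_length}"
            )
        (sense if a.strand == "+" else anti)[w] += a.count
    scale = 1e6 / normalization_total
    return DensityProfile(
        target, target_length, window_size, normalization_total,
        sense * scale, anti * scale,
    )


# ---------------------------------------------------------------------------
# Cluster composition
# ---------------------------------------------------------------------------

@dataclass
class ClusterComposition:
    """Share of genome-unique 0-mismatch read mass per annotation interval."""

    shares: dict[str, float]
    assigned_mass: float
    unassigned_mass: float

    def to_frame(self, include_unassigned: bool = False) -> pd.DataFrame:
        names = list(self.shares)
        vals = [self.shares[n] for n in names]
        if include_unassigned:
            total = self.assigned_mass + self.unassigned_mass
            names = names + ["(unassigned)"]
            if total > 0:
                vals = [v * self.assigned_mass / total for v in vals]
                vals.append(self.unassigned_mass / total)
            else:
                vals.append(0.0)
        return pd.DataFrame({"interval": names, "share": vals})


def cluster_composition(
    unique0mm: MappingResult, clusters: IntervalSet
) -> ClusterComposition:
    """Composition of genome-unique 0-mismatch reads over annotation intervals.

    A unique read is assigned to an interval when its alignment overlaps
    it by >= 1 bp; a read overlapping several intervals goes to the one
    with the larger overlap (tie: first in BED order).  Shares are over
    the interval-assigned mass.
    """
    if len(clusters) == 0:
        raise ValueError("empty cluster annotation")
    unique_seqs = unique0mm.unique_sequences()
    masses: dict[str, float] = {}
    assigned = 0.0
    unassigned = 0.0
    ambiguous = 0
    for aln in unique0mm.alignments:
        if aln.read_sequence not in unique_seqs:
            continue
        hits = clusters.overlapping(aln.reference, aln.start, aln.end)
        if not hits:
            unassigned += aln.count
            continue
        if len(hits) > 1:
            ambiguous += 1
            hits.sort(key=lambda iv: -iv.overlap(aln.start, aln.end))
        best = hits[0]
        key = best.name if best.name != "." else f"{best.contig}:{best.start}-{best.end}"
        masses[key] = masses.get(key, 0.0) + aln.count
        assigned += aln.count
    if ambiguous:
        logger.info("%d unique reads overlapped more than one interval", ambiguous)
    shares = {k: v / assigned for k, v in masses.items()} if assigned else {}
    return ClusterComposition(shares, assigned, unassigned)


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

@dataclass
class PingPongReport:
    """One transposon's full ping-pong characterisation."""

    reference: str
    z_score: float | None
    significant: bool
    ppp_percent_total: float
    ppp_percent_sense: float
    ppp_percent_antisense: float
    ppp_percent_total_distinct: float
    bias_1U_antisense_ppp: float
    bias_10A_sense_ppp: float
    pair_mass: float
    total_mass: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def signature_report(alignments, include_self: bool = False) -> PingPongReport:
    """Assemble histogram, Z-score, PPP percentages and 1U/10A biases."""
    alns = _as_alignments(alignments)
    ref = _single_reference(alns) or ""
    hist = overlap_histogram(alns)
    z, sig = pingpong_zscore(hist, include_self=include_self)
    ppp = ppp_stats(alns)
    ppp_d = ppp_stats(alns, weighting="distinct")
    has_pairs = hist.pair_mass > 0
    bias_anti = (
        nucleotide_bias(alns, subset="ppp_antisense").bias_1U if has_pairs else float("nan")
    )
    bias_sense = (
        nucleotide_bias(alns, subset="ppp_sense").bias_10A if has_pairs else float("nan")
    )
    return PingPongReport(
        reference=ref,
        z_score=z,
        significant=sig,
        ppp_percent_total=round(ppp.percent_total, 1),
        ppp_percent_sense=round(ppp.percent_sense, 1),
        ppp_percent_antisense=round(ppp.percent_antisense, 1),
        ppp_percent_total_distinct=round(ppp_d.percent_total, 1),
        bias_1U_antisense_ppp=round(bias_anti, 1) if bias_anti == bias_anti else bias_anti,
        bias_10A_sense_ppp=round(bias_sense, 1) if bias_sense == bias_sense else bias_sense,
        pair_mass=hist.pair_mass,
        total_mass=ppp.total_mass,
    )
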