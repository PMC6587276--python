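"""Synthetic small-RNA libraries and insertion-bearing genomic readsets.

Two generators make every pipeline stage testable without downloads:

``simulate_pirna_library``
    A piRNA library over a transposon consensus: an antisense *primary*
    population with a 5'-U bias, a sense *secondary* population created
    by a ping-pong rule (each primary acquires, with probability
    ``f_pp``, a sense partner whose 5' end overlaps its own by exactly
    10 nt and whose tenth base is A with probability ``p10A``), and
    uniform background reads on both strands.  Optionally the consensus
    is embedded in a synthetic genome inside a host piRNA-cluster
    interval, with decoy clusters emitting genome-unique reads at
    configurable shares, so genome mapping, RPM normalisation and
    cluster composition are exercised end to end.

``simulate_insertion_readset``
    A reference genome (optionally carrying a multi-copy diverged repeat
    family inside a cluster interval) plus a donor haplotype with a TE
    inserted at a chosen site flanked by a target-site duplication,
    sampled as Illumina-like paired-end reads with substitution errors.

Every generator draws from a single explicitly seeded NumPy generator and
emits a machine-readable truth record covering each generated read
exactly once, so tests compare against *realized* (not nominal) truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .io import (
    Interval,
    IntervalSet,
    ReadSet,
    ReferenceSet,
    revcomp,
    write_fastq,
    write_intervals,
    write_references,
)
from .mapper import Alignment, MappingResult

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TE_NAME = "TE"


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


def _set_base(seq: str, pos: int, base: str) -> str:
    return seq[:pos] + base + seq[pos + 1 :]


def _draw_biased_base(rng: np.random.Generator, favored: str, p: float) -> str:
    """The favored base with probability p, else uniform over the other three.

    Overwriting the position with a draw from this distribution makes the
    realized base frequency equal p in expectation (merely forcing the
    favored base with probability p would leave a 1/4 chance of it arising
    naturally and inflate the realized bias to p + (1-p)/4).
    """
    if rng.random() < p:
        return favored
    others = [b for b in "ACGT" if b != favored]
    return others[int(rng.integers(0, 3))]


# ---------------------------------------------------------------------------
# piRNA library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryGenomeContext:
    """Layout of the optional synthetic genome around the TE copy.

    The consensus is embedded inside a host cluster interval; decoy
    clusters elsewhere emit genome-unique reads whose mass shares follow
    ``cluster_shares`` (host cluster first), exercising cluster
    composition the way the somatic library concentrates most unique
    piRNA mass in a single cluster.
    """

    genome_length: int = 60_000
    n_decoy_clusters: int = 3
    cluster_length: int = 4_000
    n_cluster_reads: int = 0
    cluster_shares: tuple[float, ...] | None = None


@dataclass(frozen=True)
class LibrarySimConfig:
    """Parameters of the synthetic piRNA library.

    Defaults mirror the biological situation being modelled: an 8.4 kb
    LTR-retrotransposon consensus, a strong (90%) 5'-U bias on antisense
    primaries and a 90% position-10-A bias on ping-pong secondaries, read
    lengths uniform on 23-29 nt, and copy numbers geometric with mean 2.
    """

    seed: int
    te_length: int = 8_400
    n_antisense_primary: int = 2_000
    p1U: float = 0.9
    f_pp: float = 0.0
    p10A: float = 0.9
    n_background_sense: int = 0
    n_background_antisense: int = 0
    length_range: tuple[int, int] = (23, 29)
    count_mean: float = 2.0
    te_sequence: str | None = None
    genome_context: LibraryGenomeContext | None = None

    def validate(self) -> None:
        for name in ("p1U", "f_pp", "p10A"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length_range")
        if self.count_mean < 1.0:
            raise ValueError("count_mean must be >= 1")
        if self.te_length < hi + 40:
            raise ValueError("te_length too short for the read length range")


@dataclass(frozen=True)
class LibraryReadTruth:
    """Origin of one generated read (pre-collapse)."""

    read_id: str
    label: str  # primary | secondary | background_sense | background_antisense | cluster
    sequence: str
    count: int
    te_strand: str | None  # strand relative to the TE consensus, None for cluster reads
    te_five_prime: int | None
    cluster: str | None = None


@dataclass
class LibraryTruth:
    records: list[LibraryReadTruth]

    def n_with_label(self, label: str) -> int:
        return sum(1 for r in self.records if r.label == label)

    def te_records(self) -> list[LibraryReadTruth]:
        return [r for r in self.records if r.te_strand is not None]

    def realized_ppp_percent(self) -> float:
        """Count-weighted PPP percentage recomputed from emitted positions."""
        sense: dict[int, int] = {}
        anti: dict[int, int] = {}
        for r in self.te_records():
            d = sense if r.te_strand == "+" else anti
            d[r.te_five_prime] = d.get(r.te_five_prime, 0) + r.count
        member = sum(m for p, m in sense.items() if (p + 9) in anti)
        member += sum(m for p, m in anti.items() if (p - 9) in sense)
        total = sum(sense.values()) + sum(anti.values())
        return 100.0 * member / total if total else 0.0

    def length_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for r in self.records:
            hist[len(r.sequence)] = hist.get(len(r.sequence), 0) + r.count
        return hist

    def base_tally(self, position: int, label: str | None = None) -> dict[str, int]:
        """Realized count-weighted base tally at a 1-based read position."""
        tally = {b: 0 for b in "ACGT"}
        for r in self.records:
            if label is not None and r.label != label:
                continue
            if len(r.sequence) >= position:
                tally[r.sequence[position - 1]] += r.count
        return tally


@dataclass
class SimulatedLibrary:
    config: LibrarySimConfig
    reads: ReadSet
    te: ReferenceSet
    genome: ReferenceSet | None
    clusters: IntervalSet | None
    truth: LibraryTruth

    def truth_alignments(self) -> MappingResult:
        """MappingResult built from the generator's truth positions.

        Independent of the mapper: alignments are placed where the reads
        were drawn from, with the mismatch count of any forced bases left
        at zero (placement, not distance, is what the statistics read).
        """
        mass: dict[tuple[str, str, int, int], int] = {}
        for r in self.truth.te_records():
            fp = r.te_five_prime
            m = len(r.sequence)
            if r.te_strand == "+":
                start, end = fp, fp + m
            else:
                start, end = fp - m + 1, fp + 1
            key = (r.sequence, r.te_strand, start, end)
            mass[key] = mass.get(key, 0) + r.count
        alns = [
            Alignment(seq, TE_NAME, start, end, strand, 0, n)
            for (seq, strand, start, end), n in mass.items()
        ]
        status = {a.read_sequence: "unique" for a in alns}
        counts = {a.read_sequence: a.count for a in alns}
        return MappingResult(alns, status, 0, counts)

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "reads": os.path.join(outdir, "library.fastq"),
            "te": os.path.join(outdir, "te.fasta"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        records = []
        for r in self.truth.records:
            for j in range(r.count):
                records.append((f"{r.read_id}.{j}", r.sequence))
        write_fastq(records, paths["reads"])
        write_references(self.te, paths["te"])
        if self.genome is not None:
            paths["genome"] = os.path.join(outdir, "genome.fasta")
            write_references(self.genome, paths["genome"])
        if self.clusters is not None:
            paths["clusters"] = os.path.join(outdir, "clusters.bed")
            write_intervals(self.clusters, paths["clusters"])
        with open(paths["truth"], "w") as fh:
            fh.write("read_id\tlabel\tsequence\tcount\tte_strand\tte_five_prime\tcluster\n")
            for r in self.truth.records:
                fh.write(
                    f"{r.read_id}\t{r.label}\t{r.sequence}\t{r.count}\t"
                    f"{r.te_strand or '.'}\t"
                    f"{r.te_five_prime if r.te_five_prime is not None else '.'}\t"
                    f"{r.cluster or '.'}\n"
                )
        return paths


def _draw_count(rng: np.random.Generator, mean: float) -> int:
    return int(rng.geometric(1.0 / mean))


def simulate_pirna_library(cfg: LibrarySimConfig) -> SimulatedLibrary:
    """Generate a piRNA library with a configurable ping-pong structure."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    te_seq = cfg.te_sequence or _random_dna(rng, cfg.te_length)
    L = len(te_seq)
    lo, hi = cfg.length_range
    records: list[LibraryReadTruth] = []
    rid = 0

    def lengths(n: int) -> np.ndarray:
        return rng.integers(lo, hi + 1, size=n)

    # antisense primaries (and their ping-pong secondaries)
    # the antisense 5' coordinate is drawn so that a 10-nt-overlap sense
    # partner of any read length stays within the consensus
    fp_lo, fp_hi = hi - 1, L - (hi - 9) - 1
    for _ in range(cfg.n_antisense_primary):
        m = int(lengths(1)[0])
        fp = int(rng.integers(fp_lo, fp_hi + 1))
        start = fp - m + 1
        seq = revcomp(te_seq[start : fp + 1])
        seq = _set_base(seq, 0, _draw_biased_base(rng, "T", cfg.p1U))
        records.append(
            LibraryReadTruth(f"r{rid}", "primary", seq, _draw_count(rng, cfg.count_mean), "-", fp)
        )
        rid += 1
        if rng.random() < cfg.f_pp:
            m2 = int(lengths(1)[0])
            s_fp = fp - 9
            seq2 = te_seq[s_fp : s_fp + m2]
            seq2 = _set_base(seq2, 9, _draw_biased_base(rng, "A", cfg.p10A))
            records.append(
                LibraryReadTruth(
                    f"r{rid}", "secondary", seq2, _draw_count(rng, cfg.count_mean), "+", s_fp
                )
            )
            rid += 1

    for _ in range(cfg.n_background_sense):
        m = int(lengths(1)[0])
        start = int(rng.integers(0, L - m + 1))
        records.append(
            LibraryReadTruth(
                f"r{rid}", "background_sense", te_seq[start : start + m],
                _draw_count(rng, cfg.count_mean), "+", start,
            )
        )
        rid += 1
    for _ in range(cfg.n_background_antisense):
        m = int(lengths(1)[0])
        start = int(rng.integers(0, L - m + 1))
        records.append(
            LibraryReadTruth(
                f"r{rid}", "background_antisense", revcomp(te_seq[start : start + m]),
                _draw_count(rng, cfg.count_mean), "-", start + m - 1,
            )
        )
        rid += 1

    genome = clusters = None
    gc = cfg.genome_context
    if gc is not None:
        genome_seq = _random_dna(rng, gc.genome_length)
        n_clusters = gc.n_decoy_clusters + 1
        span = gc.genome_length // n_clusters
        if gc.cluster_length + L > span:
            raise ValueError("genome too short for the requested cluster layout")
        intervals = []
        # host cluster: TE embedded at the start of the first cluster interval
        host_start = span // 4
        genome_seq = (
            genome_seq[:host_start] + te_seq + genome_seq[host_start + L :]
        )
        intervals.append(
            Interval("chrSim", host_start, host_start + gc.cluster_length + L, "cluster1", "+")
        )
        for i in range(gc.n_decoy_clusters):
            s = (i + 1) * span + span // 4
            intervals.append(
                Interval("chrSim", s, s + gc.cluster_length, f"cluster{i + 2}", "+")
            )
        clusters = IntervalSet(intervals)
        genome = ReferenceSet({"chrSim": genome_seq})
        if gc.n_cluster_reads:
            shares = gc.cluster_shares or tuple(1.0 / n_clusters for _ in range(n_clusters))
            if len(shares) != n_clusters or abs(sum(shares) - 1.0) > 1e-9:
                raise ValueError("cluster_shares must sum to 1 with one entry per cluster")
            choices = rng.choice(n_clusters, size=gc.n_cluster_reads, p=list(shares))
            for c in choices:
                iv = intervals[int(c)]
                m = int(lengths(1)[0])
                # avoid the embedded TE region so cluster reads stay genome-unique
                lo_s = iv.start + (L if int(c) == 0 else 0)
                start = int(rng.integers(lo_s, iv.end - m + 1))
                seq = genome_seq[start : start + m]
                records.append(
                    LibraryReadTruth(
                        f"r{rid}", "cluster", seq, _draw_count(rng, cfg.count_mean),
                        None, None, iv.name,
                    )
                )
                rid += 1

    reads = ReadSet(provenance=f"simulated(seed={cfg.seed})")
    for r in records:
        reads.add(r.sequence, r.count)
    return SimulatedLibrary(
        config=cfg,
        reads=reads,
        te=ReferenceSet({TE_NAME: te_seq}),
        genome=genome,
        clusters=clusters,
        truth=LibraryTruth(records),
    )


# ---------------------------------------------------------------------------
# insertion readset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatFamily:
    unit_length: int = 1_500
    copy_number: int = 3
    divergence: float = 0.02  # per-base substitution divergence between copies


@dataclass(frozen=True)
class GenomeSimConfig:
    """Parameters of the insertion-bearing paired-end readset.

    The donor haplotype is the reference genome with a TE copy inserted
    at ``insertion_site`` flanked by a duplicated target site of
    ``tsd_length`` bp.  Reads are 2 x ``read_length`` with a Gaussian
    insert-size model and uniform substitution errors.  With a repeat
    family planted, ``insertion_in_repeat_copy`` places the insertion at
    the midpoint of that copy (0-based copy index), creating the
    repeat-ambiguity situation the caller must surface.
    """

    seed: int
    genome_length: int = 30_000
    te_length: int = 3_000
    te_sequence: str | None = None
    terminal_repeat_length: int = 200
    repeat_family: RepeatFamily | None = None
    insertion_site: int | None = None
    insertion_in_repeat_copy: int | None = None
    insert_te: bool = True
    tsd_length: int = 4
    read_length: int = 101
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    coverage: float = 15.0
    error_rate: float = 0.001

    def validate(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.tsd_length < 0:
            raise ValueError("tsd_length must be >= 0")
        if self.read_length < 40:
            raise ValueError("read_length too short for junction detection")


@dataclass
class InsertionTruth:
    insertion_site: int | None  # reference coordinate s: donor = ref[:s+d] + TE + ref[s:]
    tsd: str
    left_junction_donor: int | None  # donor coordinate of the genome|TE boundary
    right_junction_donor: int | None
    junction_read_ids: list[str]  # reads spanning a junction with >=20 nt on each side
    discordant_pair_ids: list[str]
    ambiguity_sites: list[int]  # equivalent reference coordinates across repeat copies
    repeat_copies: list[tuple[int, int]]  # reference intervals of planted repeat copies


@dataclass
class SimulatedInsertionRun:
    config: GenomeSimConfig
    pairs: list[tuple[str, str, str]]
    genome: ReferenceSet
    te: ReferenceSet
    clusters: IntervalSet
    truth: InsertionTruth

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "r1": os.path.join(outdir, "reads_R1.fastq"),
            "r2": os.path.join(outdir, "reads_R2.fastq"),
            "genome": os.path.join(outdir, "genome.fasta"),
            "te": os.path.join(outdir, "te.fasta"),
            "clusters": os.path.join(outdir, "clusters.bed"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        write_fastq([(f"{pid}/1", s1) for pid, s1, _ in self.pairs], paths["r1"])
        write_fastq([(f"{pid}/2", _s2, ) for pid, _, _s2 in self.pairs], paths["r2"])
        write_references(self.genome, paths["genome"])
        write_references(self.te, paths["te"])
        write_intervals(self.clusters, paths["clusters"])
        t = self.truth
        with open(paths["truth"], "w") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"insertion_site\t{t.insertion_site}\n")
            fh.write(f"tsd\t{t.tsd or '.'}\n")
            fh.write(f"junction_reads\t{','.join(t.junction_read_ids) or '.'}\n")
            fh.write(f"discordant_pairs\t{','.join(t.discordant_pair_ids) or '.'}\n")
            fh.write(
                "ambiguity_sites\t"
                + (",".join(str(s) for s in t.ambiguity_sites) or ".")
                + "\n"
            )
        return paths


def simulate_insertion_readset(cfg: GenomeSimConfig) -> SimulatedInsertionRun:
    """Paired-end readset from a donor genome carrying a planted TE insertion."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genome_seq = _random_dna(rng, cfg.genome_length)
    repeat_copies: list[tuple[int, int]] = []
    cluster_intervals: list[Interval] = []
    rf = cfg.repeat_family
    if rf is not None:
        unit = _random_dna(rng, rf.unit_length)
        region_len = rf.copy_number * (rf.unit_length + 500) + 500
        region_start = (cfg.genome_length - region_len) // 2
        if region_start < 2_000:
            raise ValueError("genome too short for the requested repeat family")
        pos = region_start + 500
        for _ in range(rf.copy_number):
            copy_seq = _mutate(rng, unit, rf.divergence)
            genome_seq = genome_seq[:pos] + copy_seq + genome_seq[pos + rf.unit_length :]
            repeat_copies.append((pos, pos + rf.unit_length))
            pos += rf.unit_length + 500
        cluster_intervals.append(
            Interval("chrSim", region_start, region_start + region_len, "cluster9", "+")
        )
    else:
        mid = cfg.genome_length // 2
        cluster_intervals.append(
            Interval("chrSim", max(0, mid - 3_000), mid + 3_000, "cluster9", "+")
        )

    te_seq = cfg.te_sequence or _random_dna(rng, cfg.te_length)
    te_len = len(te_seq)

    site: int | None = None
    ambiguity_sites: list[int] = []
    if cfg.insert_te:
        if cfg.insertion_in_repeat_copy is not None:
            if rf is None:
                raise ValueError("insertion_in_repeat_copy requires a repeat family")
            c0, _ = repeat_copies[cfg.insertion_in_repeat_copy]
            offset = rf.unit_length // 2
            site = c0 + offset
            ambiguity_sites = [start + offset for start, _ in repeat_copies]
        else:
            site = cfg.insertion_site if cfg.insertion_site is not None else cfg.genome_length // 2
            ambiguity_sites = [site]
        if not (cfg.read_length <= site <= cfg.genome_length - cfg.read_length):
            raise ValueError("insertion_site too close to a contig end")
        d = cfg.tsd_length
        donor = genome_seq[: site + d] + te_seq + genome_seq[site:]
        tsd = genome_seq[site : site + d]
        jL = site + d  # donor coordinate where TE begins
        jR = jL + te_len  # donor coordinate where TE ends
    else:
        donor = genome_seq
        tsd = ""
        jL = jR = None

    rl = cfg.read_length
    donor_len = len(donor)
    n_pairs = int(round(cfg.coverage * donor_len / (2 * rl)))
    min_frag = rl + 10

    pairs: list[tuple[str, str, str]] = []
    junction_ids: list[str] = []
    discordant_ids: list[str] = []

    def spans_junction(a: int, b: int) -> bool:
        # read interval [a, b) covers a junction with >= 20 nt on each side
        for j in (jL, jR):
            if j is not None and a <= j - 20 and b >= j + 20:
                return True
        return False

    def fully_in_te(a: int, b: int) -> bool:
        return jL is not None and jL <= a and b <= jR

    def fully_in_genome(a: int, b: int) -> bool:
        if jL is None:
            return True
        return b <= jL or a >= jR

    for i in range(n_pairs):
        frag = max(min_frag, int(round(rng.normal(cfg.insert_mean, cfg.insert_sd))))
        frag = min(frag, donor_len)
        start = int(rng.integers(0, donor_len - frag + 1))
        end = start + frag
        left = donor[start : start + rl]
        right = revcomp(donor[end - rl : end])
        left = _mutate(rng, left, cfg.error_rate)
        right = _mutate(rng, right, cfg.error_rate)
        if rng.random() < 0.5:
            s1, s2 = left, right
            iv1, iv2 = (start, start + rl), (end - rl, end)
        else:
            s1, s2 = right, left
            iv1, iv2 = (end - rl, end), (start, start + rl)
        pid = f"pair{i}"
        pairs.append((pid, s1, s2))
        for mate, (a, b) in (("1", iv1), ("2", iv2)):
            if spans_junction(a, b):
                junction_ids.append(f"{pid}/{mate}")
        if (fully_in_te(*iv1) and fully_in_genome(*iv2)) or (
            fully_in_te(*iv2) and fully_in_genome(*iv1)
        ):
            discordant_ids.append(pid)

    return SimulatedInsertionRun(
        config=cfg,
        pairs=pairs,
        genome=ReferenceSet({"chrSim": genome_seq}),
        te=ReferenceSet({TE_NAME: te_seq}),
        clusters=IntervalSet(cluster_intervals),
        truth=InsertionTruth(
            insertion_site=site,
            tsd=tsd,
            left_junction_donor=jL,
            right_junction_donor=jR,
            junction_read_ids=junction_ids,
            discordant_pair_ids=discordant_ids,
            ambiguity_sites=ambiguity_sites,
            repeat_copies=repeat_copies,
        ),
    )
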