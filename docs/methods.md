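# Methods

This note documents the models, conventions and numerical choices behind
pirnakit, and what the synthetic data used by the test suite does and
does not establish about real libraries.

## Read handling

Small-RNA libraries are collapsed to distinct sequences with copy
numbers; every downstream statistic is weighted by copy number, so a
sequence observed 50 times contributes 50 units of mass. Sequences are
uppercased and U→T normalised at load time so that all mapping and bias
logic runs on a single DNA alphabet (U is reported as T; the 1U bias is
read off the T frequency). Two collapsed-FASTA dialects circulate in
small-RNA work, so headers of the form `id_N` are interpreted as copy
number N only when `counts_in_header` is set; otherwise every record
counts 1. 2S rRNA depletion removes reads that are exact substrings of
the contaminant or its reverse complement — no mismatch tolerance, which
keeps the filter reproducible; reads containing N are retained in
library accounting but never map (an N never matches anything, not even
another N).

## Mapping model

Mapping is full-length, gap-free Hamming-distance search on both
strands. For 23–29 nt piRNAs this is the standard model: with reads this
short, indel alignment would silently change overlap statistics, and
partial-length hits have no meaning for 5′-coordinate statistics. The
search uses pigeonhole seeding — a read is split into k+1 non-overlapping
seeds, any placement with ≤ k mismatches must contain one exact seed, so
an exact-match seed index plus full verification is lossless. The unit
and acceptance suites verify set-equality against an exhaustive
per-offset scan at every k ∈ 0..3.

Two regimes are used: TE-consensus mapping at ≤ 3 mismatches (per-TE
statistics tolerate divergence between genomic copies and the consensus)
and genome mapping at 0 mismatches, which defines per-read status
(unmapped / unique / multi) and the normalisation denominator. For
per-TE statistics a multi-mapping read contributes its full copy number
exactly once, at its best placement; ties break deterministically by
(fewest mismatches, lowest start, then + strand). Counting a read once
per site would double-count mass in density profiles; the alternative is
available by using the full alignment set directly.

The RPM denominator is the 0-mismatch genome-mapped mass of the full
post-depletion 18–30 nt library, computed *before* the 23–29 nt piRNA
selection; the size-selected subset is what is mapped to TEs and
clusters. Both stages are recorded in the run manifest.

## Ping-pong statistics

The 5′-overlap of a (sense, antisense) pair is
`five_prime(antisense) − five_prime(sense) + 1`; ping-pong partners
overlap by exactly 10 nt. The overlap histogram covers lengths 1–28,
each pair weighted by the product of the two copy numbers (a
distinct-sequence variant is available via `weighting="distinct"`, and
the combined report shows both). The Z-score standardises p₁₀ against
the proportions at 1–23 nt using the sample (n−1) standard deviation
over the 22 background values, with the conventional 1.96 cut-off.

Two genuinely open conventions are resolved as follows and exposed as
flags:

* the background B excludes k = 10 by default (`include_self` restores
  inclusion): including the tested value both inflates the background
  mean and its spread and therefore deflates z;
* when sd(B) is numerically zero (≤ 1e-12 on proportions of order 1,
  e.g. a library whose entire pair mass sits at one overlap length) the
  Z-score is reported as undefined and not significant, rather than ±∞.

PPP percentages are count-weighted by default, reported overall and per
strand. The 1U/10A biases are measured on read sequences in sequenced
5′→3′ orientation, on the partnered subsets (antisense PPP for 1U, sense
PPP for 10A), matching how the germline signature is usually displayed.
Percentages are rounded to one decimal in reports; all internal math is
double precision.

## Density profiles and cluster composition

Each read is assigned to exactly one window by its 5′ coordinate (window
`floor(five_prime / window_size)`), so window masses sum exactly to the
profiled read mass — assignment by read span would break that
conservation. The last window may be short. Window sizes are a required
parameter with named presets (flamenco 428, ZAM 91, Burdock 80, Pifo 87,
Phidippo 85 nt); for unnamed references the fallback targets ~93 windows
across the element, the density the presets correspond to.

Cluster composition uses genome-unique 0-mismatch mappers only. A read
overlapping two annotation intervals is assigned to the larger overlap
(tie: first interval in BED order, logged); shares are reported over the
cluster-assigned mass, with an optional explicit unassigned bucket.

## Insertion detection

The scan implements the chimeric-read strategy that complements
concordant-mapping TE callers, which miss insertions in repetitive
regions: candidate mates are those *not uniquely mappable* full-length
at 0 mismatches (a flag restricts to fully unmapped reads instead —
the default keeps repeat-derived multi-mappers, which is the point of
the method). A candidate qualifies as a junction read when a prefix or
suffix of ≥ 20 nt matches a TE terminus (first/last 200 nt of the
consensus, i.e. covering LTR ends, in either orientation) with ≤ 1
substitution, and the remaining ≥ 20 nt flank maps to the genome with
≤ 1 substitution. The longest qualifying TE segment defines the
breakpoint offset. All flank placements are kept: in a multi-copy
repeat, the alternative placements are real ambiguity, not noise.
The minimum match lengths, mismatch tolerances and clustering distance
are not dictated by the underlying method and are exposed parameters
with the stated defaults.

Discordant pairs require one mate placed on the TE consensus (≤ 3
mismatches) and the other uniquely on the genome; the genome mate's
interval extended by mean + 3·sd of the insert-size prior (default
350 ± 50 bp) gives the window expected to contain the insertion.

Calling single-linkage clusters junction-implied breakpoints within
500 bp per contig. Per cluster, the modal position of each junction side
is taken (mode is robust to the occasional mis-decomposed read; ties go
to the smaller coordinate). When both sides are present, the two
positions bound the breakpoint interval and an overlap of 1–20 bp is
reported as the TSD, read directly off the reference. Candidates whose
flanks multi-map are grouped into ambiguity groups by connected
components over shared junction reads; because alternative placements of
the same reads are evidentially indistinguishable, candidates in a group
carry the identical union of junction evidence and support, and the
`min_support` threshold (default 2) applies to that shared evidence.
Reports use 0-based half-open coordinates with 1-based inclusive columns
alongside. No de-novo assembly of breakpoints is attempted.

## Synthetic data

The library simulator draws antisense primary piRNAs uniformly along a
TE consensus (default 8,400 nt, the length of a full-length LTR
retroelement with its two LTRs), read lengths uniform on 23–29 nt and
copy numbers geometric with mean 2 — a crude but adequate stand-in for
the skewed abundance of real libraries. The 5′ base of a primary is
drawn to be T with probability `p1U` (default 0.9) and uniform over the
other bases otherwise, so the realized 1U frequency equals `p1U` in
expectation. Each primary independently receives, with probability
`f_pp`, a sense secondary whose 5′ end overlaps the primary's by exactly
10 nt and whose tenth base is A with probability `p10A`. Background
reads on either strand have uniform 5′ positions and unconstrained
composition, and may create chance 10-nt overlaps — truth records
therefore store *realized* pairing, recomputed from emitted positions,
and tests compare against that rather than the nominal `f_pp`.
Optionally the consensus is embedded in a synthetic genome inside a host
cluster interval with decoy clusters emitting genome-unique reads at
configurable shares, which exercises genome mapping, RPM normalisation
and cluster composition end to end.

The genome simulator plants a TE (default 3,000 nt at desk scale) into a
random reference (default 30,000 nt) with a duplicated target site
(default 4 bp), optionally inside one copy of a diverged repeat family
(default 3 × 1,500 nt at 2% divergence) hosted in a cluster interval,
and samples 2 × 101 bp pairs with a Gaussian insert model (350 ± 50 bp)
and uniform substitution errors (0.001/base). Truth lists the insertion
coordinate, TSD string, every junction-spanning read (≥ 20 nt on each
side), every TE/genome discordant pair, and the equivalent coordinates
in all repeat copies (the expected ambiguity group). Emitted FASTQ
carries constant 'I' qualities — the pipeline ignores base qualities.

Every generator uses one explicitly seeded NumPy generator and no global
state; identical configurations and seeds give byte-identical output
files.

**What the simulations do not model:** sequencing-error structure beyond
uniform substitutions, PCR duplicates, adapter read-through,
transcription-level precursor biology, nucleotide composition bias of
real genomes, and TE families with many diverged genomic copies
cross-mapping to one consensus. Passing tests therefore demonstrate
correctness of the statistics and detection logic under the stated
generative model, not end-to-end accuracy on any particular real
library.

## Problem sizes in the test suite

The acceptance-level properties run at desk scale on one CPU: mapper
exactness on 50 random fixtures (references up to 10 kb, up to 500
reads, every k ∈ 0..3); Z-score null calibration on 100 replicates of
~2,000-read background-only libraries (≤ 10% may reach significance);
power and recovery on 100 replicates of ~5,000-read libraries at
`f_pp = 0.4` (significance in ≥ 95%, PPP within 2 points of realized
truth, 1U within 3 points of 90%) — these power libraries contain only
primary and secondary populations, since the 1U recovery bound refers to
the biased primary population and background antisense reads carry no 5′
bias by construction; insertion recovery on 50 replicates at 15×
coverage with a 4-bp TSD (breakpoint within ±5 bp and exact TSD in
≥ 95%), one 3-copy-repeat scenario at 25× (a complete ambiguity group of
3), and 20 TE-free replicates (at most one spurious call in total).

## Known limitations

* The mapper is exact but desk-scale: a k-mer dictionary per (reference,
  seed length) is held in memory, suitable for TE consensus sequences
  and megabase-scale simulated genomes, not whole large genomes.
* Junction decomposition is gap-free; an indel near a breakpoint shifts
  the implied position by the indel length.
* TSD detection requires junction evidence on both sides; one-sided
  candidates report a 1 bp nominal interval and no TSD.
* Insert-size estimation from concordant pairs is not implemented; the
  prior is a parameter.
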