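# Methods

This note records the model assumptions, parameter choices and
numerical conventions behind the package, and what its synthetic
benchmarks do and do not demonstrate.

## Simulator

The simulator produces the data regime the pipeline assumes, with
ground truth recorded per read (0-based half-open coordinates on the
genome's forward strand; reverse-complement reads keep forward-strand
origins with strand `-`). All randomness flows from one explicit
integer seed per call (numpy `default_rng`); there is no global state.

* **Genome.** Uniform random A/C/G/T of the requested length. Repeat
  families are planted as non-overlapping copies of a master unit, each
  copy independently substituted at `divergence/2` per base so that two
  copies differ by ≈ `divergence`. Placement is rejection-sampled;
  a repeat span exceeding the genome is rejected up front.
* **Short reads.** Paired, inward-facing from opposite ends of
  fragments drawn uniformly from the configured range; the pair count
  is chosen so emitted bases match `coverage × G` within rounding.
  Default error model: 1% substitutions, no indels.
* **Long reads.** Lengths are log-normal, parameterised by mean and
  spread (moment matching); the distribution's tail shape beyond its
  mean and spread is a modelling choice, not a claim of fidelity. An
  optional `min_length` emulates a size-selection floor by resampling.
  Default error model: ~15% total, insertion-dominated (1% mismatch,
  10% insertion, 4% deletion). Because insertions lengthen and
  deletions shorten the emitted sequence, the read-length budget is
  scaled by `1 + ins − del` so *emitted* bases match `coverage × G`
  within 1%. A `chimera_rate` fraction of reads are head-to-tail
  fusions of two uniform loci at a uniform breakpoint, second-segment
  strand random, both origins recorded.

What the simulator does **not** model: base-quality realism, GC or
positional coverage bias, polymerase kinetics, haploid/diploid
structure. Passing benchmarks therefore demonstrates algorithmic
correctness under idealised noise, not performance on real libraries.

## Super-reads

Construction is a deliberately compact form of the super-read
principle: canonical k-mer spectrum (k = 25 by default; small genomes
saturate 25-mers well), unique bidirectional extension, containment
deduplication. Two relative-abundance rules make it robust at
realistic depth:

* a **continuation** whose count is below 0.2× the dominant
  continuation's count is discarded before the uniqueness test — an
  error k-mer that recurs above `min_count` (default 2) sits near the
  spectrum floor, while a genuine repeat junction has branches of
  comparable depth;
* a read is **flagged** (excluded from seeding, still reported) when
  any of its k-mers sits below 0.2× the read's median k-mer depth, or
  is absent outright — otherwise a read whose terminal error produced
  a single recurring error k-mer would embed that error into an
  otherwise maximal unitig and defeat deduplication.

Extension stops at junctions, dead ends, or a length cap (2 Mb,
effectively unbounded at desk scale). Deduplication keeps the
lexicographically smaller of two identical sequences; output ids are
assigned after sorting by descending length then sequence, so they are
stable across runs. Conservation: the constituent counts of the
output sum to the number of reads that passed screening.

## Mega-reads

The matching word size is fixed at 15 throughout. Placement uses
exact canonical 15-mer hits chained per (super-read, strand) with a
diagonal-drift budget of `0.2 × distance + 4` bases — 15% indel error
drifts the diagonal by about 0.15 per base, so 0.2 leaves margin.
`min_hits` defaults to 3; at 15% error an exact 15-mer survives at
~8.7% of positions, so even a 100-bp placed region expects ~9 hits.
The chaining DP is quadratic, so dense hit sets (near-exact reads) are
uniformly subsampled to 500 hits (first and last retained) and the
chain weight rescaled; a dense collinear run loses no locus this way.

Two conventions matter and are this package's own choices:

* **Full-extent placements.** A chain's footprint is extended from
  the matched core to the super-read's full extent (clamped to the
  read). Exact-word chains stop stochastically ~10 bp short of the
  true boundary on noisy reads; without the extension, every
  (k−1)-base abutment between adjacent super-reads would register as
  a tiling gap and fragment the mega-reads. Extension bases are still
  super-read bases and every splice is verified, so provenance is
  unaffected.
* **Jitter-tolerant overlap verification with alignment-derived
  splices.** Two overlapping placements map read positions through
  different chains, so their coordinates disagree by the read's indel
  jitter. The implied super-read overlap is verified by aligning the
  shorter segment as an infix of the other's padded window
  (`pad = 10 + overlap/10`); overlaps of ≤ 15 bp must match exactly
  (substring of the padded window). Identity below
  `min_overlap_agreement` (default 0.95 — loose enough to accept
  overlaps within a 2%-diverged repeat family, tight enough to reject
  unrelated loci) breaks the tiling. On success, the alignment's
  location fixes the coordinate correspondence, and the splice cut is
  placed at the overlap midpoint through that correspondence, making
  splices coordinate-exact on clean overlaps.

Inconsistent placements are removed by a maximum-weight chain
selection (weight = chained hit count): a subset is consistent when
every consecutive pair makes strict forward progress on the read and
passes the overlap verification; ties prefer the lexicographically
smallest placement tuple. For ten or fewer placements this provably
matches exhaustive search (property-tested). Because weight measures
hits rather than coverage, the winning chain can leave a stretch
uncovered when the only spanning placement conflicts with a heavier,
coverage-redundant one (typical inside diverged repeats); a **gap
rescue** pass therefore re-inserts the best discarded placement that
bridges a gap and agrees with both flanks. Remaining gaps close the
current mega-read, emit a synthetic mate pair with the read-gap
length as its gap estimate, and open the next; mega-reads of one read
never overlap on it.

Chimeric long reads are not specially detected here: the defence is
downstream, in the scaffolder's minimum-support rule.

## Contigs

Greedy overlap-layout rather than a string graph: inputs are few and
accurate (mega-reads > 99% identity, super-reads near-exact), so
`min_overlap = 200` and `max_error = 0.02` with deterministic
tie-breaking (identity, length, id) suffice and are easy to test.
Overlap discovery anchors on shared 15-mers (sampled every 4 bases
when `min_overlap ≥ 60`), takes the top candidate diagonals, and
verifies with prefix edit-distance alignment; near-full coverage of
the shorter sequence is classified as containment instead (fuzz 25 bp,
suppressed for sequences shorter than 100 bp where it is meaningless).
Contained sequences are absorbed into their containers (mutual
containment of identical sequences keeps the smaller id as
container). Transitive reduction marks edges implied by a two-step
path in a single pass — marked edges still serve as witnesses, so
reduction is order-independent — and each absorbed edge credits the
support of the surviving pair. Any end still claimed by two or more
candidates is an ambiguous junction and all its joins are refused;
circular components are broken at their lowest-identity overlap.
Super-reads absorbed by a mega-read tiling do not enter contiging
(avoiding double counting); unplaced ones at least `min_overlap` long
do.

## Scaffolds

Mates are anchored by the same 15-mer chaining (minimum anchored span
50 bp; a mate whose second-best locus scores ≥ 0.8 of the best is
ambiguous and dropped). Synthetic pairs are located through the
contig layout records of their mega-reads. Inter-contig hits are
bucketed by (contig pair, junction ends); a bucket's gap estimate is
the median over hits (fragment mean minus end distances for genomic
pairs, the pair's own gap for synthetic ones). Links need
`min_support ≥ 2` (the chimera rule: one fused long read cannot force
a join) and a gap median-absolute-deviation within 2 kb; links are
taken by support, then consistency, each contig end used at most
once, cycles refused. Gap runs are `max(gap_floor, median gap)` with
`gap_floor = 10`; a negative median (implied overlap) is floored to
`gap_floor` as well — contigs are never merged at scaffolding time,
so each contig appears in exactly one scaffold exactly once. Output
includes an AGP v2.1 layout (component type W, scaffold gaps,
paired-ends evidence).

The minimum-support rule is applied to all joins by default; passing
`min_support=1` reproduces the narrower reading in which only
unconfirmed synthetic pairs are excluded — the package treats the
stricter form as the default because the chimera-resistance property
is the rule's point.

## Metrics

N50 uses exact integer comparison ("≥ half of total", no floating
point); threshold counts are strict (`>`). Fold coverages are
displayed with one decimal below 10× and nearest integer at or above
10× (raw quotients remain available with `raw=True`). Mean read
length is the nearest-integer quotient. Clone coverage is
`n_pairs × F / G`, exceeding sequence coverage by `F / 2R`;
`F < 2R` is rejected. For scaffold sets, `span_with_gaps −
total_length` equals the total N-gap length by construction.

## Evaluation

Features (nucleotide sequences sampled from the synthetic genome by
the simulator) are aligned to each target by 15-mer chaining; several
chains per target are allowed so a feature spanning a scaffold gap
still accrues to that one scaffold. Covered fraction is the union of
chained feature intervals minus N bases of the matched target spans
(N runs never seed and never count as aligned); identity is the
length-weighted edit-distance identity of the chained segments. The
best single target is chosen by covered bases, then identity, then
smaller id, and the 90% single-target containment flags derive from
it. Because every contig appears verbatim inside its scaffold,
scaffold-level containment can never fall below contig-level
(property-tested).

## Benchmark and problem sizes

The documented operating point — 200-kb genome, one 2-kb repeat
family with 5 copies at 2% divergence, 30× short reads at 1% error,
12× long reads at ~15% insertion-dominated error — is the package's
standard benchmark (`megareads.benchmark`); one replicate runs in
about half a minute on one CPU, and the test suite and acceptance
script use three replicate seeds. Error-free end-to-end recovery is
exercised on a repeat-free 50-kb genome. These sizes keep every claim
measurable at desk scale; they are not claims about behaviour at
gigabase scale, where memory layout, coverage bias and repeat content
dominate engineering effort.

## Known limitations

* Super-read construction is the extension/dedup principle only; no
  quality-aware error correction, so reads with residual errors are
  flagged rather than corrected.
* Wrong-copy splices inside a repeat family whose divergence is below
  `1 − min_overlap_agreement` are accepted by design; they cost a few
  tenths of a percent of mega-read identity on the benchmark.
* The contiger's greedy layout refuses ambiguous junctions rather
  than resolving them, so assemblies of repeat-dense genomes stay
  fragmented at repeat boundaries.
* Pipeline resumption is at whole-run granularity (a run directory is
  reused only when every configuration parameter matches its
  manifest), not per stage.
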