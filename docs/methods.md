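# Methods

## Model

`seedvote` maps a read by counting, per candidate *block* (a reference
interval of the read's length), how many of the read's fixed-length seeds
occur at indexed positions inside that block, at the right relative offset. A
seed at read offset *o* hitting genome coordinate *c* votes for the block
starting at *c* − *o*; an exact alignment therefore concentrates one vote per
in-phase indexed window on a single block start, while scattered spurious hits
spread across many blocks. The method assumes substitution-dominated reads of
at least ~100 bp: substitutions only silence the seeds overlapping them,
whereas an indel inside a read splits its votes between two block starts —
those reads survive via the vote margin being spent (low mapq) and the
Smith–Waterman rescue recovering the gapped alignment.

### Index

Each sequence is scanned left to right; windows of length `seed_length` start
at local offsets 0, w, 2w, … (the stride restarts at every sequence, so
windows never span sequence boundaries). A window is 2-bit encoded
(A=0, C=1, G=2, T=3, first base most significant) into its base-4 value and
reduced modulo the prime `M`. Windows containing any non-ACGT character are
dropped; soft-masked lowercase is uppercased. Only the forward strand is
indexed; at query time the read and its reverse complement are looked up
separately and compete in one candidate pool, which halves index memory and
treats strands symmetrically.

Because `M` < 4^`seed_length`, distinct windows can share a key. The table
stores all their coordinates in one vector (ascending genome order); during
voting, `verify_hits` (default on) compares the reference text at each
coordinate with the seed text, so collisions cost a lookup but never a wrong
vote. The table stores only non-NULL keys (a dict of numpy coordinate
vectors); the serialized index is a compressed numpy archive carrying a magic
string, format version, parameters, sequence names/lengths, the packed
reference, and the table in CSR layout. Embedding the packed reference makes
the align step self-contained and is what hit verification and rescue read
from. Serialization is byte-deterministic for identical inputs.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `seed_length` | 31 (16–32) | window/seed length, bases |
| `stride` | 8 | spacing of indexed windows, bases |
| `modulus` | 4 294 967 291 | prime hash modulus (largest prime < 2³²) |
| `min_votes` | 2 | minimum winning-block votes, else unmapped |
| `max_occurrence` | 450 | seeds hitting more coordinates are dropped |
| `mapq scale / cap` | 6 / 60 | mapq = min((optimal − suboptimal)·scale, cap) |
| rescue `pad` | 36 | block extension each side before Smith–Waterman, bases |
| rescue trigger | > 2 mismatches | ungapped placements up to 2 mismatches stand |
| `merge_window` | 0 | optional tally smoothing radius (off: rescue handles indel shifts) |

The automatic seed-length rule picks the largest s ∈ [16, 32] with
(read_length − s + 1) divisible by the stride. This makes the number of
in-phase seeds — hence the maximum vote count — identical at every alignment
phase, so a perfect-match block can never be outvoted by a mismatched block
that happens to sit at a luckier phase (with 150 bp reads and s = 32, a
2-mismatch block at phase 1 collects 15 votes while a perfect block at phase
8 collects 14; s = 31 gives 15 everywhere). The rule yields 31 for 150 bp and
30 for 125 bp reads. Reads below 36 bp are rejected outright; reads shorter
than the seed length are reported unmapped rather than erroring.

### Selection, quality, rescue

The winning block is the unique argmax of the merged two-strand pool; ties
are broken uniformly at random from the run-level seeded generator and carry
mapq 0. `suboptimal` is 0 when only one block received votes, giving isolated
unique hits the full cap. The rescue stage never changes the vote-based mapq;
it only refines position and CIGAR. Smith–Waterman uses affine gaps
(match +1, mismatch −3, gap open −5, gap extend −2; a k-gap costs
open + k·extend) — conventional short-read scoring, configurable. Traceback
tie-breaks are fixed (diagonal > up > left; gap opening preferred over
extension; first-best cell in row-major order) so alignments are
deterministic. A rescue with no positive-scoring alignment reports the read
unmapped. If the rescue relocates the read inside the padded window, the
reported SAM position is the alignment's reference start.

Paired-end mapping is deliberately minimal: mates are mapped independently;
when either mate's best blocks are tied, combinations placing the mates on
opposite strands of one sequence within `insert_max` (default 1000 bp) are
preferred — closest first — before the random tie-break, and tied selections
keep mapq 0. There is no mate-rescue alignment.

## Synthetic data

`generate_reference` draws i.i.d. uniform A/C/G/T sequences, optionally
copying a segment to a second locus (to manufacture exactly duplicated,
mapq-0 regions) and planting N runs. `simulate_reads` emulates the wgsim error
model: fragments uniform over the genome, strand uniform; a haplotype is
mutated at 0.1% per base (85% substitutions, 15% indels with geometric
lengths of mean 2 capped at 10), then sequencing errors are added at 0.4% per
base; paired mode draws FR fragments with insert ~ Normal(500, 50) clipped
below at the read length. Truth (origin sequence, leftmost forward-strand
coordinate, strand, event counts) is written to a TSV and encoded
wgsim-style in read names.

What the simulator does **not** emulate: real base-quality profiles and
position-dependent error rates, GC bias and coverage waves, repeat structure
and low-complexity tracts of real genomes, adapter or chimeric artifacts.
Passing tests on this generator therefore demonstrate the correctness of the
mechanics (indexing, voting arithmetic, rescue, evaluation), and accuracy on
uniform-random genomes — where nearly every 150-mer is unique; they do not
predict accuracy on repeat-rich real genomes, where the confident-mapping
fraction would be lower and the 450-occurrence filter actually binds.

## Evaluation

A read is scored correct when mapped to its origin sequence within 30 bp of
the true leftmost coordinate (SAM leftmost position; for reverse-strand reads
the truth is likewise the leftmost forward-strand coordinate). "Confident at
threshold t" means mapped with mapq ≥ t (a `strict` flag switches to >). The
evaluator sweeps t = 1…60 and reports confident, error-among-confident, and
unmapped fractions. The expected trade-off — error non-increasing, confident
non-increasing in t — is checked by `check_threshold_trend`; the CLI warns
rather than fails on violations because tiny read sets can fluctuate.

## Numerical and design choices

* Keys are computed with vectorized Horner evaluation in uint64 (intermediate
  values stay below 2³⁴ < 2⁶⁴), so no big-integer arithmetic is needed at
  scale; the scalar `EncodedKmer` path uses Python integers and is the
  reference implementation the vectorized path is tested against.
* Base encoding A=0, C=1, G=2, T=3 is alphabetical convention; any fixed
  bijection would do.
* Votes are tallied per exact block start, no smoothing (`merge_window` 0):
  indel-shifted vote clusters are the rescue stage's job. The knob exists for
  experimentation.
* Degenerate inputs: empty tally → unmapped; all-N reads produce no seeds;
  blocks whose interval would cross a sequence boundary are discarded during
  voting; rescue windows are clipped at sequence bounds and overhanging read
  ends are soft-clipped.
* Problem sizes in the test and acceptance suites — 1 Mb references, 10 000
  reads, 500 oracle pairs — are chosen so the whole suite runs in a couple of
  minutes on one core while keeping Monte-Carlo fractions (error rates at
  0.1–0.5% scales) statistically meaningful.

## Known limitations

* Very short reads (< 36 bp) are unsupported by design; reads between 36 bp
  and the seed length are unmapped.
* One best location is reported; tied locations are not enumerated.
* No BAM/CRAM output (convert with samtools), no multithreading, no
  minimizer/spaced-seed schemes, no bisulfite or colorspace modes.
* The paired-end concordance tie-break is a pragmatic heuristic, not a
  probabilistic fragment model; template-length statistics are not estimated
  from data.
* Mapping quality is a hard function of the vote margin; it is well
  calibrated for ranking but, unlike probabilistic mapqs, is not an error
  probability.
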