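"""Synthetic references and wgsim-style reads with encoded ground truth.

The simulator emulates the classic wgsim error model: fragments are drawn
uniformly from the reference (strand uniform), a mutated haplotype is created
at a 0.1% mutation rate split into 0.085% substitutions and 0.015% short
indels (geometric lengths, mean 2, capped at 10), and sequencing errors are
then added independently at 0.4% per base.  Truth — origin sequence, 0-based
leftmost coordinate on the forward strand, strand, and planted-event counts —
is carried both in the read name (wgsim-style ``seq_start_end_serial``) and in
a sidecar TSV so downstream evaluation is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .index import ReferenceSet, decode_codes, encode_sequence
from .mapper import ReadRecord, reverse_complement

DEFAULT_BASE_ERROR_RATE = 0.004
DEFAULT_MUTATION_RATE = 0.001
DEFAULT_SNP_FRACTION = 0.85  # SNP rate 0.00085, indel rate 0.00015

_BASES = "ACGT"


@dataclass(frozen=True)
class SimParams:
    """Read-simulation parameters (defaults are the standard study conditions)."""

    base_error_rate: float = DEFAULT_BASE_ERROR_RATE
    mutation_rate: float = DEFAULT_MUTATION_RATE
    snp_fraction: float = DEFAULT_SNP_FRACTION
    read_length: int = 150
    paired: bool = False
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    indel_mean: float = 2.0
    indel_cap: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_error_rate", "mutation_rate", "snp_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")

    @property
    def snp_rate(self) -> float:
        return self.mutation_rate * self.snp_fraction

    @property
    def indel_rate(self) -> float:
        return self.mutation_rate * (1.0 - self.snp_fraction)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read."""

    name: str
    mate: int  # 0 single-end, 1/2 paired
    sequence: str
    start: int  # 0-based leftmost forward-strand coordinate of the read origin
    end: int  # 0-based inclusive rightmost coordinate
    strand: str
    n_snps: int = 0
    n_indels: int = 0
    n_errors: int = 0


def generate_reference(
    length: int,
    n_sequences: int = 1,
    repeat_spec: Optional[Tuple[int, int, int]] = None,
    n_runs: Sequence[Tuple[int, int]] = (),
    seed: int = 0,
    name_prefix: str = "chr",
) -> ReferenceSet:
    """Uniform-random reference of ``n_sequences`` sequences of ``length`` bp each.

    ``repeat_spec = (src_start, seg_length, dest_start)`` copies a segment of
    the first sequence onto another locus of the first sequence, creating an
    exact duplication (manufactures mapq-0 ties).  ``n_runs`` is a list of
    (start, run_length) N runs planted in the first sequence.
    """
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    rng = np.random.default_rng(seed)
    seqs: List[Tuple[str, str]] = []
    for i in range(n_sequences):
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        if i == 0:
            if repeat_spec is not None:
                src, seg_len, dst = repeat_spec
                codes[dst : dst + seg_len] = codes[src : src + seg_len]
            for start, run in n_runs:
                codes[start : start + run] = 4
        seqs.append((f"{name_prefix}{i + 1}", decode_codes(codes)))
    return ReferenceSet(seqs)


def _mutate_fragment(
    frag: np.ndarray, rng: np.random.Generator, params: SimParams
) -> Tuple[np.ndarray, np.ndarray, int, int]:
    """Apply SNP/indel mutations to a coded fragment.

    Returns (haplotype codes, per-base forward-strand reference coordinate
    offsets relative to the fragment start, #SNPs, #indels).  Inserted bases
    inherit the coordinate of the preceding reference base.
    """
    hap: List[int] = []
    coord: List[int] = []
    n_snp = n_indel = 0
    snp_rate, indel_rate = params.snp_rate, params.indel_rate
    i, L = 0, len(frag)
    while i < L:
        r = rng.random()
        if r < snp_rate and frag[i] < 4:
            hap.append((int(frag[i]) + 1 + int(rng.integers(3))) % 4)
            coord.append(i)
            n_snp += 1
            i += 1
        elif r < snp_rate + indel_rate:
            k = min(int(rng.geometric(1.0 / params.indel_mean)), params.indel_cap)
            n_indel += 1
            if rng.random() < 0.5:  # insertion after the current base
                hap.append(int(frag[i]))
                coord.append(i)
                for _ in range(k):
                    hap.append(int(rng.integers(4)))
                    coord.append(i)
                i += 1
            else:  # deletion of k bases
                i += k
        else:
            hap.append(int(frag[i]))
            coord.append(i)
            i += 1
    return (
        np.asarray(hap, dtype=np.uint8),
        np.asarray(coord, dtype=np.int64),
        n_snp,
        n_indel,
    )


def _sequencing_errors(
    codes: np.ndarray, rng: np.random.Generator, rate: float
) -> Tuple[np.ndarray, int]:
    if rate <= 0:
        return codes, 0
    hits = np.nonzero(rng.random(codes.size) < rate)[0]
    out = codes.copy()
    for i in hits:
        if out[i] < 4:
            out[i] = (int(out[i]) + 1 + int(rng.integers(3))) % 4
    return out, len(hits)


def simulate_reads(
    ref: ReferenceSet,
    n_reads: int,
    params: SimParams,
) -> Tuple[List[ReadRecord], List[TruthRecord]]:
    """Draw ``n_reads`` single-end reads or ``n_reads`` pairs with known truth.

    Fragment start positions are uniform over each sequence (weighted by
    length); fragments overlapping an N run are redrawn.  In paired mode the
    mates are FR-oriented with insert length ~ Normal(insert_mean, insert_sd)
    clipped to at least the read length.
    """
    rng = np.random.default_rng(params.seed)
    rl = params.read_length
    reads: List[ReadRecord] = []
    truth: List[TruthRecord] = []
    weights = ref.lengths / ref.lengths.sum()
    margin = 2 * params.indel_cap  # slack so deletions cannot shorten below need
    for serial in range(n_reads):
        for _attempt in range(100):
            if params.paired:
                insert = int(round(rng.normal(params.insert_mean, params.insert_sd)))
                insert = max(insert, rl)
            else:
                insert = rl
            seq_idx = int(rng.choice(len(ref), p=weights))
            seq_len = int(ref.lengths[seq_idx])
            if seq_len < insert + margin:
                continue
            start = int(rng.integers(seq_len - insert - margin + 1))
            gstart = int(ref.offsets[seq_idx]) + start
            frag = ref.fetch_codes(gstart, insert + margin)
            if (frag >= 4).any():
                continue
            hap, coord, n_snp, n_indel = _mutate_fragment(frag, rng, params)
            if len(hap) < insert:
                continue
            hap, coord = hap[:insert], coord[:insert]
            strand = "+" if rng.random() < 0.5 else "-"
            frag_start = start + int(coord[0])
            frag_end = start + int(coord[-1])
            name = f"{ref.names[seq_idx]}_{frag_start + 1}_{frag_end + 1}_{serial}"

            def make_read(piece: np.ndarray, piece_coord: np.ndarray, rc: bool, mate: int):
                with_err, n_err = _sequencing_errors(piece, rng, params.base_error_rate)
                bases = decode_codes(with_err)
                if rc:
                    bases = reverse_complement(bases)
                reads.append(
                    ReadRecord(name, bases, qualities="I" * len(bases), mate_index=mate)
                )
                truth.append(
                    TruthRecord(
                        name=name,
                        mate=mate,
                        sequence=ref.names[seq_idx],
                        start=start + int(piece_coord[0]),
                        end=start + int(piece_coord[-1]),
                        strand="-" if rc else "+",
                        n_snps=n_snp,
                        n_indels=n_indel,
                        n_errors=n_err,
                    )
                )

            if params.paired:
                left, left_c = hap[:rl], coord[:rl]
                right, right_c = hap[insert - rl :], coord[insert - rl :]
                if strand == "+":
                    make_read(left, left_c, rc=False, mate=1)
                    make_read(right, right_c, rc=True, mate=2)
                else:
                    make_read(right, right_c, rc=True, mate=1)
                    make_read(left, left_c, rc=False, mate=2)
            else:
                if strand == "+":
                    make_read(hap[:rl], coord[:rl], rc=False, mate=0)
                else:
                    make_read(hap[insert - rl :], coord[insert - rl :], rc=True, mate=0)
            break
        else:
            raise RuntimeError(
                "could not draw a fragment; reference too short or too many N runs"
            )
    return reads, truth


def write_truth(truth: Iterable[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("name\tmate\tseq\tstart\tend\tstrand\tsnps\tindels\terrors\n")
        for t in truth:
            fh.write(
                f"{t.name}\t{t.mate}\t{t.sequence}\t{t.start}\t{t.end}\t{t.strand}"
                f"\t{t.n_snps}\t{t.n_indels}\t{t.n_errors}\n"
            )


def read_truth(path: str) -> Dict[Tuple[str, int], TruthRecord]:
    out: Dict[Tuple[str, int], TruthRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            rec = TruthRecord(
                name=f["name"],
                mate=int(f["mate"]),
                sequence=f["seq"],
                start=int(f["start"]),
                end=int(f["end"]),
                strand=f["strand"],
                n_snps=int(f.get("snps", 0)),
                n_indels=int(f.get("indels", 0)),
                n_errors=int(f.get("errors", 0)),
            )
            out[(rec.name, rec.mate)] = rec
    return out
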