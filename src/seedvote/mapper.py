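"""Per-read orchestration: strand handling, pairing, SAM emission.

Each read is queried in both orientations against the forward-strand index;
the two vote tallies form one candidate pool keyed by (strand, block start).
The winning block goes through the mismatch-count / Smith-Waterman rescue
stage and the result is emitted as a SAM record carrying the vote counts in
auxiliary tags (ZO = optimal, ZS = suboptimal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .index import HashIndex, ReferenceSet, encode_sequence
from .rescue import LocalAlignment, ScoringScheme, cigar_to_ops, rescue
from .voting import BlockSelection, VoteParams, mapping_quality, seed_keys_for_read, select_block

logger = logging.getLogger(__name__)

DEFAULT_INSERT_MAX = 1000

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return np.where(codes < 4, 3 - codes, 4).astype(np.uint8)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One FASTQ read; ``mate_index`` is 1 or 2 for paired input, 0 otherwise."""

    name: str
    bases: str
    qualities: Optional[str] = None
    mate_index: int = 0

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError(f"quality/base length mismatch for read {self.name!r}")


@dataclass
class AlignmentResult:
    """Mapping outcome for a single read (one SAM record)."""

    read_name: str
    mapped: bool
    ref_name: Optional[str] = None
    position: int = 0  # 1-based leftmost, 0 when unmapped
    strand: str = "+"
    mapq: int = 0
    cigar: str = "*"
    edit_distance: int = 0
    optimal: int = 0
    suboptimal: int = 0
    tied: bool = False
    reason: Optional[str] = None
    alignment: Optional[LocalAlignment] = None


def _strand_tally(
    codes: np.ndarray,
    index: HashIndex,
    params: VoteParams,
    read_length: int,
) -> Dict[int, int]:
    """Vectorized-key vote tally for one oriented read (global block starts)."""
    ref = index.reference
    sl = index.params.seed_length
    offsets, keys = seed_keys_for_read(codes, sl, index.params.modulus)
    table = index.table
    single_seq = len(ref) == 1
    total = ref.total_length
    tally: Dict[int, int] = {}
    for o, k in zip(offsets.tolist(), keys.tolist()):
        vec = table.get(k)
        if vec is None or len(vec) > params.max_occurrence:
            continue
        seed_codes = codes[o : o + sl]
        for c in vec.tolist():
            if params.verify_hits and not np.array_equal(ref.codes[c : c + sl], seed_codes):
                continue
            block = c - o
            if single_seq:
                lo, hi = 0, total
            else:
                lo, hi = ref.sequence_bounds(c)
            if block < lo or block + read_length > hi:
                continue
            tally[block] = tally.get(block, 0) + 1
    return tally


def candidate_pool(
    read: str, index: HashIndex, params: VoteParams
) -> Dict[Tuple[str, int], int]:
    """Merged forward/reverse vote pool keyed by (strand, block start)."""
    codes = encode_sequence(read)
    pool: Dict[Tuple[str, int], int] = {}
    for strand, oriented in (("+", codes), ("-", _revcomp_codes(codes))):
        for block, votes in _strand_tally(oriented, index, params, len(read)).items():
            pool[(strand, block)] = votes
    return pool


def _finalize(
    read: ReadRecord,
    selection: BlockSelection,
    index: HashIndex,
    params: VoteParams,
    scheme: ScoringScheme,
) -> AlignmentResult:
    """Rescue stage + coordinate conversion for a selected (strand, block)."""
    ref = index.reference
    strand, block = selection.block_start
    query = read.bases if strand == "+" else reverse_complement(read.bases)
    aln = rescue(query, ref, block, scheme)
    if aln is None:
        return AlignmentResult(
            read.name, False, optimal=selection.optimal,
            suboptimal=selection.suboptimal, reason="rescue_failed",
        )
    seq_idx, local = ref.locate(aln.ref_span[0])
    tied = selection.status == "tied"
    mapq = 0 if tied else mapping_quality(
        selection.optimal, selection.suboptimal, params.mapq_scale, params.mapq_cap
    )
    return AlignmentResult(
        read_name=read.name,
        mapped=True,
        ref_name=ref.names[seq_idx],
        position=local + 1,
        strand=strand,
        mapq=mapq,
        cigar=aln.cigar,
        edit_distance=aln.edit_distance,
        optimal=selection.optimal,
        suboptimal=selection.suboptimal,
        tied=tied,
        alignment=aln,
    )


def map_single(
    read: ReadRecord,
    index: HashIndex,
    params: VoteParams,
    rng: np.random.Generator,
    scheme: ScoringScheme = ScoringScheme(),
) -> AlignmentResult:
    """Map one read: vote on both strands, select, rescue, score."""
    if len(read.bases) < index.params.seed_length:
        return AlignmentResult(read.name, False, reason="read_shorter_than_seed")
    pool = candidate_pool(read.bases, index, params)
    selection = select_block(pool, params, rng)
    if selection.status == "unmapped":
        return AlignmentResult(
            read.name, False, optimal=selection.optimal, reason="below_min_votes"
        )
    return _finalize(read, selection, index, params, scheme)


def _tied_set(pool: Dict[Tuple[str, int], int], params: VoteParams):
    """(optimal, suboptimal, tied candidate list) of a pool; list empty if unmappable."""
    if not pool:
        return 0, 0, []
    optimal = max(pool.values())
    if optimal < params.min_votes:
        return optimal, 0, []
    tied = sorted(b for b, v in pool.items() if v == optimal)
    if len(tied) > 1:
        return optimal, optimal, tied
    rest = [v for b, v in pool.items() if b != tied[0]]
    return optimal, (max(rest) if rest else 0), tied


def map_pair(
    read1: ReadRecord,
    read2: ReadRecord,
    index: HashIndex,
    params: VoteParams,
    rng: np.random.Generator,
    insert_max: int = DEFAULT_INSERT_MAX,
    scheme: ScoringScheme = ScoringScheme(),
) -> Tuple[AlignmentResult, AlignmentResult]:
    """Map both mates; ties are resolved in favour of FR-concordant placements.

    Each mate is mapped independently.  When either mate has several blocks
    tied for most votes, combinations putting the mates on opposite strands
    within ``insert_max`` bp are preferred (closest first) before falling back
    to the random tie-break.  Tied selections keep mapping quality 0 either way.
    """
    ref = index.reference
    results: List[Optional[AlignmentResult]] = [None, None]
    pools = []
    for i, read in enumerate((read1, read2)):
        if len(read.bases) < index.params.seed_length:
            results[i] = AlignmentResult(read.name, False, reason="read_shorter_than_seed")
            pools.append({})
        else:
            pools.append(candidate_pool(read.bases, index, params))
    stats = [_tied_set(pool, params) for pool in pools]

    chosen: List[Optional[Tuple[str, int]]] = [None, None]
    if all(s[2] for s in stats) and (len(stats[0][2]) > 1 or len(stats[1][2]) > 1):
        combos = []
        for c1 in stats[0][2]:
            for c2 in stats[1][2]:
                if c1[0] == c2[0]:
                    continue
                if ref.sequence_bounds(c1[1]) != ref.sequence_bounds(c2[1]):
                    continue
                dist = abs(c1[1] - c2[1])
                if dist <= insert_max:
                    combos.append((dist, c1, c2))
        if combos:
            combos.sort()
            _, chosen[0], chosen[1] = combos[0]

    for i, read in enumerate((read1, read2)):
        if results[i] is not None:
            continue
        optimal, suboptimal, tied = stats[i]
        if not tied:
            results[i] = AlignmentResult(
                read.name, False, optimal=optimal, reason="below_min_votes"
            )
            continue
        if chosen[i] is not None:
            pick = chosen[i]
        elif len(tied) > 1:
            pick = tied[int(rng.integers(len(tied)))]
        else:
            pick = tied[0]
        status = "tied" if len(tied) > 1 else "mapped"
        results[i] = _finalize(
            read, BlockSelection(status, pick, optimal, suboptimal), index, params, scheme
        )
    return results[0], results[1]


# ---------------------------------------------------------------------------
# SAM emission


def cigar_reference_span(cigar: str) -> int:
    return sum(n for n, op in cigar_to_ops(cigar) if op in ("M", "D"))


def sam_header(ref: ReferenceSet, program_args: str = "", version: str = "1.0.0") -> str:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, length in zip(ref.names, ref.lengths.tolist()):
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    pg = f"@PG\tID:seedvote\tPN:seedvote\tVN:{version}"
    if program_args:
        pg += f"\tCL:{program_args}"
    lines.append(pg)
    return "\n".join(lines) + "\n"


def _is_proper(a: AlignmentResult, b: AlignmentResult, insert_max: int) -> bool:
    return (
        a.mapped
        and b.mapped
        and a.ref_name == b.ref_name
        and a.strand != b.strand
        and abs(a.position - b.position) <= insert_max
    )


def to_sam(
    result: AlignmentResult,
    read: ReadRecord,
    mate: Optional[AlignmentResult] = None,
    proper: bool = False,
) -> str:
    """One SAM line; reverse-strand hits store the reverse-complemented sequence."""
    flag = 0
    paired = read.mate_index in (1, 2)
    if paired:
        flag |= 0x1
        flag |= 0x40 if read.mate_index == 1 else 0x80
        if proper:
            flag |= 0x2
        if mate is not None:
            if not mate.mapped:
                flag |= 0x8
            elif mate.strand == "-":
                flag |= 0x20
    seq = read.bases
    qual = read.qualities or "*"
    if not result.mapped:
        flag |= 0x4
        rname, pos, mapq, cigar = "*", 0, 0, "*"
    else:
        rname, pos, mapq, cigar = result.ref_name, result.position, result.mapq, result.cigar
        if result.strand == "-":
            flag |= 0x10
            seq = reverse_complement(read.bases)
            if read.qualities:
                qual = read.qualities[::-1]
    rnext, pnext, tlen = "*", 0, 0
    if paired and mate is not None and mate.mapped:
        rnext = "=" if (result.mapped and mate.ref_name == result.ref_name) else mate.ref_name
        pnext = mate.position
        if result.mapped and mate.ref_name == result.ref_name:
            self_end = result.position + cigar_reference_span(result.cigar)
            mate_end = mate.position + cigar_reference_span(mate.cigar)
            left = min(result.position, mate.position)
            right = max(self_end, mate_end)
            outer = right - left
            if result.position < mate.position or (
                result.position == mate.position and read.mate_index == 1
            ):
                tlen = outer
            else:
                tlen = -outer
    fields = [
        read.name,
        str(flag),
        rname,
        str(pos),
        str(mapq),
        cigar,
        rnext,
        str(pnext),
        str(tlen),
        seq,
        qual,
        f"NM:i:{result.edit_distance}",
        f"ZO:i:{result.optimal}",
        f"ZS:i:{result.suboptimal}",
    ]
    return "\t".join(fields)
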