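"""Mismatch counting and Smith-Waterman rescue of the selected block.

A read is first compared position-by-position against its winning block.  Up
to two mismatches the ungapped placement stands.  With more than two, the
block is extended 36 bp upstream and downstream (clipped at sequence bounds)
and a local affine-gap alignment (Gotoh) is computed between the read and the
extended segment; the read's reported position becomes the alignment's
reference start and unaligned read ends are soft-clipped.

Gap cost convention: a gap of length k scores ``gap_open + k * gap_extend``
(both negative), i.e. the opening penalty is charged on top of the first
extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .index import ReferenceSet, encode_sequence

RESCUE_PAD = 36
RESCUE_MISMATCH_LIMIT = 2


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap scores must be negative")


@dataclass(frozen=True)
class LocalAlignment:
    """A local alignment of a read against a reference segment.

    ``ref_span`` is global and half-open; ``read_span`` is half-open on the
    read; ``cigar`` covers the whole read (soft-clips included).
    """

    score: int
    read_span: Tuple[int, int]
    ref_span: Tuple[int, int]
    cigar: str
    edit_distance: int


def count_mismatches(read: str, ref: ReferenceSet, block_start: int) -> int:
    """Hamming distance of the read against its block (ambiguous ref base = mismatch)."""
    n = len(read)
    lo, hi = ref.sequence_bounds(block_start)
    if block_start < lo or block_start + n > hi:
        raise ValueError(f"block [{block_start}, {block_start + n}) outside its sequence")
    read_codes = encode_sequence(read)
    block_codes = ref.fetch_codes(block_start, n)
    return int(((read_codes != block_codes) | (block_codes >= 4)).sum())


def extend_block(
    ref: ReferenceSet, block_start: int, read_length: int, pad: int = RESCUE_PAD
) -> Tuple[int, int]:
    """Global half-open interval of the block padded by ``pad`` on both sides.

    Clipped to the containing sequence so the rescue window never spans a
    sequence boundary.
    """
    lo, hi = ref.sequence_bounds(block_start)
    return max(block_start - pad, lo), min(block_start + read_length + pad, hi)


def cigar_to_ops(cigar: str) -> List[Tuple[int, str]]:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def _ops_to_cigar(ops: List[Tuple[int, str]]) -> str:
    merged: List[Tuple[int, str]] = []
    for n, op in ops:
        if n == 0:
            continue
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    return "".join(f"{n}{op}" for n, op in merged)


def smith_waterman(
    read: str, ref_segment: str, scheme: ScoringScheme = ScoringScheme()
) -> Optional[LocalAlignment]:
    """Optimal local affine-gap alignment with full traceback.

    Ties are broken by operator precedence diagonal > up (insertion to the
    reference, consumes read) > left (deletion, consumes segment), and gap
    openings are preferred over extensions when scores tie; the best cell is
    the first maximum in row-major order.  Spans in the result are relative to
    the inputs (callers shift ``ref_span`` to global coordinates).  Returns
    None when the best score is not positive.
    """
    if not read or not ref_segment:
        raise ValueError("both sequences must be non-empty")
    q = encode_sequence(read)
    t = encode_sequence(ref_segment)
    n, m = len(q), len(t)
    ma, mi = scheme.match, scheme.mismatch
    go, ge = scheme.gap_open, scheme.gap_extend
    neg = -(10**9)

    h_prev = [0] * (m + 1)
    # pointer codes for H: 0 stop, 1 diag, 2 up (I), 3 left (D)
    ph = [bytearray(m + 1) for _ in range(n + 1)]
    pe = [bytearray(m + 1) for _ in range(n + 1)]  # 1 = extended from E
    pf = [bytearray(m + 1) for _ in range(n + 1)]  # 1 = extended from F
    f_col = [neg] * (m + 1)  # F per column: gap in segment (up moves, 'I')

    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        h_cur = [0] * (m + 1)
        e_cur = [neg] * (m + 1)
        ph_i, pe_i, pf_i = ph[i], pe[i], pf[i]
        for j in range(1, m + 1):
            sub = ma if (qi == t[j - 1] and qi < 4) else mi
            diag = h_prev[j - 1] + sub
            e_open = h_cur[j - 1] + go + ge
            e_ext = e_cur[j - 1] + ge
            if e_ext > e_open:
                e = e_ext
                pe_i[j] = 1
            else:
                e = e_open
            f_open = h_prev[j] + go + ge
            f_ext = f_col[j] + ge
            if f_ext > f_open:
                f = f_ext
                pf_i[j] = 1
            else:
                f = f_open
            e_cur[j] = e
            f_col[j] = f
            h, p = diag, 1  # ties: diagonal beats up beats left
            if f > h:
                h, p = f, 2
            if e > h:
                h, p = e, 3
            if h <= 0:
                h, p = 0, 0
            h_cur[j] = h
            ph_i[j] = p
            if h > best:
                best, bi, bj = h, i, j
        h_prev = h_cur

    if best <= 0:
        return None

    # traceback with an explicit H/E/F state machine
    ops: List[Tuple[int, str]] = []
    i, j, state = bi, bj, "H"
    edit = 0
    while i > 0 and j > 0:
        if state == "H":
            p = ph[i][j]
            if p == 0:
                break
            if p == 1:
                ops.append((1, "M"))
                if q[i - 1] != t[j - 1] or q[i - 1] >= 4:
                    edit += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # up: consume read
            ops.append((1, "I"))
            edit += 1
            if pf[i][j] == 0:
                state = "H"
            i -= 1
        else:  # E, left: consume segment
            ops.append((1, "D"))
            edit += 1
            if pe[i][j] == 0:
                state = "H"
            j -= 1
    ops.reverse()

    read_start, read_end = i, bi
    ref_start, ref_end = j, bj
    cigar_ops: List[Tuple[int, str]] = []
    if read_start > 0:
        cigar_ops.append((read_start, "S"))
    cigar_ops.extend(ops)
    if read_end < n:
        cigar_ops.append((n - read_end, "S"))
    return LocalAlignment(
        score=best,
        read_span=(read_start, read_end),
        ref_span=(ref_start, ref_end),
        cigar=_ops_to_cigar(cigar_ops),
        edit_distance=edit,
    )


def rescore_cigar(read: str, segment: str, aln: LocalAlignment, scheme: ScoringScheme) -> int:
    """Independent re-scoring of an alignment's cigar (consistency checks)."""
    i, j = aln.read_span[0], aln.ref_span[0]
    score = 0
    for n, op in cigar_to_ops(aln.cigar):
        if op == "S":
            continue
        if op == "M":
            for _ in range(n):
                score += scheme.match if read[i] == segment[j] else scheme.mismatch
                i += 1
                j += 1
        elif op in ("I", "D"):
            score += scheme.gap_open + n * scheme.gap_extend
            if op == "I":
                i += n
            else:
                j += n
    return score


def rescue(
    read: str,
    ref: ReferenceSet,
    block_start: int,
    scheme: ScoringScheme = ScoringScheme(),
    mismatch_limit: int = RESCUE_MISMATCH_LIMIT,
    pad: int = RESCUE_PAD,
) -> Optional[LocalAlignment]:
    """Final alignment of a read against its selected block.

    Up to ``mismatch_limit`` mismatches: the ungapped placement is returned as
    an all-M alignment.  Beyond it, Smith-Waterman against the padded block;
    the result's reference span is global.  None means the rescue produced no
    positive-scoring alignment and the read is unmapped.
    """
    n = len(read)
    mismatches = count_mismatches(read, ref, block_start)
    if mismatches <= mismatch_limit:
        score = (n - mismatches) * scheme.match + mismatches * scheme.mismatch
        return LocalAlignment(
            score=score,
            read_span=(0, n),
            ref_span=(block_start, block_start + n),
            cigar=f"{n}M",
            edit_distance=mismatches,
        )
    seg_start, seg_end = extend_block(ref, block_start, n, pad)
    segment = ref.fetch(seg_start, seg_end - seg_start)
    aln = smith_waterman(read, segment, scheme)
    if aln is None:
        return None
    return LocalAlignment(
        score=aln.score,
        read_span=aln.read_span,
        ref_span=(seg_start + aln.ref_span[0], seg_start + aln.ref_span[1]),
        cigar=aln.cigar,
        edit_distance=aln.edit_distance,
    )
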