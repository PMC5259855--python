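"""Seed extraction, block voting, block selection and mapping quality.

A read of length n yields one seed per start offset (n - sl + 1 seeds).  Each
seed's key is looked up in the stride-w index; every returned coordinate casts
one vote for the *block* starting at ``coordinate - read_offset`` — the
read-length reference interval that would place the seed where it sits in the
read.  The block with the most votes wins; confidence is the vote margin over
the runner-up, scaled by 6 and capped at 60.

Filtering rules applied during voting and selection:

* a seed whose coordinate vector exceeds ``max_occurrence`` (450 by default)
  is unrepresentative and dropped entirely;
* the winning block needs at least ``min_votes`` (2) votes, otherwise the read
  is unmapped;
* several blocks tied for most votes -> one is picked at random and the
  mapping quality is forced to 0;
* with ``verify_hits`` (default), a coordinate only counts when the reference
  text there equals the seed text, eliminating mod-M hash collisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

import numpy as np

from .index import (
    MAX_SEED_LENGTH,
    MIN_SEED_LENGTH,
    EncodedKmer,
    HashIndex,
    ReferenceSet,
    encode_sequence,
    window_keys,
)

MIN_READ_LENGTH = 36

DEFAULT_MIN_VOTES = 2
DEFAULT_MAX_OCCURRENCE = 450
MAPQ_SCALE = 6
MAPQ_CAP = 60


class UnsupportedReadLengthError(ValueError):
    """Read too short for seed-and-vote mapping (below 36 bp)."""


@dataclass(frozen=True)
class VoteParams:
    """Voting-stage knobs; defaults are the recommended operating point."""

    min_votes: int = DEFAULT_MIN_VOTES
    max_occurrence: int = DEFAULT_MAX_OCCURRENCE
    seed_length: Optional[int] = None  # None -> take from index / auto rule
    mapq_scale: int = MAPQ_SCALE
    mapq_cap: int = MAPQ_CAP
    verify_hits: bool = True
    merge_window: int = 0

    def __post_init__(self) -> None:
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")
        if self.max_occurrence < 1:
            raise ValueError("max_occurrence must be >= 1")


@dataclass(frozen=True)
class BlockSelection:
    """Outcome of picking the best-voted block for one read."""

    status: str  # "mapped" | "unmapped" | "tied"
    block_start: Optional[Hashable]
    optimal: int
    suboptimal: int


def auto_seed_length(read_length: int, stride: int = 8) -> int:
    """Pick the seed length for a read length.

    Chooses the largest s in [16, 32] such that the number of seed positions,
    read_length - s + 1, is a multiple of the stride.  That makes the maximum
    attainable vote count identical for every alignment phase, so a perfectly
    matching block can never be outvoted by a mismatched one purely because of
    where the indexed windows fall.  Reproduces the recommended choices:
    150 bp -> 31, 125 bp -> 30.
    """
    if read_length < MIN_READ_LENGTH:
        raise UnsupportedReadLengthError(
            f"read length {read_length} below supported minimum {MIN_READ_LENGTH}"
        )
    for s in range(MAX_SEED_LENGTH, MIN_SEED_LENGTH - 1, -1):
        if (read_length - s + 1) % stride == 0:
            return s
    return min(31, read_length)


def extract_seeds(read: str, seed_length: int) -> List[Tuple[int, EncodedKmer]]:
    """All unit-stride seeds of a read as (read_offset, encoded k-mer) pairs.

    Seeds overlapping a non-ACGT character are omitted.  A read shorter than
    the seed length yields no seeds (and is unmapped downstream).
    """
    codes = encode_sequence(read)
    offsets, kmers = _seed_arrays(codes, seed_length)
    return [(int(o), k) for o, k in zip(offsets, kmers)]


def _seed_arrays(codes: np.ndarray, seed_length: int) -> Tuple[np.ndarray, List[EncodedKmer]]:
    n = codes.size
    m = n - seed_length + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64), []
    bad = np.concatenate([[0], np.cumsum(codes >= 4, dtype=np.int64)])
    valid = (bad[seed_length:] - bad[:-seed_length]) == 0
    offsets = np.nonzero(valid)[0].astype(np.int64)
    kmers = []
    for o in offsets:
        value = 0
        for c in codes[o : o + seed_length]:
            value = (value << 2) | int(c)
        kmers.append(EncodedKmer(value=value, length=seed_length))
    return offsets, kmers


def seed_keys_for_read(
    codes: np.ndarray, seed_length: int, modulus: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized (offsets, keys) for all valid seeds of a coded read."""
    keys, valid = window_keys(codes, seed_length, modulus)
    offsets = np.nonzero(valid)[0].astype(np.int64)
    return offsets, keys[offsets]


def collect_votes(
    seeds: Sequence[Tuple[int, EncodedKmer]],
    index: HashIndex,
    ref: ReferenceSet,
    params: VoteParams,
    read_length: Optional[int] = None,
) -> Dict[int, int]:
    """Tally votes per candidate block start for one read on one strand.

    For each seed the key is looked up; over-occurring seeds are skipped;
    verified coordinates each add one vote to block ``coordinate - offset``.
    Blocks that would start before their sequence or run past its end are
    discarded.  ``read_length`` defaults to the span implied by the seeds.
    """
    if read_length is None:
        read_length = (
            max(o for o, _ in seeds) + seeds[0][1].length if seeds else 0
        )
    tally: Dict[int, int] = {}
    for offset, kmer in seeds:
        vec = index.table.get(kmer.value % index.params.modulus)
        if vec is None or len(vec) > params.max_occurrence:
            continue
        seed_codes = kmer.codes() if params.verify_hits else None
        for coord in vec.tolist():
            if params.verify_hits and not np.array_equal(
                ref.codes[coord : coord + kmer.length], seed_codes
            ):
                continue
            block = coord - offset
            lo, hi = ref.sequence_bounds(coord)
            if block < lo or block + read_length > hi:
                continue
            tally[block] = tally.get(block, 0) + 1
    if params.merge_window > 0:
        tally = merge_tally(tally, params.merge_window)
    return tally


def merge_tally(tally: Dict[int, int], window: int) -> Dict[int, int]:
    """Fold blocks within ``window`` bp of a stronger block into it.

    Off by default; candidate clusters shifted by small indels are normally
    handled by the Smith-Waterman rescue instead.
    """
    merged: Dict[int, int] = {}
    for block in sorted(tally, key=lambda b: (-tally[b], b)):
        for target in merged:
            if abs(block - target) <= window:
                merged[target] += tally[block]
                break
        else:
            merged[block] = tally[block]
    return merged


def select_block(
    tally: Dict[Hashable, int],
    params: VoteParams,
    rng: np.random.Generator,
) -> BlockSelection:
    """Pick the best-voted block; tie -> uniform random choice flagged 'tied'.

    Unmapped when the best block has fewer than ``min_votes`` votes.  The
    suboptimal count is the second-best block's votes (0 when there is no
    second block).  Deterministic given the rng state.
    """
    if not tally:
        return BlockSelection("unmapped", None, 0, 0)
    optimal = max(tally.values())
    if optimal < params.min_votes:
        return BlockSelection("unmapped", None, optimal, 0)
    tied = sorted(b for b, v in tally.items() if v == optimal)
    if len(tied) > 1:
        choice = tied[int(rng.integers(len(tied)))]
        return BlockSelection("tied", choice, optimal, optimal)
    rest = [v for b, v in tally.items() if b != tied[0]]
    suboptimal = max(rest) if rest else 0
    return BlockSelection("mapped", tied[0], optimal, suboptimal)


def mapping_quality(
    optimal: int,
    suboptimal: int,
    scale: int = MAPQ_SCALE,
    cap: int = MAPQ_CAP,
) -> int:
    """mapq = min((optimal - suboptimal) * 6, 60); callers force ties to 0."""
    if optimal < suboptimal or suboptimal < 0:
        raise ValueError(f"require optimal >= suboptimal >= 0, got ({optimal}, {suboptimal})")
    return min((optimal - suboptimal) * scale, cap)


def max_votes_closed_form(read_length: int, seed_length: int, stride: int, phase: int) -> int:
    """Maximum vote count for a perfectly matching read at a given phase.

    ``phase`` is the 1-based read offset of the first seed that lands on an
    indexed position; in-phase seeds then follow every ``stride`` bases, so the
    count is floor((read_length - seed_length + 1 - phase) / stride) + 1
    (0 when no seed fits).
    """
    if not 1 <= phase <= stride:
        raise ValueError("phase must be in 1..stride")
    v = (read_length - seed_length + 1 - phase) // stride + 1
    return max(v, 0)
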