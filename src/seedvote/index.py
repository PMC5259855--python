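"""Genome hash index: 2-bit k-mer encoding, modular-prime keys, stride-w table.

The index converts every w-th reference subsequence of length ``sl`` (31 by
default) into a base-4 integer (A=0, C=1, G=2, T=3, first base most
significant), reduces it modulo a large prime ``M`` that fits in an unsigned
32-bit word, and stores the genomic start coordinate in the vector belonging
to that key.  Keys with no indexed subsequence are absent from the table
(NULL).  Windows that contain any character other than A/C/G/T are dropped
without key calculation.  Only the forward strand is indexed; reverse-strand
queries are handled at mapping time.
"""

from __future__ import annotations

import io
import logging
import zipfile
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: Largest prime below 2**32 — the default modulus.
DEFAULT_MODULUS = 4_294_967_291
DEFAULT_SEED_LENGTH = 31
DEFAULT_STRIDE = 8

MIN_SEED_LENGTH = 16
MAX_SEED_LENGTH = 32

_INDEX_MAGIC = b"SEEDVOTE_INDEX"
_INDEX_VERSION = 1

# ASCII -> 2-bit code; 4 marks every non-ACGT character (N, IUPAC codes, ...).
_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
    _CODE_TABLE[_b + 32] = _i  # soft-masked lowercase

_BASES = "ACGT"


class AmbiguousBaseError(ValueError):
    """A k-mer contained a character outside A/C/G/T."""


class IndexFormatError(IOError):
    """An index file is truncated, corrupt, or from an incompatible version."""


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes 0..3 (A,C,G,T); 4 for anything else."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def decode_codes(codes: np.ndarray) -> str:
    lookup = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lookup[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class EncodedKmer:
    """A k-mer as a base-4 big-endian unsigned integer."""

    value: int
    length: int

    def __post_init__(self) -> None:
        if not 0 <= self.value < 4**self.length:
            raise ValueError(f"value {self.value} out of range for length {self.length}")

    def decode(self) -> str:
        digits = []
        v = self.value
        for _ in range(self.length):
            digits.append(_BASES[v & 3])
            v >>= 2
        return "".join(reversed(digits))

    def codes(self) -> np.ndarray:
        """Digits as a uint8 array, most significant first."""
        out = np.empty(self.length, dtype=np.uint8)
        v = self.value
        for i in range(self.length - 1, -1, -1):
            out[i] = v & 3
            v >>= 2
        return out


@dataclass(frozen=True)
class IndexParams:
    """Indexing parameters: seed length sl, stride w, prime modulus M."""

    seed_length: int = DEFAULT_SEED_LENGTH
    stride: int = DEFAULT_STRIDE
    modulus: int = DEFAULT_MODULUS

    def __post_init__(self) -> None:
        if not MIN_SEED_LENGTH <= self.seed_length <= MAX_SEED_LENGTH:
            raise ValueError(
                f"seed length must be in [{MIN_SEED_LENGTH}, {MAX_SEED_LENGTH}], "
                f"got {self.seed_length}"
            )
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not 1 < self.modulus <= 2**32 - 1:
            raise ValueError("modulus must fit in an unsigned 32-bit integer")
        if not _is_prime(self.modulus):
            raise ValueError(f"modulus {self.modulus} is not prime")


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    if n % 2 == 0:
        return n == 2
    f = 3
    while f * f <= n:
        if n % f == 0:
            return False
        f += 2
    return True


class ReferenceSet:
    """An ordered collection of named sequences with a virtual concatenation.

    Coordinates are global and 0-based: sequence ``i`` occupies
    ``[offsets[i], offsets[i] + lengths[i])`` in the concatenation.  Bases are
    stored 2-bit coded (4 = ambiguous) in one contiguous array.
    """

    def __init__(self, sequences: Sequence[Tuple[str, str]]):
        if not sequences:
            raise ValueError("reference must contain at least one sequence")
        self.names: List[str] = [name for name, _ in sequences]
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names in reference")
        self.lengths = np.array([len(seq) for _, seq in sequences], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)]).astype(np.int64)
        self.codes = (
            np.concatenate([encode_sequence(seq) for _, seq in sequences])
            if self.total_length
            else np.empty(0, dtype=np.uint8)
        )

    @property
    def total_length(self) -> int:
        return int(self.offsets[-1])

    def __len__(self) -> int:
        return len(self.names)

    def locate(self, coord: int) -> Tuple[int, int]:
        """Global coordinate -> (sequence index, local 0-based position)."""
        if not 0 <= coord < self.total_length:
            raise ValueError(f"coordinate {coord} outside reference")
        i = int(np.searchsorted(self.offsets, coord, side="right")) - 1
        return i, coord - int(self.offsets[i])

    def sequence_bounds(self, coord: int) -> Tuple[int, int]:
        """Global [start, end) of the sequence containing ``coord``."""
        i, _ = self.locate(coord)
        return int(self.offsets[i]), int(self.offsets[i + 1])

    def fetch_codes(self, start: int, length: int) -> np.ndarray:
        return self.codes[start : start + length]

    def fetch(self, start: int, length: int) -> str:
        return decode_codes(self.fetch_codes(start, length))

    def sequence(self, i: int) -> str:
        return decode_codes(self.codes[self.offsets[i] : self.offsets[i + 1]])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ReferenceSet)
            and self.names == other.names
            and np.array_equal(self.lengths, other.lengths)
            and np.array_equal(self.codes, other.codes)
        )


def encode_kmer(seq: str) -> EncodedKmer:
    """Encode an A/C/G/T string as a base-4 big-endian integer.

    Raises :class:`AmbiguousBaseError` for any other character — callers drop
    such windows.
    """
    value = 0
    for ch in seq.upper():
        try:
            value = (value << 2) | _BASES.index(ch)
        except ValueError:
            raise AmbiguousBaseError(f"non-ACGT character {ch!r} in k-mer") from None
    return EncodedKmer(value=value, length=len(seq))


def compute_key(kmer: EncodedKmer, modulus: int = DEFAULT_MODULUS) -> int:
    """Reduce a k-mer's integer value modulo the prime M: the hash-table key."""
    return kmer.value % modulus


def window_keys(codes: np.ndarray, seed_length: int, modulus: int) -> Tuple[np.ndarray, np.ndarray]:
    """Keys and validity for every window start 0..len-sl of a coded sequence.

    Vectorized Horner evaluation: key = (((c0*4)+c1)*4+...) mod M.  A window is
    valid iff it contains no ambiguous code.  Returns (keys, valid), both of
    length ``len(codes) - seed_length + 1`` (empty when the sequence is shorter
    than the seed).
    """
    n = codes.size
    m = n - seed_length + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    mod = np.uint64(modulus)
    four = np.uint64(4)
    keys = np.zeros(m, dtype=np.uint64)
    safe = np.where(codes < 4, codes, 0).astype(np.uint64)
    for j in range(seed_length):
        keys = (keys * four + safe[j : j + m]) % mod
    bad = np.concatenate([[0], np.cumsum(codes >= 4, dtype=np.int64)])
    valid = (bad[seed_length:] - bad[:-seed_length]) == 0
    return keys, valid


class HashIndex:
    """The key -> coordinate-vector table plus the reference it was built from.

    Only non-NULL keys are stored (the conceptual table has M slots).  Each
    vector holds global 0-based start coordinates in ascending genome order.
    """

    def __init__(
        self,
        params: IndexParams,
        reference: ReferenceSet,
        keys: np.ndarray,
        indptr: np.ndarray,
        coords: np.ndarray,
    ):
        self.params = params
        self.reference = reference
        self._keys = keys.astype(np.uint64)
        self._indptr = indptr.astype(np.int64)
        self._coords = coords.astype(np.int64)
        self.table: Dict[int, np.ndarray] = {
            int(k): self._coords[self._indptr[i] : self._indptr[i + 1]]
            for i, k in enumerate(self._keys)
        }

    @property
    def n_windows(self) -> int:
        return int(self._coords.size)

    @property
    def n_keys(self) -> int:
        return int(self._keys.size)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, HashIndex)
            and self.params == other.params
            and self.reference == other.reference
            and np.array_equal(self._keys, other._keys)
            and np.array_equal(self._indptr, other._indptr)
            and np.array_equal(self._coords, other._coords)
        )


def build_index(ref: ReferenceSet, params: IndexParams = IndexParams()) -> HashIndex:
    """Index every w-th window of every sequence (stride restarts per sequence).

    Windows containing non-ACGT characters are skipped; coordinate vectors come
    out in ascending genome order because sequences are scanned left to right.
    """
    sl, w, mod = params.seed_length, params.stride, params.modulus
    all_keys: List[np.ndarray] = []
    all_coords: List[np.ndarray] = []
    dropped = 0
    for i in range(len(ref)):
        seq_codes = ref.codes[ref.offsets[i] : ref.offsets[i + 1]]
        keys, valid = window_keys(seq_codes, sl, mod)
        if keys.size == 0:
            continue
        starts = np.arange(0, keys.size, w, dtype=np.int64)
        ok = valid[starts]
        dropped += int((~ok).sum())
        all_keys.append(keys[starts[ok]])
        all_coords.append(starts[ok] + ref.offsets[i])
    if all_keys:
        keys = np.concatenate(all_keys)
        coords = np.concatenate(all_coords)
    else:
        keys = np.empty(0, dtype=np.uint64)
        coords = np.empty(0, dtype=np.int64)
    if keys.size == 0:
        logger.warning("reference contains no indexable window; index is empty")
        return HashIndex(params, ref, keys, np.zeros(1, dtype=np.int64), coords)
    # stable sort keeps coordinates ascending within each key
    order = np.argsort(keys, kind="stable")
    keys_sorted = keys[order]
    coords_sorted = coords[order]
    uniq, counts = np.unique(keys_sorted, return_counts=True)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    if dropped:
        logger.info("dropped %d windows overlapping ambiguous bases", dropped)
    logger.info(
        "indexed %d windows under %d keys (occupancy %.4f of M)",
        coords.size,
        uniq.size,
        uniq.size / params.modulus,
    )
    return HashIndex(params, ref, uniq, indptr, coords_sorted)


def lookup(index: HashIndex, key: int) -> Optional[np.ndarray]:
    """Coordinate vector for a key, or None for a NULL (unseen) key."""
    if not 0 <= key < index.params.modulus:
        raise ValueError(f"key {key} outside [0, M)")
    return index.table.get(int(key))


def save_index(index: HashIndex, path: str) -> None:
    """Write a self-describing archive: magic, version, params, reference, table."""
    ref = index.reference
    with open(path, "wb") as fh:
        np.savez_compressed(
            fh,
            magic=np.frombuffer(_INDEX_MAGIC, dtype=np.uint8),
            version=np.array([_INDEX_VERSION], dtype=np.int64),
            params=np.array(
                [index.params.seed_length, index.params.stride, index.params.modulus],
                dtype=np.int64,
            ),
            names=np.array(ref.names, dtype=np.str_),
            lengths=ref.lengths,
            ref_codes=ref.codes,
            keys=index._keys,
            indptr=index._indptr,
            coords=index._coords,
        )


def load_index(path: str) -> HashIndex:
    """Load an index written by :func:`save_index`; fails cleanly on bad files."""
    try:
        with np.load(path, allow_pickle=False) as data:
            arrays = {k: data[k] for k in data.files}
    except (zipfile.BadZipFile, OSError, ValueError, KeyError) as exc:
        raise IndexFormatError(f"cannot read index file {path!r}: {exc}") from exc
    required = {"magic", "version", "params", "names", "lengths", "ref_codes", "keys", "indptr", "coords"}
    if not required <= arrays.keys():
        raise IndexFormatError(f"index file {path!r} is missing fields")
    if arrays["magic"].tobytes() != _INDEX_MAGIC:
        raise IndexFormatError(f"{path!r} is not an index file (bad magic)")
    if int(arrays["version"][0]) != _INDEX_VERSION:
        raise IndexFormatError(f"unsupported index version {int(arrays['version'][0])}")
    sl, w, mod = (int(v) for v in arrays["params"])
    params = IndexParams(seed_length=sl, stride=w, modulus=mod)
    ref = ReferenceSet.__new__(ReferenceSet)
    ref.names = [str(n) for n in arrays["names"]]
    ref.lengths = arrays["lengths"].astype(np.int64)
    ref.offsets = np.concatenate([[0], np.cumsum(ref.lengths)]).astype(np.int64)
    ref.codes = arrays["ref_codes"].astype(np.uint8)
    return HashIndex(params, ref, arrays["keys"], arrays["indptr"], arrays["coords"])
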