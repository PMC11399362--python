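"""Exact-membership bitmap index over host 16-mers.

The host transcriptome is decomposed into all overlapping 16-mers
(window step 1, i.e. 15-base overlap between neighbours). Each 16-mer
is packed into a 32-bit integer at 2 bits per base (A=00, C=01, G=10,
T=11, first base in the most significant bit pair, so numeric order of
codes coincides with lexicographic order of 16-mers). Membership of the
full 2^32 code space is recorded in a presence bitmap of 2^32 bits =
536,870,912 bytes (512 MiB). The bitmap's size is a property of the
code space, not of the input: indexing additional sequences sets more
bits but never grows the structure.

A hash-set backend with identical semantics is provided for
memory-constrained runs; the bitmap is the default and the documented
size applies to it.

On-disk format (:func:`save_index` / :func:`load_index`): a fixed
24-byte header — magic ``ROAIDX``, 1-byte format version, 1-byte k,
little-endian uint64 sequence count, little-endian uint64 distinct-code
count — followed by the raw bitmap, where bit ``j`` of byte ``i``
(little-endian within the byte) records code ``i*8 + j``.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import (
    CodeRangeError,
    ConfigError,
    IndexCorruptionError,
    IndexFormatError,
    KmerLengthError,
)
from .sequences import NucSequence, validate_alphabet

K = 16
CODE_SPACE = 1 << (2 * K)  # 4**16 == 2**32 possible codes
BITMAP_BYTES = CODE_SPACE // 8  # 536,870,912 bytes == 512 MiB

_MAGIC = b"ROAIDX"
_FORMAT_VERSION = 1
_HEADER = struct.Struct("<6sBBQQ")  # magic, version, k, n_sequences, n_kmers_set

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"

# byte -> 2-bit base code lookup for vectorized window encoding; 255 marks
# characters outside A/C/G/T so their windows can be skipped.
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _LUT[ord(_b)] = _c


def encode_kmer(seq: str, k: int = K) -> int:
    """Pack a k-mer string into its integer code (2 bits per base).

    The encoding is a bijection between k-mers and ``[0, 4**k)``; for
    k=16 the code fits exactly in 32 bits.
    """
    if len(seq) != k:
        raise KmerLengthError(f"expected a {k}-mer, got length {len(seq)}")
    validate_alphabet(seq)
    value = 0
    for base in seq:
        value = (value << 2) | _BASE_CODE[base]
    return value


def decode_kmer(code: int, k: int = K) -> str:
    """Inverse of :func:`encode_kmer`."""
    if not 0 <= code < (1 << (2 * k)):
        raise CodeRangeError(f"code {code} outside [0, 4**{k})")
    bases = []
    for shift in range(2 * (k - 1), -1, -2):
        bases.append(_CODE_BASE[(code >> shift) & 3])
    return "".join(bases)


def enumerate_kmers(
    seq: NucSequence | str, k: int = K
) -> list[tuple[int, int]]:
    """All ``(start, code)`` windows of ``seq`` at step 1, 0-based.

    Windows containing any non-ACGT character are skipped; the start
    position still advances by one, so a clean sequence of length L
    yields exactly ``L - k + 1`` windows.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    residues = seq.residues if isinstance(seq, NucSequence) else seq
    n = len(residues) - k + 1
    if n <= 0:
        return []
    base_codes = _LUT[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    windows = sliding_window_view(base_codes, k)
    valid = (windows != 255).all(axis=1)
    weights = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    codes = windows.astype(np.uint64) @ weights
    starts = np.nonzero(valid)[0]
    return list(zip(starts.tolist(), codes[valid].tolist()))


class HostIndex:
    """Presence index over all possible 16-mer codes.

    backend="bitmap" (default): one bit per code, constant 512 MiB.
    backend="set": a Python set of codes; identical answers, size
    proportional to content. Both maintain ``n_kmers_set`` (distinct
    codes present) and ``n_sequences`` (sequences indexed).
    """

    def __init__(self, backend: str = "bitmap", k: int = K):
        if k != K:
            raise ConfigError(f"only k={K} is supported, got {k}")
        if backend not in ("bitmap", "set"):
            raise ConfigError(f"unknown backend {backend!r}")
        self.k = k
        self.backend = backend
        self.n_sequences = 0
        self._n_set = 0
        if backend == "bitmap":
            self._bits: np.ndarray | None = np.zeros(BITMAP_BYTES, dtype=np.uint8)
            self._codes: set[int] | None = None
        else:
            self._bits = None
            self._codes = set()

    @property
    def n_kmers_set(self) -> int:
        return self._n_set

    @property
    def capacity_bytes(self) -> int | None:
        """Bitmap size in bytes (constant 2^29); None for the set backend."""
        return BITMAP_BYTES if self.backend == "bitmap" else None

    def add_sequence(self, seq: NucSequence | str) -> None:
        """Set the bit of every 16-mer window of ``seq`` (monotone)."""
        kmers = enumerate_kmers(seq, self.k)
        codes = np.unique(np.fromiter((c for _, c in kmers), dtype=np.uint64))
        if self.backend == "bitmap":
            assert self._bits is not None
            byte_idx = (codes >> np.uint64(3)).astype(np.int64)
            masks = (np.uint8(1) << (codes & np.uint64(7)).astype(np.uint8))
            newly = (self._bits[byte_idx] & masks) == 0
            self._n_set += int(np.count_nonzero(newly))
            np.bitwise_or.at(self._bits, byte_idx, masks)
        else:
            assert self._codes is not None
            self._codes.update(codes.tolist())
            self._n_set = len(self._codes)
        self.n_sequences += 1

    def contains(self, code: int) -> bool:
        """True iff the 16-mer with this code occurs in any indexed sequence."""
        if not 0 <= code < CODE_SPACE:
            raise CodeRangeError(f"code {code} outside [0, 2**32)")
        if self.backend == "bitmap":
            assert self._bits is not None
            return bool((self._bits[code >> 3] >> (code & 7)) & 1)
        assert self._codes is not None
        return code in self._codes

    def __contains__(self, code: int) -> bool:
        return self.contains(code)

    def contains_any(self, codes: Iterable[int]) -> bool:
        return any(self.contains(c) for c in codes)

    def popcount(self) -> int:
        """Recount set bits from the backing store (verification aid)."""
        if self.backend == "bitmap":
            assert self._bits is not None
            lut = np.array([bin(i).count("1") for i in range(256)], dtype=np.uint64)
            return int(lut[self._bits].sum())
        assert self._codes is not None
        return len(self._codes)

    def _bitmap_bytes(self) -> np.ndarray:
        if self.backend == "bitmap":
            assert self._bits is not None
            return self._bits
        assert self._codes is not None
        bits = np.zeros(BITMAP_BYTES, dtype=np.uint8)
        if self._codes:
            codes = np.fromiter(self._codes, dtype=np.uint64)
            byte_idx = (codes >> np.uint64(3)).astype(np.int64)
            masks = (np.uint8(1) << (codes & np.uint64(7)).astype(np.uint8))
            np.bitwise_or.at(bits, byte_idx, masks)
        return bits


def build_host_index(
    sequences: Sequence[NucSequence | str], backend: str = "bitmap"
) -> HostIndex:
    """Index every 16-mer of every sequence; capacity is content-independent."""
    if not sequences:
        raise ConfigError("at least one host sequence is required")
    index = HostIndex(backend=backend)
    for seq in sequences:
        index.add_sequence(seq)
    return index


def save_index(index: HostIndex, path: str | Path) -> None:
    """Persist an index (header + raw bitmap); byte-exact round trip."""
    path = Path(path)
    header = _HEADER.pack(
        _MAGIC, _FORMAT_VERSION, index.k, index.n_sequences, index.n_kmers_set
    )
    with open(path, "wb") as fh:
        fh.write(header)
        index._bitmap_bytes().tofile(fh)


def load_index(path: str | Path) -> HostIndex:
    """Load a bitmap-backend index saved by :func:`save_index`."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = fh.read(_HEADER.size)
        if len(raw) < _HEADER.size:
            raise IndexCorruptionError(f"{path}: truncated header")
        magic, version, k, n_sequences, n_kmers_set = _HEADER.unpack(raw)
        if magic != _MAGIC:
            raise IndexFormatError(f"{path}: bad magic {magic!r}")
        if version != _FORMAT_VERSION:
            raise IndexFormatError(f"{path}: unsupported version {version}")
        if k != K:
            raise IndexFormatError(f"{path}: unsupported k {k}")
        bits = np.fromfile(fh, dtype=np.uint8)
    if bits.size != BITMAP_BYTES:
        raise IndexCorruptionError(
            f"{path}: bitmap body has {bits.size} bytes, expected {BITMAP_BYTES}"
        )
    index = HostIndex(backend="bitmap")
    index._bits = bits
    index.n_sequences = n_sequences
    index._n_set = n_kmers_set
    return index
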