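"""Reusable lossless coding primitives.

Run-length encoding, delta encoding, canonical Huffman coding, 2-bit
nucleotide packing, LEB128 varints and zigzag folding of signed integers.
Every encode/decode pair here is an exact bijection on its declared domain;
the per-field strategies in :mod:`samzip.fields` compose these primitives.

Bit-level streams pack most-significant-bit first within each byte and
zero-pad the final partial byte.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import CorruptStreamError, EncodingError

# ---------------------------------------------------------------------------
# varints and zigzag
# ---------------------------------------------------------------------------


def varint_encode(u: int) -> bytes:
    """Serialize a non-negative integer as an LEB128 varint.

    Little-endian base-128 with a continuation bit in the MSB of each byte.
    """
    if u < 0:
        raise EncodingError(f"varint requires a non-negative integer, got {u}")
    out = bytearray()
    while True:
        b = u & 0x7F
        u >>= 7
        if u:
            out.append(b | 0x80)
        else:
            out.append(b)
            return bytes(out)


def varint_decode(buf: bytes, pos: int = 0) -> tuple[int, int]:
    """Decode one varint from ``buf`` at ``pos``; return (value, next_pos)."""
    result = 0
    shift = 0
    while True:
        if pos >= len(buf):
            raise CorruptStreamError("truncated varint")
        b = buf[pos]
        pos += 1
        result |= (b & 0x7F) << shift
        if not b & 0x80:
            return result, pos
        shift += 7


def zigzag_encode(i: int) -> int:
    """Fold a signed integer onto the non-negative integers (0,-1,1,-2,... -> 0,1,2,3,...)."""
    return (i << 1) if i >= 0 else ((-i << 1) - 1)


def zigzag_decode(u: int) -> int:
    if u < 0:
        raise CorruptStreamError("zigzag input must be non-negative")
    return (u >> 1) if not (u & 1) else -((u + 1) >> 1)


class ByteReader:
    """Cursor over a byte buffer with bounds-checked reads."""

    __slots__ = ("_data", "_pos")

    def __init__(self, data: bytes, pos: int = 0):
        self._data = data
        self._pos = pos

    @property
    def pos(self) -> int:
        return self._pos

    def at_end(self) -> bool:
        return self._pos >= len(self._data)

    def read(self, n: int) -> bytes:
        if n < 0 or self._pos + n > len(self._data):
            raise CorruptStreamError(
                f"truncated stream: wanted {n} bytes at offset {self._pos}, "
                f"have {len(self._data) - self._pos}"
            )
        chunk = self._data[self._pos : self._pos + n]
        self._pos += n
        return chunk

    def read_byte(self) -> int:
        return self.read(1)[0]

    def read_varint(self) -> int:
        value, self._pos = varint_decode(self._data, self._pos)
        return value


# ---------------------------------------------------------------------------
# bitstreams
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bitstream:
    """A packed bit sequence: MSB-first within each byte, zero-padded tail."""

    data: bytes
    bit_count: int

    def __post_init__(self) -> None:
        if len(self.data) != (self.bit_count + 7) // 8:
            raise EncodingError(
                f"bitstream of {self.bit_count} bits needs "
                f"{(self.bit_count + 7) // 8} bytes, got {len(self.data)}"
            )


class BitWriter:
    """Accumulates bits MSB-first and flushes whole bytes."""

    def __init__(self) -> None:
        self._buf = bytearray()
        self._acc = 0
        self._nbits = 0
        self._total = 0

    def write_bits(self, value: int, nbits: int) -> None:
        if nbits == 0:
            return
        self._acc = (self._acc << nbits) | (value & ((1 << nbits) - 1))
        self._nbits += nbits
        self._total += nbits
        while self._nbits >= 8:
            self._nbits -= 8
            self._buf.append((self._acc >> self._nbits) & 0xFF)
        self._acc &= (1 << self._nbits) - 1

    def finish(self) -> Bitstream:
        buf = bytearray(self._buf)
        if self._nbits:
            buf.append((self._acc << (8 - self._nbits)) & 0xFF)
        return Bitstream(bytes(buf), self._total)


class BitReader:
    """Reads bits MSB-first from a packed buffer."""

    def __init__(self, data: bytes, bit_count: int | None = None):
        self._data = data
        self._bit_count = len(data) * 8 if bit_count is None else bit_count
        self._pos = 0

    @property
    def bits_left(self) -> int:
        return self._bit_count - self._pos

    def read_bit(self) -> int:
        if self._pos >= self._bit_count:
            raise CorruptStreamError("bitstream exhausted")
        byte = self._data[self._pos >> 3]
        bit = (byte >> (7 - (self._pos & 7))) & 1
        self._pos += 1
        return bit

    def read_bits(self, nbits: int) -> int:
        value = 0
        for _ in range(nbits):
            value = (value << 1) | self.read_bit()
        return value


# ---------------------------------------------------------------------------
# run-length encoding
# ---------------------------------------------------------------------------

Run = tuple[object, int]


def rle_encode(tokens: Sequence) -> list[Run]:
    """Collapse a token sequence into (value, count) runs.

    Adjacent runs always hold distinct values and the counts sum to the
    input length, so :func:`rle_decode` inverts exactly.
    """
    runs: list[list] = []
    for t in tokens:
        if runs and runs[-1][0] == t:
            runs[-1][1] += 1
        else:
            runs.append([t, 1])
    return [(v, c) for v, c in runs]


def rle_decode(runs: Iterable[Run]) -> list:
    out: list = []
    for value, count in runs:
        if count <= 0:
            raise CorruptStreamError(f"non-positive run count {count}")
        out.extend([value] * count)
    return out


# ---------------------------------------------------------------------------
# delta encoding
# ---------------------------------------------------------------------------


def delta_encode(values: Sequence[int]) -> tuple[int | None, list[int]]:
    """Return (first value, successive differences); (None, []) for empty input."""
    if not values:
        return None, []
    return values[0], [b - a for a, b in zip(values, values[1:])]


def delta_decode(first: int | None, diffs: Sequence[int]) -> list[int]:
    if first is None:
        if diffs:
            raise CorruptStreamError("diffs present without a first value")
        return []
    out = [first]
    acc = first
    for d in diffs:
        acc += d
        out.append(acc)
    return out


# ---------------------------------------------------------------------------
# canonical Huffman
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodecTable:
    """A canonical Huffman code described solely by per-symbol code lengths.

    Canonical codes are reconstructable from the lengths alone: symbols are
    sorted by (length, symbol) and assigned consecutive codewords, so only
    the length table needs to be serialized alongside a stream.
    """

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise EncodingError("empty code table")
        kraft = 0.0
        for sym, ln in self.lengths.items():
            if ln <= 0:
                raise EncodingError(f"non-positive code length for {sym!r}")
            kraft += 2.0 ** -ln
        if kraft > 1.0 + 1e-9:
            raise EncodingError(f"code lengths violate the Kraft inequality ({kraft:.4f} > 1)")

    def canonical_codes(self) -> dict[str, tuple[int, int]]:
        """Map each symbol to its (codeword, length) pair."""
        ordered = sorted(self.lengths, key=lambda s: (self.lengths[s], s))
        codes: dict[str, tuple[int, int]] = {}
        code = 0
        prev_len = self.lengths[ordered[0]]
        for i, sym in enumerate(ordered):
            ln = self.lengths[sym]
            if i:
                code = (code + 1) << (ln - prev_len)
            codes[sym] = (code, ln)
            prev_len = ln
        return codes


def huffman_build(freqs: Mapping[str, int]) -> CodecTable:
    """Build a canonical Huffman table from symbol counts.

    Ties during tree construction are broken deterministically by insertion
    order over lexicographically sorted symbols. A single-symbol alphabet is
    assigned a 1-bit code so decode framing stays uniform.
    """
    items = [(sym, count) for sym, count in freqs.items() if count > 0]
    if not items:
        raise EncodingError("huffman_build requires at least one positive count")
    if any(count < 0 for _, count in freqs.items()):
        raise EncodingError("negative symbol count")
    if len(items) == 1:
        return CodecTable({items[0][0]: 1})

    lengths = {sym: 0 for sym, _ in items}
    heap: list[tuple[int, int, list[str]]] = []
    seq = 0
    for sym, count in sorted(items):
        heap.append((count, seq, [sym]))
        seq += 1
    heapq.heapify(heap)
    while len(heap) > 1:
        w1, _, s1 = heapq.heappop(heap)
        w2, _, s2 = heapq.heappop(heap)
        for sym in s1:
            lengths[sym] += 1
        for sym in s2:
            lengths[sym] += 1
        heapq.heappush(heap, (w1 + w2, seq, s1 + s2))
        seq += 1
    return CodecTable(lengths)


def huffman_encode(tokens: Iterable[str], table: CodecTable) -> Bitstream:
    codes = table.canonical_codes()
    writer = BitWriter()
    for t in tokens:
        try:
            code, ln = codes[t]
        except KeyError:
            raise EncodingError(f"token {t!r} absent from code table") from None
        writer.write_bits(code, ln)
    return writer.finish()


class CanonicalDecoder:
    """Incremental decoder for one canonical code table.

    Usable on a shared :class:`BitReader` so that streams interleaving
    symbols from several tables (e.g. TAG then VTYPE) decode in lockstep.
    """

    def __init__(self, table: CodecTable):
        self._by_len: dict[int, dict[int, str]] = {}
        for sym, (code, ln) in table.canonical_codes().items():
            self._by_len.setdefault(ln, {})[code] = sym
        self._max_len = max(self._by_len)

    def decode_one(self, reader: BitReader) -> str:
        code = 0
        for ln in range(1, self._max_len + 1):
            code = (code << 1) | reader.read_bit()
            bucket = self._by_len.get(ln)
            if bucket is not None and code in bucket:
                return bucket[code]
        raise CorruptStreamError("bit pattern matches no codeword")


def huffman_decode(bits: Bitstream, table: CodecTable, n: int) -> list[str]:
    reader = BitReader(bits.data, bits.bit_count)
    decoder = CanonicalDecoder(table)
    return [decoder.decode_one(reader) for _ in range(n)]


# ---------------------------------------------------------------------------
# 2-bit nucleotide packing
# ---------------------------------------------------------------------------

_BASE_TO_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_BITS_TO_BASE = "ACGT"


def pack_2bit(seq: str) -> Bitstream:
    """Pack an A/C/G/T string at 2 bits per base (A=00, C=01, G=10, T=11)."""
    writer = BitWriter()
    for ch in seq:
        try:
            writer.write_bits(_BASE_TO_BITS[ch], 2)
        except KeyError:
            raise EncodingError(f"character {ch!r} outside the ACGT alphabet") from None
    return writer.finish()


def unpack_2bit(bits: Bitstream, n: int) -> str:
    if bits.bit_count < 2 * n:
        raise CorruptStreamError(f"2-bit stream holds {bits.bit_count} bits, need {2 * n}")
    reader = BitReader(bits.data, bits.bit_count)
    return "".join(_BITS_TO_BASE[reader.read_bits(2)] for _ in range(n))
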