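"""Per-field encoding strategies.

Each of the 12 SAM columns gets a codec matched to its empirical statistics:

* QNAME — read names share a fixed template; only the embedded counters vary,
  and those are delta-coded column-wise.
* FLAG / RNAME / MAPQ / CIGAR / MPOS — heavily repetitive token streams,
  run-length coded over whole values.
* POS — sorted files show small, repetitive position increments: delta
  coding followed by run-length coding of the diffs.
* MRNM — usually just "=" or "*": a 1-bit-per-record bitmap.
* ISIZE — most files carry a constant 0: stored as a zero-byte constant mode.
* SEQ — A/C/G/T packed at 2 bits per base, with rare N positions excised
  into a sidecar stream.
* QUAL — run-length coded character-wise across the concatenated records.
* TAGS — TAG and VTYPE codes come from tiny alphabets and are Huffman coded;
  VALUE bytes are kept verbatim.

Every encoder is guarded: a representation is only used when it both
round-trips exactly and is no larger than the raw column; otherwise the
column falls back to verbatim text. The worst case is therefore the raw
column plus a small fixed stream header.
"""

from __future__ import annotations

import re
import struct
import zlib
from dataclasses import dataclass

from . import codecs
from .codecs import ByteReader, varint_encode, zigzag_decode, zigzag_encode
from .errors import CorruptContainerError, CorruptStreamError
from .sam_io import MANDATORY_FIELDS, TAGS_COLUMN, OptionalField

# --- stream identities ------------------------------------------------------

FIELD_IDS = {
    "HEADER": 0,
    "QNAME": 1,
    "FLAG": 2,
    "RNAME": 3,
    "POS": 4,
    "MAPQ": 5,
    "CIGAR": 6,
    "MRNM": 7,
    "MPOS": 8,
    "ISIZE": 9,
    "SEQ": 10,
    "QUAL": 11,
    "TAGS": 12,
    "SEQN": 13,  # sidecar holding N positions excised from SEQ
}
FIELD_NAMES = {v: k for k, v in FIELD_IDS.items()}

# codec ids
RAW = 0
RLE_TOKEN = 1
RLE_CHAR = 2
DELTA_RLE = 3
QNAME_TEMPLATE = 4
MRNM_BITMAP = 5
CONST_ZERO = 6
SEQ_2BIT = 7
N_SIDECAR = 8
TAGS_HUFF = 9

CODEC_NAMES = {
    RAW: "raw",
    RLE_TOKEN: "rle",
    RLE_CHAR: "rle-char",
    DELTA_RLE: "delta+rle",
    QNAME_TEMPLATE: "template",
    MRNM_BITMAP: "bitmap",
    CONST_ZERO: "const-zero",
    SEQ_2BIT: "2bit",
    N_SIDECAR: "n-sidecar",
    TAGS_HUFF: "huffman",
}

#: serialized stream header is at most this many bytes beyond params+payload
#: (2 id bytes + flag + two 5-byte length varints + 4-byte CRC)
STREAM_OVERHEAD_BOUND = 17

_INT63 = 1 << 63


@dataclass(frozen=True)
class EncodedStream:
    """One field's encoded column: codec id, parameter block and payload."""

    field_id: int
    codec_id: int
    fallback: bool
    params: bytes
    payload: bytes
    n_records: int

    @property
    def size(self) -> int:
        return len(self.params) + len(self.payload)


# --- raw (verbatim) representation -----------------------------------------


def _raw_join(values: list[str]) -> bytes:
    return "\n".join(values).encode("latin-1")


def _raw_split(payload: bytes, n: int) -> list[str]:
    if n == 0:
        if payload:
            raise CorruptStreamError("raw stream with 0 records has payload")
        return []
    values = payload.decode("latin-1").split("\n")
    if len(values) != n:
        raise CorruptStreamError(f"raw stream holds {len(values)} values, expected {n}")
    return values


def _render_tags(group: tuple[OptionalField, ...]) -> str:
    return "\t".join(f.render() for f in group)


def _parse_tag_text(text: str) -> tuple[OptionalField, ...]:
    if not text:
        return ()
    out = []
    for tok in text.split("\t"):
        tag, vtype, value = tok.split(":", 2)
        out.append(OptionalField(tag, vtype, value))
    return tuple(out)


def _raw_stream(field_name: str, column: list) -> EncodedStream:
    if field_name == TAGS_COLUMN:
        payload = _raw_join([_render_tags(g) for g in column])
    else:
        payload = _raw_join(column)
    return EncodedStream(FIELD_IDS[field_name], RAW, True, b"", payload, len(column))


def _guarded(field_name: str, column: list, candidate: EncodedStream) -> EncodedStream:
    """Return the candidate unless raw text would be at least as small."""
    raw = _raw_stream(field_name, column)
    return candidate if candidate.size < len(raw.payload) else raw


# --- token RLE (FLAG, RNAME, MAPQ, CIGAR, MPOS) and char RLE (QUAL) --------


def encode_rle_text(column: list[str], field_name: str) -> EncodedStream:
    """Run-length code a column, over whole values or (for QUAL) characters.

    Serialized as ``varint(n_runs)`` then per run ``varint(count),
    varint(len(value)), value``; the character variant prefixes per-record
    lengths so record boundaries are recoverable. Falls back to raw text
    whenever RLE would not be strictly smaller.
    """
    if field_name == "QUAL":
        return _encode_rle_char(column, field_name)
    runs = codecs.rle_encode(column)
    out = bytearray(varint_encode(len(runs)))
    for value, count in runs:
        vb = value.encode("latin-1")
        out += varint_encode(count)
        out += varint_encode(len(vb))
        out += vb
    candidate = EncodedStream(
        FIELD_IDS[field_name], RLE_TOKEN, False, b"", bytes(out), len(column)
    )
    return _guarded(field_name, column, candidate)


def _decode_rle_token(stream: EncodedStream) -> list[str]:
    r = ByteReader(stream.payload)
    n_runs = r.read_varint()
    runs = []
    for _ in range(n_runs):
        count = r.read_varint()
        vlen = r.read_varint()
        runs.append((r.read(vlen).decode("latin-1"), count))
    values = codecs.rle_decode(runs)
    if len(values) != stream.n_records:
        raise CorruptStreamError(
            f"RLE stream expands to {len(values)} values, expected {stream.n_records}"
        )
    return values


def _encode_rle_char(column: list[str], field_name: str) -> EncodedStream:
    # record boundaries carried as explicit per-record lengths, so runs may
    # span records without ambiguity
    out = bytearray()
    for v in column:
        out += varint_encode(len(v))
    runs = codecs.rle_encode("".join(column))
    out += varint_encode(len(runs))
    for ch, count in runs:
        out += varint_encode(count)
        out += ch.encode("latin-1")
    candidate = EncodedStream(
        FIELD_IDS[field_name], RLE_CHAR, False, b"", bytes(out), len(column)
    )
    return _guarded(field_name, column, candidate)


def _decode_rle_char(stream: EncodedStream) -> list[str]:
    r = ByteReader(stream.payload)
    lengths = [r.read_varint() for _ in range(stream.n_records)]
    n_runs = r.read_varint()
    runs = []
    for _ in range(n_runs):
        count = r.read_varint()
        runs.append((r.read(1).decode("latin-1"), count))
    chars = codecs.rle_decode(runs)
    if len(chars) != sum(lengths):
        raise CorruptStreamError("character RLE length mismatch")
    text = "".join(chars)
    out, pos = [], 0
    for ln in lengths:
        out.append(text[pos : pos + ln])
        pos += ln
    return out


# --- POS / ISIZE integer paths ---------------------------------------------


def _canonical_ints(column: list[str], signed: bool) -> list[int] | None:
    """Parse a column as integers whose re-rendering is byte-identical."""
    values = []
    for v in column:
        try:
            i = int(v)
        except ValueError:
            return None
        if str(i) != v or (not signed and i < 0) or not -_INT63 <= i < _INT63:
            return None
        values.append(i)
    return values


def _delta_rle_payload(values: list[int]) -> bytes:
    first, diffs = codecs.delta_encode(values)
    out = bytearray()
    if first is None:
        return bytes(out)
    out += varint_encode(zigzag_encode(first))
    runs = codecs.rle_encode(diffs)
    out += varint_encode(len(runs))
    for diff, count in runs:
        out += varint_encode(count)
        out += varint_encode(zigzag_encode(diff))
    return bytes(out)


def _decode_delta_rle(stream: EncodedStream) -> list[str]:
    if stream.n_records == 0:
        if stream.payload:
            raise CorruptStreamError("delta stream with 0 records has payload")
        return []
    r = ByteReader(stream.payload)
    first = zigzag_decode(r.read_varint())
    n_runs = r.read_varint()
    runs = []
    for _ in range(n_runs):
        count = r.read_varint()
        runs.append((zigzag_decode(r.read_varint()), count))
    diffs = codecs.rle_decode(runs)
    values = codecs.delta_decode(first, diffs)
    if len(values) != stream.n_records:
        raise CorruptStreamError(
            f"delta stream expands to {len(values)} values, expected {stream.n_records}"
        )
    return [str(v) for v in values]


def encode_pos(column: list[str]) -> EncodedStream:
    """Delta-code sorted positions, then run-length code the increments.

    Requires every value to be a canonically rendered non-negative integer;
    otherwise (e.g. a leading zero, whose text would not survive int
    round-tripping) the column falls back to raw.
    """
    values = _canonical_ints(column, signed=False)
    if values is None:
        return _raw_stream("POS", column)
    candidate = EncodedStream(
        FIELD_IDS["POS"], DELTA_RLE, False, b"", _delta_rle_payload(values), len(column)
    )
    return _guarded("POS", column, candidate)


def encode_isize(column: list[str]) -> EncodedStream:
    """Insert sizes: constant-zero mode, else signed delta+RLE, else RLE, else raw."""
    n = len(column)
    if all(v == "0" for v in column):
        return EncodedStream(FIELD_IDS["ISIZE"], CONST_ZERO, False, b"", b"", n)
    raw_size = len(_raw_join(column))
    values = _canonical_ints(column, signed=True)
    if values is not None:
        payload = _delta_rle_payload(values)
        if len(payload) < raw_size:
            return EncodedStream(FIELD_IDS["ISIZE"], DELTA_RLE, False, b"", payload, n)
    rle = encode_rle_text(column, "ISIZE")
    return rle  # encode_rle_text already falls back to raw on expansion


# --- MRNM -------------------------------------------------------------------


def encode_mrnm(column: list[str]) -> EncodedStream:
    """Mate reference name: 1 bit per record when the column is all '='/'*'.

    '=' maps to bit 0 (it dominates in coordinate-sorted paired files) and
    '*' to bit 1; any other value routes the column to token RLE.
    """
    if all(v in ("=", "*") for v in column):
        writer = codecs.BitWriter()
        for v in column:
            writer.write_bits(0 if v == "=" else 1, 1)
        bits = writer.finish()
        candidate = EncodedStream(
            FIELD_IDS["MRNM"], MRNM_BITMAP, False, b"", bits.data, len(column)
        )
        return _guarded("MRNM", column, candidate)
    return encode_rle_text(column, "MRNM")


def _decode_mrnm_bitmap(stream: EncodedStream) -> list[str]:
    reader = codecs.BitReader(stream.payload, bit_count=stream.n_records)
    return ["*" if reader.read_bit() else "=" for _ in range(stream.n_records)]


# --- QNAME ------------------------------------------------------------------

_QNAME_TOKEN = re.compile(r"\d+|\D+")

_SLOT_DELTA = 0  # canonical integers, no leading zeros
_SLOT_FIXED = 1  # constant digit width, leading zeros preserved by zero-fill
_SLOT_RAW = 2  # verbatim digit strings


def _qname_tokenize(name: str) -> list[str]:
    return _QNAME_TOKEN.findall(name)


def encode_qname(column: list[str]) -> EncodedStream:
    """Factor read names into a shared template plus per-record counters.

    Names are tokenized into alternating digit / non-digit runs. When every
    record shares the same non-digit skeleton, that skeleton is stored once
    and each digit slot becomes an integer column, delta-coded with zigzag
    varints. Constant-width slots preserve leading zeros by zero-filling;
    slots that cannot be represented as integers exactly are stored as raw
    digit text. Records with diverging skeletons force raw fallback for the
    whole column.
    """
    n = len(column)
    if n == 0:
        return _raw_stream("QNAME", column)

    token_rows = [_qname_tokenize(name) for name in column]
    shape = [(tok.isdigit(), tok) for tok in token_rows[0]]
    for row in token_rows[1:]:
        if len(row) != len(shape):
            return _raw_stream("QNAME", column)
        for (is_digit, text), tok in zip(shape, row):
            if tok.isdigit() != is_digit or (not is_digit and tok != text):
                return _raw_stream("QNAME", column)

    params = bytearray(varint_encode(len(shape)))
    slots: list[int] = []
    for idx, (is_digit, text) in enumerate(shape):
        if is_digit:
            params.append(1)
            slots.append(idx)
        else:
            tb = text.encode("latin-1")
            params.append(0)
            params += varint_encode(len(tb))
            params += tb

    payload = bytearray()
    for idx in slots:
        texts = [row[idx] for row in token_rows]
        ints = [int(t) for t in texts]
        widths = {len(t) for t in texts}
        canonical = all(str(i) == t for i, t in zip(ints, texts))
        in_range = all(i < _INT63 for i in ints)
        if canonical and in_range:
            payload.append(_SLOT_DELTA)
            payload += _delta_rle_payload(ints)
        elif len(widths) == 1 and in_range:
            payload.append(_SLOT_FIXED)
            payload += varint_encode(widths.pop())
            payload += _delta_rle_payload(ints)
        else:
            blob = _raw_join(texts)
            payload.append(_SLOT_RAW)
            payload += varint_encode(len(blob))
            payload += blob

    candidate = EncodedStream(
        FIELD_IDS["QNAME"], QNAME_TEMPLATE, False, bytes(params), bytes(payload), n
    )
    return _guarded("QNAME", column, candidate)


def _decode_qname(stream: EncodedStream) -> list[str]:
    n = stream.n_records
    p = ByteReader(stream.params)
    n_tokens = p.read_varint()
    template: list[str | None] = []  # None marks a digit slot
    for _ in range(n_tokens):
        kind = p.read_byte()
        if kind == 0:
            ln = p.read_varint()
            template.append(p.read(ln).decode("latin-1"))
        else:
            template.append(None)

    r = ByteReader(stream.payload)
    slot_texts: list[list[str]] = []
    for _ in [t for t in template if t is None]:
        mode = r.read_byte()
        if mode == _SLOT_RAW:
            ln = r.read_varint()
            slot_texts.append(_raw_split(r.read(ln), n))
            continue
        width = r.read_varint() if mode == _SLOT_FIXED else None
        # delta payload is self-delimiting; decode in place
        if n:
            first = zigzag_decode(r.read_varint())
            n_runs = r.read_varint()
            runs = []
            for _ in range(n_runs):
                count = r.read_varint()
                runs.append((zigzag_decode(r.read_varint()), count))
            ints = codecs.delta_decode(first, codecs.rle_decode(runs))
        else:
            ints = []
        if len(ints) != n:
            raise CorruptStreamError("QNAME slot length mismatch")
        if width is None:
            slot_texts.append([str(i) for i in ints])
        else:
            slot_texts.append([str(i).zfill(width) for i in ints])

    names = []
    for i in range(n):
        parts = []
        slot_no = 0
        for t in template:
            if t is None:
                parts.append(slot_texts[slot_no][i])
                slot_no += 1
            else:
                parts.append(t)
        names.append("".join(parts))
    return names


# --- SEQ --------------------------------------------------------------------

_SEQ_ALPHABET = frozenset("ACGTN")


def encode_seq(column: list[str]) -> tuple[EncodedStream, EncodedStream]:
    """Pack ACGT bases at 2 bits each; N positions go to a sidecar stream.

    The base stream stores per-record lengths (varints) followed by the
    packed bases; the sidecar stores each N occurrence as a (record-index
    delta, position delta) varint pair. Any character outside the ACGTN
    alphabet — including the ``*`` placeholder — forces raw fallback for the
    whole column, the scheme's stated limitation.
    """
    n = len(column)
    empty_sidecar = EncodedStream(FIELD_IDS["SEQN"], N_SIDECAR, False, b"", b"", n)
    if any(set(seq) - _SEQ_ALPHABET for seq in column):
        return _raw_stream("SEQ", column), empty_sidecar

    payload = bytearray()
    for seq in column:
        payload += varint_encode(len(seq))
    sidecar = bytearray()
    n_positions = 0
    prev_rec, prev_pos = 0, -1
    acgt_parts = []
    for rec_idx, seq in enumerate(column):
        for pos, ch in enumerate(seq):
            if ch == "N":
                dr = rec_idx - prev_rec
                dp = pos - prev_pos if dr == 0 else pos
                sidecar += varint_encode(dr)
                sidecar += varint_encode(dp)
                prev_rec, prev_pos = rec_idx, pos
                n_positions += 1
        acgt_parts.append(seq.replace("N", ""))
    bits = codecs.pack_2bit("".join(acgt_parts))
    payload += bits.data

    base = EncodedStream(FIELD_IDS["SEQ"], SEQ_2BIT, False, b"", bytes(payload), n)
    side = EncodedStream(
        FIELD_IDS["SEQN"],
        N_SIDECAR,
        False,
        varint_encode(n_positions),
        bytes(sidecar),
        n,
    )
    raw_size = len(_raw_join(column))
    if base.size + side.size >= raw_size:
        return _raw_stream("SEQ", column), empty_sidecar
    return base, side


def _decode_seq(base: EncodedStream, sidecar: EncodedStream) -> list[str]:
    n = base.n_records
    if base.codec_id == RAW:
        return _raw_split(base.payload, n)
    if sidecar.codec_id != N_SIDECAR:
        raise CorruptContainerError("SEQ stream without its N-position sidecar")
    r = ByteReader(base.payload)
    lengths = [r.read_varint() for _ in range(n)]

    n_positions = ByteReader(sidecar.params).read_varint() if sidecar.params else 0
    sr = ByteReader(sidecar.payload)
    n_sites: dict[int, list[int]] = {}
    prev_rec, prev_pos = 0, -1
    for _ in range(n_positions):
        dr = sr.read_varint()
        dp = sr.read_varint()
        rec = prev_rec + dr
        pos = (prev_pos + dp) if dr == 0 else dp
        n_sites.setdefault(rec, []).append(pos)
        prev_rec, prev_pos = rec, pos

    total_acgt = sum(lengths) - n_positions
    packed = base.payload[r.pos :]
    bases = codecs.unpack_2bit(
        codecs.Bitstream(packed, len(packed) * 8), total_acgt
    )
    out, cursor = [], 0
    for rec_idx, ln in enumerate(lengths):
        sites = set(n_sites.get(rec_idx, ()))
        chars = []
        for pos in range(ln):
            if pos in sites:
                chars.append("N")
            else:
                chars.append(bases[cursor])
                cursor += 1
        out.append("".join(chars))
    if cursor != total_acgt:
        raise CorruptStreamError("SEQ base stream length mismatch")
    return out


# --- TAGS -------------------------------------------------------------------


def _serialize_table(table: codecs.CodecTable | None, sym_width: int) -> bytes:
    if table is None:
        return varint_encode(0)
    out = bytearray(varint_encode(len(table.lengths)))
    for sym in sorted(table.lengths):
        sb = sym.encode("latin-1")
        if len(sb) != sym_width:
            raise CorruptStreamError(f"symbol {sym!r} is not {sym_width} bytes")
        out += sb
        out.append(table.lengths[sym])
    return bytes(out)


def _parse_table(r: ByteReader, sym_width: int) -> codecs.CodecTable | None:
    n_syms = r.read_varint()
    if n_syms == 0:
        return None
    lengths = {}
    for _ in range(n_syms):
        sym = r.read(sym_width).decode("latin-1")
        lengths[sym] = r.read_byte()
    return codecs.CodecTable(lengths)


def encode_tags(column: list[tuple[OptionalField, ...]]) -> EncodedStream:
    """Huffman-code TAG and VTYPE symbols; keep VALUE bytes verbatim.

    TAG (2 characters) and VTYPE (1 character) come from small fixed
    repertoires, so per-file canonical Huffman tables — serialized as code
    lengths in the parameter block — code them in a few bits each. The
    payload carries per-record tag counts, the interleaved TAG/VTYPE
    bitstream, then each VALUE as length-prefixed bytes, preserving order.
    """
    n = len(column)
    all_tags = [f for group in column for f in group]
    tag_freqs: dict[str, int] = {}
    vtype_freqs: dict[str, int] = {}
    for f in all_tags:
        tag_freqs[f.tag] = tag_freqs.get(f.tag, 0) + 1
        vtype_freqs[f.vtype] = vtype_freqs.get(f.vtype, 0) + 1

    tag_table = codecs.huffman_build(tag_freqs) if tag_freqs else None
    vtype_table = codecs.huffman_build(vtype_freqs) if vtype_freqs else None
    params = _serialize_table(tag_table, 2) + _serialize_table(vtype_table, 1)

    writer = codecs.BitWriter()
    if all_tags:
        tag_codes = tag_table.canonical_codes()
        vtype_codes = vtype_table.canonical_codes()
        for f in all_tags:
            code, ln = tag_codes[f.tag]
            writer.write_bits(code, ln)
            code, ln = vtype_codes[f.vtype]
            writer.write_bits(code, ln)
    bits = writer.finish()

    payload = bytearray()
    for group in column:
        payload += varint_encode(len(group))
    payload += varint_encode(bits.bit_count)
    payload += bits.data
    for f in all_tags:
        vb = f.value.encode("latin-1")
        payload += varint_encode(len(vb))
        payload += vb

    candidate = EncodedStream(
        FIELD_IDS["TAGS"], TAGS_HUFF, False, params, bytes(payload), n
    )
    return _guarded(TAGS_COLUMN, column, candidate)


def _decode_tags(stream: EncodedStream) -> list[tuple[OptionalField, ...]]:
    if stream.codec_id == RAW:
        return [_parse_tag_text(t) for t in _raw_split(stream.payload, stream.n_records)]
    p = ByteReader(stream.params)
    tag_table = _parse_table(p, 2)
    vtype_table = _parse_table(p, 1)

    r = ByteReader(stream.payload)
    counts = [r.read_varint() for _ in range(stream.n_records)]
    total = sum(counts)
    bit_count = r.read_varint()
    bit_bytes = r.read((bit_count + 7) // 8)

    pairs: list[tuple[str, str]] = []
    if total:
        if tag_table is None or vtype_table is None:
            raise CorruptStreamError("tag stream has symbols but no code table")
        reader = codecs.BitReader(bit_bytes, bit_count)
        tag_dec = codecs.CanonicalDecoder(tag_table)
        vtype_dec = codecs.CanonicalDecoder(vtype_table)
        for _ in range(total):
            pairs.append((tag_dec.decode_one(reader), vtype_dec.decode_one(reader)))

    values = []
    for _ in range(total):
        ln = r.read_varint()
        values.append(r.read(ln).decode("latin-1"))

    out, cursor = [], 0
    for c in counts:
        group = tuple(
            OptionalField(pairs[cursor + j][0], pairs[cursor + j][1], values[cursor + j])
            for j in range(c)
        )
        cursor += c
        out.append(group)
    return out


# --- column-level dispatch --------------------------------------------------


def encode_column(field_name: str, column: list) -> list[EncodedStream]:
    """Encode one column with its field-appropriate strategy.

    Returns one stream, except for SEQ which yields its base stream plus the
    N-position sidecar. Encoders see only their own column, keeping fields
    independently processable.
    """
    if field_name == "QNAME":
        return [encode_qname(column)]
    if field_name in ("FLAG", "RNAME", "MAPQ", "CIGAR", "MPOS", "QUAL"):
        return [encode_rle_text(column, field_name)]
    if field_name == "POS":
        return [encode_pos(column)]
    if field_name == "MRNM":
        return [encode_mrnm(column)]
    if field_name == "ISIZE":
        return [encode_isize(column)]
    if field_name == "SEQ":
        return list(encode_seq(column))
    if field_name == TAGS_COLUMN:
        return [encode_tags(column)]
    raise ValueError(f"unknown field {field_name!r}")


def encode_fields(columns: dict[str, list]) -> list[EncodedStream]:
    """Encode all 12 columns into their streams, in canonical field order."""
    streams: list[EncodedStream] = []
    for name in (*MANDATORY_FIELDS, TAGS_COLUMN):
        streams.extend(encode_column(name, columns[name]))
    return streams


def decode_field(streams: list[EncodedStream]) -> list:
    """Decode one field's stream(s) back to its column (exact inverse)."""
    primary = streams[0]
    name = FIELD_NAMES.get(primary.field_id)
    if name is None:
        raise CorruptContainerError(f"unknown field id {primary.field_id}")
    if name == "SEQ":
        if len(streams) != 2:
            raise CorruptContainerError("SEQ requires base + sidecar streams")
        return _decode_seq(streams[0], streams[1])
    if len(streams) != 1:
        raise CorruptContainerError(f"field {name} expects a single stream")
    if name == "TAGS":
        return _decode_tags(primary)

    codec = primary.codec_id
    if codec == RAW:
        return _raw_split(primary.payload, primary.n_records)
    if codec == RLE_TOKEN:
        return _decode_rle_token(primary)
    if codec == RLE_CHAR:
        return _decode_rle_char(primary)
    if codec == DELTA_RLE:
        return _decode_delta_rle(primary)
    if codec == QNAME_TEMPLATE:
        return _decode_qname(primary)
    if codec == MRNM_BITMAP:
        return _decode_mrnm_bitmap(primary)
    if codec == CONST_ZERO:
        if primary.payload:
            raise CorruptStreamError("constant-zero stream has payload")
        return ["0"] * primary.n_records
    raise CorruptContainerError(f"unknown codec id {codec} for field {name}")


def decode_fields(streams: list[EncodedStream]) -> dict[str, list]:
    """Decode a full stream set back into the 12 columns.

    Streams must agree on the record count; a disagreement means the
    container was assembled from mismatched parts and is rejected.
    """
    n_counts = {s.n_records for s in streams}
    if len(n_counts) > 1:
        raise CorruptContainerError(f"streams disagree on record count: {sorted(n_counts)}")
    by_field: dict[int, list[EncodedStream]] = {}
    for s in streams:
        by_field.setdefault(s.field_id, []).append(s)

    columns: dict[str, list] = {}
    for name in MANDATORY_FIELDS:
        fid = FIELD_IDS[name]
        if fid not in by_field:
            raise CorruptContainerError(f"missing stream for field {name}")
        if name == "SEQ":
            side = by_field.get(FIELD_IDS["SEQN"])
            if side is None:
                raise CorruptContainerError("missing SEQ sidecar stream")
            columns[name] = decode_field(by_field[fid] + side)
        else:
            columns[name] = decode_field(by_field[fid])
    tags_id = FIELD_IDS["TAGS"]
    if tags_id not in by_field:
        raise CorruptContainerError("missing TAGS stream")
    columns[TAGS_COLUMN] = decode_field(by_field[tags_id])
    return columns


# --- stream framing ---------------------------------------------------------


def serialize_stream(stream: EncodedStream) -> bytes:
    """Frame a stream: ids, flag, length-prefixed params and payload, CRC32."""
    out = bytearray()
    out.append(stream.field_id)
    out.append(stream.codec_id)
    out.append(1 if stream.fallback else 0)
    out += varint_encode(len(stream.params))
    out += stream.params
    out += varint_encode(len(stream.payload))
    out += stream.payload
    out += struct.pack(">I", zlib.crc32(stream.payload))
    return bytes(out)


def parse_stream(r: ByteReader, n_records: int) -> EncodedStream:
    field_id = r.read_byte()
    codec_id = r.read_byte()
    fallback = bool(r.read_byte())
    params = r.read(r.read_varint())
    payload = r.read(r.read_varint())
    (crc,) = struct.unpack(">I", r.read(4))
    if crc != zlib.crc32(payload):
        name = FIELD_NAMES.get(field_id, str(field_id))
        raise CorruptContainerError(f"CRC mismatch in stream for field {name}")
    return EncodedStream(field_id, codec_id, fallback, params, payload, n_records)
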