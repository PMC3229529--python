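"""Archive framing and the general-purpose post-compression stage.

The encoded field streams are intentionally left "moderately" compressed:
the design splits the work into a fast specialized pre-coder and a
best-effort general-purpose compressor run on the encoded output. Two
layouts are supported:

* single-file ``.smz`` container (the default): all framed streams are
  concatenated and the selected backend (none / DEFLATE / bzip2 / LZMA)
  compresses the whole body;
* a directory of per-field ``.smzf`` files, one per field, mirroring the
  original workflow where an external tool compresses the per-field files.

A raw mode stores a file verbatim (still post-compressed) for inputs the
columnar model cannot represent, e.g. mixed newline conventions.
"""

from __future__ import annotations

import bz2
import lzma
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from .codecs import ByteReader, varint_encode
from .errors import CorruptContainerError, CorruptStreamError, SamzipError
from .fields import (
    FIELD_IDS,
    FIELD_NAMES,
    EncodedStream,
    parse_stream,
    serialize_stream,
)

MAGIC = b"SMZ1"
FIELD_MAGIC = b"SMZF"
VERSION = 1

_FLAG_RAW_FILE = 0x10

BACKENDS = {"none": 0, "deflate": 1, "bzip2": 2, "lzma": 3}
BACKEND_NAMES = {v: k for k, v in BACKENDS.items()}

#: directory-mode file stem for each field id
FIELD_FILENAMES = {fid: name.lower() for name, fid in FIELD_IDS.items()}


def _post_compress(body: bytes, backend: str) -> bytes:
    if backend == "none":
        return body
    if backend == "deflate":
        return zlib.compress(body, 9)
    if backend == "bzip2":
        return bz2.compress(body, 9)
    if backend == "lzma":
        return lzma.compress(body, preset=6)
    raise SamzipError(f"unknown post-compression backend {backend!r}")


def _post_decompress(body: bytes, backend: str) -> bytes:
    try:
        if backend == "none":
            return body
        if backend == "deflate":
            return zlib.decompress(body)
        if backend == "bzip2":
            return bz2.decompress(body)
        if backend == "lzma":
            return lzma.decompress(body)
    except Exception as exc:
        raise CorruptContainerError(f"post-compression stage failed to invert: {exc}") from exc
    raise CorruptContainerError(f"unknown backend id in container: {backend!r}")


@dataclass
class ContainerContent:
    """Everything needed to reconstruct the original SAM bytes."""

    n_records: int = 0
    newline: bytes = b"\n"
    trailing_newline: bool = False
    header_blob: bytes = b""
    streams: list[EncodedStream] = field(default_factory=list)
    backend: str = "deflate"
    raw_file: bytes | None = None  # set when the whole file is stored verbatim


def _encode_body(content: ContainerContent) -> bytes:
    body = bytearray()
    body += varint_encode(content.n_records)
    body.append(1 if content.newline == b"\r\n" else 0)
    body.append(1 if content.trailing_newline else 0)
    body += varint_encode(len(content.header_blob))
    body += content.header_blob
    body += varint_encode(len(content.streams))
    for stream in content.streams:
        body += serialize_stream(stream)
    return bytes(body)


def write_container(content: ContainerContent) -> bytes:
    """Serialize to the single-file layout with a whole-file CRC32 trailer."""
    if content.backend not in BACKENDS:
        raise SamzipError(f"unknown post-compression backend {content.backend!r}")
    flags = BACKENDS[content.backend]
    if content.raw_file is not None:
        flags |= _FLAG_RAW_FILE
        body = content.raw_file
    else:
        body = _encode_body(content)
    compressed = _post_compress(body, content.backend)
    out = bytearray(MAGIC)
    out.append(VERSION)
    out.append(flags)
    out += varint_encode(len(compressed))
    out += compressed
    out += struct.pack(">I", zlib.crc32(bytes(out)))
    return bytes(out)


def read_container(blob: bytes) -> ContainerContent:
    """Parse and verify a single-file container (exact inverse of write)."""
    try:
        return _read_container_inner(blob)
    except CorruptContainerError:
        raise
    except CorruptStreamError as exc:
        raise CorruptContainerError(f"container truncated or malformed: {exc}") from exc


def _read_container_inner(blob: bytes) -> ContainerContent:
    if len(blob) < len(MAGIC) + 2:
        raise CorruptContainerError("container truncated before header")
    if blob[: len(MAGIC)] != MAGIC:
        raise CorruptContainerError(f"bad magic {blob[:4]!r}, expected {MAGIC!r}")
    r = ByteReader(blob, len(MAGIC))
    version = r.read_byte()
    if version != VERSION:
        raise CorruptContainerError(f"unsupported container version {version}")
    flags = r.read_byte()
    backend = BACKEND_NAMES.get(flags & 0x03)
    if backend is None:
        raise CorruptContainerError(f"unknown backend id {flags & 0x03}")
    body_len = r.read_varint()
    compressed = r.read(body_len)
    crc_offset = r.pos
    if len(blob) < crc_offset + 4:
        raise CorruptContainerError("container truncated before checksum")
    (crc,) = struct.unpack(">I", blob[crc_offset : crc_offset + 4])
    if crc != zlib.crc32(blob[:crc_offset]):
        raise CorruptContainerError("whole-file CRC mismatch")

    body = _post_decompress(compressed, backend)
    if flags & _FLAG_RAW_FILE:
        return ContainerContent(backend=backend, raw_file=body)

    br = ByteReader(body)
    n_records = br.read_varint()
    newline = b"\r\n" if br.read_byte() else b"\n"
    trailing = bool(br.read_byte())
    header_blob = br.read(br.read_varint())
    n_streams = br.read_varint()
    streams = [parse_stream(br, n_records) for _ in range(n_streams)]
    if not br.at_end():
        raise CorruptContainerError("trailing bytes after final stream")
    return ContainerContent(n_records, newline, trailing, header_blob, streams, backend)


# --- directory (per-field files) layout -------------------------------------


def _frame_field_file(body: bytes, backend: str) -> bytes:
    compressed = _post_compress(body, backend)
    out = bytearray(FIELD_MAGIC)
    out.append(VERSION)
    out.append(BACKENDS[backend])
    out += varint_encode(len(compressed))
    out += compressed
    out += struct.pack(">I", zlib.crc32(bytes(out)))
    return bytes(out)


def _unframe_field_file(blob: bytes, path: Path) -> bytes:
    if blob[: len(FIELD_MAGIC)] != FIELD_MAGIC:
        raise CorruptContainerError(f"{path.name}: bad field-file magic")
    r = ByteReader(blob, len(FIELD_MAGIC))
    version = r.read_byte()
    if version != VERSION:
        raise CorruptContainerError(f"{path.name}: unsupported version {version}")
    backend = BACKEND_NAMES.get(r.read_byte())
    if backend is None:
        raise CorruptContainerError(f"{path.name}: unknown backend id")
    compressed = r.read(r.read_varint())
    if len(blob) < r.pos + 4:
        raise CorruptContainerError(f"{path.name}: truncated before checksum")
    (crc,) = struct.unpack(">I", blob[r.pos : r.pos + 4])
    if crc != zlib.crc32(blob[: r.pos]):
        raise CorruptContainerError(f"{path.name}: CRC mismatch")
    return _post_decompress(compressed, backend)


def write_directory(content: ContainerContent, directory: Path) -> list[Path]:
    """Write one ``.smzf`` file per field plus ``header.smzf`` with metadata."""
    if content.raw_file is not None:
        raise SamzipError("raw-file mode is only supported by the single-file layout")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    meta = bytearray()
    meta += varint_encode(content.n_records)
    meta.append(1 if content.newline == b"\r\n" else 0)
    meta.append(1 if content.trailing_newline else 0)
    meta += varint_encode(len(content.header_blob))
    meta += content.header_blob
    path = directory / "header.smzf"
    path.write_bytes(_frame_field_file(bytes(meta), content.backend))
    written.append(path)

    for stream in content.streams:
        name = FIELD_FILENAMES[stream.field_id]
        path = directory / f"{name}.smzf"
        path.write_bytes(_frame_field_file(serialize_stream(stream), content.backend))
        written.append(path)
    return written


def read_directory(directory: Path) -> ContainerContent:
    directory = Path(directory)
    meta_path = directory / "header.smzf"
    if not meta_path.exists():
        raise CorruptContainerError(f"missing {meta_path}")
    meta = ByteReader(_unframe_field_file(meta_path.read_bytes(), meta_path))
    n_records = meta.read_varint()
    newline = b"\r\n" if meta.read_byte() else b"\n"
    trailing = bool(meta.read_byte())
    header_blob = meta.read(meta.read_varint())

    streams = []
    for fid in sorted(FIELD_NAMES):
        if fid == FIELD_IDS["HEADER"]:
            continue
        path = directory / f"{FIELD_FILENAMES[fid]}.smzf"
        if not path.exists():
            raise CorruptContainerError(f"missing per-field file {path.name}")
        body = _unframe_field_file(path.read_bytes(), path)
        streams.append(parse_stream(ByteReader(body), n_records))
    return ContainerContent(n_records, newline, trailing, header_blob, streams)
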