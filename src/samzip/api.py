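"""High-level compress / decompress entry points.

``compress_bytes`` / ``decompress_bytes`` are the byte-level round trip;
file and directory variants wrap them. ``measure_roundtrip`` additionally
times each phase and produces the :class:`~samzip.metrics.CompressionReport`
used by the transmission-time model.
"""

from __future__ import annotations

import time
from pathlib import Path

from . import container as _container
from .container import ContainerContent, read_container, read_directory, write_container
from .errors import MixedNewlineError
from .fields import CODEC_NAMES, FIELD_NAMES, decode_fields, encode_fields
from .metrics import CompressionReport
from .sam_io import SamDocument, from_columns, parse_sam, render_sam, transpose


def encode_document(doc: SamDocument, backend: str = "deflate") -> ContainerContent:
    """Columnar-encode a parsed document into container content."""
    streams = encode_fields(transpose(doc))
    return ContainerContent(
        n_records=len(doc.records),
        newline=doc.newline,
        trailing_newline=doc.trailing_newline,
        header_blob=doc.header_block,
        streams=streams,
        backend=backend,
    )


def decode_document(content: ContainerContent) -> SamDocument:
    columns = decode_fields(content.streams)
    return SamDocument(
        header_block=content.header_blob,
        records=from_columns(columns),
        newline=content.newline,
        trailing_newline=content.trailing_newline,
    )


def compress_bytes(raw: bytes, backend: str = "deflate") -> bytes:
    """Compress SAM bytes into a single-file container.

    Files mixing LF and CRLF terminators cannot be modelled columnarly and
    are stored verbatim (still post-compressed) so the round trip stays
    byte-exact.
    """
    try:
        doc = parse_sam(raw)
    except MixedNewlineError:
        return write_container(ContainerContent(backend=backend, raw_file=raw))
    return write_container(encode_document(doc, backend))


def decompress_bytes(blob: bytes) -> bytes:
    content = read_container(blob)
    if content.raw_file is not None:
        return content.raw_file
    return render_sam(decode_document(content))


def compress_file(in_path: Path, out_path: Path, backend: str = "deflate") -> None:
    Path(out_path).write_bytes(compress_bytes(Path(in_path).read_bytes(), backend))


def decompress_file(in_path: Path, out_path: Path) -> None:
    Path(out_path).write_bytes(decompress_bytes(Path(in_path).read_bytes()))


def compress_to_dir(raw: bytes, directory: Path, backend: str = "deflate") -> list[Path]:
    """Write the per-field file layout (one ``.smzf`` per field)."""
    doc = parse_sam(raw)  # mixed newlines raise: directory mode has no raw fallback
    return _container.write_directory(encode_document(doc, backend), directory)


def decompress_dir(directory: Path) -> bytes:
    return render_sam(decode_document(read_directory(directory)))


def stream_stats(blob: bytes) -> list[dict]:
    """Per-field stream sizes and codec choices for a container blob."""
    content = read_container(blob)
    if content.raw_file is not None:
        return [
            {
                "field": "FILE",
                "codec": "raw-file",
                "fallback": True,
                "params_bytes": 0,
                "payload_bytes": len(content.raw_file),
            }
        ]
    rows = []
    for s in content.streams:
        rows.append(
            {
                "field": FIELD_NAMES[s.field_id],
                "codec": CODEC_NAMES.get(s.codec_id, str(s.codec_id)),
                "fallback": s.fallback,
                "params_bytes": len(s.params),
                "payload_bytes": len(s.payload),
            }
        )
    return rows


def measure_roundtrip(raw: bytes, backend: str = "deflate") -> CompressionReport:
    """Compress, decompress and verify, timing each phase.

    The encoded size is measured with the identity backend; the final size
    after the selected post-compression backend feeds the transmission-time
    model. Raises if the round trip is not byte-identical.
    """
    t0 = time.perf_counter()
    plain = compress_bytes(raw, backend="none")
    t1 = time.perf_counter()
    blob = compress_bytes(raw, backend=backend)
    t2 = time.perf_counter()
    restored = decompress_bytes(blob)
    t3 = time.perf_counter()
    if restored != raw:
        raise AssertionError("round trip produced different bytes")

    per_field = {row["field"]: row["params_bytes"] + row["payload_bytes"] for row in stream_stats(plain)}
    return CompressionReport(
        original_bytes=len(raw),
        encoded_bytes=len(plain),
        final_bytes=len(blob),
        per_field_bytes=per_field,
        encode_seconds=t1 - t0,
        post_seconds=t2 - t1,
        decode_seconds=t3 - t2,
    )
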