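"""Exact, loss-free SAM text parsing and rendering.

A SAM file has a header section (lines starting with ``@``) followed by an
alignment section of TAB-delimited lines with 11 mandatory fields — QNAME,
FLAG, RNAME, POS, MAPQ, CIGAR, MRNM, MPOS, ISIZE, SEQ, QUAL — plus optional
``TAG:VTYPE:VALUE`` fields. This layer treats every field as opaque text:
it never normalises numbers, never reorders tags and never touches header
bytes, so ``render_sam(parse_sam(x)) == x`` holds byte-for-byte for any
well-formed input.

Bytes are mapped to ``str`` via latin-1 (a bijection on single bytes), so
unusual but legal byte content survives the round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .errors import IntegrityError, MixedNewlineError, SamFormatError

MANDATORY_FIELDS = (
    "QNAME",
    "FLAG",
    "RNAME",
    "POS",
    "MAPQ",
    "CIGAR",
    "MRNM",
    "MPOS",
    "ISIZE",
    "SEQ",
    "QUAL",
)

#: transpose() adds one pseudo-column holding each record's optional fields
TAGS_COLUMN = "TAGS"


class OptionalField(NamedTuple):
    """One optional field; serialized as ``tag:vtype:value``."""

    tag: str
    vtype: str
    value: str

    def render(self) -> str:
        return f"{self.tag}:{self.vtype}:{self.value}"


@dataclass(frozen=True)
class FieldVector:
    """One alignment record: the 11 mandatory values plus its optional fields."""

    mandatory: tuple[str, ...]
    optional: tuple[OptionalField, ...] = ()

    def __post_init__(self) -> None:
        if len(self.mandatory) != 11:
            raise SamFormatError(
                f"record must carry exactly 11 mandatory fields, got {len(self.mandatory)}"
            )


@dataclass
class SamDocument:
    """A parsed SAM file that can be re-rendered byte-identically.

    ``header_block`` keeps the header bytes verbatim, including their line
    terminators; ``newline`` records the file's terminator convention and
    ``trailing_newline`` whether the final line is terminated.
    """

    header_block: bytes = b""
    records: list[FieldVector] = field(default_factory=list)
    newline: bytes = b"\n"
    trailing_newline: bool = False


def _split_tag(token: str, line_no: int) -> OptionalField:
    parts = token.split(":", 2)
    if len(parts) != 3:
        raise SamFormatError(
            f"line {line_no}: optional field {token!r} lacks the two ':' separators"
        )
    tag, vtype, value = parts
    if len(tag) != 2 or len(vtype) != 1:
        raise SamFormatError(
            f"line {line_no}: optional field {token!r} is not <2-char TAG>:<1-char VTYPE>:<VALUE>"
        )
    return OptionalField(tag, vtype, value)


def parse_sam(raw: bytes) -> SamDocument:
    """Parse SAM text into a :class:`SamDocument`.

    Raises :class:`SamFormatError` for alignment lines with fewer than 11
    TAB-separated tokens (naming the 1-based line number), for malformed
    optional fields, and for ``@`` lines appearing after the first alignment
    line. Raises :class:`MixedNewlineError` when LF and CRLF terminators are
    mixed, since a single convention tag could not restore them.
    """
    if not raw:
        return SamDocument()

    if b"\r\n" in raw:
        newline = b"\r\n"
        if raw.count(b"\r\n") != raw.count(b"\n"):
            raise MixedNewlineError("file mixes CRLF and bare-LF line terminators")
    else:
        newline = b"\n"

    trailing = raw.endswith(newline)
    lines = raw.split(newline)
    if trailing:
        lines.pop()

    n_header = 0
    while n_header < len(lines) and lines[n_header].startswith(b"@"):
        n_header += 1
    header_lines = lines[:n_header]
    aln_lines = lines[n_header:]

    if header_lines:
        header_block = newline.join(header_lines)
        if aln_lines or trailing:
            header_block += newline
    else:
        header_block = b""

    records: list[FieldVector] = []
    for i, line in enumerate(aln_lines):
        line_no = n_header + i + 1
        if line.startswith(b"@"):
            raise SamFormatError(
                f"line {line_no}: header line appears after the first alignment line"
            )
        tokens = line.decode("latin-1").split("\t")
        if len(tokens) < 11:
            raise SamFormatError(
                f"line {line_no}: alignment line has {len(tokens)} fields, expected >= 11"
            )
        optional = tuple(_split_tag(tok, line_no) for tok in tokens[11:])
        records.append(FieldVector(tuple(tokens[:11]), optional))

    return SamDocument(header_block, records, newline, trailing)


def render_record(rec: FieldVector) -> str:
    return "\t".join(list(rec.mandatory) + [f.render() for f in rec.optional])


def render_sam(doc: SamDocument) -> bytes:
    """Render a document back to SAM bytes (exact inverse of :func:`parse_sam`)."""
    nl = doc.newline.decode("latin-1")
    parts: list[str] = []
    for rec in doc.records:
        for v in rec.mandatory:
            if "\t" in v or "\n" in v:
                raise IntegrityError(f"mandatory field value {v!r} contains TAB or newline")
        for f in rec.optional:
            for v in (f.tag, f.vtype, f.value):
                if "\t" in v or "\n" in v:
                    raise IntegrityError(f"optional field part {v!r} contains TAB or newline")
        parts.append(render_record(rec))
    body = nl.join(parts)
    if parts and doc.trailing_newline:
        body += nl
    return doc.header_block + body.encode("latin-1")


def transpose(doc: SamDocument) -> dict[str, list]:
    """Project the record sequence into 12 per-field columns.

    Returns the 11 mandatory columns (lists of strings, in record order)
    plus a ``TAGS`` column whose entries are each record's ordered tuple of
    :class:`OptionalField`. Field codecs receive exactly one column each,
    which keeps the fields independently processable.
    """
    columns: dict[str, list] = {name: [] for name in MANDATORY_FIELDS}
    columns[TAGS_COLUMN] = []
    for rec in doc.records:
        for name, value in zip(MANDATORY_FIELDS, rec.mandatory):
            columns[name].append(value)
        columns[TAGS_COLUMN].append(rec.optional)
    return columns


def from_columns(columns: dict[str, list]) -> list[FieldVector]:
    """Reassemble records from the 12 columns produced by :func:`transpose`."""
    n_values = {name: len(columns[name]) for name in (*MANDATORY_FIELDS, TAGS_COLUMN)}
    if len(set(n_values.values())) > 1:
        raise SamFormatError(f"columns disagree on record count: {n_values}")
    n = n_values["QNAME"]
    records = []
    for i in range(n):
        mandatory = tuple(columns[name][i] for name in MANDATORY_FIELDS)
        optional = tuple(columns[TAGS_COLUMN][i])
        records.append(FieldVector(mandatory, optional))
    return records
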