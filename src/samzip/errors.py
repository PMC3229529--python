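"""Exception hierarchy.

Parse-time problems (malformed SAM) are distinct from decode-time problems
(corrupt archives): callers typically want to report the former to the user
who supplied the file and treat the latter as data loss.
"""


class SamzipError(Exception):
    """Base class for all samzip errors."""


class SamFormatError(SamzipError):
    """The input is not well-formed SAM text."""


class MixedNewlineError(SamFormatError):
    """The file mixes LF and CRLF line terminators.

    Columnar encoding would not be able to restore the terminator of each
    individual line, so the compressor stores such files verbatim instead.
    """


class IntegrityError(SamzipError):
    """A document violates an invariant required for exact re-rendering."""


class EncodingError(SamzipError):
    """A value cannot be represented by the requested codec."""


class CorruptStreamError(SamzipError):
    """An encoded stream is truncated or internally inconsistent."""


class CorruptContainerError(CorruptStreamError):
    """A container fails framing, checksum or cross-stream consistency checks."""
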