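"""Deterministic synthetic SAM generation.

The generator emulates the column statistics a coordinate-sorted short-read
alignment actually shows — the statistics the per-field codecs exploit:
read names stamped from one template with an incrementing counter, a few
reference names, non-decreasing positions with small geometric gaps, a
small FLAG/MAPQ palette, one dominant CIGAR shape, mostly-'=' mate
reference names, mostly-zero insert sizes, ACGT reads with rare N, and
quality strings made of runs. It does not emulate biology: there is no
genome, no error model, and no consistency between SEQ, CIGAR and POS
beyond well-formedness.

``generate_adversarial`` produces the negations: files engineered to defeat
each specialized codec and force its fallback path.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .errors import SamzipError

ADVERSARIAL_KINDS = (
    "no-repeats",
    "mixed-newlines-rejected",
    "non-ACGTN-seq",
    "leading-zero-pos",
    "divergent-qnames",
)


@dataclass(frozen=True)
class GenParams:
    """Knobs of the synthetic SAM generator; the defaults describe a
    well-behaved coordinate-sorted single-reference file.

    ``qual_alphabet``/``qual_mean_run`` control how runny quality strings
    are; ``pos_gap_mean`` is the mean of the geometric gap between
    consecutive positions; ``n_rate`` is the per-base probability of an
    ambiguous N call.
    """

    n_records: int = 1000
    qname_prefix: str = "r"
    qname_start: int = 1
    qname_width: int = 4  # zero-padded counter width; 0 disables padding
    references: tuple[str, ...] = ("ref",)
    reference_weights: tuple[float, ...] | None = None
    sorted_pos: bool = True
    pos_start: int = 1
    pos_gap_mean: float = 3.0
    flag_palette: tuple[int, ...] = (99, 147, 83, 163, 0, 16)
    flag_weights: tuple[float, ...] = (0.3, 0.3, 0.15, 0.15, 0.05, 0.05)
    mapq_palette: tuple[int, ...] = (60, 37, 0)
    mapq_weights: tuple[float, ...] = (0.8, 0.15, 0.05)
    read_length: int = 36
    n_rate: float = 0.001
    qual_alphabet: str = "!#%')+-/13579;=?ACEGI"
    qual_levels: int = 6  # distinct levels actually drawn from the alphabet
    qual_mean_run: float = 4.0
    mrnm_eq_fraction: float = 0.95
    isize_zero: bool = True
    tag_palette: tuple[tuple[str, str, tuple[str, ...]], ...] = (
        ("NM", "i", ("0", "1", "2")),
        ("MD", "Z", ("36", "20A15", "10T25")),
    )
    tag_rate: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise SamzipError("n_records must be non-negative")
        if self.pos_gap_mean <= 0 or self.qual_mean_run <= 0:
            raise SamzipError("distribution means must be positive")
        if not 0.0 <= self.n_rate <= 1.0 or not 0.0 <= self.mrnm_eq_fraction <= 1.0:
            raise SamzipError("rates must lie in [0, 1]")
        for weights, values in (
            (self.reference_weights, self.references),
            (self.flag_weights, self.flag_palette),
            (self.mapq_weights, self.mapq_palette),
        ):
            if weights is not None and (
                len(weights) != len(values) or abs(sum(weights) - 1.0) > 1e-9
            ):
                raise SamzipError("weights must match their palette and sum to 1")


def _geometric(rng: random.Random, mean: float) -> int:
    # support {1, 2, ...} with the requested mean
    p = 1.0 / mean if mean >= 1.0 else 1.0
    u = rng.random()
    k = 1
    q = p
    while u > q and k < 10_000:
        u -= q
        q *= 1.0 - p
        k += 1
    return k


def _qual_string(rng: random.Random, params: GenParams) -> str:
    levels = params.qual_alphabet[-params.qual_levels :]
    out: list[str] = []
    while len(out) < params.read_length:
        ch = rng.choice(levels)
        run = _geometric(rng, params.qual_mean_run)
        out.extend(ch * run)
    return "".join(out[: params.read_length])


def _seq_string(rng: random.Random, params: GenParams) -> str:
    bases = [
        "N" if rng.random() < params.n_rate else rng.choice("ACGT")
        for _ in range(params.read_length)
    ]
    return "".join(bases)


def _header(references: tuple[str, ...]) -> list[str]:
    lines = ["@HD\tVN:1.0\tSO:coordinate"]
    for ref in references:
        lines.append(f"@SQ\tSN:{ref}\tLN:100000")
    return lines


def generate(params: GenParams) -> bytes:
    """Generate a well-formed SAM file; the seed fixes the output exactly."""
    rng = random.Random(params.seed)
    lines = _header(params.references)

    ref_weights = params.reference_weights or tuple(
        1.0 / len(params.references) for _ in params.references
    )
    pos = params.pos_start
    counter = params.qname_start
    for _ in range(params.n_records):
        text = str(counter)
        if params.qname_width:
            text = text.zfill(params.qname_width)
        qname = params.qname_prefix + text
        counter += 1

        flag = rng.choices(params.flag_palette, params.flag_weights)[0]
        rname = rng.choices(params.references, ref_weights)[0]
        if params.sorted_pos:
            pos += _geometric(rng, params.pos_gap_mean) - 1
        else:
            pos = rng.randrange(1, 1_000_000)
        mapq = rng.choices(params.mapq_palette, params.mapq_weights)[0]
        cigar = f"{params.read_length}M"
        if rng.random() < params.mrnm_eq_fraction:
            mrnm = "="
            mpos = pos + params.read_length
            isize = "0" if params.isize_zero else str(rng.choice((-200, -150, 150, 200)))
        else:
            mrnm = "*"
            mpos = 0
            isize = "0"
        seq = _seq_string(rng, params)
        qual = _qual_string(rng, params)

        fields = [
            qname,
            str(flag),
            rname,
            str(pos),
            str(mapq),
            cigar,
            mrnm,
            str(mpos),
            isize,
            seq,
            qual,
        ]
        for tag, vtype, values in params.tag_palette:
            if rng.random() < params.tag_rate:
                fields.append(f"{tag}:{vtype}:{rng.choice(values)}")
        lines.append("\t".join(fields))

    return ("\n".join(lines) + "\n").encode("ascii")


def generate_adversarial(kind: str, n: int = 100, seed: int = 0) -> bytes:
    """Generate a fixture engineered to force a specific fallback path."""
    rng = random.Random(seed)
    if kind == "no-repeats":
        # zero repetitive structure anywhere: every RLE/delta/template codec
        # must take its raw fallback
        lines = _header(("ref",))
        printable = "".join(chr(c) for c in range(33, 127) if chr(c) != "\t")
        for i in range(n):
            qname = "".join(rng.choice("abcdefghijklmnopqrstuvwxyz_:#") for _ in range(10)) + str(
                rng.randrange(10**9)
            )
            fields = [
                qname,
                str(rng.randrange(0, 4096)),
                f"contig{rng.randrange(10**6)}",
                str(rng.randrange(1, 10**9)),
                str(rng.randrange(0, 255)),
                f"{rng.randrange(1, 50)}M{rng.randrange(1, 50)}S",
                f"mate{rng.randrange(10**6)}",
                str(rng.randrange(1, 10**9)),
                str(rng.randrange(-10**6, 10**6)),
                "".join(rng.choice("ACGT") for _ in range(rng.randrange(20, 40))),
                "".join(rng.choice(printable) for _ in range(rng.randrange(20, 40))),
            ]
            lines.append("\t".join(fields))
        return ("\n".join(lines) + "\n").encode("ascii")

    if kind == "mixed-newlines-rejected":
        base = generate(GenParams(n_records=n, seed=seed))
        lines = base.split(b"\n")
        # terminate every other line with CRLF
        out = bytearray()
        for i, line in enumerate(l for l in lines if l):
            out += line
            out += b"\r\n" if i % 2 else b"\n"
        return bytes(out)

    if kind == "non-ACGTN-seq":
        base = generate(GenParams(n_records=n, seed=seed))
        doc_lines = base.decode("ascii").rstrip("\n").split("\n")
        out_lines = []
        for line in doc_lines:
            if line.startswith("@"):
                out_lines.append(line)
                continue
            parts = line.split("\t")
            parts[9] = "*"  # SEQ unavailable placeholder, outside ACGTN
            parts[10] = "*"
            out_lines.append("\t".join(parts))
        return ("\n".join(out_lines) + "\n").encode("ascii")

    if kind == "leading-zero-pos":
        base = generate(GenParams(n_records=n, seed=seed))
        doc_lines = base.decode("ascii").rstrip("\n").split("\n")
        out_lines = []
        for line in doc_lines:
            if line.startswith("@"):
                out_lines.append(line)
                continue
            parts = line.split("\t")
            parts[3] = parts[3].zfill(9)  # legal text, not a canonical integer
            out_lines.append("\t".join(parts))
        return ("\n".join(out_lines) + "\n").encode("ascii")

    if kind == "divergent-qnames":
        base = generate(GenParams(n_records=n, seed=seed))
        doc_lines = base.decode("ascii").rstrip("\n").split("\n")
        out_lines = []
        i = 0
        for line in doc_lines:
            if line.startswith("@"):
                out_lines.append(line)
                continue
            parts = line.split("\t")
            # alternate token skeletons so no shared template exists
            parts[0] = f"read_{i}_A" if i % 2 else f"q{i}x{i}"
            i += 1
            out_lines.append("\t".join(parts))
        return ("\n".join(out_lines) + "\n").encode("ascii")

    raise SamzipError(f"unknown adversarial kind {kind!r}; choose from {ADVERSARIAL_KINDS}")


def preset(name: str, n_records: int = 10_000, seed: int = 0) -> bytes:
    """Named generation presets.

    ``paperlike`` is the well-behaved coordinate-sorted profile the codecs
    were designed for; ``worstcase`` has no repetitive structure at all.
    """
    if name == "paperlike":
        return generate(replace(GenParams(), n_records=n_records, seed=seed))
    if name == "worstcase":
        return generate_adversarial("no-repeats", n=n_records, seed=seed)
    raise SamzipError(f"unknown preset {name!r}; choose paperlike or worstcase")
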