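# samzip

Field-aware, lossless columnar compression for SAM alignment files.

Alignment data in SAM format is bulky text, and moving it between sites is
often the bottleneck of a sequencing analysis: on a T1 link (0.193 MB/s)
every gigabyte of compressed output costs about 88 minutes of transfer.
General-purpose compressors see a SAM file as one undifferentiated byte
stream; `samzip` instead exploits what each of the 11 mandatory columns is
known to contain and encodes every column with a codec matched to its
statistics, producing a compact intermediate that a general-purpose
compressor (DEFLATE, bzip2 or LZMA here) then squeezes further. Decoding
reverses every step exactly: `decompress(compress(x)) == x` byte for byte,
enforced by per-stream CRC32 checksums and a whole-file checksum.

| field | statistic exploited | codec |
|-------|--------------------|-------|
| QNAME | shared name template, embedded counters | template + delta/zigzag varints |
| FLAG, MAPQ | few repeated small integers | run-length (whole values) |
| RNAME | a few reference names | run-length |
| POS | sorted, small repetitive increments | delta + run-length of diffs |
| CIGAR, MPOS | long runs of identical values | run-length with byte lengths |
| MRNM | almost always `=` or `*` | 1 bit per record |
| ISIZE | constant 0 in many files | zero-byte constant mode |
| SEQ | A/C/G/T with rare N | 2 bits/base, N positions in a sidecar |
| QUAL | long single-character runs | run-length over characters |
| TAG:VTYPE:VALUE | tiny TAG/VTYPE alphabets | canonical Huffman; values verbatim |

Every codec is guarded: if its output would not round-trip exactly or would
be at least as large as the raw column, the column is stored verbatim, so
adversarial input costs at most the raw text plus small fixed headers.

## Worked example

```python
from samzip import compress_bytes, decompress_bytes, stream_stats
from samzip.synth import GenParams, generate

raw = generate(GenParams(n_records=2000, seed=7))   # synthetic sorted SAM
blob = compress_bytes(raw, backend="deflate")
assert decompress_bytes(blob) == raw
print(len(raw), len(blob))          # 242560 46282  -> ratio 5.24x
```

Per-field stream sizes before post-compression (`python
examples/compress_roundtrip.py`):

```
QNAME    template           12
FLAG     rle              6755
RNAME    rle                 7
POS      delta+rle        3201
...
SEQ      2bit            19983
QUAL     rle-char        34478
```

The 2,000 read names collapse to a 12-byte template stream, one reference
name costs 7 bytes, SEQ sits at 2 bits/base, and the high-entropy QUAL
column dominates what remains — exactly the per-field behaviour the scheme
is designed around.

The same works from the shell:

```sh
samzip-genfixture --preset paperlike --records 2000 --seed 7 -o in.sam
samzip compress in.sam -o in.smz --post deflate
samzip decompress in.smz -o back.sam
samzip verify in.sam in.smz        # prints "identical"
samzip stats in.smz                # per-field TSV
samzip esttime --size-gb 3.5       # 18569.95 s / 309.50 min over T1
```

`samzip compress --split-files` writes one `.smzf` file per field instead
of a single container, the layout that lets an external compressor be
applied to the encoded output directly.

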