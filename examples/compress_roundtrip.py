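"""Compress a synthetic coordinate-sorted SAM file and verify the round trip.

Generates a 2,000-record file with the statistics the codecs exploit,
compresses it with the DEFLATE backend, prints the per-field stream sizes
and confirms the decompressed bytes are identical to the input.
"""

from samzip import compress_bytes, decompress_bytes, stream_stats
from samzip.synth import GenParams, generate

raw = generate(GenParams(n_records=2000, seed=7))
blob = compress_bytes(raw, backend="deflate")
restored = decompress_bytes(blob)

print(f"original     : {len(raw):8d} bytes")
print(f"compressed   : {len(blob):8d} bytes  (ratio {len(raw) / len(blob):.2f}x)")
print(f"round trip   : {'byte-identical' if restored == raw else 'MISMATCH'}")
print()
print("per-field encoded streams (before post-compression):")
print(f"{'field':8s} {'codec':12s} {'bytes':>8s}")
for row in stream_stats(compress_bytes(raw, backend='none')):
    size = row["params_bytes"] + row["payload_bytes"]
    print(f"{row['field']:8s} {row['codec']:12s} {size:8d}")
# Small streams (RNAME, CIGAR, ISIZE) show fields collapsing to a handful of
# runs or a constant; SEQ sits near 2 bits/base; QUAL and TAGS dominate.
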