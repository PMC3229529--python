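"""Show the fallback ladder on inputs engineered to defeat each codec.

Every specialized codec is guarded: if its output would not round-trip or
would be no smaller than the raw column, the column is stored verbatim.
These fixtures force those paths; the round trip stays byte-exact and the
container never grows beyond the raw text plus small fixed headers.
"""

from samzip import compress_bytes, decompress_bytes, stream_stats
from samzip.synth import ADVERSARIAL_KINDS, generate_adversarial

for kind in ADVERSARIAL_KINDS:
    raw = generate_adversarial(kind, n=200, seed=0)
    blob = compress_bytes(raw, backend="none")
    ok = decompress_bytes(blob) == raw
    rows = stream_stats(blob)
    fallbacks = [r["field"] for r in rows if r["fallback"]]
    print(f"{kind:24s} round-trip={'ok' if ok else 'FAIL':4s} "
          f"container/raw={len(blob) / len(raw):.3f} "
          f"fallback streams: {', '.join(fallbacks) or 'none'}")
# 'no-repeats' defeats every run-length codec; 'mixed-newlines-rejected'
# stores the whole file verbatim; the ratio stays at or below ~1 even so.
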