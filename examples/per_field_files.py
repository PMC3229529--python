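"""Write the per-field file layout and reassemble the SAM from it.

Instead of one .smz container, each field's encoded stream goes to its own
.smzf file (qname.smzf, pos.smzf, ...), the layout that lets an external
general-purpose compressor be pointed at the encoded output directly.
"""

import tempfile
from pathlib import Path

from samzip import compress_to_dir, decompress_dir
from samzip.synth import GenParams, generate

raw = generate(GenParams(n_records=500, seed=3))
with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "streams"
    paths = compress_to_dir(raw, out, backend="deflate")
    total = 0
    for path in sorted(paths):
        size = path.stat().st_size
        total += size
        print(f"{path.name:12s} {size:8d} bytes")
    print(f"{'TOTAL':12s} {total:8d} bytes  (original {len(raw)})")
    restored = decompress_dir(out)
print("reassembled:", "byte-identical" if restored == raw else "MISMATCH")
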