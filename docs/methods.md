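# Methods

## The model

`samzip` is a two-stage lossless compressor for SAM text. Stage one is a
fast, format-aware pre-coder: the alignment section is transposed into one
column per field, and each column is encoded independently with a codec
matched to that field's statistics. Stage two hands the concatenated
encoded streams to a general-purpose compressor (DEFLATE, bzip2 or LZMA).
The split rests on the observation that a best-effort compressor cannot
usefully be run twice, but a cheap specialized transform *before* it
exposes structure the general model would otherwise spend its budget
rediscovering — and shrinks the input the expensive stage has to chew
through. Field independence is architectural: every encoder receives
exactly one column and nothing else, so columns could be processed in
parallel (not implemented here) and a corrupt stream is detected per field.

The only hard guarantee is losslessness. All fields are carried as *text*,
never as parsed numbers: a codec that wants integer semantics (POS, ISIZE,
QNAME counters) must first prove that re-rendering its parse reproduces
the original bytes, and otherwise falls back. The fallback ladder per
column is: specialized codec → token RLE (where applicable) → verbatim
text; the first representation that round-trips and is strictly smaller
than the raw column wins. The worst case is therefore the raw column plus
a per-stream header bounded by 17 bytes.

## Per-field codecs and their assumptions

* **QNAME.** Read names are assumed to be stamped from one template
  (`machine_lane_tile_x_y` style): tokenized into alternating digit /
  non-digit runs, the shared non-digit skeleton is stored once and each
  digit slot becomes an integer column coded as delta + zigzag + varint.
  A true longest-common-subsequence factorisation would not be uniquely
  invertible, so the token template is used instead. Slots with constant
  digit width keep leading zeros by zero-filling; variable-width slots
  with leading zeros, or values ≥ 2^63, store that slot as raw digit
  text; records with diverging skeletons send the whole column to raw.
* **FLAG / RNAME / MAPQ / CIGAR / MPOS.** Whole-value run-length coding,
  serialized as (count, byte-length, bytes) triples of varints. MPOS gets
  the same treatment as CIGAR: its values resemble POS but without the
  monotone increase, so delta coding has no edge.
* **POS.** Values must be canonically rendered non-negative integers;
  the sequence is delta-coded and the diffs (mostly small, often equal in
  sorted files) are run-length coded, with zigzag+varint serialization
  because unsorted input yields negative diffs.
* **MRNM.** When the column is drawn from {`=`, `*`} it costs 1 bit per
  record; `=` maps to 0 because it dominates coordinate-sorted paired
  files. Any other value routes the column to token RLE.
* **ISIZE.** An all-zero column is recorded as a constant mode with an
  empty payload. Otherwise a signed delta+RLE integer path is tried (the
  constant-zero case alone would lose losslessness on real files), then
  RLE, then raw.
* **SEQ.** Restricted to the A/C/G/T/N alphabet. N positions are excised
  into a sidecar stream of (record-delta, position-delta) varint pairs and
  the remaining bases are packed at exactly 2 bits each, A=00, C=01, G=10,
  T=11, MSB-first. Any other character — including the `*` placeholder —
  forces verbatim fallback for the whole column.
* **QUAL.** Run-length coding over the *character* stream of all records
  concatenated (per-record lengths are stored, so runs may span records).
  Qualities are the high-entropy column; on realistic data this codec
  wins only when runs are long, and the guard falls back to raw otherwise.
* **TAGS.** Per-file canonical Huffman tables over the observed TAG
  (2-char) and VTYPE (1-char) alphabets, serialized as code lengths only;
  VALUE bytes are kept verbatim with varint length prefixes, and tag order
  within a record is preserved exactly.

## Numerical and format choices

* Canonical Huffman with ties broken by (weight, insertion order over
  sorted symbols) during tree building and (length, symbol) during code
  assignment; a single-symbol alphabet gets a 1-bit code so decode framing
  never needs a special case. Table cost is optimal regardless of
  tie-break, which is what the exhaustive brute-force test pins down.
* All bit packing is MSB-first; varints are little-endian base-128
  (LEB128); signed integers are zigzag-folded before varint coding.
* Bytes map to `str` via latin-1 (bijective per byte), so any legal SAM
  byte content survives parse → encode → decode → render unchanged.
* The newline convention (LF/CRLF) and presence of a final terminator are
  recorded once per file. Files mixing conventions cannot be represented
  columnarly and are stored verbatim in a raw-mode container — still
  post-compressed, still checksummed, still byte-exact.
* Header lines are never re-encoded: the header block passes through
  verbatim and relies on the post-compression stage.
* Integrity: CRC32 per stream payload plus a CRC32 over the whole
  container; truncation, bit flips, bad magic and version mismatch raise
  distinct container errors rather than yielding partial output.
* Containers: a single `.smz` file (default) or one `.smzf` file per
  field, mirroring a workflow where an external compressor is applied to
  the per-field files; both modes are exact inverses of their writers.

## The synthetic generator

The generator emulates the column statistics the codecs target, as seen in
a coordinate-sorted short-read alignment: templated read names with an
incrementing zero-padded counter, one or a few reference names, positions
advancing by geometric gaps (mean 3), a small FLAG palette dominated by
proper-pair values, one dominant CIGAR shape, 95% `=` mate references,
all-zero insert sizes by default, 36-base ACGT reads with a 0.1% N rate,
quality strings built from runs (mean run length 4 over 6 levels), and an
NM/MD tag pair at 80% incidence. These defaults are deliberately ordinary
for sorted single-library data; the directional acceptance comparison is
run at 10,000 records, large enough for stable stream statistics yet small
enough that the whole suite runs in seconds.

What the generator does **not** emulate: a real genome, base-error or
quality models, CIGAR/SEQ/POS mutual consistency beyond well-formedness,
read pairing semantics, or long-read characteristics. Passing tests
therefore demonstrate exact reversibility and the expected *relative*
behaviour of the codecs on structured vs unstructured input — not the
absolute compression ratios any particular real dataset would show.
`generate_adversarial` produces the negations (no repetition anywhere,
non-ACGTN sequences, leading-zero positions, divergent name skeletons,
mixed newlines) to force and test every fallback path.

## The transmission-time model

Transfer time is modelled as size divided by a constant link rate, with
the T1 line (1.544 Mbps = 0.193 MB/s) as the reference and GB→MB
conversion at 1024 (3.5 GB → 3584 MB → 18569.95 s ≈ 309.50 min). The
offline scenario counts transmission of the final file alone; the online
scenario adds measured compression and decompression time
(`total_online_time`). Times are displayed to two decimals.

## Known limitations

* BAM/BGZF input, random access and block indexing are out of scope; the
  container is a stream format.
* SEQ compression is reference-free; no CRAM-style reference alignment.
* Quality scores are kept exactly (no lossy quantization), which caps the
  achievable ratio on real data where QUAL dominates the entropy.
* Encoding is single-threaded even though the column split would permit
  parallelism.
* The QUAL codec assumes runny qualities; modern binned qualities satisfy
  this, but full-range instrument qualities will usually take the raw
  fallback and lean entirely on the post-compression stage.
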