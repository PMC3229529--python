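"""Primitive codec bijections and the Huffman optimality oracle."""

import math
from collections import Counter
from itertools import combinations_with_replacement

import pytest
from hypothesis import given
from hypothesis import strategies as st

from samzip import codecs
from samzip.codecs import (
    Bitstream,
    CodecTable,
    delta_decode,
    delta_encode,
    huffman_build,
    huffman_decode,
    huffman_encode,
    pack_2bit,
    rle_decode,
    rle_encode,
    unpack_2bit,
    varint_decode,
    varint_encode,
    zigzag_decode,
    zigzag_encode,
)
from samzip.errors import CorruptStreamError, EncodingError


def optimal_prefix_cost(counts: list[int]) -> int:
    """Brute-force minimum cost of any prefix-free code for these counts.

    Enumerates every non-decreasing length multiset satisfying the Kraft
    inequality (lengths at most k-1 suffice for k >= 2 symbols) and pairs
    the largest counts with the shortest lengths. Independent of the
    Huffman construction it checks.
    """
    k = len(counts)
    if k == 1:
        return counts[0]  # one symbol, 1-bit code
    ordered = sorted(counts, reverse=True)
    best = math.inf
    for lengths in combinations_with_replacement(range(1, k), k):
        if sum(2.0**-l for l in lengths) <= 1.0 + 1e-12:
            best = min(best, sum(c * l for c, l in zip(ordered, lengths)))
    return best


def table_cost(table: CodecTable, freqs: dict) -> int:
    return sum(freqs[s] * ln for s, ln in table.lengths.items())


class TestRle:
    @pytest.mark.parametrize(
        "tokens, runs",
        [
            (["0", "0", "0", "16"], [("0", 3), ("16", 1)]),
            ([], []),
            (["a", "b", "c"], [("a", 1), ("b", 1), ("c", 1)]),
        ],
    )
    def test_known_groupings(self, tokens, runs):
        assert rle_encode(tokens) == runs
        assert rle_decode(runs) == tokens

    def test_expansion_by_count(self):
        assert rle_decode([("I", 5)]) == ["I"] * 5

    def test_non_positive_count_rejected(self):
        with pytest.raises(CorruptStreamError):
            rle_decode([("x", 0)])

    @given(st.lists(st.sampled_from("abcX"), max_size=1000))
    def test_roundtrip_property(self, tokens):
        runs = rle_encode(tokens)
        assert rle_decode(runs) == tokens
        assert all(a[0] != b[0] for a, b in zip(runs, runs[1:]))
        assert sum(c for _, c in runs) == len(tokens)


class TestDelta:
    @pytest.mark.parametrize(
        "values, first, diffs",
        [
            ([7, 7, 9, 9, 9, 16], 7, [0, 2, 0, 0, 7]),
            ([5], 5, []),
            ([10, 4], 10, [-6]),
            ([], None, []),
        ],
    )
    def test_known_values_and_inverse(self, values, first, diffs):
        assert delta_encode(values) == (first, diffs)
        assert delta_decode(first, diffs) == values

    @given(st.lists(st.integers(-(10**12), 10**12)))
    def test_roundtrip_property(self, values):
        assert delta_decode(*delta_encode(values)) == values


class TestVarintZigzag:
    @pytest.mark.parametrize("u, enc", [(0, b"\x00"), (127, b"\x7f"), (128, b"\x80\x01")])
    def test_known_encodings(self, u, enc):
        assert varint_encode(u) == enc
        assert varint_decode(enc) == (u, len(enc))

    def test_roundtrip_exhaustive_small(self):
        for u in range(1 << 16):
            value, _ = varint_decode(varint_encode(u))
            assert value == u
        for shift in range(7, 64, 7):  # continuation-byte boundaries
            for u in ((1 << shift) - 1, 1 << shift, (1 << shift) + 1):
                assert varint_decode(varint_encode(u))[0] == u

    def test_truncated_varint_rejected(self):
        with pytest.raises(CorruptStreamError):
            varint_decode(b"\x80")

    def test_negative_rejected(self):
        with pytest.raises(EncodingError):
            varint_encode(-1)

    @pytest.mark.parametrize("i, u", [(0, 0), (-1, 1), (1, 2), (-2, 3)])
    def test_zigzag_known_values(self, i, u):
        assert zigzag_encode(i) == u
        assert zigzag_decode(u) == i

    def test_zigzag_roundtrip_range(self):
        for i in range(-(10**4), 10**4):
            assert zigzag_decode(zigzag_encode(i)) == i

    @given(st.integers(-(10**18), 10**18))
    def test_zigzag_bijection_property(self, i):
        u = zigzag_encode(i)
        assert u >= 0 and zigzag_decode(u) == i


class TestHuffman:
    def test_uniform_four_symbols_is_plain_binary(self):
        table = huffman_build({s: 10 for s in "ACGT"})
        assert set(table.lengths.values()) == {2}

    def test_skewed_counts_match_bruteforce_cost(self):
        freqs = {"A": 4, "B": 2, "C": 1, "D": 1}
        table = huffman_build(freqs)
        assert table_cost(table, freqs) == 14 == optimal_prefix_cost(list(freqs.values()))

    def test_single_symbol_gets_length_one(self):
        table = huffman_build({"X": 100})
        assert table.lengths == {"X": 1}
        bits = huffman_encode(["X"] * 5, table)
        assert bits.bit_count == 5
        assert huffman_decode(bits, table, 5) == ["X"] * 5

    def test_uniform_table_eight_tokens_is_sixteen_bits(self):
        table = huffman_build({s: 1 for s in "ACGT"})
        bits = huffman_encode(list("ACGTACGT"), table)
        assert bits.bit_count == 16

    def test_empty_frequency_mapping_rejected(self):
        with pytest.raises(EncodingError):
            huffman_build({})

    def test_unknown_token_rejected(self):
        table = huffman_build({"A": 1, "B": 1})
        with pytest.raises(EncodingError):
            huffman_encode(["C"], table)

    def test_exhausted_bitstream_rejected(self):
        table = huffman_build({"A": 1, "B": 1})
        bits = huffman_encode(["A", "B"], table)
        with pytest.raises(CorruptStreamError):
            huffman_decode(bits, table, 3)

    def test_empty_token_sequence_gives_zero_bits(self):
        table = huffman_build({"A": 1})
        assert huffman_encode([], table).bit_count == 0

    @given(st.lists(st.sampled_from("abcdef"), min_size=1, max_size=300))
    def test_roundtrip_property(self, tokens):
        table = huffman_build(Counter(tokens))
        bits = huffman_encode(tokens, table)
        assert huffman_decode(bits, table, len(tokens)) == tokens
        assert bits.bit_count == sum(table.lengths[t] for t in tokens)

    @given(st.lists(st.sampled_from("abcdef"), min_size=2, max_size=400).filter(lambda t: len(set(t)) >= 2))
    def test_mean_code_length_within_one_bit_of_entropy(self, tokens):
        counts = Counter(tokens)
        n = len(tokens)
        entropy = -sum(c / n * math.log2(c / n) for c in counts.values())
        table = huffman_build(counts)
        mean_len = sum(counts[s] * ln for s, ln in table.lengths.items()) / n
        assert entropy <= mean_len + 1e-9
        assert mean_len < entropy + 1

    def test_canonical_codes_are_prefix_free(self):
        table = huffman_build({"A": 7, "B": 3, "C": 2, "D": 1, "E": 1})
        codes = {f"{code:0{ln}b}" for code, ln in table.canonical_codes().values()}
        assert len(codes) == 5
        for a in codes:
            for b in codes:
                assert a == b or not b.startswith(a)


class TestPack2Bit:
    def test_acgt_packs_to_0x1b(self):
        bits = pack_2bit("ACGT")
        assert bits.data == b"\x1b" and bits.bit_count == 8

    def test_empty_and_all_a(self):
        assert pack_2bit("").data == b""
        assert pack_2bit("AAAA").data == b"\x00"

    def test_non_acgt_rejected(self):
        with pytest.raises(EncodingError):
            pack_2bit("ACGN")

    @given(st.text(alphabet="ACGT", max_size=500))
    def test_roundtrip_and_size_property(self, seq):
        bits = pack_2bit(seq)
        assert len(bits.data) == (len(seq) + 3) // 4
        assert bits.bit_count == 2 * len(seq)
        assert unpack_2bit(bits, len(seq)) == seq


class TestBitstream:
    def test_msb_first_packing(self):
        w = codecs.BitWriter()
        w.write_bits(0b1, 1)
        w.write_bits(0b01, 2)
        bits = w.finish()
        assert bits.data == b"\xa0" and bits.bit_count == 3

    def test_reader_rejects_overrun(self):
        r = codecs.BitReader(b"\xff", bit_count=3)
        r.read_bits(3)
        with pytest.raises(CorruptStreamError):
            r.read_bit()

    def test_inconsistent_bitstream_rejected(self):
        with pytest.raises(EncodingError):
            Bitstream(b"\x00\x00", 3)
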