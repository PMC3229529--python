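"""Per-field strategies: exact inversion, codec selection and fallback guards."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from samzip import fields as fc
from samzip.errors import CorruptContainerError
from samzip.fields import (
    CONST_ZERO,
    DELTA_RLE,
    MRNM_BITMAP,
    QNAME_TEMPLATE,
    RAW,
    RLE_CHAR,
    RLE_TOKEN,
    SEQ_2BIT,
    STREAM_OVERHEAD_BOUND,
    TAGS_HUFF,
    decode_field,
    decode_fields,
    encode_column,
    encode_isize,
    encode_mrnm,
    encode_pos,
    encode_qname,
    encode_rle_text,
    encode_seq,
    encode_tags,
)
from samzip.sam_io import OptionalField


def roundtrip(field_name, column):
    streams = encode_column(field_name, column)
    return streams, decode_field(streams)


class TestQname:
    def test_template_with_fixed_width_counter(self):
        col = ["r001", "r002", "r002", "r003", "r003", "r004"]
        (stream,), back = roundtrip("QNAME", col)
        assert stream.codec_id == QNAME_TEMPLATE and not stream.fallback
        assert back == col

    def test_constant_names_have_no_slots(self):
        col = ["x", "x", "x"]
        (stream,), back = roundtrip("QNAME", col)
        assert stream.codec_id == QNAME_TEMPLATE
        assert back == col

    def test_divergent_skeletons_fall_back_to_raw(self):
        col = ["read_7_A", "read_9_B"]
        (stream,), back = roundtrip("QNAME", col)
        assert stream.codec_id == RAW and stream.fallback
        assert back == col

    def test_variable_width_leading_zeros_use_raw_slot(self):
        col = ["r01", "r002", "r3"]
        assert decode_field(encode_column("QNAME", col)) == col

    def test_huge_counters_still_roundtrip(self):
        col = [f"m{2**70 + i}" for i in range(4)]
        _, back = roundtrip("QNAME", col)
        assert back == col

    @given(
        st.lists(
            st.tuples(st.sampled_from(["run", "lane.", "x_"]), st.integers(0, 10**9)),
            max_size=30,
        )
    )
    def test_roundtrip_property(self, parts):
        col = [f"{p}{i}" for p, i in parts]
        assert decode_field(encode_column("QNAME", col)) == col


class TestRleText:
    def test_flag_runs(self):
        col = ["0", "0", "0", "16", "16"]
        stream = encode_rle_text(col, "FLAG")
        assert stream.codec_id == RLE_TOKEN
        assert decode_field([stream]) == col

    def test_qual_char_runs_across_records(self):
        col = ["IIIIIIII", "IIII"]
        stream = encode_rle_text(col, "QUAL")
        assert stream.codec_id == RLE_CHAR
        assert decode_field([stream]) == col

    def test_all_distinct_cigars_fall_back_raw(self):
        col = [f"{i}M{i + 1}S" for i in range(20)]
        stream = encode_rle_text(col, "CIGAR")
        assert stream.codec_id == RAW and stream.fallback
        assert decode_field([stream]) == col


class TestPos:
    def test_sorted_positions_delta_then_rle(self):
        col = ["7", "7", "9", "9", "9", "16"]
        stream = encode_pos(col)
        assert stream.codec_id == DELTA_RLE
        assert decode_field([stream]) == col

    def test_single_record(self):
        stream = encode_pos(["100"])
        assert decode_field([stream]) == ["100"]

    def test_leading_zero_forces_raw(self):
        col = ["007", "8"]
        stream = encode_pos(col)
        assert stream.codec_id == RAW and stream.fallback
        assert decode_field([stream]) == col


class TestMrnm:
    def test_two_valued_column_is_bitmap(self):
        col = ["=", "=", "*", "="]
        stream = encode_mrnm(col)
        assert stream.codec_id == MRNM_BITMAP
        assert stream.payload == b"\x20"  # bits 0010, MSB-first
        assert decode_field([stream]) == col

    def test_mixed_values_use_rle(self):
        col = ["chr2", "chr2", "="]
        stream = encode_mrnm(col)
        assert stream.codec_id == RLE_TOKEN
        assert decode_field([stream]) == col

    def test_empty_column(self):
        stream = encode_mrnm([])
        assert stream.payload == b""
        assert decode_field([stream]) == []


class TestIsize:
    def test_all_zero_column_stores_nothing(self):
        stream = encode_isize(["0", "0", "0"])
        assert stream.codec_id == CONST_ZERO
        assert stream.size == 0
        assert decode_field([stream]) == ["0"] * 3

    def test_signed_values_roundtrip(self):
        col = ["0", "-120", "120"]
        stream = encode_isize(col)
        assert decode_field([stream]) == col

    def test_empty_column_is_constant_mode(self):
        stream = encode_isize([])
        assert stream.codec_id == CONST_ZERO
        assert decode_field([stream]) == []


class TestSeq:
    def test_packing_without_n(self):
        base, side = encode_seq(["ACGT", "TTAG"])
        assert base.codec_id == SEQ_2BIT
        # two length varints + ceil(8/4)=2 packed bytes
        assert len(base.payload) == 4
        assert side.payload == b""
        assert decode_field([base, side]) == ["ACGT", "TTAG"]

    def test_n_excision_into_sidecar(self):
        col = ["ANGTACGTACGTACGT", "ACGTACGTACGTACGT"]
        base, side = encode_seq(col)
        assert base.codec_id == SEQ_2BIT
        assert side.params != b"" and side.payload != b""
        assert decode_field([base, side]) == col

    def test_tiny_column_with_n_takes_raw_fallback(self):
        # sidecar overhead would exceed the 4 raw bytes; the guard wins
        base, side = encode_seq(["ANGT"])
        assert base.fallback
        assert decode_field([base, side]) == ["ANGT"]

    def test_star_placeholder_forces_raw(self):
        base, side = encode_seq(["*"])
        assert base.codec_id == RAW and base.fallback
        assert decode_field([base, side]) == ["*"]

    @given(st.lists(st.text(alphabet="ACGTN", max_size=20), max_size=20))
    def test_roundtrip_property(self, col):
        base, side = encode_seq(col)
        assert decode_field([base, side]) == col

    @given(st.lists(st.text(alphabet="ACGT", min_size=10, max_size=40), min_size=3, max_size=20))
    def test_payload_size_bound_without_n(self, col):
        base, _ = encode_seq(col)
        if base.codec_id == SEQ_2BIT:
            total = sum(len(s) for s in col)
            n_length_bytes = len(base.payload) - (total + 3) // 4
            assert n_length_bytes == len(col)  # one varint byte per short read


class TestTags:
    def test_uniform_single_tag_costs_one_bit_each(self):
        col = [(OptionalField("NM", "i", "0"),)] * 4
        stream = encode_tags(col)
        assert stream.codec_id == TAGS_HUFF
        assert decode_field([stream]) == col

    def test_record_without_tags(self):
        col = [(), (OptionalField("NM", "i", "1"),), ()]
        stream = encode_tags(col)
        assert decode_field([stream]) == col

    def test_tag_order_preserved(self):
        group = (OptionalField("NM", "i", "1"), OptionalField("MD", "Z", "5A0"))
        col = [group] * 3
        assert decode_field([encode_tags(col)]) == col

    @given(
        st.lists(
            st.lists(
                st.tuples(
                    st.sampled_from(["NM", "MD", "AS", "X0"]),
                    st.sampled_from("iZA"),
                    st.text(alphabet="0123456789A:^", max_size=6),
                ),
                max_size=3,
            ),
            max_size=15,
        )
    )
    def test_roundtrip_property(self, groups):
        col = [tuple(OptionalField(*t) for t in g) for g in groups]
        assert decode_field([encode_tags(col)]) == col


class TestStreamSet:
    def test_record_count_disagreement_rejected(self):
        s1 = encode_pos(["1", "2"])
        s2 = encode_isize(["0"])
        with pytest.raises(CorruptContainerError, match="disagree"):
            decode_fields([s1, s2])

    def test_framing_roundtrip_with_crc(self):
        stream = encode_pos(["5", "9", "14"])
        blob = fc.serialize_stream(stream)
        parsed = fc.parse_stream(fc.ByteReader(blob), 3)
        assert parsed == stream
        corrupted = bytearray(blob)
        corrupted[-6] ^= 0xFF  # flip a payload byte; CRC must catch it
        with pytest.raises(CorruptContainerError, match="CRC"):
            fc.parse_stream(fc.ByteReader(bytes(corrupted)), 3)


_VALUE_CHARS = [c for c in map(chr, range(33, 127)) if c != "\t"]


@given(
    name=st.sampled_from(["QNAME", "FLAG", "RNAME", "POS", "MAPQ", "CIGAR", "MRNM", "MPOS", "ISIZE", "SEQ", "QUAL"]),
    col=st.lists(st.text(alphabet=_VALUE_CHARS, min_size=1, max_size=12), max_size=25),
)
def test_adversarial_columns_roundtrip_and_respect_guard(name, col):
    """Any text column round-trips and never expands beyond raw + header bound."""
    streams = encode_column(name, col)
    assert decode_field(streams) == col
    raw_size = len("\n".join(col).encode("latin-1"))
    total = sum(s.size for s in streams)
    assert total <= raw_size + STREAM_OVERHEAD_BOUND * len(streams)
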