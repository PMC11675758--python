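"""Unit and property tests for the spatial codec."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ascdna import codec
from ascdna.codec import (
    AlphabetError,
    BitLengthError,
    CodebookDomainError,
    DEFAULT_CODEBOOK,
    EncodedMessage,
    MalformedMessageError,
    PAYLOAD_BITS_TO_BASE,
    bits_to_dna,
    clusters_to_primer,
    decode_message,
    decode_word,
    dna_to_bits,
    encode_bits,
    encode_dna,
    encode_word,
    extend_word,
    primer_to_clusters,
    split_concatenated,
    split_words,
    truncate_word,
)
from ascdna.fixtures import random_bits, random_dna, worked_example

bit_strings = st.text(alphabet="01", max_size=300)


class TestBaseBitTranslation:
    @pytest.mark.parametrize(
        "dna,bits",
        [("TGCA", "00011011"), ("", ""), ("AATT", "11110000")],
    )
    def test_binarization_table(self, dna, bits):
        assert dna_to_bits(dna) == bits
        assert bits_to_dna(bits) == dna

    def test_lowercase_is_canonicalized(self):
        assert dna_to_bits("tgca") == "00011011"

    def test_invalid_symbol_names_position(self):
        with pytest.raises(AlphabetError, match="position 2"):
            dna_to_bits("ACNT")

    def test_odd_bit_length_rejected(self):
        with pytest.raises(BitLengthError):
            bits_to_dna("010")

    @given(st.text(alphabet="ACGT", max_size=120))
    @settings(derandomize=True)
    def test_binarization_round_trip(self, seq):
        assert bits_to_dna(dna_to_bits(seq)) == seq


class TestWords:
    def test_worked_example_word_split(self):
        ex = worked_example()
        words, pad = split_words(ex.bit_stream)
        assert words == list(ex.words)
        assert pad == 0

    @pytest.mark.parametrize(
        "bits,words,pad",
        [("", [], 0), ("0100", ["010", "000"], 2), ("01001", ["010", "010"], 1)],
    )
    def test_right_zero_padding(self, bits, words, pad):
        assert split_words(bits) == (words, pad)

    @pytest.mark.parametrize("w,w4", [("010", "0010"), ("001", "0001"), ("111", "0111")])
    def test_zero_extension(self, w, w4):
        assert extend_word(w) == w4
        assert truncate_word(w4) == w

    def test_extend_truncate_are_inverse_exhaustively(self):
        for v in range(8):
            w = f"{v:03b}"
            assert truncate_word(extend_word(w)) == w

    def test_wrong_lengths_rejected(self):
        with pytest.raises(BitLengthError):
            extend_word("01")
        with pytest.raises(BitLengthError):
            truncate_word("010")

    def test_nonzero_msb_rejected(self):
        with pytest.raises(CodebookDomainError):
            truncate_word("1010")


class TestCodebook:
    # Pairs printed in the traced example, verbatim.
    PRINTED = [
        ("0000", "T", 0),
        ("0001", "G", 0),
        ("0010", "T", 1),
        ("0011", "G", 1),
        ("0101", "A", 0),
    ]
    # Entries forced by the closed-form spatial rule.
    INFERRED = [("0100", "C", 0), ("0110", "C", 1), ("0111", "A", 1)]

    @pytest.mark.parametrize("w4,base,cluster", PRINTED + INFERRED)
    def test_encode_decode_pairs(self, w4, base, cluster):
        assert encode_word(w4) == (base, cluster)
        assert decode_word(base, cluster) == w4

    def test_bijectivity_over_all_eight_words(self):
        pairs = {encode_word(f"0{v:03b}") for v in range(8)}
        assert len(pairs) == 8
        for v in range(8):
            w4 = f"0{v:03b}"
            assert decode_word(*encode_word(w4)) == w4

    def test_cluster_law_against_lookup_oracle(self):
        # Independent oracle: base from the payload table on (b2, b0),
        # cluster equal to the middle bit.
        for v in range(8):
            b2, b1, b0 = (v >> 2) & 1, (v >> 1) & 1, v & 1
            base, cluster = encode_word(f"0{b2}{b1}{b0}")
            assert base == PAYLOAD_BITS_TO_BASE[f"{b2}{b0}"]
            assert cluster == b1

    def test_msb_one_is_outside_domain(self):
        with pytest.raises(CodebookDomainError):
            encode_word("1000")

    def test_codebook_rejects_non_bijection(self):
        bad = {f"0{v:03b}": ("A", 0) for v in range(8)}
        with pytest.raises(codec.AscdnaError):
            codec.Codebook(payload_map=bad)

    def test_alternative_codebook_is_injectable(self):
        # Swap the roles of the two clusters; the codec must still invert.
        swapped = {
            w4: (base, 1 - cl) for w4, (base, cl) in DEFAULT_CODEBOOK.payload_map.items()
        }
        cb = codec.Codebook(payload_map=swapped)
        bits = random_bits(90, seed=7)
        assert decode_message(encode_bits(bits, cb), cb) == bits


class TestPrimerChannel:
    def test_worked_example_primer(self):
        ex = worked_example()
        assert clusters_to_primer(list(ex.clusters)) == ex.primer
        assert primer_to_clusters(ex.primer) == list(ex.clusters)

    @pytest.mark.parametrize(
        "clusters,primer", [([0, 0], "A"), ([1], "G"), ([], ""), ([1, 1, 0, 1], "CT")]
    )
    def test_pairing_and_padding(self, clusters, primer):
        assert clusters_to_primer(clusters) == primer

    @given(st.lists(st.integers(0, 1)).filter(lambda c: len(c) % 2 == 0))
    @settings(derandomize=True)
    def test_primer_inverse_on_even_streams(self, clusters):
        assert primer_to_clusters(clusters_to_primer(clusters)) == clusters


class TestEncodeDecode:
    def test_worked_example_all_views(self):
        ex = worked_example()
        msg = encode_bits(ex.bit_stream)
        assert msg.primer == ex.primer
        assert msg.payload == ex.bases
        assert msg.concatenated == ex.concatenated
        assert len(msg) == 30
        assert decode_message(msg) == ex.bit_stream

    def test_empty_message(self):
        msg = encode_bits("")
        assert (msg.primer, msg.payload, msg.original_bit_length) == ("", "", 0)
        assert decode_message(msg) == ""

    def test_length_law(self):
        for n in [0, 1, 2, 3, 5, 6, 12, 100, 10_000]:
            msg = encode_bits("1" * n)
            payload = -(-n // 3)
            assert len(msg.payload) == payload
            assert len(msg.primer) == -(-payload // 2)
            if n and n % 6 == 0:
                assert len(msg) == n // 2

    def test_round_trip_exhaustive_short(self):
        for n in range(13):
            for v in range(2**n):
                bits = format(v, f"0{n}b") if n else ""
                assert decode_message(encode_bits(bits)) == bits

    @given(bit_strings)
    @settings(derandomize=True, max_examples=300)
    def test_round_trip_property(self, bits):
        assert decode_message(encode_bits(bits)) == bits

    def test_round_trip_seeded_batch(self):
        for i in range(1000):
            bits = random_bits(i % 301, seed=i)
            assert decode_message(encode_bits(bits)) == bits

    def test_encode_dna_matches_composition(self):
        seq = random_dna(120, seed=3)
        assert encode_dna(seq) == encode_bits(dna_to_bits(seq))

    def test_single_base_message(self):
        msg = encode_dna("T")
        assert (len(msg.payload), len(msg.primer), msg.original_bit_length) == (1, 1, 2)
        assert msg.payload == "T" and msg.primer == "A"
        assert bits_to_dna(decode_message(msg)) == "T"


class TestSplitConcatenated:
    def test_worked_example_split(self):
        msg = split_concatenated("GGACGCACGGTGTAGATTTTTTTGTGTTTA")
        assert len(msg.primer) == 10
        assert len(msg.payload) == 20
        assert msg.original_bit_length == 60

    @pytest.mark.parametrize("total,primer,payload", [(0, 0, 0), (8, 3, 5), (30, 10, 20)])
    def test_general_split_rule(self, total, primer, payload):
        msg = split_concatenated("A" * total)
        assert (len(msg.primer), len(msg.payload)) == (primer, payload)

    @pytest.mark.parametrize("total", [1, 4, 7, 10])
    def test_unrealizable_lengths_rejected(self, total):
        with pytest.raises(MalformedMessageError):
            split_concatenated("A" * total)

    def test_split_inverts_concatenation(self):
        for n in range(0, 100):
            msg = encode_bits(random_bits(n, seed=n))
            again = split_concatenated(msg.concatenated, n)
            assert again == msg

    def test_bad_structure_rejected(self):
        with pytest.raises(MalformedMessageError):
            EncodedMessage(primer="A", payload="ACGT", original_bit_length=12)
        with pytest.raises(MalformedMessageError):
            EncodedMessage(primer="AC", payload="ACG", original_bit_length=4)


class TestOutputStatistics:
    def test_uniform_bits_give_balanced_gc(self):
        # Uniform message bits make both payload and primer bases uniform,
        # so the GC fraction of the full strand converges to 1/2.
        bits = random_bits(100_000, seed=42)
        msg = encode_bits(bits)
        strand = msg.concatenated
        gc = sum(c in "GC" for c in strand) / len(strand)
        # ~50k bases: 4 sigma of a fair binomial is ~0.009
        assert abs(gc - 0.5) < 0.01

    def test_payload_base_frequencies_near_uniform(self):
        bits = random_bits(99_999, seed=7)
        msg = encode_bits(bits)
        n = len(msg.payload)
        for base in "ACGT":
            assert abs(msg.payload.count(base) / n - 0.25) < 0.01
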