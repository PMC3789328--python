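"""Variant nomenclature: describe, encode, parse, decode, and PC naming."""

import numpy as np
import pytest

from conftest import random_dna
from sharkmir.annotator import (
    KnownMiRNA,
    NAME_PATTERN,
    NameParseError,
    NoRelationError,
    VariantDescriptor,
    assign_pc_names,
    best_known_match,
    decode_name,
    describe_variant,
    encode_name,
    parse_name,
    pc_name,
)

KNOWN = KnownMiRNA("fru-miR-126", "TCGTACCGTGAGTAATAATGCG")


class TestDescribeVariant:
    def test_exact_match_is_identity(self):
        vd = describe_variant(KNOWN.rep_seq, KNOWN)
        assert vd.is_identity
        assert encode_name(KNOWN.name, vd) == "fru-miR-126"

    def test_trimmed_right_end(self):
        vd = describe_variant(KNOWN.rep_seq[:-1], KNOWN)
        assert (vd.left_offset, vd.right_offset, vd.substitutions) == (0, -1, ())
        assert encode_name(KNOWN.name, vd) == "fru-miR-126_R-1"

    def test_extended_right_end(self):
        vd = describe_variant(KNOWN.rep_seq + "A", KNOWN)
        assert (vd.left_offset, vd.right_offset) == (0, 1)
        assert encode_name(KNOWN.name, vd) == "fru-miR-126_R+1"

    def test_combined_offsets_and_substitution(self):
        detected = KNOWN.rep_seq[1:] + "GG"
        detected = detected[:11] + "A" + detected[12:]  # substitution at pos 12
        vd = describe_variant(detected, KNOWN)
        assert (vd.left_offset, vd.right_offset) == (-1, 2)
        assert vd.substitutions == ((12, KNOWN.rep_seq[12], "A"),)
        assert encode_name(KNOWN.name, vd).endswith("_L-1R+2_1ss12TA")

    def test_unrelated_sequence_raises(self):
        with pytest.raises(NoRelationError):
            describe_variant("TTTTTTTTTTTTTTTTTTTT", KNOWN)

    def test_minimality_prefers_fewer_substitutions(self):
        # shifting by one would align with many mismatches; identity wins
        vd = describe_variant(KNOWN.rep_seq, KNOWN)
        assert len(vd.substitutions) == 0 and vd.left_offset == 0


class TestEncodeDecode:
    def test_identity_renders_bare_name(self):
        assert encode_name("fru-miR-126", VariantDescriptor()) == "fru-miR-126"

    def test_right_extension_name(self):
        name = encode_name("ola-miR-1388-3p", VariantDescriptor(0, 5))
        assert name == "ola-miR-1388-3p_R+5"

    def test_two_substitution_token(self):
        vd = VariantDescriptor(0, 0, ((5, "T", "C"), (13, "T", "A")))
        assert encode_name("x-miR-1", vd) == "x-miR-1_2ss5TC13TA"

    def test_decode_r_minus_1(self):
        assert decode_name("fru-miR-126_R-1", KNOWN) == KNOWN.rep_seq[:-1]

    def test_decode_bare_name(self):
        assert decode_name("fru-miR-126", KNOWN) == KNOWN.rep_seq

    def test_decode_extension_needs_flank(self):
        with pytest.raises(ValueError):
            decode_name("fru-miR-126_R+2", KNOWN)
        assert (
            decode_name("fru-miR-126_R+2", KNOWN, flank=("", "GTAC"))
            == KNOWN.rep_seq + "GT"
        )

    def test_malformed_suffix_reports_token(self):
        with pytest.raises(NameParseError):
            parse_name("fru-miR-126_X+1", "fru-miR-126")
        with pytest.raises(NameParseError):
            parse_name("fru-miR-126_2ss5TC", "fru-miR-126")  # count mismatch

    def test_emitted_names_match_grammar_and_reparse(self):
        cases = [
            VariantDescriptor(),
            VariantDescriptor(0, -1),
            VariantDescriptor(2, 0),
            VariantDescriptor(-1, 2, ((12, "T", "A"),)),
            VariantDescriptor(0, 0, ((5, "T", "C"), (13, "T", "A"))),
        ]
        for vd in cases:
            name = encode_name("fru-miR-126", vd)
            assert NAME_PATTERN.match(name), name
            assert parse_name(name, "fru-miR-126") == vd


def test_roundtrip_identity_over_random_pairs():
    """decode(encode(describe(d, k))) == d for seeded random variant pairs."""
    rng = np.random.default_rng(42)
    for _ in range(300):
        region = random_dna(rng, 60)
        a, klen = 20, int(rng.integers(18, 24))
        known = KnownMiRNA("k-miR-1", region[a : a + klen])
        left = int(rng.integers(-5, 6))
        right = int(rng.integers(-5, 6))
        dlen = klen + left + right
        if not 10 <= dlen <= 34:
            continue
        detected = list(region[a - left : a + klen + right])
        # up to 3 substitutions within the overlap with the known sequence
        lo, hi = max(0, left), min(dlen, klen + left)
        n_subs = int(rng.integers(0, 4))
        pos_pool = list(range(lo, hi))
        rng.shuffle(pos_pool)
        for p in sorted(pos_pool[:n_subs]):
            alt = [b for b in "ACGT" if b != detected[p]]
            detected[p] = alt[int(rng.integers(0, 3))]
        detected = "".join(detected)
        flank = (region[:a], region[a + klen :])
        try:
            vd = describe_variant(detected, known, flank=flank)
        except NoRelationError:
            continue  # mutations can push past the 3-substitution bound
        name = encode_name(known.name, vd)
        assert decode_name(name, known, flank) == detected


class TestPcNaming:
    def test_name_format(self):
        assert pc_name("5p", 14, 74120) == "PC-5p-14_74120"

    def test_rank_by_abundance_per_arm(self):
        names = assign_pc_names(
            [("AAA", "5p", 10), ("CCC", "5p", 99), ("GGG", "3p", 5)]
        )
        assert names == ["PC-5p-2_10", "PC-5p-1_99", "PC-3p-1_5"]


def test_best_known_match_picks_minimal_edit():
    knowns = [KNOWN, KnownMiRNA("other-miR", "GGCCGGAATTCCGGAATTCC")]
    match = best_known_match(KNOWN.rep_seq[:-1], knowns)
    assert match is not None and match[0].name == "fru-miR-126"
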