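"""Surrogate folding, hairpin metrics, and the twelve criteria."""

import math

import pytest

from conftest import PAIR_WEIGHTS, enumerate_structures, oracle_max_weight, random_rna
from sharkmir.hairpin import (
    CriteriaReport,
    FoldError,
    FoldResult,
    HairpinMetrics,
    HairpinScreen,
    MatureSpan,
    compute_mfei,
    evaluate_criteria,
    fold,
    hairpin_metrics,
    parse_fold_text,
    pairs,
    read_fold_file,
    structure_weight,
    surrogate_energy,
    write_fold_file,
)
from sharkmir.util import revcomp


class TestFold:
    def test_gc_stem_with_tetraloop(self):
        fr = fold("GGGGAAAACCCC")
        assert fr.structure == "((((....))))"
        assert fr.n_pairs == 4
        # 4 GC pairs (weight 12) minus one loop penalty
        assert fr.dG == -11.5

    def test_no_complementarity_means_no_pairs(self):
        fr = fold("A" * 21)
        assert fr.structure == "." * 21
        assert fr.dG == 0.0

    def test_dna_input_accepted(self):
        assert fold("GGTGAAAACACC").structure == fold("GGUGAAAACACC").structure

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(FoldError):
            fold("ACGX" * 5)

    def test_minimum_loop_never_violated(self, rng):
        for _ in range(50):
            seq = random_rna(rng, int(rng.integers(10, 40)))
            for i, j in pairs(fold(seq).structure):
                assert j - i - 1 >= 3

    def test_matches_exhaustive_enumeration_tiny(self, rng):
        """Full structure enumeration agrees with the DP on tiny inputs."""
        for _ in range(25):
            seq = random_rna(rng, int(rng.integers(8, 15)))
            rna = seq.replace("T", "U")
            best = max(
                (
                    sum(PAIR_WEIGHTS[(rna[i], rna[j])] for i, j in s)
                    for s in enumerate_structures(seq)
                ),
                default=0,
            )
            fr = fold(seq)
            assert structure_weight(fr.sequence, fr.structure) == best

    def test_matches_recursive_oracle(self, rng):
        for _ in range(40):
            seq = random_rna(rng, int(rng.integers(15, 31)))
            fr = fold(seq)
            assert structure_weight(fr.sequence, fr.structure) == oracle_max_weight(seq)

    def test_deterministic(self, rng):
        seq = random_rna(rng, 60)
        assert fold(seq).structure == fold(seq).structure

    def test_reverse_complement_of_hairpin_still_qualifies(self, rng):
        from sharkmir.synthetic_fixtures import plant_hairpin

        ph = plant_hairpin(rng)
        rc = revcomp(ph.precursor)
        n = len(ph.precursor)
        mature_rc = MatureSpan(n - ph.mature.end, n - ph.mature.start)
        report = evaluate_criteria(hairpin_metrics(fold(rc), mature_rc))
        assert report.passed


class TestMfei:
    def test_printed_formula(self):
        assert compute_mfei(-30, 75, 50) == pytest.approx(0.8)
        assert compute_mfei(0, 75, 50) == 0.0
        assert compute_mfei(-52.5, 100, 75) == pytest.approx(0.7)

    def test_scale_invariance(self):
        base = compute_mfei(-40, 80, 55)
        assert compute_mfei(-40, 160, 55) == pytest.approx(base / 2)

    def test_zero_gc_is_undefined(self):
        with pytest.raises(ValueError):
            compute_mfei(-30, 75, 0)


def _perfect_hairpin(stem: int = 25, loop: int = 8):
    """Perfect GC stem; mature = the 5' arm. Hand-countable by construction."""
    seq = "G" * stem + "A" * loop + "C" * stem
    structure = "(" * stem + "." * loop + ")" * stem
    fr = FoldResult(seq.replace("T", "U"), structure, surrogate_energy(seq, structure))
    return fr, MatureSpan(0, stem)


class TestMetrics:
    def test_perfect_stem_hand_counts(self):
        fr, mature = _perfect_hairpin()
        m = hairpin_metrics(fr, mature)
        assert m.stem_bp == 25
        assert m.loop_length == 8
        assert m.hairpin_length == 58
        assert m.mature_bp == 25
        assert m.mature_errors == 0
        assert m.pm_percent == 100.0
        assert m.largest_stem_bulge == 0
        assert m.biased_mature_bulges == 0

    def test_simple_structure_direct_reading(self):
        fr = FoldResult("GGGGAAAACCCC", "((((....))))", -11.5)
        m = hairpin_metrics(fr, MatureSpan(0, 4))
        assert m.stem_bp == 4 and m.loop_length == 4

    def test_asymmetric_bulge_is_biased(self):
        # 5' arm carries a 2-nt bulge with no counterpart on the 3' arm
        seq = "GGGGG" + "AA" + "GGGG" + "AAAA" + "CCCCCCCCC"
        structure = "(((((" + ".." + "((((" + "...." + ")))))))))"
        fr = FoldResult(seq, structure, surrogate_energy(seq, structure))
        m = hairpin_metrics(fr, MatureSpan(0, 11))
        assert m.largest_stem_bulge == 2
        assert m.largest_mature_bulge == 2
        assert m.biased_mature_errors_in_bulge == 2
        assert m.biased_mature_bulges == 1

    def test_multiloop_flagged_and_longest_stem_used(self):
        seq = "GGGGAAAACCCCGGGGGAAAACCCCC"
        structure = "((((....))))(((((....)))))"
        fr = FoldResult(seq, structure, -20.0)
        m = hairpin_metrics(fr, MatureSpan(12, 17))
        assert m.multi_loop
        assert m.stem_bp == 5  # the longer stem-loop wins

    def test_planted_hairpin_matches_construction(self, rng):
        from sharkmir.synthetic_fixtures import plant_hairpin

        ph = plant_hairpin(rng, stem_bp=26, loop_len=12, gc_frac=0.5, mature_len=20)
        m = hairpin_metrics(fold(ph.precursor), ph.mature)
        assert m.stem_bp == 26
        assert m.loop_length == 12
        assert m.hairpin_length == 2 * 26 + 12


def _passing_metrics(**overrides) -> HairpinMetrics:
    base = dict(
        dG=-40.0, mir_len=70, gc_percent=55.0, hairpin_length=62, stem_bp=26,
        loop_length=10, mature_bp=22, pm_percent=100.0, mature_errors=0,
        largest_stem_bulge=0, largest_mature_bulge=0,
        biased_mature_errors_in_bulge=0, biased_mature_bulges=0, mfei=1.0,
    )
    base.update(overrides)
    return HairpinMetrics(**base)


class TestCriteria:
    # (field, passing boundary value, failing value, criterion index)
    BOUNDARIES = [
        ("dG", -15.0, -14.9, 0),
        ("hairpin_length", 50, 49, 1),
        ("stem_bp", 16, 15, 2),
        ("loop_length", 20, 21, 3),
        ("mature_bp", 12, 11, 4),
        ("pm_percent", 80.0, 79.9, 5),
        ("mature_errors", 7, 8, 6),
        ("largest_stem_bulge", 12, 13, 7),
        ("largest_mature_bulge", 8, 9, 8),
        ("biased_mature_errors_in_bulge", 4, 5, 9),
        ("biased_mature_bulges", 2, 3, 10),
        ("mfei", 0.7, 0.69, 11),
    ]

    @pytest.mark.parametrize("field,passing,failing,idx", BOUNDARIES)
    def test_each_bound_verbatim(self, field, passing, failing, idx):
        ok = evaluate_criteria(_passing_metrics(**{field: passing}))
        assert ok.verdicts[idx] and ok.passed
        bad = evaluate_criteria(_passing_metrics(**{field: failing}))
        assert not bad.verdicts[idx] and not bad.passed

    def test_monotone_in_single_metric(self):
        """Worsening a metric past its bound never flips fail -> pass."""
        failing = _passing_metrics(stem_bp=15)
        assert not evaluate_criteria(failing).passed
        worse = _passing_metrics(stem_bp=15, mature_errors=9)
        assert not evaluate_criteria(worse).passed

    def test_undefined_mfei_fails_criterion_12(self):
        report = evaluate_criteria(_passing_metrics(mfei=math.nan))
        assert not report.verdicts[11]


class TestFoldFileInterop:
    def test_parse_energy_sign(self):
        fr = parse_fold_text("GGGGAAAACCCC\n((((....)))) (-23.40)\n")
        assert fr.dG == -23.4
        assert fr.structure == "((((....))))"

    def test_length_mismatch_is_error(self):
        with pytest.raises(FoldError):
            parse_fold_text("GGGGAAAACCCC\n(((....))) (-5.0)\n")

    def test_unbalanced_brackets_is_error(self):
        with pytest.raises(FoldError):
            parse_fold_text("GGGGAAAACCCC\n((((....)).) (-5.0)\n")

    def test_roundtrip_identity(self, tmp_path):
        fr = fold("GGGGGGAAAACCCCCC")
        path = tmp_path / "fold.txt"
        write_fold_file(fr, path, name="candidate")
        back = read_fold_file(path)
        assert back == fr


class TestHairpinScreen:
    def test_planted_flank_passes(self, rng):
        from sharkmir.synthetic_fixtures import plant_hairpin
        from conftest import random_dna

        ph = plant_hairpin(rng)
        flank = random_dna(rng, 80) + ph.precursor + random_dna(rng, 80)
        m_start = 80 + ph.mature.start
        call = HairpinScreen().evaluate(flank, m_start, m_start + len(ph.mature))
        assert call.passed and call.folded

    def test_random_flank_does_not_pass(self, rng):
        from conftest import random_dna

        flank = random_dna(rng, 180)
        call = HairpinScreen().evaluate(flank, 80, 102)
        assert not call.passed
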