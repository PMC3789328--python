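"""Target-site scanning: alignment scoring, seed weighting, energy filter."""

import pytest

from conftest import random_rna
from sharkmir.target_scan import ScanParams, TargetHit, duplex_energy, scan, scan_many
from sharkmir.util import revcomp


MIRNA = "UGGAGUGUGACAAUGGUGUUUG"  # 22 nt


def perfect_target(mirna: str, pad5: str = "AAAA", pad3: str = "AAAA") -> str:
    """Embed the exact reverse complement of the miRNA in a target."""
    return pad5 + revcomp(mirna) + pad3


class TestScan:
    def test_perfect_complement_scores_above_threshold(self):
        params = ScanParams()
        hits = scan(MIRNA, perfect_target(MIRNA), params)
        assert len(hits) == 1
        hit = hits[0]
        # closed form: every position matches (+5), seed positions 2-8 doubled
        expected = 5.0 * len(MIRNA) + 5.0 * 7
        assert hit.score == pytest.approx(expected)
        assert hit.score > params.score_threshold
        assert hit.n_pairs == len(MIRNA)

    def test_no_complementarity_no_hits(self):
        assert scan("A" * 22, "A" * 60) == []

    def test_energy_threshold_filters_weak_duplexes(self):
        hits_loose = scan(MIRNA, perfect_target(MIRNA),
                          ScanParams(energy_threshold=0.0))
        assert hits_loose
        energy = hits_loose[0].energy
        # tighten the threshold just past the surrogate energy: hit disappears
        assert scan(MIRNA, perfect_target(MIRNA),
                    ScanParams(energy_threshold=energy - 0.1)) == []

    def test_seed_mutation_costs_at_least_as_much(self):
        """Mutating a seed position never hurts less than the paired non-seed one."""
        target = perfect_target(MIRNA)
        params = ScanParams(score_threshold=0.0, energy_threshold=0.0)
        base = scan(MIRNA, target, params)[0].score

        def mutated_score(pos_from_5p: int) -> float:
            # disrupt the target base complementary to this miRNA position
            idx = 4 + (len(MIRNA) - pos_from_5p)  # within revcomp block
            q = MIRNA[pos_from_5p - 1]
            t = list(target)
            t[idx] = "C" if q in "AU" else "A"  # neither WC nor wobble with q
            hits = scan(MIRNA, "".join(t), params)
            return hits[0].score if hits else 0.0

        for seed_pos, plain_pos in [(2, 12), (5, 15), (8, 18)]:
            assert base - mutated_score(seed_pos) >= base - mutated_score(plain_pos)

    def test_perfect_site_is_the_maximal_window(self, rng):
        """No window outscores the exact reverse-complement site."""
        target = random_rna(rng, 80) + revcomp(MIRNA) + random_rna(rng, 80)
        params = ScanParams(score_threshold=30.0, energy_threshold=0.0)
        hits = scan(MIRNA, target, params)
        assert hits
        best = hits[0]
        assert best.target_start >= 75 and best.target_end <= 80 + len(MIRNA) + 5

    def test_raising_score_threshold_only_removes_hits(self, rng):
        target = random_rna(rng, 150) + revcomp(MIRNA) + random_rna(rng, 150)
        loose = scan(MIRNA, target, ScanParams(score_threshold=40.0,
                                               energy_threshold=0.0))
        strict = scan(MIRNA, target, ScanParams(score_threshold=80.0,
                                                energy_threshold=0.0))
        loose_keys = {(h.target_start, h.target_end) for h in loose}
        assert {(h.target_start, h.target_end) for h in strict} <= loose_keys

    def test_input_validation(self):
        with pytest.raises(ValueError):
            scan("ACGU" * 2, "A" * 50)  # miRNA too short
        with pytest.raises(ValueError):
            scan(MIRNA, "ACGU")  # target shorter than miRNA


class TestDuplexEnergy:
    def test_all_gc_gapless_duplex(self):
        cols = [("G", "C")] * 22
        assert duplex_energy(cols) == pytest.approx(-2.2 * 21)

    def test_single_pair_has_no_stack(self):
        assert duplex_energy([("G", "C")]) == 0.0

    def test_interior_loop_penalty(self):
        cols = [("G", "C"), ("G", "C"), ("A", "A"), ("G", "C"), ("G", "C")]
        # two stacks of -2.2 plus one loop opening of +4.1
        assert duplex_energy(cols) == pytest.approx(-2.2 * 2 + 4.1)

    def test_matches_independent_resummation(self, rng):
        """Oracle: re-sum stacks/loops with an independent pass."""
        stack_e = {"GC": -2.2, "AU": -1.1, "GU": -0.5}

        def kind(q, t):
            if q is None or t is None:
                return None
            if (q, t) in {("G", "C"), ("C", "G")}:
                return "GC"
            if (q, t) in {("A", "U"), ("U", "A")}:
                return "AU"
            if (q, t) in {("G", "U"), ("U", "G")}:
                return "GU"
            return None

        def oracle(cols):
            kinds = [kind(q, t) for q, t in cols]
            total = 0.0
            for i in range(1, len(kinds)):
                if kinds[i] and kinds[i - 1]:
                    total += stack_e[kinds[i]]
            # loop openings: gaps between consecutive paired columns
            paired_idx = [i for i, k in enumerate(kinds) if k]
            for a, b in zip(paired_idx, paired_idx[1:]):
                if b - a > 1:
                    total += 4.1
            return total

        bases = list("ACGU")
        for _ in range(100):
            cols = []
            for _ in range(int(rng.integers(2, 30))):
                q = None if rng.random() < 0.1 else bases[int(rng.integers(0, 4))]
                t = None if (q is not None and rng.random() < 0.1) \
                    else bases[int(rng.integers(0, 4))]
                cols.append((q, t))
            assert duplex_energy(cols) == pytest.approx(oracle(cols))


def test_scan_many_table(rng):
    mirnas = {"miR-a": MIRNA}
    targets = {
        "est1": perfect_target(MIRNA, random_rna(rng, 30), random_rna(rng, 30)),
        "est2": random_rna(rng, 80),
    }
    df = scan_many(mirnas, targets)
    assert set(df.target_id) <= {"est1", "est2"}
    assert (df[df.target_id == "est1"].score >= 50.0).all()
    assert "Query 3'" in df.iloc[0].alignment
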