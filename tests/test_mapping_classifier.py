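"""Mapping, the group-classification cascade, and the group table."""

import pytest

from conftest import random_dna
from sharkmir.datasets import GROUP_READ_COUNTS, GROUP_PERCENTAGES, LIBRARY_TOTALS
from sharkmir.hairpin import HairpinScreen
from sharkmir.mapping_classifier import (
    ConsistencyError,
    GroupAssignment,
    MappingPolicy,
    ReferenceBundle,
    classify,
    classify_all,
    group_percentages,
    map_tag,
    map_tag_to_mature,
    tabulate_from_counts,
    tabulate_groups,
)
from sharkmir.reads_io import CleanTag, Library
from sharkmir.synthetic_fixtures import SimConfig, build_genome
from sharkmir.util import revcomp


def brute_force_hits(tag, ref, max_mm):
    """Independent mismatch scan over every offset."""
    out = []
    for pos in range(len(ref) - len(tag) + 1):
        mm = sum(1 for a, b in zip(tag, ref[pos : pos + len(tag)]) if a != b)
        if mm <= max_mm:
            out.append((pos, mm))
    return out


class TestMapTag:
    def test_exact_substring_hit(self):
        hits = map_tag("ACGTACGTACGTACGTACGT", {"ref1": "TT" + "ACGTACGTACGTACGTACGT" + "GG"})
        assert len(hits) == 1 and hits[0].position == 2 and hits[0].mismatches == 0

    def test_no_match_returns_empty(self):
        assert map_tag("A" * 20, {"ref1": "C" * 100}) == []

    def test_minus_strand_hit_on_genome(self):
        tag = "ACGTACGTACGTACGTACGA"
        genome = {"chr1": "TT" + revcomp(tag) + "GG"}
        hits = map_tag(tag, genome, both_strands=True)
        assert len(hits) == 1 and hits[0].strand == "-" and hits[0].position == 2

    def test_agrees_with_bruteforce_scan(self, rng):
        ref = random_dna(rng, 500)
        for _ in range(20):
            start = int(rng.integers(0, 480))
            tag = ref[start : start + 20]
            for max_mm in (0, 1, 2):
                got = [(h.position, h.mismatches)
                       for h in map_tag(tag, {"r": ref}, max_mm)]
                assert got == brute_force_hits(tag, ref, max_mm)

    def test_planted_coordinate_recovered(self):
        sim = build_genome(SimConfig(seed=7, n_hairpins=3, n_duplex=1, n_known=1))
        row = sim.truth.iloc[0]
        hits = map_tag(row.sequence, sim.genome, both_strands=True)
        assert (hits[0].ref_id, hits[0].position, hits[0].strand) == (
            row.chrom, row.start, row.strand
        )

    def test_mature_end_overhang(self):
        mature = "ACGTACGTACGTACGTACGT"
        # tag extends one base past the right end of the reference
        hits = map_tag_to_mature(mature[2:] + "G", {"m": mature}, max_mismatches=0)
        assert hits and hits[0].position == 2


def _bundle(sim):
    return ReferenceBundle(
        selected_premirna=sim.known_premirna,
        selected_mature=sim.known_mature,
        genome=sim.genome,
    )


@pytest.fixture(scope="module")
def sim():
    return build_genome(SimConfig(seed=11, n_hairpins=4, n_duplex=1, n_known=2))


class TestClassifyCascade:
    def test_unmappable_tag_is_group_6(self, sim):
        tag = CleanTag("TATATATATATACACACACA", {"LN": 1})
        assert classify(tag, _bundle(sim)).group == "6"

    def test_known_precursor_in_genome_is_group_1b(self, sim):
        known = sim.truth[sim.truth.kind == "known"].iloc[0]
        tag = CleanTag(known.sequence, {"LN": 5})
        a = classify(tag, _bundle(sim))
        assert a.group == "1b" and a.evidence

    def test_known_mirna_without_genomic_precursor_is_group_2(self, sim):
        refs = _bundle(sim)
        # reference precursor absent from the genome
        refs.selected_premirna = dict(refs.selected_premirna)
        refs.selected_premirna["foreign-mir"] = "ACGGTTACGGATCCGGTTAAGGCCTTACGATCGATCGGAATTCCGGAATT"
        tag = CleanTag("ACGGTTACGGATCCGGTTAA", {"LN": 1})
        a = classify(tag, refs)
        assert a.group == "2b"  # known hit, not genome-mappable

    def test_other_rna_hit_with_genome_is_3a_without_is_3b(self, sim):
        refs = _bundle(sim)
        genome = sim.genome["chr1"]
        refs.other_rna = {
            "rRNA-like": genome[100:200],            # also in the genome
            "mRNA-like": "TTGACCATTGACCAGGCCAATTGGCCAATT",  # genome-absent
        }
        in_both = CleanTag(genome[110:130], {"LN": 1})
        only_ref = CleanTag("TTGACCATTGACCAGGCCAA", {"LN": 1})
        assert classify(in_both, refs).group == "3a"
        assert classify(only_ref, refs).group == "3b"

    def test_planted_novel_is_group_4a(self, sim):
        novel = sim.truth[sim.truth.kind == "novel"].iloc[0]
        tag = CleanTag(novel.sequence, {"LN": 9})
        a = classify(tag, _bundle(sim))
        assert a.group == "4a"
        assert a.hairpin is not None and a.hairpin.passed
        assert a.precursor_locus is not None

    def test_genomic_non_hairpin_is_group_5(self, sim):
        # a tag from plain random spacer: maps to genome, no planted hairpin
        genome = sim.genome["chr1"]
        tag = CleanTag(genome[300:322], {"LN": 1})
        a = classify(tag, _bundle(sim))
        assert a.group in ("4b", "5")  # spacer may fold weakly by chance
        assert not a.hairpin.passed

    def test_mismatch_loosening_never_creates_group_6(self, sim):
        refs = _bundle(sim)
        tags = [CleanTag(s, {"LN": 1}) for s in sim.truth.sequence.head(4)]
        strict = {a.tag.sequence: a.group
                  for a in classify_all(tags, refs, MappingPolicy(max_mismatches=0))}
        loose = {a.tag.sequence: a.group
                 for a in classify_all(tags, refs, MappingPolicy(max_mismatches=2))}
        for seq, g in strict.items():
            if g != "6":
                assert loose[seq] != "6"


class TestGroupTable:
    def test_percentages_reproduce_published_values(self):
        for lib in ("LN", "LR24"):
            assert group_percentages(GROUP_READ_COUNTS[lib]) == GROUP_PERCENTAGES[lib]

    def test_single_group_is_100_percent(self):
        assert group_percentages({"4a": 123})["4a"] == 100.0

    def test_published_counts_sum_to_totals(self):
        table = tabulate_from_counts(GROUP_READ_COUNTS)
        totals = table[table.group == "total"].iloc[0]
        assert totals["LN_reads"] == LIBRARY_TOTALS["LN"]
        assert totals["LR24_reads"] == LIBRARY_TOTALS["LR24"]

    def test_partition_additivity_enforced(self):
        tag = CleanTag("A" * 20, {"LN": 5})
        assignments = [GroupAssignment(tag, "6")]
        with pytest.raises(ConsistencyError):
            tabulate_groups(assignments, [Library("LN", 4)])
        table = tabulate_groups(assignments, [Library("LN", 5)])
        assert table[table.group == "6"].iloc[0]["LN_reads"] == 5
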