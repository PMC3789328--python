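"""Cascaded mapping of clean tags into the ten read groups.

Every unique tag is assigned to exactly one group by mapping, in order,
against (1) precursors of the focal species, (2) known precursors/matures of
related species, (3) other non-miRNA RNA (mRNA/Rfam/Repbase surrogate), and
(4) a proxy genome whose flanks are screened for qualifying hairpins:

====== ==========================================================
group  meaning
====== ==========================================================
1a     matches a focal-species pre-miRNA
1b     matches a known pre-miRNA that itself maps to the genome
2a     matches a known miRNA; genomic flank forms a qualifying hairpin
2b     matches a known miRNA; no qualifying genomic hairpin
3a     matches other RNA and the genome
3b     matches other RNA only
4a     genome only, flank passes all hairpin criteria (PC miRNA)
4b     genome only, flank folds but fails the criteria
5      genome only, no credible fold
6      no match anywhere
====== ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .hairpin import HairpinCall, HairpinScreen
from .util import as_dna, revcomp, round_half_up
from .reads_io import CleanTag, Library

GROUPS = ("1a", "1b", "2a", "2b", "3a", "3b", "4a", "4b", "5", "6")


class ConsistencyError(RuntimeError):
    """Internal additivity violated (group counts do not sum to totals)."""


@dataclass
class ReferenceBundle:
    """All reference sequence sets used by the classification cascade.

    Sequences are normalized to uppercase DNA (U -> T) at load time.
    """

    specific_premirna: Dict[str, str] = field(default_factory=dict)
    selected_premirna: Dict[str, str] = field(default_factory=dict)
    selected_mature: Dict[str, str] = field(default_factory=dict)
    other_rna: Dict[str, str] = field(default_factory=dict)
    genome: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("specific_premirna", "selected_premirna", "selected_mature",
                     "other_rna", "genome"):
            coll = getattr(self, name)
            setattr(self, name, {k: as_dna(v) for k, v in coll.items()})


@dataclass(frozen=True)
class MappingPolicy:
    """Mapping tolerances of the cascade.

    ``max_mismatches`` applies to matching against known-miRNA and other-RNA
    references, ``genome_max_mismatches`` to the proxy genome (exact by
    default), ``max_end_overhang`` lets a tag extend past a mature reference
    end, and ``flank_extension`` is the genomic context pulled on each side
    of a genome hit for hairpin screening.
    """

    max_mismatches: int = 1
    genome_max_mismatches: int = 0
    max_end_overhang: int = 2
    flank_extension: int = 80

    def __post_init__(self) -> None:
        for f in ("max_mismatches", "genome_max_mismatches",
                  "max_end_overhang", "flank_extension"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass(frozen=True)
class Hit:
    ref_id: str
    position: int           # 0-based offset on the reference forward strand
    strand: str             # '+' or '-'
    mismatches: int


@dataclass
class GroupAssignment:
    tag: CleanTag
    group: str
    evidence: List[Hit] = field(default_factory=list)
    hairpin: Optional[HairpinCall] = None
    # genomic coordinates of the screened precursor window, when any
    precursor_locus: Optional[Tuple[str, int, int, str]] = None


# ---------------------------------------------------------------------------
# low-level mapping
# ---------------------------------------------------------------------------

def _scan(query: str, ref: str, max_mm: int) -> Iterable[Tuple[int, int]]:
    """Yield (position, mismatches) for every placement of query in ref."""
    qlen = len(query)
    if max_mm == 0:
        start = ref.find(query)
        while start != -1:
            yield start, 0
            start = ref.find(query, start + 1)
        return
    for pos in range(len(ref) - qlen + 1):
        mm = 0
        for a, b in zip(query, ref[pos : pos + qlen]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            yield pos, mm


def map_tag(
    tag_seq: str,
    refs: Mapping[str, str],
    max_mismatches: int = 0,
    both_strands: bool = False,
) -> List[Hit]:
    """Brute-force substring search of a tag against a reference collection.

    Minus-strand hits report the position of the match on the forward
    strand; hits are sorted by (mismatches, reference id, position, strand).
    """
    query = as_dna(tag_seq)
    hits: List[Hit] = []
    for ref_id, ref in refs.items():
        for pos, mm in _scan(query, ref, max_mismatches):
            hits.append(Hit(ref_id, pos, "+", mm))
        if both_strands:
            rc = revcomp(query)
            for pos, mm in _scan(rc, ref, max_mismatches):
                hits.append(Hit(ref_id, pos, "-", mm))
    hits.sort(key=lambda h: (h.mismatches, h.ref_id, h.position, h.strand))
    return hits


def map_tag_to_mature(
    tag_seq: str,
    matures: Mapping[str, str],
    max_mismatches: int = 1,
    max_end_overhang: int = 2,
) -> List[Hit]:
    """Match a tag against mature references allowing short end overhangs.

    The hit position may be negative when the tag extends past the 5' end of
    the reference.
    """
    query = as_dna(tag_seq)
    qlen = len(query)
    hits: List[Hit] = []
    for ref_id, ref in matures.items():
        rlen = len(ref)
        for shift in range(-max_end_overhang, rlen - qlen + max_end_overhang + 1):
            left_over = max(0, -shift)
            right_over = max(0, shift + qlen - rlen)
            if left_over > max_end_overhang or right_over > max_end_overhang:
                continue
            lo, hi = left_over, qlen - right_over
            if hi - lo < qlen - 2 * max_end_overhang or hi <= lo:
                continue
            mm = sum(
                1 for i in range(lo, hi) if query[i] != ref[shift + i]
            )
            if mm <= max_mismatches:
                hits.append(Hit(ref_id, shift, "+", mm))
    hits.sort(key=lambda h: (h.mismatches, h.ref_id, h.position))
    return hits


# ---------------------------------------------------------------------------
# classification cascade
# ---------------------------------------------------------------------------

def _genome_flank(
    genome: Mapping[str, str], hit: Hit, tag_len: int, extension: int
) -> Tuple[str, int, int, int, int]:
    """Extract the extended flank around a genome hit, in tag-sense orientation.

    Returns (flank_seq, mature_start, mature_end, win_start, win_end) where
    win_* are forward-strand genomic coordinates of the flank.
    """
    chrom_seq = genome[hit.ref_id]
    ws = max(0, hit.position - extension)
    we = min(len(chrom_seq), hit.position + tag_len + extension)
    flank = chrom_seq[ws:we]
    if hit.strand == "+":
        m_start = hit.position - ws
    else:
        flank = revcomp(flank)
        m_start = we - (hit.position + tag_len)
    return flank, m_start, m_start + tag_len, ws, we


def classify(
    tag: CleanTag,
    refs: ReferenceBundle,
    policy: MappingPolicy = MappingPolicy(),
    hairpin_oracle: Optional[HairpinScreen] = None,
) -> GroupAssignment:
    """Assign one tag to its group via the mapping decision cascade."""
    if hairpin_oracle is None:
        hairpin_oracle = HairpinScreen()
    seq = as_dna(tag.sequence)

    # (i) focal-species precursors
    hits = map_tag(seq, refs.specific_premirna, policy.max_mismatches)
    if hits:
        return GroupAssignment(tag, "1a", hits)

    # (ii) known precursors / matures of related species
    pre_hits = map_tag(seq, refs.selected_premirna, policy.max_mismatches)
    mat_hits = map_tag_to_mature(
        seq, refs.selected_mature, policy.max_mismatches, policy.max_end_overhang
    )
    if pre_hits or mat_hits:
        for hit in pre_hits:
            pre_seq = refs.selected_premirna[hit.ref_id]
            if map_tag(pre_seq, refs.genome, policy.genome_max_mismatches,
                       both_strands=True):
                return GroupAssignment(tag, "1b", pre_hits + mat_hits)
        ghits = map_tag(seq, refs.genome, policy.genome_max_mismatches,
                        both_strands=True)
        if ghits:
            call, locus = _screen_genome_hits(seq, refs, ghits, policy,
                                              hairpin_oracle)
            if call.passed:
                a = GroupAssignment(tag, "2a", pre_hits + mat_hits + ghits)
                a.hairpin, a.precursor_locus = call, locus
                return a
        return GroupAssignment(tag, "2b", pre_hits + mat_hits)

    # (iii) other RNA
    other_hits = map_tag(seq, refs.other_rna, policy.max_mismatches)
    if other_hits:
        ghits = map_tag(seq, refs.genome, policy.genome_max_mismatches,
                        both_strands=True)
        group = "3a" if ghits else "3b"
        return GroupAssignment(tag, group, other_hits + ghits)

    # (iv) genome only
    ghits = map_tag(seq, refs.genome, policy.genome_max_mismatches,
                    both_strands=True)
    if ghits:
        call, locus = _screen_genome_hits(seq, refs, ghits, policy,
                                          hairpin_oracle)
        if call.passed:
            group = "4a"
        elif call.folded:
            group = "4b"
        else:
            group = "5"
        a = GroupAssignment(tag, group, ghits)
        a.hairpin, a.precursor_locus = call, locus
        return a

    # (v) nothing
    return GroupAssignment(tag, "6")


def _screen_genome_hits(
    seq: str,
    refs: ReferenceBundle,
    hits: Sequence[Hit],
    policy: MappingPolicy,
    oracle: HairpinScreen,
    max_hits: int = 4,
) -> Tuple[HairpinCall, Optional[Tuple[str, int, int, str]]]:
    """Screen the flanks of the top genome hits; any passing flank qualifies.

    A read excised from a duplex arm legitimately maps at both arms of its
    palindromic stem, so the precursor may only reveal itself at one of the
    mapped positions.
    """
    best: Optional[Tuple[HairpinCall, Optional[Tuple[str, int, int, str]]]] = None
    for hit in hits[:max_hits]:
        call, locus = _screen_genome_hit(seq, refs, hit, policy, oracle)
        if call.passed:
            return call, locus
        if best is None or (call.folded and not best[0].folded):
            best = (call, locus)
    assert best is not None
    return best


def _screen_genome_hit(
    seq: str,
    refs: ReferenceBundle,
    hit: Hit,
    policy: MappingPolicy,
    oracle: HairpinScreen,
) -> Tuple[HairpinCall, Optional[Tuple[str, int, int, str]]]:
    flank, m_start, m_end, ws, we = _genome_flank(
        refs.genome, hit, len(seq), policy.flank_extension
    )
    call = oracle.evaluate(flank, m_start, m_end)
    locus = None
    if call.window is not None:
        a, b = call.window
        if hit.strand == "+":
            locus = (hit.ref_id, ws + a, ws + b, "+")
        else:
            locus = (hit.ref_id, we - b, we - a, "-")
    return call, locus


def classify_all(
    tags: Sequence[CleanTag],
    refs: ReferenceBundle,
    policy: MappingPolicy = MappingPolicy(),
    hairpin_oracle: Optional[HairpinScreen] = None,
) -> List[GroupAssignment]:
    if hairpin_oracle is None:
        hairpin_oracle = HairpinScreen()
    return [classify(t, refs, policy, hairpin_oracle) for t in tags]


# ---------------------------------------------------------------------------
# group tabulation
# ---------------------------------------------------------------------------

def group_percentages(counts: Mapping[str, int]) -> Dict[str, float]:
    """Per-group percentages of a count column, half-up to one decimal."""
    total = sum(counts.values())
    if total == 0:
        return {g: 0.0 for g in counts}
    return {g: round_half_up(100.0 * c / total, 1) for g, c in counts.items()}


def tabulate_groups(
    assignments: Sequence[GroupAssignment],
    libraries: Sequence[Library],
) -> pd.DataFrame:
    """Per-group read counts and percentages per library.

    Raises :class:`ConsistencyError` when group counts do not sum exactly to
    a library's clean-read total (the additivity the published distribution
    table satisfies).
    """
    lib_ids = [lib.library_id for lib in libraries]
    counts = {lib: {g: 0 for g in GROUPS} for lib in lib_ids}
    for a in assignments:
        for lib, c in a.tag.counts.items():
            if lib in counts:
                counts[lib][a.group] += c
    for lib in libraries:
        got = sum(counts[lib.library_id].values())
        if got != lib.total_clean_reads:
            raise ConsistencyError(
                f"library {lib.library_id}: group counts sum to {got}, "
                f"expected {lib.total_clean_reads}"
            )
    return tabulate_from_counts(
        {lib: counts[lib] for lib in lib_ids}
    )


def tabulate_from_counts(counts_by_library: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Build the group distribution table from per-library group counts."""
    rows = []
    totals = {lib: sum(c.values()) for lib, c in counts_by_library.items()}
    header = {"group": "total"}
    for lib, t in totals.items():
        header[f"{lib}_reads"] = t
        header[f"{lib}_percent"] = 100.0
    rows.append(header)
    for g in GROUPS:
        row = {"group": g}
        for lib, c in counts_by_library.items():
            pct = group_percentages(c)
            row[f"{lib}_reads"] = c.get(g, 0)
            row[f"{lib}_percent"] = pct.get(g, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def assignments_table(assignments: Sequence[GroupAssignment]) -> pd.DataFrame:
    """Per-tag assignment table with flattened evidence."""
    rows = []
    for a in assignments:
        ev = ";".join(
            f"{h.ref_id}:{h.position}{h.strand}/{h.mismatches}mm" for h in a.evidence
        )
        rows.append(
            {
                "sequence": a.tag.sequence,
                "total_count": a.tag.total,
                "group": a.group,
                "evidence": ev,
                "precursor_locus": (
                    "{}:{}-{}({})".format(*a.precursor_locus)
                    if a.precursor_locus else ""
                ),
            }
        )
    return pd.DataFrame(rows)
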