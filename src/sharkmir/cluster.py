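"""Genomic miRNA cluster detection (10-kb single linkage) and duplex pairing.

Two miRNA loci belong to one cluster when they sit on the same chromosome
within 10,000 bp of each other; clustering is transitive (single linkage).
Distance is the gap between the loci by default (end of the left one to
start of the right one), with start-to-start as a config option; clustering
ignores strand.  Loci sharing a precursor are 5p/3p duplex partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

DEFAULT_WINDOW = 10_000


class DataError(ValueError):
    """Inconsistent locus annotation (e.g. >2 loci for one precursor)."""


@dataclass(frozen=True)
class GenomicLocus:
    """A mapped miRNA position (0-based half-open coordinates)."""

    mirna_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    precursor_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.mirna_id}: start must be < end")
        if self.end - self.start > 200:
            raise ValueError(f"{self.mirna_id}: locus longer than 200 bp")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class Cluster:
    cluster_id: int
    members: Tuple[GenomicLocus, ...]
    chrom: str
    span_start: int
    span_end: int

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class DuplexPair:
    precursor_id: str
    arm_a: GenomicLocus
    arm_b: GenomicLocus


def _distance(a: GenomicLocus, b: GenomicLocus, metric: str) -> int:
    """Inter-locus distance; negative gaps (overlap) count as 0."""
    if metric == "gap":
        lo, hi = (a, b) if a.start <= b.start else (b, a)
        return max(0, hi.start - lo.end)
    if metric == "start":
        return abs(a.start - b.start)
    raise ValueError(f"unknown distance metric {metric!r}")


def find_clusters(
    loci: Iterable[GenomicLocus],
    window: int = DEFAULT_WINDOW,
    metric: str = "gap",
) -> List[Cluster]:
    """Single-linkage clustering of loci per chromosome.

    Two loci join when their distance is <= window (boundary inclusive);
    clusters are numbered 1.. by (chromosome, leftmost start).  The result
    is a partition: every locus is in exactly one cluster, singletons
    included.
    """
    by_chrom: Dict[str, List[GenomicLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)

    clusters: List[List[GenomicLocus]] = []
    for chrom in sorted(by_chrom):
        members = sorted(
            by_chrom[chrom], key=lambda l: (l.start, l.end, l.mirna_id)
        )
        current: List[GenomicLocus] = []
        max_end = None
        anchor = None  # rightmost start seen, for the start-to-start metric
        for locus in members:
            if current:
                if metric == "gap":
                    dist = max(0, locus.start - max_end)
                else:
                    dist = locus.start - anchor
                if dist <= window:
                    current.append(locus)
                    max_end = max(max_end, locus.end)
                    anchor = locus.start
                    continue
                clusters.append(current)
            current = [locus]
            max_end = locus.end
            anchor = locus.start
        if current:
            clusters.append(current)

    clusters.sort(key=lambda c: (c[0].chrom, min(l.start for l in c)))
    return [
        Cluster(
            cluster_id=i,
            members=tuple(c),
            chrom=c[0].chrom,
            span_start=min(l.start for l in c),
            span_end=max(l.end for l in c),
        )
        for i, c in enumerate(clusters, start=1)
    ]


def pair_duplex(cluster: Cluster) -> Tuple[List[DuplexPair], bool]:
    """5p/3p duplex pairs within a cluster, plus a duplex-only flag.

    Loci sharing a ``precursor_id`` form one pair (two mature miRNAs cleaved
    from one precursor).  A cluster consisting of exactly one duplex is
    flagged duplex-only.  More than two loci for one precursor is a data
    error.
    """
    by_precursor: Dict[str, List[GenomicLocus]] = {}
    for locus in cluster.members:
        if locus.precursor_id is not None:
            by_precursor.setdefault(locus.precursor_id, []).append(locus)
    pairs: List[DuplexPair] = []
    for pid in sorted(by_precursor):
        group = sorted(by_precursor[pid], key=lambda l: l.start)
        if len(group) > 2:
            raise DataError(f"precursor {pid} has {len(group)} loci (max 2)")
        if len(group) == 2:
            pairs.append(DuplexPair(pid, group[0], group[1]))
    duplex_only = len(pairs) == 1 and len(cluster.members) == 2
    return pairs, duplex_only


def all_duplex_pairs(clusters: Sequence[Cluster]) -> List[DuplexPair]:
    out: List[DuplexPair] = []
    for c in clusters:
        out.extend(pair_duplex(c)[0])
    return out


# ---------------------------------------------------------------------------
# I/O: BED / GFF3 loci and the cluster table
# ---------------------------------------------------------------------------

def read_bed(path) -> List[GenomicLocus]:
    """Read loci from BED (0-based half-open, name in column 4)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 else "+"
            out.append(
                GenomicLocus(
                    mirna_id=f[3] if len(f) > 3 else f"{f[0]}:{f[1]}",
                    chrom=f[0], start=int(f[1]), end=int(f[2]), strand=strand,
                )
            )
    return out


def read_gff3(path) -> List[GenomicLocus]:
    """Read loci from GFF3 (1-based inclusive converted to 0-based half-open).

    ``ID`` names the locus; ``Derives_from`` (when present) carries the
    precursor id used for duplex pairing.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            out.append(
                GenomicLocus(
                    mirna_id=attrs.get("ID", attrs.get("Name", f"{f[0]}:{f[3]}")),
                    chrom=f[0],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6] if f[6] in "+-" else "+",
                    precursor_id=attrs.get("Derives_from"),
                )
            )
    return out


def clusters_table(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Cluster summary with 1-based inclusive span coordinates for reporting."""
    rows = []
    for c in clusters:
        pairs, duplex_only = pair_duplex(c)
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "chrom": c.chrom,
                "span_start": c.span_start + 1,
                "span_end": c.span_end,
                "n_members": len(c),
                "members": ",".join(l.mirna_id for l in c.members),
                "n_duplex_pairs": len(pairs),
                "duplex_only": duplex_only,
            }
        )
    return pd.DataFrame(rows)
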