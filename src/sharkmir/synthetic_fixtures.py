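"""Seeded synthetic fixtures: toy genome, planted hairpins, simulated reads.

The generator plants criterion-passing hairpin precursors (perfect stems
with a chosen GC content plus a short loop, certified by closed-form
arithmetic at construction time) into a random genome, builds a miniature
known-miRNA reference, and simulates adapter-carrying small-RNA reads with
a ground-truth table, so the whole pipeline is testable offline.  All
output is a pure function of (seed, config).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import hairpin as hp
from .cluster import GenomicLocus
from .util import as_dna, revcomp

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # common small-RNA 3' adapter


class ConstructionError(ValueError):
    """Requested hairpin constraints cannot satisfy the criteria."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs of the simulator."""

    seed: int = 1
    n_hairpins: int = 20          # novel (PC-like) precursors
    n_duplex: int = 3             # of those, how many express both arms
    n_known: int = 5              # planted copies of mini-reference precursors
    read_depth: float = 100.0     # mean reads per expressed mature
    noise_reads: int = 0          # random background reads (group-6 truth)
    ct_noise_sd: float = 0.1      # cycles, for synthetic Ct tables
    genome_length: Optional[int] = None  # None: sized from the layout
    cluster_pairs: int = 2        # precursor pairs placed within the 10-kb window
    read_length: int = 40
    adapter: str = DEFAULT_ADAPTER
    stem_bp: int = 28
    loop_len: int = 10
    gc_frac: float = 0.55
    mature_len: int = 22

    def __post_init__(self) -> None:
        if min(self.n_hairpins, self.n_duplex, self.n_known,
               self.noise_reads, self.cluster_pairs) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_duplex > self.n_hairpins:
            raise ValueError("n_duplex cannot exceed n_hairpins")
        if self.genome_length is not None:
            need = (self.n_hairpins + self.n_known) * 300
            if self.genome_length < need:
                raise ValueError(f"genome_length must be >= {need}")


@dataclass(frozen=True)
class PlantedHairpin:
    precursor: str          # DNA
    mature: hp.MatureSpan   # within the precursor
    star: hp.MatureSpan
    arm: str                # arm carrying the mature: '5p' or '3p'


@dataclass
class SimulatedData:
    genome: Dict[str, str]
    truth: pd.DataFrame                 # one row per expressed mature miRNA
    known_premirna: Dict[str, str]
    known_mature: Dict[str, str]
    loci: List[GenomicLocus]
    expected_clusters: int
    expected_duplex_pairs: int
    config: SimConfig


# ---------------------------------------------------------------------------
# hairpin construction
# ---------------------------------------------------------------------------

def plant_hairpin(
    rng: np.random.Generator,
    stem_bp: int = 28,
    loop_len: int = 10,
    gc_frac: float = 0.55,
    mature_len: int = 22,
    arm: str = "5p",
    forbidden: Sequence[str] = (),
    verify: bool = True,
) -> PlantedHairpin:
    """Construct a perfect-stem precursor certified to pass the 12 criteria.

    Certification is constructive: a perfect stem of ``stem_bp`` pairs with
    ``round(stem_bp*gc_frac)`` G:C pairs has a closed-form surrogate energy
    of -(3*n_gc + 2*n_au) + 0.5 and trivially satisfies the pairing and
    bulge bounds; the loop is all-A, non-pairing on either strand.  The
    arithmetic bounds are checked here, independent of the evaluator; with
    ``verify`` the built-in fold + criteria are additionally required to
    agree (they must, and a disagreement raises).
    """
    if not 3 <= loop_len <= 20:
        raise ConstructionError("terminal loop must be 3-20 nt")
    if stem_bp < 16:
        raise ConstructionError("stem must hold >= 16 base pairs")
    if 2 * stem_bp + loop_len < 50:
        raise ConstructionError("hairpin shorter than 50 nt")
    if not 15 <= mature_len <= min(30, stem_bp):
        raise ConstructionError("mature must be 15-30 nt and fit in one arm")
    if arm not in ("5p", "3p"):
        raise ConstructionError("arm must be '5p' or '3p'")

    n_gc = round(stem_bp * gc_frac)
    n_au = stem_bp - n_gc
    # closed-form certification against the numeric criteria
    weight = 3 * n_gc + 2 * n_au
    dg = -(weight) + hp.LOOP_PENALTY  # one terminal loop
    total_len = 2 * stem_bp + loop_len
    # the all-A loop contributes no G/C, so precursor GC% is exact
    min_gc_pct = 100.0 * (2 * n_gc) / total_len
    if dg > -15.0:
        raise ConstructionError(f"surrogate dG {dg:.1f} above -15")
    if -dg * 100.0 / total_len / min_gc_pct < 0.7 and min_gc_pct > 0:
        raise ConstructionError("MFEI below 0.7 for the requested stem")

    for _ in range(50):
        bases = ["G"] * ((n_gc + 1) // 2) + ["C"] * (n_gc // 2) \
            + ["A"] * ((n_au + 1) // 2) + ["T"] * (n_au // 2)
        arm5 = "".join(rng.permutation(bases))
        # all-A loop: non-pairing in the precursor (A-A) and, crucially, in
        # its reverse complement too (U-U), so no spurious in-loop helices
        loop = "A" * loop_len
        precursor = arm5 + loop + revcomp(arm5)
        if any(f in precursor for f in forbidden):
            continue
        if arm == "5p":
            start = int(rng.integers(0, stem_bp - mature_len + 1))
            mature = hp.MatureSpan(start, start + mature_len)
            star = hp.MatureSpan(
                total_len - (start + mature_len), total_len - start
            )
        else:
            start = stem_bp + loop_len + int(rng.integers(0, stem_bp - mature_len + 1))
            mature = hp.MatureSpan(start, start + mature_len)
            star = hp.MatureSpan(
                total_len - (start + mature_len), total_len - start
            )
        if verify:
            fr = hp.fold(precursor)
            report = hp.evaluate_criteria(hp.hairpin_metrics(fr, mature))
            if not report.passed:
                continue  # pathological arm composition; redraw
        return PlantedHairpin(precursor=precursor, mature=mature, star=star, arm=arm)
    raise ConstructionError("could not realize a verifying hairpin in 50 draws")


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def build_genome(config: SimConfig) -> SimulatedData:
    """Assemble the toy genome with planted hairpins and the truth table.

    Layout (one chromosome): precursors separated by 12-20 kb random
    spacers so each would form its own 10-kb cluster, except for
    ``cluster_pairs`` precursors that are dropped 2-5 kb after their
    predecessor to merge clusters.  Expected cluster count is therefore
    (n_known + n_hairpins) - cluster_pairs.
    """
    rng = np.random.default_rng(config.seed)
    forbidden = (as_dna(config.adapter)[:8],)

    # mini known reference (related-species style names)
    known_premirna: Dict[str, str] = {}
    known_mature: Dict[str, str] = {}
    planted: List[Tuple[str, str, PlantedHairpin]] = []  # (precursor_id, kind, ph)
    for i in range(config.n_known):
        arm = "5p" if i % 2 == 0 else "3p"
        ph = plant_hairpin(
            rng, config.stem_bp, config.loop_len, config.gc_frac,
            config.mature_len, arm=arm, forbidden=forbidden,
        )
        name = f"fru-mir-{101 + i}"
        known_premirna[name] = ph.precursor
        known_mature[f"fru-miR-{101 + i}-{arm}"] = ph.precursor[
            ph.mature.start : ph.mature.end
        ]
        planted.append((f"kn{i + 1}", "known", ph))

    for i in range(config.n_hairpins):
        arm = "5p" if i % 2 == 0 else "3p"
        ph = plant_hairpin(
            rng, config.stem_bp, config.loop_len, config.gc_frac,
            config.mature_len, arm=arm, forbidden=forbidden,
        )
        planted.append((f"hp{i + 1}", "novel", ph))

    n_planted = len(planted)
    close = set()
    n_close = min(config.cluster_pairs, max(0, n_planted - 1))
    if n_close:
        # every second slot (never the first) gets a short gap
        step = max(2, n_planted // (n_close + 1))
        idx = 1
        while len(close) < n_close and idx < n_planted:
            close.add(idx)
            idx += step

    chrom = "chr1"
    parts: List[str] = []
    cursor = 0
    truth_rows = []
    loci: List[GenomicLocus] = []
    lead = _random_dna(rng, 2000)
    parts.append(lead)
    cursor += len(lead)
    for idx, (pid, kind, ph) in enumerate(planted):
        if idx > 0:
            gap = int(rng.integers(2000, 5001)) if idx in close \
                else int(rng.integers(12000, 20001))
            spacer = _random_dna(rng, gap)
            parts.append(spacer)
            cursor += gap
        p_start = cursor
        parts.append(ph.precursor)
        cursor += len(ph.precursor)

        spans = [("mature", ph.mature, ph.arm)]
        if kind == "novel" and pid in {f"hp{i + 1}" for i in range(config.n_duplex)}:
            star_arm = "3p" if ph.arm == "5p" else "5p"
            spans.append(("star", ph.star, star_arm))
        for role, span, span_arm in spans:
            g_start = p_start + span.start
            g_end = p_start + span.end
            seq = ph.precursor[span.start : span.end]
            if kind == "known":
                mirna_id = f"fru-miR-{101 + int(pid[2:]) - 1}-{span_arm}"
                expected_group = "1b"
            else:
                mirna_id = f"{pid}-{span_arm}"
                expected_group = "4a"
            truth_rows.append(
                {
                    "mirna_id": mirna_id,
                    "sequence": seq,
                    "chrom": chrom,
                    "start": g_start,
                    "end": g_end,
                    "strand": "+",
                    "arm": span_arm,
                    "role": role,
                    "precursor_id": pid,
                    "precursor_start": p_start,
                    "precursor_end": p_start + len(ph.precursor),
                    "kind": kind,
                    "expected_group": expected_group,
                }
            )
            loci.append(
                GenomicLocus(
                    mirna_id=mirna_id, chrom=chrom, start=g_start, end=g_end,
                    strand="+", precursor_id=pid,
                )
            )
    tail = _random_dna(rng, 2000)
    parts.append(tail)
    cursor += len(tail)

    if config.genome_length is not None and cursor < config.genome_length:
        parts.append(_random_dna(rng, config.genome_length - cursor))
        cursor = config.genome_length

    genome = {chrom: "".join(parts)}
    truth = pd.DataFrame(truth_rows)
    return SimulatedData(
        genome=genome,
        truth=truth,
        known_premirna=known_premirna,
        known_mature=known_mature,
        loci=loci,
        expected_clusters=n_planted - len(close),
        expected_duplex_pairs=config.n_duplex,
        config=config,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    sim: SimulatedData,
    config: Optional[SimConfig] = None,
    library_id: str = "LN",
    rng: Optional[np.random.Generator] = None,
):
    """Simulate adapter-carrying reads for every expressed mature miRNA.

    Per-miRNA counts are Poisson around ``read_depth``; background reads
    are random 15-30-mers rejection-sampled against the genome and the
    references so their no-match (group 6) truth label is guaranteed.
    Returns (reads, counts) where reads are (id, sequence, quality) tuples
    and counts maps sequence -> drawn read count.
    """
    config = config or sim.config
    if rng is None:
        rng = np.random.default_rng(
            [config.seed, zlib.crc32(library_id.encode()) & 0x7FFFFFFF]
        )
    adapter = as_dna(config.adapter)
    reads: List[Tuple[str, str, str]] = []
    counts: Dict[str, int] = {}

    def make_read(insert: str, rid: str) -> Tuple[str, str, str]:
        seq = insert + adapter
        if len(seq) < config.read_length:
            seq += _random_dna(rng, config.read_length - len(seq))
        seq = seq[: config.read_length]
        return (rid, seq, "I" * len(seq))

    serial = 0
    for row in sim.truth.itertuples():
        count = int(rng.poisson(config.read_depth))
        counts[row.sequence] = counts.get(row.sequence, 0) + count
        for _ in range(count):
            serial += 1
            reads.append(make_read(row.sequence, f"read{serial}"))

    genome_seqs = list(sim.genome.values())
    ref_seqs = list(sim.known_premirna.values()) + list(sim.known_mature.values())
    made = 0
    while made < config.noise_reads:
        length = int(rng.integers(15, 31))
        cand = _random_dna(rng, length)
        rc = revcomp(cand)
        if any(cand in g or rc in g for g in genome_seqs):
            continue
        if any(cand in r or rc in r for r in ref_seqs):
            continue
        made += 1
        serial += 1
        counts[cand] = counts.get(cand, 0) + 1
        reads.append(make_read(cand, f"noise{serial}"))

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return reads, counts


def simulate_ct_table(
    rng: np.random.Generator,
    true_folds: Dict[str, Dict[str, float]],
    reference_gene: str = "18S",
    control_group: str = "LN",
    replicates: int = 3,
    noise_sd: float = 0.1,
    base_ct: float = 22.0,
) -> pd.DataFrame:
    """Long-format Ct replicates realizing chosen true fold changes.

    ``true_folds[gene][group]`` is the intended 2^-ddCt; Ct values are
    built as base_ct shifted by -log2(fold) plus Gaussian noise.
    """
    rows = []
    groups = sorted({g for folds in true_folds.values() for g in folds} | {control_group})
    for group in groups:
        for _ in range(replicates):
            rows.append(
                {"gene": reference_gene, "group": group,
                 "ct": base_ct + float(rng.normal(0, noise_sd))}
            )
    for gene, folds in true_folds.items():
        for group in groups:
            fold = folds.get(group, 1.0) if group != control_group else 1.0
            true_ct = base_ct + 3.0 - np.log2(fold)
            for _ in range(replicates):
                rows.append(
                    {"gene": gene, "group": group,
                     "ct": true_ct + float(rng.normal(0, noise_sd))}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------

def write_fasta(seqs: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def write_fastq(reads: Sequence[Tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_truth_gff3(sim: SimulatedData, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in sim.truth.itertuples():
            attrs = f"ID={row.mirna_id};Derives_from={row.precursor_id}"
            fh.write(
                f"{row.chrom}\tsharkmir_sim\tmiRNA\t{row.start + 1}\t{row.end}"
                f"\t.\t{row.strand}\t.\t{attrs}\n"
            )


def write_fixtures(sim: SimulatedData, outdir, library_id: str = "LN") -> None:
    """Write genome/reference FASTA, truth GFF3/TSV, and a FASTQ library."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_fasta(sim.genome, os.path.join(outdir, "genome.fa"))
    write_fasta(sim.known_premirna, os.path.join(outdir, "known_premirna.fa"))
    write_fasta(sim.known_mature, os.path.join(outdir, "known_mature.fa"))
    write_truth_gff3(sim, os.path.join(outdir, "truth.gff3"))
    sim.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    reads, counts = simulate_reads(sim, library_id=library_id)
    write_fastq(reads, os.path.join(outdir, f"{library_id}.fastq"))
    pd.DataFrame(
        [{"sequence": s, "count": c} for s, c in sorted(counts.items())]
    ).to_csv(os.path.join(outdir, f"{library_id}_counts.tsv"), sep="\t", index=False)
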