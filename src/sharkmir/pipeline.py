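"""End-to-end orchestration: trim -> collapse -> classify -> annotate ->
cluster -> quantify, as one deterministic, resumable run.

:func:`run_pipeline` is the in-memory engine; :func:`run_all` wraps it with
file loading and report writing for the command line.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import reads_io
from .annotator import KnownMiRNA, best_known_match, encode_name, assign_pc_names
from .cluster import Cluster, GenomicLocus, all_duplex_pairs, clusters_table, find_clusters
from .hairpin import HairpinScreen
from .mapping_classifier import (
    GroupAssignment,
    MappingPolicy,
    ReferenceBundle,
    assignments_table,
    classify_all,
    map_tag,
    tabulate_groups,
)
from .quantify import expression_table
from .reads_io import CleanStats, Library, TrimPolicy, clean_reads, collapse_libraries
from .util import as_dna


@dataclass
class RunConfig:
    """File-based pipeline configuration (see ``examples/`` for YAML layout)."""

    reads: Dict[str, str]                 # library_id -> FASTQ/FASTA path
    adapter: str
    genome: Optional[str] = None
    specific_premirna: Optional[str] = None
    selected_premirna: Optional[str] = None
    selected_mature: Optional[str] = None
    other_rna: Optional[str] = None
    outdir: str = "sharkmir_out"
    cluster_window: int = 10_000
    policy: MappingPolicy = field(default_factory=MappingPolicy)
    trim: TrimPolicy = field(default_factory=TrimPolicy)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        policy = MappingPolicy(**raw.pop("policy", {}))
        trim = TrimPolicy(**raw.pop("trim", {}))
        return cls(policy=policy, trim=trim, **raw)


@dataclass
class RunReport:
    libraries: List[Library]
    stats: Dict[str, CleanStats]
    group_table: pd.DataFrame
    assignments: List[GroupAssignment]
    named: pd.DataFrame            # final names for 1b/2a/4a tags
    clusters: List[Cluster]
    cluster_table: pd.DataFrame
    n_duplex_pairs: int
    expression: Optional[pd.DataFrame]

    def summary(self) -> str:
        lines = ["sharkmir run report", "==================="]
        for lib in self.libraries:
            lines.append(f"library {lib.library_id}: {lib.total_clean_reads} clean reads")
        named_known = (self.named["kind"] == "known").sum() if len(self.named) else 0
        named_pc = (self.named["kind"] == "PC").sum() if len(self.named) else 0
        lines.append(f"known miRNAs (groups 1b/2a): {named_known}")
        lines.append(f"PC miRNAs (group 4a): {named_pc}")
        lines.append(f"clusters: {len(self.clusters)}")
        lines.append(f"duplex (5p/3p) pairs: {self.n_duplex_pairs}")
        if self.expression is not None:
            n_diff = int(self.expression["differential"].sum())
            lines.append(f"differential miRNAs (|log2 ratio| > 1): {n_diff}")
        return "\n".join(lines)


def _merge_windows(
    windows: Sequence[Tuple[str, int, int, str]]
) -> List[Tuple[str, int, int]]:
    """Union-merge overlapping genomic intervals (strand-blind)."""
    merged: List[Tuple[str, int, int]] = []
    for chrom, start, end, _ in sorted(windows, key=lambda w: (w[0], w[1], w[2])):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def _precursor_id_for(
    window: Tuple[str, int, int, str],
    merged: Sequence[Tuple[str, int, int]],
) -> str:
    chrom, start, end, _ = window
    for i, (c, s, e) in enumerate(merged, start=1):
        if c == chrom and start < e and s < end:
            return f"prec{i}"
    return f"prec?{chrom}:{start}"


def run_pipeline(
    raw_reads: Mapping[str, Iterable[reads_io.RawRead]],
    adapter: str,
    refs: ReferenceBundle,
    policy: MappingPolicy = MappingPolicy(),
    trim: TrimPolicy = TrimPolicy(),
    screen: Optional[HairpinScreen] = None,
    cluster_window: int = 10_000,
) -> RunReport:
    """Run the full discovery pipeline on in-memory read streams."""
    if screen is None:
        screen = HairpinScreen()

    inserts: Dict[str, List[str]] = {}
    stats: Dict[str, CleanStats] = {}
    for lib_id, reads in raw_reads.items():
        inserts[lib_id], stats[lib_id] = clean_reads(reads, adapter, trim)
    tags, libraries = collapse_libraries(inserts)

    assignments = classify_all(tags, refs, policy, screen)
    group_table = tabulate_groups(assignments, libraries)

    # --- naming ---------------------------------------------------------
    knowns = [KnownMiRNA(n, s) for n, s in refs.selected_mature.items()
              if 15 <= len(s) <= 30]
    named_rows = []
    pc_candidates = []
    pc_assignments = []
    for a in assignments:
        if a.group in ("1b", "2a"):
            match = best_known_match(a.tag.sequence, knowns) if knowns else None
            if match is not None:
                known, vd = match
                name = encode_name(known.name, vd)
            else:
                name = a.tag.sequence
            named_rows.append(
                {"sequence": a.tag.sequence, "group": a.group, "kind": "known",
                 "name": name, "total_count": a.tag.total}
            )
        elif a.group == "4a":
            arm = "5p"
            if a.hairpin is not None and a.hairpin.mature_in_window is not None:
                ws, we = a.hairpin.window
                # mature_in_window is window-relative; compare to the middle
                mid = (a.hairpin.mature_in_window.start
                       + a.hairpin.mature_in_window.end) / 2
                arm = "5p" if mid < (we - ws) / 2 else "3p"
            pc_candidates.append((a.tag.sequence, arm, a.tag.total))
            pc_assignments.append(a)
    pc_names = assign_pc_names(pc_candidates)
    for (seq, arm, count), name in zip(pc_candidates, pc_names):
        named_rows.append(
            {"sequence": seq, "group": "4a", "kind": "PC",
             "name": name, "total_count": count}
        )
    named = pd.DataFrame(named_rows)
    name_by_seq = {r["sequence"]: r["name"] for r in named_rows}

    # --- genomic loci and clusters -------------------------------------
    prec_windows = [
        a.precursor_locus for a in assignments
        if a.group in ("2a", "4a") and a.precursor_locus is not None
    ]
    # known precursors that anchor 1b tags also occupy genomic space
    premirna_spans: Dict[str, Tuple[str, int, int, str]] = {}
    for name, seq in refs.selected_premirna.items():
        hits = map_tag(seq, refs.genome, policy.genome_max_mismatches,
                       both_strands=True)
        if hits:
            h = hits[0]
            premirna_spans[name] = (h.ref_id, h.position, h.position + len(seq),
                                    h.strand)
    merged = _merge_windows(list(prec_windows) + list(premirna_spans.values()))

    loci: List[GenomicLocus] = []
    seen_ids: Dict[str, int] = {}
    for a in assignments:
        if a.group not in ("1b", "2a", "4a"):
            continue
        ghits = map_tag(a.tag.sequence, refs.genome,
                        policy.genome_max_mismatches, both_strands=True)
        if not ghits:
            continue
        h = ghits[0]
        if a.precursor_locus is not None:
            pid = _precursor_id_for(a.precursor_locus, merged)
        else:
            pid = _precursor_id_for(
                (h.ref_id, h.position, h.position + len(a.tag.sequence), h.strand),
                merged,
            )
        base = name_by_seq.get(a.tag.sequence, a.tag.sequence)
        n = seen_ids.get(base, 0)
        seen_ids[base] = n + 1
        mirna_id = base if n == 0 else f"{base}.{n + 1}"
        loci.append(
            GenomicLocus(
                mirna_id=mirna_id, chrom=h.ref_id, start=h.position,
                end=h.position + len(a.tag.sequence), strand=h.strand,
                precursor_id=pid,
            )
        )
    clusters = find_clusters(loci, window=cluster_window)
    duplex_pairs = all_duplex_pairs(clusters)

    # --- expression -----------------------------------------------------
    expression = None
    if len(libraries) >= 2:
        mirna_tags = {
            a.tag.sequence: a for a in assignments if a.group in ("1b", "2a", "4a")
        }
        counts = pd.DataFrame(
            {
                lib.library_id: [
                    mirna_tags[s].tag.counts.get(lib.library_id, 0)
                    for s in mirna_tags
                ]
                for lib in libraries
            },
            index=[name_by_seq.get(s, s) for s in mirna_tags],
        )
        totals = {lib.library_id: lib.total_clean_reads for lib in libraries}
        control, treated = libraries[0].library_id, libraries[1].library_id
        if len(counts):
            expression = expression_table(counts, totals, treated, control)

    return RunReport(
        libraries=libraries,
        stats=stats,
        group_table=group_table,
        assignments=assignments,
        named=named,
        clusters=clusters,
        cluster_table=clusters_table(clusters),
        n_duplex_pairs=len(duplex_pairs),
        expression=expression,
    )


# ---------------------------------------------------------------------------
# file-based entry point
# ---------------------------------------------------------------------------

def _load_fasta_dict(path: Optional[str]) -> Dict[str, str]:
    if not path:
        return {}
    out: Dict[str, str] = {}
    for read in reads_io.read_fasta(path):
        out[read.read_id] = as_dna(read.sequence)
    return out


def run_all(config: RunConfig) -> RunReport:
    """Load inputs from disk, run the pipeline, write the report tree."""
    refs = ReferenceBundle(
        specific_premirna=_load_fasta_dict(config.specific_premirna),
        selected_premirna=_load_fasta_dict(config.selected_premirna),
        selected_mature=_load_fasta_dict(config.selected_mature),
        other_rna=_load_fasta_dict(config.other_rna),
        genome=_load_fasta_dict(config.genome),
    )
    raw = {lib: reads_io.read_reads(path) for lib, path in config.reads.items()}
    report = run_pipeline(
        raw, config.adapter, refs, config.policy, config.trim,
        cluster_window=config.cluster_window,
    )

    os.makedirs(config.outdir, exist_ok=True)
    report.group_table.to_csv(
        os.path.join(config.outdir, "group_table.tsv"), sep="\t", index=False
    )
    assignments_table(report.assignments).to_csv(
        os.path.join(config.outdir, "assignments.tsv"), sep="\t", index=False
    )
    report.named.to_csv(
        os.path.join(config.outdir, "mirna_names.tsv"), sep="\t", index=False
    )
    report.cluster_table.to_csv(
        os.path.join(config.outdir, "clusters.tsv"), sep="\t", index=False
    )
    if report.expression is not None:
        report.expression.to_csv(
            os.path.join(config.outdir, "expression.tsv"), sep="\t"
        )
    with open(os.path.join(config.outdir, "report.txt"), "w") as fh:
        fh.write(report.summary() + "\n")
    return report
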