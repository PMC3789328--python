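"""Raw small-RNA read processing: adapter trimming, cleaning, tag collapsing.

A sequencing read is kept when the 3' adapter is found and the insert in
front of it is 15-30 nt with no ambiguous base; surviving inserts are
collapsed into unique counted tags per library.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .util import as_dna

MIN_CLEAN_LEN = 15
MAX_CLEAN_LEN = 30


@dataclass(frozen=True)
class RawRead:
    """A sequencing read as parsed from FASTQ/FASTA."""

    read_id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length != sequence length")


@dataclass
class CleanTag:
    """A unique trimmed read sequence with per-library counts."""

    sequence: str
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class Library:
    library_id: str
    total_clean_reads: int


@dataclass(frozen=True)
class TrimPolicy:
    """Adapter-trimming parameters.

    The adapter is located by the exact leftmost occurrence of its first
    ``seed_len`` bases; a single mismatch is tolerated when the full adapter
    fits inside the read.  Reads without an adapter are dropped unless
    ``require_adapter`` is off, and inserts shorter than ``min_insert``
    (including adapter-dimers with an empty insert) are dropped.
    """

    require_adapter: bool = True
    min_insert: int = MIN_CLEAN_LEN
    seed_len: int = 8
    full_adapter_mismatches: int = 1


def trim_adapter(read: RawRead, adapter3: str, policy: TrimPolicy = TrimPolicy()) -> Optional[str]:
    """Return the insert preceding the leftmost 3' adapter hit, or None.

    Rejections (None): no adapter found under a require-adapter policy,
    adapter at position 0 (adapter-dimer), or insert shorter than the
    policy minimum.
    """
    adapter = as_dna(adapter3)
    if len(adapter) < 6:
        raise ValueError("adapter must be at least 6 nt")
    seq = as_dna(read.sequence)
    seed = adapter[: policy.seed_len]
    alen = len(adapter)

    pos = -1
    for p in range(len(seq)):
        if seq.startswith(seed, p):
            pos = p
            break
        if p + alen <= len(seq):
            mm = sum(1 for a, b in zip(seq[p : p + alen], adapter) if a != b)
            if mm <= policy.full_adapter_mismatches:
                pos = p
                break

    if pos < 0:
        return None if policy.require_adapter else seq
    if pos == 0:
        return None  # adapter-dimer
    insert = seq[:pos]
    if len(insert) < policy.min_insert:
        return None
    return insert


def filter_clean(seq: str, min_len: int = MIN_CLEAN_LEN, max_len: int = MAX_CLEAN_LEN) -> bool:
    """True iff the insert is 15-30 nt (by default) and free of N."""
    return min_len <= len(seq) <= max_len and "N" not in seq.upper()


def collapse(seqs: Iterable[str], library_id: str) -> Tuple[List[CleanTag], Library]:
    """Collapse clean inserts into unique counted tags for one library.

    Output order is deterministic: descending count, then lexicographic.
    """
    counter = Counter(as_dna(s) for s in seqs)
    tags = [
        CleanTag(sequence=s, counts={library_id: c})
        for s, c in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return tags, Library(library_id, sum(counter.values()))


def collapse_libraries(reads_by_library: Mapping[str, Iterable[str]]) -> Tuple[List[CleanTag], List[Library]]:
    """Collapse several libraries into one tag table with per-library counts."""
    per_lib: Dict[str, Counter] = {}
    libraries: List[Library] = []
    for lib_id, seqs in reads_by_library.items():
        c = Counter(as_dna(s) for s in seqs)
        per_lib[lib_id] = c
        libraries.append(Library(lib_id, sum(c.values())))
    all_seqs = set()
    for c in per_lib.values():
        all_seqs.update(c)
    tags = [
        CleanTag(sequence=s, counts={lib: per_lib[lib][s] for lib in per_lib if per_lib[lib][s]})
        for s in all_seqs
    ]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags, libraries


@dataclass
class CleanStats:
    total_raw: int = 0
    no_adapter: int = 0
    too_short: int = 0
    junk: int = 0
    clean: int = 0


def clean_reads(
    reads: Iterable[RawRead],
    adapter3: str,
    policy: TrimPolicy = TrimPolicy(),
    min_len: int = MIN_CLEAN_LEN,
    max_len: int = MAX_CLEAN_LEN,
) -> Tuple[List[str], CleanStats]:
    """Trim + filter a read stream; returns clean inserts and tally of losses."""
    stats = CleanStats()
    out: List[str] = []
    for read in reads:
        stats.total_raw += 1
        insert = trim_adapter(read, adapter3, policy)
        if insert is None:
            # distinguish the two rejection modes for the report
            probe = trim_adapter(
                read, adapter3,
                TrimPolicy(require_adapter=False, min_insert=0,
                           seed_len=policy.seed_len,
                           full_adapter_mismatches=policy.full_adapter_mismatches),
            )
            if probe == as_dna(read.sequence):
                stats.no_adapter += 1
            else:
                stats.too_short += 1
            continue
        if not filter_clean(insert, min_len, max_len):
            if "N" in insert:
                stats.junk += 1
            else:
                stats.too_short += 1
            continue
        stats.clean += 1
        out.append(insert)
    return out, stats


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> Iterable[RawRead]:
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            yield RawRead(read_id=title.split()[0], sequence=seq.upper())


def read_fastq(path) -> Iterable[RawRead]:
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield RawRead(read_id=title.split()[0], sequence=seq.upper(), quality=qual)


def read_reads(path) -> Iterable[RawRead]:
    """Dispatch on file content: '@' first byte means FASTQ, '>' FASTA."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    if first == ">":
        return read_fasta(path)
    raise ValueError(f"unrecognized read file format: {path}")


def write_collapsed_fasta(tags: Iterable[CleanTag], path) -> None:
    """Write tags as `>tag{idx}_x{count}` FASTA records."""
    with open(path, "w") as fh:
        for idx, tag in enumerate(tags, start=1):
            fh.write(f">tag{idx}_x{tag.total}\n{tag.sequence}\n")


def write_tag_table(tags: Iterable[CleanTag], libraries: Iterable[Library], path) -> None:
    lib_ids = [lib.library_id for lib in libraries]
    with open(path, "w") as fh:
        fh.write("sequence\t" + "\t".join(lib_ids) + "\n")
        for tag in tags:
            row = "\t".join(str(tag.counts.get(lib, 0)) for lib in lib_ids)
            fh.write(f"{tag.sequence}\t{row}\n")


def read_tag_table(path) -> Tuple[List[CleanTag], List[Library]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        lib_ids = header[1:]
        totals = {lib: 0 for lib in lib_ids}
        tags: List[CleanTag] = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            counts = {}
            for lib, v in zip(lib_ids, fields[1:]):
                c = int(v)
                if c:
                    counts[lib] = c
                    totals[lib] += c
            tags.append(CleanTag(sequence=fields[0], counts=counts))
    return tags, [Library(lib, totals[lib]) for lib in lib_ids]
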