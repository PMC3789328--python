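"""Hairpin folding and pre-miRNA criteria evaluation.

Candidate precursors are folded with a built-in surrogate: a Nussinov-style
dynamic program that maximizes stacking-weighted base pairs (GC=3, AU=2,
GU=1) subject to a minimum hairpin loop of 3 nt.  The free energy is
estimated from the optimal structure as -1.0 kcal/mol per weight unit,
penalized 0.5 kcal/mol for every enclosed run of unpaired bases (loop or
bulge).  This is deliberately NOT a thermodynamic nearest-neighbour model;
externally computed folds (e.g. from RNAfold/Mfold) can be supplied through
:func:`read_fold_file` and are evaluated by the identical criteria logic.

The twelve annotation criteria (free energy, hairpin/stem/loop geometry,
mature-region pairing, bulge symmetry, and the minimal folding energy index
MFEI = -dG*100/length/GC%) are evaluated verbatim by
:func:`evaluate_criteria`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .util import as_rna, gc_percent

MIN_LOOP = 3  # minimum hairpin loop length enforced by the fold

#: stacking-weighted pair scores for the surrogate fold
PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}

#: per-unpaired-run free-energy penalty (kcal/mol) in the surrogate energy
LOOP_PENALTY = 0.5

_VALID_RNA = re.compile(r"^[ACGU]+$")


class FoldError(ValueError):
    """Invalid input to the folding routines."""


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldResult:
    """A folded sequence: dot-bracket structure plus free energy (kcal/mol)."""

    sequence: str
    structure: str
    dG: float

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise FoldError(
                f"structure length {len(self.structure)} != sequence length "
                f"{len(self.sequence)}"
            )
        pairs(self.structure)  # raises on unbalanced brackets

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


@dataclass(frozen=True)
class MatureSpan:
    """Position of the mature (or star) sequence within the precursor.

    Coordinates are 0-based half-open.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid mature span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class HairpinMetrics:
    """All quantities entering the twelve hairpin-determination criteria."""

    dG: float
    mir_len: int                      # precursor length (nt), MFEI denominator
    gc_percent: float                 # CG% of the precursor, 0-100
    hairpin_length: int               # up + down stem + terminal loop (nt)
    stem_bp: int                      # base pairs in the stem
    loop_length: int                  # terminal loop (nt)
    mature_bp: int                    # paired positions in the mature region
    pm_percent: float                 # % of the small RNA inside the stem arms
    mature_errors: int                # unpaired positions in the mature region
    largest_stem_bulge: int           # longest unpaired run in the stem
    largest_mature_bulge: int         # same, restricted to the mature region
    biased_mature_errors_in_bulge: int  # asymmetric errors in worst mature bulge
    biased_mature_bulges: int         # asymmetric bulges touching the mature region
    mfei: float                       # -dG*100/mir_len/gc_percent (NaN if GC%=0)
    multi_loop: bool = False          # structure had >1 terminal loop


#: criterion labels, in order (1)-(12)
CRITERIA_LABELS = (
    "dG <= -15 kcal/mol",
    "hairpin length >= 50 nt",
    "stem base pairs >= 16",
    "terminal loop <= 20 nt",
    "mature-region base pairs >= 12",
    "small RNA in stem (pm) >= 80%",
    "mature-region errors <= 7",
    "largest stem bulge <= 12",
    "largest mature bulge <= 8",
    "biased errors in worst mature bulge <= 4",
    "biased mature bulges <= 2",
    "MFEI >= 0.7",
)


@dataclass(frozen=True)
class CriteriaReport:
    """Twelve boolean verdicts, one per criterion, and their conjunction."""

    verdicts: tuple

    def __post_init__(self) -> None:
        if len(self.verdicts) != 12:
            raise ValueError("expected exactly 12 verdicts")

    @property
    def passed(self) -> bool:
        return all(self.verdicts)

    def failed_criteria(self) -> list:
        return [CRITERIA_LABELS[i] for i, ok in enumerate(self.verdicts) if not ok]


# ---------------------------------------------------------------------------
# structure utilities
# ---------------------------------------------------------------------------

def pairs(structure: str) -> list:
    """Base pairs (i, j) of a dot-bracket string; raises on unbalanced input."""
    stack: list = []
    out: list = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise FoldError(f"unbalanced ')' at position {i}")
            out.append((stack.pop(), i))
        elif c != ".":
            raise FoldError(f"invalid structure character {c!r}")
    if stack:
        raise FoldError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(out)


def structure_weight(seq: str, structure: str) -> int:
    """Total stacking weight of a structure under :data:`PAIR_WEIGHTS`."""
    rna = as_rna(seq)
    return sum(PAIR_WEIGHTS.get((rna[i], rna[j]), 0) for i, j in pairs(structure))


def _enclosed_unpaired_runs(structure: str) -> int:
    """Count maximal runs of unpaired positions enclosed by at least one pair."""
    depth = 0
    runs = 0
    in_run = False
    for c in structure:
        if c == "(":
            depth += 1
            in_run = False
        elif c == ")":
            depth -= 1
            in_run = False
        else:
            if depth > 0 and not in_run:
                runs += 1
            in_run = depth > 0
    return runs


def surrogate_energy(seq: str, structure: str) -> float:
    """Surrogate dG of a structure: -weight + 0.5 per enclosed unpaired run."""
    w = structure_weight(seq, structure)
    if w == 0:
        return 0.0
    return min(0.0, -float(w) + LOOP_PENALTY * _enclosed_unpaired_runs(structure))


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

def _pair_weight(a: str, b: str) -> int:
    return PAIR_WEIGHTS.get((a, b), 0)


def fold(seq: str) -> FoldResult:
    """Fold an RNA sequence with the surrogate maximum-weight dynamic program.

    Accepts DNA input (T is read as U).  Deterministic: traceback ties are
    broken toward pairing the leftmost candidate position.
    """
    rna = as_rna(seq)
    if not rna:
        raise FoldError("empty sequence")
    if not _VALID_RNA.match(rna):
        bad = sorted(set(rna) - set("ACGU"))
        raise FoldError(f"invalid characters in sequence: {bad}")

    n = len(rna)
    # M[i][j] = max weight over nested structures of rna[i..j] inclusive
    M = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i][j - 1]  # j unpaired
            row_j = rna[j]
            for k in range(i, j - MIN_LOOP):
                w = _pair_weight(rna[k], row_j)
                if not w:
                    continue
                left = M[i][k - 1] if k > i else 0
                inner = M[k + 1][j - 1] if k + 1 <= j - 1 else 0
                cand = left + w + inner
                if cand > best:
                    best = cand
            M[i][j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        best = M[i][j]
        if best == 0:
            continue
        paired = False
        for k in range(i, j - MIN_LOOP):
            w = _pair_weight(rna[k], rna[j])
            if not w:
                continue
            left = M[i][k - 1] if k > i else 0
            inner = M[k + 1][j - 1] if k + 1 <= j - 1 else 0
            if left + w + inner == best:
                structure[k] = "("
                structure[j] = ")"
                if k > i:
                    stack.append((i, k - 1))
                if k + 1 <= j - 1:
                    stack.append((k + 1, j - 1))
                paired = True
                break
        if not paired:
            stack.append((i, j - 1))

    s = "".join(structure)
    return FoldResult(sequence=rna, structure=s, dG=surrogate_energy(rna, s))


# ---------------------------------------------------------------------------
# MFEI and metrics
# ---------------------------------------------------------------------------

def compute_mfei(dG: float, mir_len: int, gc: float) -> float:
    """Minimal folding energy index: -dG*100 / mir_len / CG%."""
    if mir_len <= 0:
        raise ValueError("mir_len must be positive")
    if gc <= 0:
        raise ValueError("MFEI undefined for CG% = 0")
    return -dG * 100.0 / mir_len / gc


def _stem_chains(structure: str) -> list:
    """Decompose a structure into stem-loops.

    Each chain is the list of pairs from outermost to innermost of one
    helix-with-bulges region ending in a hairpin loop; chains stop at
    multiloop branch points.
    """
    plist = pairs(structure)
    partner = {}
    for i, j in plist:
        partner[i] = j
        partner[j] = i
    paired = set(partner)
    # innermost pairs: nothing paired strictly inside
    chains = []
    for (a, b) in plist:
        if any(p in paired for p in range(a + 1, b)):
            continue
        chain = [(a, b)]
        i, j = a, b
        while True:
            # scan left from i for the directly enclosing pair
            p = i - 1
            while p >= 0 and p not in paired:
                p -= 1
            if p < 0 or partner[p] < p:
                break  # exterior or sibling closing bracket: branch point
            q = partner[p]
            if q < j:
                break
            # the right gap must hold no other helix for a clean continuation
            if any(r in paired for r in range(j + 1, q)):
                break
            chain.append((p, q))
            i, j = p, q
        chain.reverse()  # outermost first
        chains.append(chain)
    return chains


def hairpin_metrics(fr: FoldResult, mature: MatureSpan) -> HairpinMetrics:
    """Compute all criterion metrics for a fold and a mature span.

    Multi-branch structures are flagged and evaluated on the stem-loop with
    the most base pairs.
    """
    n = len(fr.sequence)
    if mature.end > n:
        raise ValueError("mature span outside the precursor")
    gc = gc_percent(fr.sequence)
    mfei = compute_mfei(fr.dG, n, gc) if gc > 0 else math.nan
    mature_set = set(range(mature.start, mature.end))
    mlen = len(mature_set)

    chains = _stem_chains(fr.structure)
    if not chains:
        return HairpinMetrics(
            dG=fr.dG, mir_len=n, gc_percent=gc, hairpin_length=0, stem_bp=0,
            loop_length=0, mature_bp=0, pm_percent=0.0, mature_errors=mlen,
            largest_stem_bulge=0, largest_mature_bulge=0,
            biased_mature_errors_in_bulge=0, biased_mature_bulges=0,
            mfei=mfei, multi_loop=False,
        )

    multi = len(chains) > 1
    chain = max(chains, key=lambda c: (len(c), -c[0][0]))
    (i_out, j_out), (a, b) = chain[0], chain[-1]

    paired = set()
    for i, j in pairs(fr.structure):
        paired.add(i)
        paired.add(j)

    loop_length = b - a - 1
    stem_bp = len(chain)
    hairpin_length = j_out - i_out + 1
    stem_positions = set(range(i_out, a + 1)) | set(range(b, j_out + 1))

    mature_bp = sum(1 for p in mature_set if p in paired)
    mature_errors = mlen - mature_bp
    pm = 100.0 * len(mature_set & stem_positions) / mlen if mlen else 0.0

    # maximal unpaired runs within each stem arm
    def runs(lo: int, hi: int) -> Iterable[range]:
        start = None
        for p in range(lo, hi + 1):
            if p not in paired:
                if start is None:
                    start = p
            elif start is not None:
                yield range(start, p)
                start = None
        if start is not None:
            yield range(start, hi + 1)

    all_runs = list(runs(i_out, a)) + list(runs(b, j_out))
    largest_stem_bulge = max((len(r) for r in all_runs), default=0)
    largest_mature_bulge = max(
        (len(set(r) & mature_set) for r in all_runs), default=0
    )

    # internal loops/bulges between consecutive stem pairs; bias = asymmetry
    biased_err = 0
    biased_count = 0
    for (i1, j1), (i2, j2) in zip(chain, chain[1:]):
        left = range(i1 + 1, i2)
        right = range(j2 + 1, j1)
        if not left and not right:
            continue
        touches = bool((set(left) | set(right)) & mature_set)
        asym = abs(len(left) - len(right))
        if touches:
            biased_err = max(biased_err, asym)
            if asym > 0:
                biased_count += 1

    return HairpinMetrics(
        dG=fr.dG, mir_len=n, gc_percent=gc, hairpin_length=hairpin_length,
        stem_bp=stem_bp, loop_length=loop_length, mature_bp=mature_bp,
        pm_percent=pm, mature_errors=mature_errors,
        largest_stem_bulge=largest_stem_bulge,
        largest_mature_bulge=largest_mature_bulge,
        biased_mature_errors_in_bulge=biased_err,
        biased_mature_bulges=biased_count,
        mfei=mfei, multi_loop=multi,
    )


def evaluate_criteria(m: HairpinMetrics) -> CriteriaReport:
    """Apply the twelve annotation criteria verbatim.

    An undefined MFEI (CG% = 0, stored as NaN) fails criterion 12.
    """
    verdicts = (
        m.dG <= -15.0,
        m.hairpin_length >= 50,
        m.stem_bp >= 16,
        m.loop_length <= 20,
        m.mature_bp >= 12,
        m.pm_percent >= 80.0,
        m.mature_errors <= 7,
        m.largest_stem_bulge <= 12,
        m.largest_mature_bulge <= 8,
        m.biased_mature_errors_in_bulge <= 4,
        m.biased_mature_bulges <= 2,
        bool(m.mfei >= 0.7),  # NaN compares False
    )
    return CriteriaReport(verdicts=verdicts)


# ---------------------------------------------------------------------------
# external fold interop (Vienna-style text)
# ---------------------------------------------------------------------------

_ENERGY_RE = re.compile(r"^([.()]+)\s*\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def parse_fold_text(text: str) -> FoldResult:
    """Parse one Vienna-style record: sequence line, then structure (dG)."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise FoldError("expected a sequence line and a structure line")
    seq = as_rna(lines[0])
    if not _VALID_RNA.match(seq):
        raise FoldError("invalid sequence line")
    m = _ENERGY_RE.match(lines[1])
    if not m:
        raise FoldError(f"malformed structure line: {lines[1]!r}")
    structure, dg = m.group(1), float(m.group(2))
    return FoldResult(sequence=seq, structure=structure, dG=dg)


def read_fold_file(path) -> FoldResult:
    """Read a Vienna-style fold file (see :func:`parse_fold_text`)."""
    with open(path) as fh:
        return parse_fold_text(fh.read())


def write_fold_file(fr: FoldResult, path, name: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if name:
            fh.write(f">{name}\n")
        fh.write(f"{fr.sequence}\n{fr.structure} ({fr.dG:.2f})\n")


# ---------------------------------------------------------------------------
# precursor screening over genomic flanks
# ---------------------------------------------------------------------------

@dataclass
class HairpinCall:
    """Outcome of screening a genomic flank for a qualifying precursor."""

    passed: bool                       # some window satisfies all 12 criteria
    folded: bool                       # some window forms a credible stem-loop
    window: Optional[tuple] = None     # (start, end) within the flank
    fold: Optional[FoldResult] = None
    metrics: Optional[HairpinMetrics] = None
    report: Optional[CriteriaReport] = None
    mature_in_window: Optional[MatureSpan] = None


@dataclass
class HairpinScreen:
    """Scan candidate precursor windows around a mapped small RNA.

    The mature read marks one stem arm but the precursor boundaries are
    unknown, so windows of several lengths are anchored at either end of the
    read (read as 5p arm and as 3p arm) and each is folded and judged by the
    twelve criteria.  ``fold_min_bp``/``fold_max_dg`` define the weaker
    "forms a hairpin at all" call used to separate hairpin-failing
    candidates from non-folding loci.
    """

    window_lengths: Sequence[int] = (60, 70, 80, 90, 100, 110)
    margins: Sequence[int] = (2, 8)
    min_window: int = 50
    fold_min_bp: int = 10
    fold_max_dg: float = -10.0

    def candidate_windows(self, flank_len: int, m_start: int, m_end: int):
        seen = set()
        for length in self.window_lengths:
            for margin in self.margins:
                for ws, we in (
                    (m_start - margin, m_start - margin + length),  # read = 5p arm
                    (m_end + margin - length, m_end + margin),      # read = 3p arm
                ):
                    ws, we = max(0, ws), min(flank_len, we)
                    if we - ws < self.min_window:
                        continue
                    if not (ws <= m_start and m_end <= we):
                        continue
                    if (ws, we) not in seen:
                        seen.add((ws, we))
                        yield ws, we

    def evaluate(self, flank: str, m_start: int, m_end: int) -> HairpinCall:
        """Screen every candidate window; return the first criteria-passing one."""
        folded = False
        best: Optional[HairpinCall] = None
        for ws, we in self.candidate_windows(len(flank), m_start, m_end):
            fr = fold(flank[ws:we])
            mature = MatureSpan(m_start - ws, m_end - ws)
            metrics = hairpin_metrics(fr, mature)
            if metrics.stem_bp >= self.fold_min_bp and fr.dG <= self.fold_max_dg:
                folded = True
            report = evaluate_criteria(metrics)
            call = HairpinCall(
                passed=report.passed, folded=folded, window=(ws, we), fold=fr,
                metrics=metrics, report=report,
                mature_in_window=mature,
            )
            if report.passed:
                return call
            if best is None or sum(report.verdicts) > sum(best.report.verdicts):
                best = call
        if best is None:
            return HairpinCall(passed=False, folded=False)
        best.folded = folded
        return best
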