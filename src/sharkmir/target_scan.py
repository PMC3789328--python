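"""miRNA target-site scanning by complementarity alignment.

The miRNA (read 3'->5') is locally aligned against each target (5'->3')
with pair-complementarity scoring: Watson-Crick pairs score ``match``, G:U
wobbles ``wobble``, other juxtapositions ``mismatch``; affine gap penalties
``gap_open``/``gap_extend``.  Substitution scores at miRNA seed positions
(2-8 from the 5' end by default) are multiplied by ``scaling``.  A site is
reported when its alignment score reaches ``score_threshold`` AND its
duplex energy is at or below ``energy_threshold``.

The duplex energy is a simple stacking surrogate (per helix stack: GC -2.2,
AU -1.1, GU -0.5 kcal/mol; +4.1 per interior loop/bulge opening), not a
nearest-neighbour thermodynamic model; externally computed energies can be
injected through the ``energy_fn`` hook.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .util import as_rna

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}

STACK_ENERGY = {"GC": -2.2, "AU": -1.1, "GU": -0.5}
LOOP_OPEN_ENERGY = 4.1


@dataclass(frozen=True)
class ScanParams:
    """Scan thresholds and scoring weights."""

    gap_open: float = -8.0
    gap_extend: float = -2.0
    score_threshold: float = 50.0
    energy_threshold: float = -20.0
    scaling: float = 2.0
    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    seed_start: int = 2   # 1-based, from the miRNA 5' end, inclusive
    seed_end: int = 8

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.scaling < 1:
            raise ValueError("scaling must be >= 1")


@dataclass
class TargetHit:
    """One reported miRNA binding site on a target sequence."""

    mirna_id: str
    target_id: str
    target_start: int        # 0-based half-open window on the target
    target_end: int
    score: float
    energy: float
    alignment: Tuple[str, str, str]  # query 3'->5', pair line, target 5'->3'
    n_pairs: int

    def render(self) -> str:
        q, m, t = self.alignment
        return (
            f"Query 3' {q} 5'\n"
            f"         {m}\n"
            f"Ref   5' {t} 3'"
        )


def _pair_kind(q: str, t: str) -> Optional[str]:
    """'GC'/'AU'/'GU' when (q, t) can pair, else None."""
    if (q, t) in WC:
        return "GC" if q in "GC" else "AU"
    if (q, t) in WOBBLE:
        return "GU"
    return None


def duplex_energy(alignment_columns: Sequence[Tuple[Optional[str], Optional[str]]]) -> float:
    """Surrogate duplex energy of aligned (query_base, target_base) columns.

    A gap is encoded as None.  Each stack of two adjacent paired columns
    adds the energy of its inner pair; every interruption between paired
    columns (mismatch run or bulge) opens one interior loop at +4.1.
    A lone base pair has no stack and costs nothing.
    """
    energy = 0.0
    prev_paired = False
    seen_pair = False
    pending_loop = False
    for q, t in alignment_columns:
        kind = _pair_kind(q, t) if (q is not None and t is not None) else None
        if kind is not None:
            if prev_paired:
                energy += STACK_ENERGY[kind]
            elif seen_pair and pending_loop:
                energy += LOOP_OPEN_ENERGY
            seen_pair = True
            prev_paired = True
            pending_loop = False
        else:
            if seen_pair:
                pending_loop = True
            prev_paired = False
    return energy


# ---------------------------------------------------------------------------
# local alignment
# ---------------------------------------------------------------------------

def _position_scale(params: ScanParams, mirna_len: int, rev_idx: int) -> float:
    """Seed scaling for reversed-query index (0-based)."""
    pos_from_5p = mirna_len - rev_idx  # 1-based
    if params.seed_start <= pos_from_5p <= params.seed_end:
        return params.scaling
    return 1.0


def _substitution(params: ScanParams, q: str, t: str, scale: float) -> float:
    kind = _pair_kind(q, t)
    if kind is None:
        base = params.mismatch
    elif kind == "GU":
        base = params.wobble
    else:
        base = params.match
    return base * scale


def _smith_waterman(
    query: str, target: str, params: ScanParams, mirna_len: int
) -> Tuple[List[List[float]], List[List[float]], List[List[float]]]:
    """Affine-gap local alignment matrices (H: match end, E/F: gap states)."""
    n, m = len(query), len(target)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (target consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target
    for i in range(1, n + 1):
        scale = _position_scale(params, mirna_len, i - 1)
        qi = query[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + params.gap_open, E[i][j - 1] + params.gap_extend)
            F[i][j] = max(H[i - 1][j] + params.gap_open, F[i - 1][j] + params.gap_extend)
            diag = H[i - 1][j - 1] + _substitution(params, qi, target[j - 1], scale)
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
    return H, E, F


def _traceback(
    H, E, F, query: str, target: str, params: ScanParams, mirna_len: int,
    i: int, j: int,
) -> Tuple[List[Tuple[Optional[str], Optional[str]]], int]:
    """Recover the alignment ending at (i, j); returns columns and target start."""
    cols: List[Tuple[Optional[str], Optional[str]]] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0.0:
                break
            scale = _position_scale(params, mirna_len, i - 1)
            diag = H[i - 1][j - 1] + _substitution(
                params, query[i - 1], target[j - 1], scale
            )
            if H[i][j] == diag:
                cols.append((query[i - 1], target[j - 1]))
                i -= 1
                j -= 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols.append((None, target[j - 1]))
            if E[i][j] == H[i][j - 1] + params.gap_open:
                state = "H"
            j -= 1
        else:
            cols.append((query[i - 1], None))
            if F[i][j] == H[i - 1][j] + params.gap_open:
                state = "H"
            i -= 1
    cols.reverse()
    return cols, j


def _alignment_strings(
    cols: Sequence[Tuple[Optional[str], Optional[str]]]
) -> Tuple[str, str, str]:
    q_line, m_line, t_line = [], [], []
    for q, t in cols:
        q_line.append(q or "-")
        t_line.append(t or "-")
        if q is not None and t is not None:
            kind = _pair_kind(q, t)
            m_line.append("|" if kind in ("GC", "AU") else ":" if kind else " ")
        else:
            m_line.append(" ")
    return "".join(q_line), "".join(m_line), "".join(t_line)


def scan(
    mirna: str,
    target: str,
    params: ScanParams = ScanParams(),
    mirna_id: str = "miRNA",
    target_id: str = "target",
    energy_fn: Optional[Callable[[Sequence[Tuple[Optional[str], Optional[str]]]], float]] = None,
) -> List[TargetHit]:
    """Report miRNA binding sites on one target passing both thresholds.

    Candidate sites are local-alignment score peaks along the target; sites
    overlapping an already-kept site by >= 50% are dropped (higher score
    wins).  Hits come back sorted by descending score.
    """
    mi = as_rna(mirna)
    tg = as_rna(target)
    if not 15 <= len(mi) <= 30:
        raise ValueError("miRNA must be 15-30 nt")
    if len(tg) < len(mi):
        raise ValueError("target shorter than the miRNA")
    if energy_fn is None:
        energy_fn = duplex_energy

    query = mi[::-1]  # 3'->5'
    H, E, F = _smith_waterman(query, tg, params, len(mi))

    # best alignment ending at each target column
    m = len(tg)
    col_best: List[Tuple[float, int]] = []
    for j in range(m + 1):
        bi, bs = 0, 0.0
        for i in range(len(query) + 1):
            if H[i][j] > bs:
                bs, bi = H[i][j], i
        col_best.append((bs, bi))

    candidates = []
    for j in range(1, m + 1):
        s = col_best[j][0]
        if s < params.score_threshold:
            continue
        left = col_best[j - 1][0] if j >= 1 else 0.0
        right = col_best[j + 1][0] if j + 1 <= m else 0.0
        if s >= left and s > right or (s >= left and j == m):
            candidates.append((s, j, col_best[j][1]))
    candidates.sort(key=lambda c: (-c[0], c[1]))

    hits: List[TargetHit] = []
    kept_windows: List[Tuple[int, int]] = []
    for score, j, i in candidates:
        cols, t_start = _traceback(H, E, F, query, tg, params, len(mi), i, j)
        if not cols:
            continue
        window = (t_start, j)
        span = window[1] - window[0]
        overlaps = False
        for ws, we in kept_windows:
            ov = min(we, window[1]) - max(ws, window[0])
            if ov > 0 and ov >= 0.5 * min(span, we - ws):
                overlaps = True
                break
        if overlaps:
            continue
        energy = energy_fn(cols)
        if energy > params.energy_threshold:
            continue
        n_pairs = sum(
            1 for q, t in cols
            if q is not None and t is not None and _pair_kind(q, t)
        )
        hits.append(
            TargetHit(
                mirna_id=mirna_id, target_id=target_id,
                target_start=t_start, target_end=j,
                score=score, energy=energy,
                alignment=_alignment_strings(cols),
                n_pairs=n_pairs,
            )
        )
        kept_windows.append(window)
    hits.sort(key=lambda h: (-h.score, h.target_start))
    return hits


def scan_many(
    mirnas: Mapping[str, str],
    targets: Mapping[str, str],
    params: ScanParams = ScanParams(),
) -> pd.DataFrame:
    """Scan every miRNA against every target; one row per reported site."""
    rows = []
    for mid, mseq in mirnas.items():
        for tid, tseq in targets.items():
            if len(tseq) < len(mseq):
                continue
            for hit in scan(mseq, tseq, params, mirna_id=mid, target_id=tid):
                rows.append(
                    {
                        "mirna_id": hit.mirna_id,
                        "target_id": hit.target_id,
                        "target_start": hit.target_start + 1,  # 1-based report
                        "target_end": hit.target_end,
                        "score": hit.score,
                        "energy": hit.energy,
                        "n_pairs": hit.n_pairs,
                        "alignment": hit.render(),
                    }
                )
    return pd.DataFrame(rows)
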