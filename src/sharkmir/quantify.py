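"""Expression quantification: RPM normalization, log2 ratios, and 2^-ddCt.

Sequencing counts are normalized to reads per million (RPM) per library and
compared as log2 ratios with a small pseudocount; |log2 ratio| > 1 flags a
miRNA as differential.  qPCR tables are reduced by the comparative-Ct
method: dCt = Ct(target) - Ct(reference) on replicate means,
ddCt = dCt(group) - dCt(control group), relative expression = 2^-ddCt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_PSEUDOCOUNT = 0.25


@dataclass(frozen=True)
class FoldChange:
    """Relative expression of one gene in one group by 2^-ddCt."""

    gene: str
    group: str
    delta_ct: float
    delta_delta_ct: float
    fold: float
    se: float  # SE of ddCt (cycles), propagated in quadrature


def normalize_rpm(counts, totals):
    """Reads-per-million: counts * 1e6 / library total.

    Accepts scalars, numpy arrays, or a DataFrame with one column per
    library (``totals`` then maps library -> total).
    """
    if isinstance(counts, pd.DataFrame):
        out = counts.astype(float).copy()
        for col in out.columns:
            total = totals[col]
            if total <= 0:
                raise ValueError(f"library {col}: total must be > 0")
            out[col] = out[col] * 1e6 / total
        return out
    totals = np.asarray(totals, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("library totals must be > 0")
    return np.asarray(counts, dtype=float) * 1e6 / totals


def log2_ratio(a_rpm: float, b_rpm: float, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2((a + pseudocount) / (b + pseudocount))."""
    if a_rpm < 0 or b_rpm < 0:
        raise ValueError("RPM values must be >= 0")
    return math.log2((a_rpm + pseudocount) / (b_rpm + pseudocount))


def is_differential(ratio: float, threshold: float = 1.0) -> bool:
    """Strict |log2 ratio| > threshold (exact doubling is not flagged)."""
    return abs(ratio) > threshold


def expression_table(
    counts: pd.DataFrame,
    totals: Mapping[str, int],
    treated: str,
    control: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-miRNA RPM, log2(treated/control) and the differential flag.

    ``counts`` is indexed by miRNA id with one raw-count column per library.
    """
    rpm = normalize_rpm(counts, totals)
    out = counts.copy()
    for col in counts.columns:
        out[f"{col}_rpm"] = rpm[col]
    out["log2_ratio"] = [
        log2_ratio(a, b, pseudocount)
        for a, b in zip(rpm[treated], rpm[control])
    ]
    out["differential"] = [is_differential(r) for r in out["log2_ratio"]]
    return out


# ---------------------------------------------------------------------------
# qPCR 2^-ddCt
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """Replicate Ct values in long format plus the analysis anchors.

    ``data`` columns: gene, group, replicate, ct.
    """

    data: pd.DataFrame
    reference_gene: str
    control_group: str

    def __post_init__(self) -> None:
        required = {"gene", "group", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be > 0")
        if self.reference_gene not in set(self.data["gene"]):
            raise ValueError(f"reference gene {self.reference_gene!r} absent")
        if self.control_group not in set(self.data["group"]):
            raise ValueError(f"control group {self.control_group!r} absent")

    @classmethod
    def from_csv(cls, path, reference_gene: str, control_group: str,
                 sep: Optional[str] = None) -> "CtTable":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls(pd.read_csv(path, sep=sep), reference_gene, control_group)

    def genes(self) -> Sequence[str]:
        return [g for g in self.data["gene"].unique() if g != self.reference_gene]

    def groups(self) -> Sequence[str]:
        return list(self.data["group"].unique())

    def _cell(self, gene: str, group: str) -> np.ndarray:
        sel = self.data[(self.data["gene"] == gene) & (self.data["group"] == group)]
        if sel.empty:
            raise ValueError(f"no Ct replicates for gene={gene!r} group={group!r}")
        return sel["ct"].to_numpy(dtype=float)

    def mean_ct(self, gene: str, group: str) -> float:
        return float(self._cell(gene, group).mean())

    def sem_ct(self, gene: str, group: str) -> float:
        v = self._cell(gene, group)
        if len(v) < 2:
            return 0.0
        return float(v.std(ddof=1) / math.sqrt(len(v)))


def ddct(table: CtTable, gene: str, group: str) -> FoldChange:
    """Comparative-Ct relative expression of one gene in one group.

    Replicates are averaged before differencing; the control group comes
    out at fold 1 exactly.  The SE is that of ddCt, combining the four
    mean-Ct standard errors in quadrature.
    """
    d_group = table.mean_ct(gene, group) - table.mean_ct(table.reference_gene, group)
    d_control = (
        table.mean_ct(gene, table.control_group)
        - table.mean_ct(table.reference_gene, table.control_group)
    )
    dd = d_group - d_control
    se = math.sqrt(
        table.sem_ct(gene, group) ** 2
        + table.sem_ct(table.reference_gene, group) ** 2
        + table.sem_ct(gene, table.control_group) ** 2
        + table.sem_ct(table.reference_gene, table.control_group) ** 2
    )
    return FoldChange(
        gene=gene, group=group, delta_ct=d_group, delta_delta_ct=dd,
        fold=2.0 ** (-dd), se=se,
    )


def ddct_table(table: CtTable) -> pd.DataFrame:
    """2^-ddCt for every (gene, group), mirroring a mean +/- SE presentation."""
    rows = []
    for gene in table.genes():
        for group in table.groups():
            fc = ddct(table, gene, group)
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "mean_ct": table.mean_ct(gene, group),
                    "sem_ct": table.sem_ct(gene, group),
                    "delta_ct": fc.delta_ct,
                    "delta_delta_ct": fc.delta_delta_ct,
                    "fold_2_neg_ddct": fc.fold,
                    "se_ddct": fc.se,
                }
            )
    return pd.DataFrame(rows)
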