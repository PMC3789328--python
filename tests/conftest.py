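"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from functools import lru_cache
from typing import FrozenSet, List, Tuple

import numpy as np
import pytest

PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


def oracle_max_weight(seq: str) -> int:
    """Maximum stacking weight over nested structures with loop >= 3.

    Independent of the package's fold: memoized recursion branching on the
    leftmost position (pair it with every admissible partner, or leave it
    unpaired), equivalent to exhaustive enumeration of nested structures.
    """
    rna = seq.upper().replace("T", "U")

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if j - i < 4:  # too short to hold a pair with loop >= 3
            return 0
        best = go(i + 1, j)  # i unpaired
        for k in range(i + 4, j + 1):
            w = PAIR_WEIGHTS.get((rna[i], rna[k]), 0)
            if w:
                cand = w + go(i + 1, k - 1) + go(k + 1, j)
                if cand > best:
                    best = cand
        return best

    return go(0, len(rna) - 1)


def enumerate_structures(seq: str) -> List[FrozenSet[Tuple[int, int]]]:
    """All nested pair sets with loop >= 3 (exponential; tiny inputs only)."""
    rna = seq.upper().replace("T", "U")

    def go(i: int, j: int):
        if j - i < 4:
            yield frozenset()
            return
        for s in go(i + 1, j):
            yield s
        for k in range(i + 4, j + 1):
            if PAIR_WEIGHTS.get((rna[i], rna[k]), 0):
                for inner in go(i + 1, k - 1):
                    for right in go(k + 1, j):
                        yield frozenset({(i, k)}) | inner | right

    return list(go(0, len(rna) - 1))


def union_find_clusters(loci, window: int) -> FrozenSet[FrozenSet[str]]:
    """Brute-force single-linkage partition over pairwise gap distances."""
    n = len(loci)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = loci[i], loci[j]
            if a.chrom != b.chrom:
                continue
            lo, hi = (a, b) if a.start <= b.start else (b, a)
            gap = max(0, hi.start - lo.end)
            if gap <= window:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(loci[i].mirna_id)
    return frozenset(frozenset(g) for g in groups.values())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130917)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
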