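"""Small shared helpers: alphabet normalization, reverse complement, rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def as_dna(seq: str) -> str:
    """Uppercase and convert U -> T."""
    return seq.upper().replace("U", "T")


def as_rna(seq: str) -> str:
    """Uppercase and convert T -> U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement; accepts DNA or RNA, preserves the alphabet."""
    s = seq.upper()
    if "U" in s:
        return s.translate(_RNA_COMPLEMENT)[::-1]
    return s.translate(_DNA_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """G+C content on a 0-100 scale."""
    if not seq:
        return 0.0
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed report tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
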