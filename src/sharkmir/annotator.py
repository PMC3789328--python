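"""isomiR-style variant nomenclature against known reference miRNAs.

A detected mature sequence is named after its closest known miRNA plus a
suffix encoding how it differs: ``L-n``/``L+n`` for n bases fewer/more on
the left end, ``R-n``/``R+n`` on the right end, and ``<k>ss`` followed by
``<pos><from><to>`` tokens for k substitutions (1-based positions within the
detected sequence, DNA alphabet).  ``fru-miR-144_L-1R+2_1ss12TA`` therefore
reads: one base trimmed on the left, two added on the right, one
substitution T->A at position 12.  An exact match renders the bare known
name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .util import as_dna


class NoRelationError(ValueError):
    """Detected sequence cannot be related to the known miRNA within bounds."""


class NameParseError(ValueError):
    """Malformed variant-name suffix."""


#: full grammar of an emitted variant name
NAME_PATTERN = re.compile(
    r"^[\w-]+(_L[+-]\d+)?(R[+-]\d+)?(_\d+ss(\d+[ACGTU]{2})+)?$"
)

_SUB_TOKEN = re.compile(r"(\d+)([ACGTU])([ACGTU])")
_OFFSET_PART = re.compile(r"^(?:L(?P<l>[+-]\d+))?(?:R(?P<r>[+-]\d+))?$")
_SUBS_PART = re.compile(r"^(?P<k>\d+)ss(?P<subs>(?:\d+[ACGTU]{2})+)$")


@dataclass(frozen=True)
class KnownMiRNA:
    """A reference mature miRNA (the representative sequence of its family)."""

    name: str
    rep_seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("empty miRNA name")
        object.__setattr__(self, "rep_seq", as_dna(self.rep_seq))
        if not 15 <= len(self.rep_seq) <= 30:
            raise ValueError("rep_seq length must be 15-30 nt")


@dataclass(frozen=True)
class VariantDescriptor:
    """End offsets and substitutions relating detected to known.

    ``left_offset``/``right_offset`` follow the sign convention of the name:
    negative = the detected sequence is shorter on that side, positive =
    longer.  Substitution positions are 1-based within the detected
    sequence.
    """

    left_offset: int = 0
    right_offset: int = 0
    substitutions: Tuple[Tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        last = 0
        for pos, frm, to in self.substitutions:
            if pos <= last:
                raise ValueError("substitution positions must be strictly increasing")
            if frm == to:
                raise ValueError("substitution with identical bases")
            last = pos

    @property
    def is_identity(self) -> bool:
        return (
            self.left_offset == 0
            and self.right_offset == 0
            and not self.substitutions
        )


def describe_variant(
    detected: str,
    known: KnownMiRNA,
    max_offset: int = 5,
    max_substitutions: int = 3,
    flank: Optional[Tuple[str, str]] = None,
) -> VariantDescriptor:
    """Find the minimal-substitution ungapped alignment of detected to known.

    End offsets are searched over +/- ``max_offset`` on each side; ties in
    substitution count are broken by smaller total end displacement, then by
    the smaller left offset.  When ``flank`` (upstream, downstream genomic
    context of the known sequence) is given, candidate alignments must
    reconstruct the detected sequence exactly, extension bases included.
    """
    d = as_dna(detected)
    k = known.rep_seq
    best: Optional[Tuple[int, int, int, VariantDescriptor]] = None
    for left in range(-max_offset, max_offset + 1):
        right = len(d) - len(k) - left
        if abs(right) > max_offset:
            continue
        lo = max(0, left)                 # first detected index over known
        hi = min(len(d), len(k) + left)   # one past last such index
        if hi - lo <= 0:
            continue
        subs = []
        ok = True
        for i in range(lo, hi):
            if d[i] != k[i - left]:
                subs.append((i + 1, k[i - left], d[i]))
                if len(subs) > max_substitutions:
                    ok = False
                    break
        if not ok:
            continue
        vd = VariantDescriptor(left, right, tuple(subs))
        if flank is not None:
            try:
                if apply_descriptor(vd, known, flank) != d:
                    continue
            except (ValueError, IndexError):
                continue
        key = (len(subs), abs(left) + abs(right), left)
        if best is None or key < best[:3]:
            best = (*key, vd)
    if best is None:
        raise NoRelationError(
            f"{d} cannot be related to {known.name} within +/-{max_offset} "
            f"end offsets and {max_substitutions} substitutions"
        )
    return best[3]


def encode_name(known_name: str, vd: VariantDescriptor) -> str:
    """Render the annotated name; the identity variant is the bare known name."""
    parts = [known_name]
    off = ""
    if vd.left_offset:
        off += f"L{vd.left_offset:+d}"
    if vd.right_offset:
        off += f"R{vd.right_offset:+d}"
    if off:
        parts.append(off)
    if vd.substitutions:
        parts.append(
            f"{len(vd.substitutions)}ss"
            + "".join(f"{p}{f}{t}" for p, f, t in vd.substitutions)
        )
    return "_".join(parts)


def parse_name(name: str, known_name: str) -> VariantDescriptor:
    """Inverse of :func:`encode_name` for a given known miRNA name."""
    if name == known_name:
        return VariantDescriptor()
    if not name.startswith(known_name + "_"):
        raise NameParseError(f"{name!r} is not a variant of {known_name!r}")
    suffix = name[len(known_name) + 1 :]
    parts = suffix.split("_")
    if len(parts) > 2 or not parts[0]:
        raise NameParseError(f"malformed suffix {suffix!r}")

    left = right = 0
    subs: Tuple[Tuple[int, str, str], ...] = ()
    first = parts[0]
    m_off = _OFFSET_PART.match(first)
    if m_off and (m_off.group("l") or m_off.group("r")):
        left = int(m_off.group("l") or 0)
        right = int(m_off.group("r") or 0)
        rest = parts[1] if len(parts) == 2 else None
    else:
        rest = first
        if len(parts) == 2:
            raise NameParseError(f"unrecognized offset token {first!r}")
    if rest is not None:
        m_subs = _SUBS_PART.match(rest)
        if not m_subs:
            raise NameParseError(f"unrecognized substitution token {rest!r}")
        tokens = _SUB_TOKEN.findall(m_subs.group("subs"))
        if len(tokens) != int(m_subs.group("k")):
            raise NameParseError(
                f"substitution count {m_subs.group('k')} does not match "
                f"{len(tokens)} tokens in {rest!r}"
            )
        subs = tuple(
            (int(p), as_dna(f), as_dna(t)) for p, f, t in tokens
        )
    return VariantDescriptor(left, right, subs)


def apply_descriptor(
    vd: VariantDescriptor,
    known: KnownMiRNA,
    flank: Tuple[str, str] = ("", ""),
) -> str:
    """Reconstruct the detected sequence from known + descriptor.

    Positive end offsets draw bases from ``flank`` (upstream, downstream
    genomic context of the known sequence).
    """
    up, down = as_dna(flank[0]), as_dna(flank[1])
    k = known.rep_seq
    core_start = max(0, -vd.left_offset)
    core_end = len(k) + min(0, vd.right_offset)
    if core_end <= core_start:
        raise ValueError("offsets leave no overlap with the known sequence")
    prefix = ""
    if vd.left_offset > 0:
        if len(up) < vd.left_offset:
            raise ValueError("upstream flank too short for left extension")
        prefix = up[len(up) - vd.left_offset :]
    suffix = ""
    if vd.right_offset > 0:
        if len(down) < vd.right_offset:
            raise ValueError("downstream flank too short for right extension")
        suffix = down[: vd.right_offset]
    detected = list(prefix + k[core_start:core_end] + suffix)
    for pos, frm, to in vd.substitutions:
        if not 1 <= pos <= len(detected):
            raise ValueError(f"substitution position {pos} outside sequence")
        if detected[pos - 1] != as_dna(frm):
            raise ValueError(
                f"substitution at {pos} expects {frm}, found {detected[pos - 1]}"
            )
        detected[pos - 1] = as_dna(to)
    return "".join(detected)


def decode_name(
    name: str,
    known: KnownMiRNA,
    flank: Tuple[str, str] = ("", ""),
) -> str:
    """Reconstruct a detected sequence from its annotated name."""
    return apply_descriptor(parse_name(name, known.name), known, flank)


# ---------------------------------------------------------------------------
# putative-candidate (PC) naming and the annotation table
# ---------------------------------------------------------------------------

def pc_name(arm: str, rank: int, count: int) -> str:
    """Name a putative-candidate miRNA: PC-{arm}-{rank}_{count}.

    ``rank`` orders candidates of that arm by descending read abundance.
    """
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    return f"PC-{arm}-{rank}_{count}"


def assign_pc_names(candidates: Sequence[Tuple[str, str, int]]) -> List[str]:
    """Name (sequence, arm, count) candidates, ranking per arm by abundance.

    Ties are broken lexicographically on the sequence for determinism.
    """
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-candidates[i][2], candidates[i][0]),
    )
    names = [""] * len(candidates)
    rank = {"5p": 0, "3p": 0}
    for i in order:
        seq, arm, count = candidates[i]
        rank[arm] += 1
        names[i] = pc_name(arm, rank[arm], count)
    return names


def best_known_match(
    detected: str,
    knowns: Iterable[KnownMiRNA],
    max_offset: int = 5,
    max_substitutions: int = 3,
) -> Optional[Tuple[KnownMiRNA, VariantDescriptor]]:
    """The known miRNA relating to the detected sequence with fewest edits."""
    best = None
    for known in knowns:
        try:
            vd = describe_variant(detected, known, max_offset, max_substitutions)
        except NoRelationError:
            continue
        key = (
            len(vd.substitutions),
            abs(vd.left_offset) + abs(vd.right_offset),
            known.name,
        )
        if best is None or key < best[0]:
            best = (key, known, vd)
    if best is None:
        return None
    return best[1], best[2]


def annotation_table(
    detected_seqs: Sequence[str],
    knowns: Sequence[KnownMiRNA],
    max_offset: int = 5,
    max_substitutions: int = 3,
) -> pd.DataFrame:
    """Name every detected sequence against a known-miRNA reference set."""
    rows = []
    for seq in detected_seqs:
        match = best_known_match(seq, knowns, max_offset, max_substitutions)
        if match is None:
            rows.append(
                {"sequence": seq, "known": "", "left_offset": 0,
                 "right_offset": 0, "substitutions": "", "name": ""}
            )
            continue
        known, vd = match
        rows.append(
            {
                "sequence": seq,
                "known": known.name,
                "left_offset": vd.left_offset,
                "right_offset": vd.right_offset,
                "substitutions": "".join(
                    f"{p}{f}{t}" for p, f, t in vd.substitutions
                ),
                "name": encode_name(known.name, vd),
            }
        )
    return pd.DataFrame(rows)
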