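"""Wildcard pattern classification by per-position score extremization.

A pattern such as ``CxFLWx`` fixes some positions and leaves others free
('x' = any of the 20 residues; ``[ILV]`` = a restricted choice).  Since
the amyloidogenicity value is a sum of independent per-position terms,
the exact minimum and maximum of A over all peptides matching a pattern
are obtained in closed form by extremizing each slot separately — no
enumeration over the (up to 20**length) matching peptides is needed.
A pattern is all-amyloidogenic iff its minimum A is >= 0 and
all-non-amyloidogenic iff its maximum A is < 0, consistent with the
peptide-level decision threshold.

Patterns whose extreme value lies within ~0.03 of the threshold are
sensitive to the 2-decimal rounding of the published matrix and are
flagged as such rather than adjudicated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import reduce
from typing import Literal

import numpy as np

from .scoring import AMINO_ACIDS, EffectMatrix, PeptideError, PredictedClass

PatternClass = Literal["all_amyloidogenic", "all_non_amyloidogenic", "mixed"]

#: |extreme A| below this is within rounding error of the 2-decimal weights.
ROUNDING_SENSITIVITY = 0.03

_TOKEN_RE = re.compile(r"\[([A-Za-z]+)\]|([A-Za-z])")

_FULL_SET = frozenset(AMINO_ACIDS)


class PatternError(ValueError):
    """A pattern string is malformed for the given length."""


@dataclass(frozen=True)
class Pattern:
    """Per-position allowed-residue sets."""

    slots: tuple[frozenset[str], ...]

    @property
    def length(self) -> int:
        return len(self.slots)

    @property
    def cardinality(self) -> int:
        """Number of peptides matching the pattern (product of slot sizes)."""
        n = 1
        for s in self.slots:
            n *= len(s)
        return n

    def __str__(self) -> str:
        return format_pattern(self)


def parse_pattern(text: str, length: int = 6) -> Pattern:
    """Parse pattern notation into per-position residue sets.

    ``x``/``X`` is a full wildcard, a single letter a fixed residue, and
    a bracketed group like ``[ILV]`` a restricted wildcard.
    """
    text = text.strip()
    slots: list[frozenset[str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise PatternError(
                f"bad token at offset {pos} in pattern {text!r}"
            )
        group, single = m.group(1), m.group(2)
        if single is not None:
            ch = single.upper()
            if ch == "X":
                slots.append(_FULL_SET)
            elif ch in _FULL_SET:
                slots.append(frozenset(ch))
            else:
                raise PatternError(
                    f"invalid residue {single!r} at slot {len(slots) + 1} "
                    f"in pattern {text!r}"
                )
        else:
            members = frozenset(group.upper())
            bad = members - _FULL_SET
            if bad:
                raise PatternError(
                    f"invalid residue(s) {''.join(sorted(bad))!r} in set "
                    f"at slot {len(slots) + 1} of pattern {text!r}"
                )
            if not members:
                raise PatternError(
                    f"empty set at slot {len(slots) + 1} of pattern {text!r}"
                )
            slots.append(members)
        pos = m.end()
    if len(slots) != length:
        raise PatternError(
            f"pattern {text!r} has {len(slots)} slots, expected {length}"
        )
    return Pattern(tuple(slots))


def format_pattern(pattern: Pattern) -> str:
    """Render a pattern back to its string notation (round-trips parse)."""
    parts = []
    for s in pattern.slots:
        if s == _FULL_SET:
            parts.append("x")
        elif len(s) == 1:
            parts.append(next(iter(s)))
        else:
            parts.append("[" + "".join(sorted(s)) + "]")
    return "".join(parts)


def _slot_contributions(
    matrix: EffectMatrix, pattern: Pattern
) -> list[np.ndarray]:
    """Per slot: contribution array over its alphabetically sorted residues."""
    if pattern.length != matrix.length:
        raise PatternError(
            f"pattern has {pattern.length} slots but matrix length is "
            f"{matrix.length}"
        )
    out = []
    for i, slot in enumerate(pattern.slots):
        residues = sorted(slot)
        out.append(
            np.array(
                [matrix.contribution(r, i + 1) for r in residues], dtype=float
            )
        )
    return out


def pattern_extreme_scores(
    matrix: EffectMatrix, pattern: Pattern
) -> tuple[float, float, str, str]:
    """Exact (min A, max A, argmin peptide, argmax peptide) over a pattern.

    Closed form by slot-wise extremization; ties among residues are
    broken alphabetically (slots are scanned in alphabetical order and
    ``argmin``/``argmax`` keep the first extreme).
    """
    contribs = _slot_contributions(matrix, pattern)
    lo = matrix.intercept
    hi = matrix.intercept
    argmin_chars = []
    argmax_chars = []
    for slot, arr in zip(pattern.slots, contribs):
        residues = sorted(slot)
        lo += float(arr.min())
        hi += float(arr.max())
        argmin_chars.append(residues[int(arr.argmin())])
        argmax_chars.append(residues[int(arr.argmax())])
    return lo, hi, "".join(argmin_chars), "".join(argmax_chars)


def classify_pattern(matrix: EffectMatrix, pattern: Pattern) -> PatternClass:
    """Classify all matching peptides at once.

    ``all_amyloidogenic`` iff min A >= 0; ``all_non_amyloidogenic`` iff
    max A < 0; otherwise ``mixed``.
    """
    lo, hi, _, _ = pattern_extreme_scores(matrix, pattern)
    if lo >= 0:
        return "all_amyloidogenic"
    if hi < 0:
        return "all_non_amyloidogenic"
    return "mixed"


def is_rounding_sensitive(matrix: EffectMatrix, pattern: Pattern) -> bool:
    """True if the decisive extreme lies within rounding error of 0."""
    lo, hi, _, _ = pattern_extreme_scores(matrix, pattern)
    return min(abs(lo), abs(hi)) < ROUNDING_SENSITIVITY


def count_class(
    matrix: EffectMatrix,
    pattern: Pattern,
    cls: PredictedClass,
    cap: int = 10_000_000,
) -> int:
    """Exact count of matching peptides predicted as ``cls``, by enumeration.

    The scores of all matching peptides are built as the broadcast sum
    of per-slot contribution arrays.  Patterns wider than ``cap``
    matching peptides are refused (the closed-form extrema are always
    available instead).
    """
    card = pattern.cardinality
    if card > cap:
        lo, hi, _, _ = pattern_extreme_scores(matrix, pattern)
        raise PatternError(
            f"pattern matches {card:,} peptides, above the enumeration cap "
            f"{cap:,}; closed-form score range is [{lo:.3f}, {hi:.3f}]"
        )
    contribs = _slot_contributions(matrix, pattern)
    scores = reduce(np.add.outer, contribs).ravel() + matrix.intercept
    n_amyloid = int((scores >= 0).sum())
    if cls is PredictedClass.AMYLOIDOGENIC:
        return n_amyloid
    return card - n_amyloid


def enumerate_extremes_bruteforce(
    matrix: EffectMatrix, pattern: Pattern, cap: int = 1_000_000
) -> tuple[float, float]:
    """(min A, max A) by scoring every matching peptide; cross-check only."""
    card = pattern.cardinality
    if card > cap:
        raise PatternError(
            f"pattern matches {card:,} peptides, above the brute-force cap"
        )
    from itertools import product

    scores = [
        matrix.score("".join(combo))
        for combo in product(*[sorted(s) for s in pattern.slots])
    ]
    return min(scores), max(scores)
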