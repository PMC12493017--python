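"""The mutation graph on fixed-length peptides.

Vertices are all ``20**length`` peptides over the 20 proteogenic
residues (64,000,000 for hexapeptides); two peptides are adjacent iff
they differ in exactly one position, so every vertex has ``19 * length``
neighbors (114 for hexapeptides).  The graph is never materialized —
every operation here is local and on demand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .scoring import (
    AMINO_ACIDS,
    EffectMatrix,
    PeptideError,
    PredictedClass,
    clean_peptide,
)


def vertex_count(length: int = 6) -> int:
    """Number of vertices of the mutation graph: ``20 ** length``."""
    return 20 ** length


def hamming(p1: str, p2: str) -> int:
    """Number of positions at which two equal-length peptides differ."""
    a, b = p1.strip().upper(), p2.strip().upper()
    if len(a) != len(b):
        raise PeptideError(
            f"length mismatch: {a!r} ({len(a)}) vs {b!r} ({len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


def is_edge(p1: str, p2: str) -> bool:
    """True iff the two peptides are adjacent (Hamming distance exactly 1)."""
    return hamming(p1, p2) == 1


def neighbors(peptide: str, length: int = 6) -> list[str]:
    """All peptides at Hamming distance exactly 1, in deterministic order.

    Order is position-major, then residue-alphabetical; the peptide
    itself is excluded, so the list has ``19 * length`` entries.
    """
    seq = clean_peptide(peptide, length)
    out: list[str] = []
    for i in range(len(seq)):
        for aa in sorted(AMINO_ACIDS):
            if aa != seq[i]:
                out.append(seq[:i] + aa + seq[i + 1:])
    return out


@dataclass(frozen=True)
class PathValidation:
    """Check of a candidate path: chain property, scores, class homogeneity."""

    is_chain: bool
    homogeneous_class: Optional[PredictedClass]
    per_node_scores: tuple[float, ...]
    violations: tuple[tuple[int, str], ...]

    @property
    def ok(self) -> bool:
        return self.is_chain and not self.violations


def validate_path(
    matrix: EffectMatrix,
    path: Iterable[str],
    expected_class: Optional[PredictedClass] = None,
) -> PathValidation:
    """Validate a peptide path against the mutation graph and a class.

    Every consecutive pair must be an edge (Hamming distance 1); every
    node is scored, and nodes whose predicted class differs from
    ``expected_class`` (default: the class of the first node) are
    recorded as violations.
    """
    nodes = [clean_peptide(p, matrix.length) for p in path]
    if not nodes:
        raise PeptideError("empty path")
    violations: list[tuple[int, str]] = []
    is_chain = True
    for i in range(1, len(nodes)):
        d = hamming(nodes[i - 1], nodes[i])
        if d != 1:
            is_chain = False
            violations.append(
                (i, f"Hamming distance {d} to previous node (expected 1)")
            )
    scores = tuple(matrix.score(p) for p in nodes)
    if expected_class is None:
        expected_class = matrix.predict(nodes[0])
    homogeneous: Optional[PredictedClass] = expected_class
    for i, (node, a) in enumerate(zip(nodes, scores)):
        cls = (
            PredictedClass.AMYLOIDOGENIC
            if a >= 0
            else PredictedClass.NON_AMYLOIDOGENIC
        )
        if cls is not expected_class:
            homogeneous = None
            violations.append(
                (i, f"{node} predicted {cls.value} (A={a:.3f}), "
                    f"expected {expected_class.value}")
            )
    return PathValidation(is_chain, homogeneous, scores, tuple(violations))


def parse_path(text: str, length: int = 6) -> list[str]:
    """Read a path from dash notation ("A-B-C") or one peptide per line."""
    text = text.strip()
    if "-" in text.replace("\n", ""):
        tokens = [t for t in text.replace("\n", "-").split("-") if t.strip()]
    else:
        tokens = [t for t in text.splitlines() if t.strip()]
    return [clean_peptide(t, length) for t in tokens]


def format_path(nodes: Iterable[str]) -> str:
    """Render a path in the dash notation ``A-B-C``."""
    return "-".join(nodes)
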