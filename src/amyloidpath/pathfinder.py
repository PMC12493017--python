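"""Class-preserving single-substitution paths between same-class peptides.

Because the score is a sum of independent per-position terms, any two
peptides predicted in the same class can be joined through the "meet"
peptide — the coordinate-wise most amyloidogenic combination (xMAX) for
amyloidogenic pairs, the least (xMIN) for non-amyloidogenic pairs.  Each
leg substitutes one differing coordinate at a time toward the meet, so
the score changes monotonically along it and never crosses the decision
threshold.  A coordinate changed on one leg is never changed on the
other, hence the total edge count equals the Hamming distance of the
endpoints (at most the peptide length) and the constructed path is a
shortest path in the mutation graph even ignoring the class constraint.

Nothing here is specific to the published weights: the construction is
valid for any linear position-weight classifier, which the verification
harness exercises with random matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Literal, Optional, Sequence

import networkx as nx
import numpy as np

from .graph import hamming, validate_path
from .ordering import PositionOrdering, max_residue, min_residue
from .scoring import (
    AMINO_ACIDS,
    EffectMatrix,
    PeptideError,
    PredictedClass,
    clean_peptide,
)

LegDirection = Literal["non_decreasing", "non_increasing"]
Leg2Order = Literal["from-endpoint", "from-meet"]


class CrossClassError(ValueError):
    """The two endpoints are predicted in different classes.

    The construction guarantees nothing about mixed pairs, so the
    request is refused rather than answered best-effort.
    """


class NotComparableError(ValueError):
    """The leg endpoints are not coordinate-wise ordered.

    Signals that the caller must go through the meet construction
    instead of a single monotone leg.
    """


@dataclass(frozen=True)
class PathReport:
    """A constructed two-leg path and its bookkeeping."""

    path: tuple[str, ...]
    meet: str
    leg1_length: int
    leg2_length: int
    node_scores: tuple[float, ...]
    path_class: PredictedClass

    @property
    def n_edges(self) -> int:
        return len(self.path) - 1


@dataclass(frozen=True)
class VerificationSummary:
    """Aggregate result of verifying the construction on random pairs."""

    n_pairs: int
    seed: int
    max_path_length: int
    n_class_violations: int
    n_length_violations: int

    @property
    def ok(self) -> bool:
        return self.n_class_violations == 0 and self.n_length_violations == 0


def meet_peptide(
    ordering: PositionOrdering, p1: str, p2: str, cls: PredictedClass
) -> str:
    """Coordinate-wise extreme of two peptides.

    xMAX (per-position more amyloidogenic residue) for the amyloidogenic
    class, xMIN for the non-amyloidogenic class.  Every coordinate of the
    result equals the corresponding coordinate of one of the inputs.
    """
    length = ordering.length
    a = clean_peptide(p1, length)
    b = clean_peptide(p2, length)
    pick = max_residue if cls is PredictedClass.AMYLOIDOGENIC else min_residue
    return "".join(pick(ordering, i + 1, a[i], b[i]) for i in range(length))


def monotone_leg(
    matrix: EffectMatrix,
    ordering: PositionOrdering,
    start: str,
    end: str,
    direction: LegDirection,
) -> list[str]:
    """Path from ``start`` to ``end`` substituting one coordinate at a time.

    Requires ``end`` to dominate ``start`` coordinate-wise (contribution
    at every position >= for ``non_decreasing``, <= for
    ``non_increasing``); differing positions are substituted in
    ascending order, so the score is monotone along the leg and the edge
    count equals the Hamming distance.
    """
    a = clean_peptide(start, matrix.length)
    b = clean_peptide(end, matrix.length)
    for i in range(matrix.length):
        if a[i] == b[i]:
            continue
        ca = matrix.contribution(a[i], i + 1)
        cb = matrix.contribution(b[i], i + 1)
        bad = cb < ca if direction == "non_decreasing" else cb > ca
        if bad:
            raise NotComparableError(
                f"{b} is not coordinate-wise {direction.replace('_', '-')} "
                f"from {a} at position {i + 1} ({a[i]}:{ca:+.2f} vs "
                f"{b[i]}:{cb:+.2f})"
            )
    leg = [a]
    current = a
    for i in range(matrix.length):
        if current[i] != b[i]:
            current = current[:i] + b[i] + current[i + 1:]
            leg.append(current)
    return leg


def connect(
    matrix: EffectMatrix,
    ordering: PositionOrdering,
    p1: str,
    p2: str,
    leg2_order: Leg2Order = "from-endpoint",
) -> PathReport:
    """Connect two same-class peptides by a class-preserving shortest path.

    Leg 1 runs from ``p1`` to the meet; leg 2 joins the meet to ``p2``.
    With ``leg2_order="from-endpoint"`` (default) leg 2 is built from
    ``p2`` toward the meet in ascending position order and then
    reversed; ``"from-meet"`` substitutes from the meet toward ``p2``
    instead.  Monotonicity holds under either order.
    """
    a = clean_peptide(p1, matrix.length)
    b = clean_peptide(p2, matrix.length)
    cls_a, cls_b = matrix.predict(a), matrix.predict(b)
    if cls_a is not cls_b:
        raise CrossClassError(
            f"cross-class pair: {a} scores {matrix.score(a):+.3f} "
            f"({cls_a.value}) but {b} scores {matrix.score(b):+.3f} "
            f"({cls_b.value}); paths are only constructed within a class"
        )
    cls = cls_a
    meet = meet_peptide(ordering, a, b, cls)
    up: LegDirection = (
        "non_decreasing"
        if cls is PredictedClass.AMYLOIDOGENIC
        else "non_increasing"
    )
    down: LegDirection = (
        "non_increasing" if up == "non_decreasing" else "non_decreasing"
    )
    leg1 = monotone_leg(matrix, ordering, a, meet, up)
    if leg2_order == "from-endpoint":
        leg2 = list(reversed(monotone_leg(matrix, ordering, b, meet, up)))
    elif leg2_order == "from-meet":
        leg2 = monotone_leg(matrix, ordering, meet, b, down)
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown leg2_order {leg2_order!r}")
    path = tuple(leg1 + leg2[1:])
    scores = tuple(matrix.score(p) for p in path)
    return PathReport(
        path=path,
        meet=meet,
        leg1_length=len(leg1) - 1,
        leg2_length=len(leg2) - 1,
        node_scores=scores,
        path_class=cls,
    )


def bfs_shortest_class_path(
    matrix: EffectMatrix,
    p1: str,
    p2: str,
    candidate_residues: Optional[Sequence[set[str]]] = None,
) -> Optional[int]:
    """Independent oracle: BFS shortest same-class path in a sub-lattice.

    The search runs over the peptides whose residue at each position is
    drawn from ``candidate_residues`` (default: the endpoint residues
    plus the per-position extreme residue of the pair, at most 3 choices
    per position), restricted to nodes predicted in the endpoints'
    class.  Returns the shortest path length, or ``None`` if the
    endpoints are disconnected within the sub-lattice.  Deliberately
    avoids the constructive machinery (orderings, meets, legs): the
    meet-equivalent residues are read off the matrix directly.
    """
    a = clean_peptide(p1, matrix.length)
    b = clean_peptide(p2, matrix.length)
    cls_a, cls_b = matrix.predict(a), matrix.predict(b)
    if cls_a is not cls_b:
        raise CrossClassError(
            f"cross-class pair {a} / {b}: BFS oracle only runs within a class"
        )
    cls = cls_a
    if candidate_residues is None:
        take = max if cls is PredictedClass.AMYLOIDOGENIC else min
        candidate_residues = []
        for i in range(matrix.length):
            extreme = take(
                (a[i], b[i]), key=lambda r: matrix.contribution(r, i + 1)
            )
            candidate_residues.append({a[i], b[i], extreme})
    else:
        candidate_residues = [set(s) for s in candidate_residues]
        for i in range(matrix.length):
            if a[i] not in candidate_residues[i] or b[i] not in candidate_residues[i]:
                raise PeptideError(
                    f"candidate set at position {i + 1} must contain both "
                    f"endpoint residues"
                )
    nodes = [
        "".join(combo)
        for combo in product(*[sorted(s) for s in candidate_residues])
        if matrix.predict("".join(combo)) is cls
    ]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    node_set = set(nodes)
    for node in nodes:
        for i in range(matrix.length):
            for res in candidate_residues[i]:
                if res != node[i]:
                    other = node[:i] + res + node[i + 1:]
                    if other in node_set:
                        g.add_edge(node, other)
    if a not in node_set or b not in node_set:  # pragma: no cover - by construction
        return None
    try:
        return nx.shortest_path_length(g, a, b)
    except nx.NetworkXNoPath:
        return None


def random_peptides(
    rng: np.random.Generator, n: int, length: int = 6
) -> list[str]:
    """``n`` peptides drawn uniformly over the 20-letter alphabet."""
    letters = np.array(list(AMINO_ACIDS))
    draws = rng.integers(0, len(letters), size=(n, length))
    return ["".join(letters[row]) for row in draws]


def sample_class_peptides(
    matrix: EffectMatrix,
    cls: PredictedClass,
    n: int,
    rng: np.random.Generator,
    batch: int = 256,
) -> list[str]:
    """Rejection-sample ``n`` uniform peptides predicted in class ``cls``."""
    out: list[str] = []
    while len(out) < n:
        for pep in random_peptides(rng, batch, matrix.length):
            if matrix.predict(pep) is cls:
                out.append(pep)
                if len(out) == n:
                    break
    return out


def sample_verify(
    matrix: EffectMatrix,
    ordering: PositionOrdering,
    n_pairs: int,
    seed: int,
    cls: PredictedClass,
    leg2_order: Leg2Order = "from-endpoint",
) -> VerificationSummary:
    """Verify the construction on ``n_pairs`` random same-class pairs.

    Draws peptides uniformly with rejection to class ``cls``, connects
    each pair, and validates the result: every node must be predicted in
    ``cls`` and the edge count must equal the endpoints' Hamming
    distance (hence at most the peptide length).  Deterministic for a
    given seed.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    rng = np.random.default_rng(seed)
    peps = sample_class_peptides(matrix, cls, 2 * n_pairs, rng)
    max_len = 0
    n_class = 0
    n_length = 0
    for k in range(n_pairs):
        a, b = peps[2 * k], peps[2 * k + 1]
        report = connect(matrix, ordering, a, b, leg2_order=leg2_order)
        check = validate_path(matrix, report.path, expected_class=cls)
        if not check.is_chain or any(
            "predicted" in reason for _, reason in check.violations
        ):
            n_class += sum(
                1 for _, reason in check.violations if "predicted" in reason
            )
        if report.n_edges != hamming(a, b) or report.n_edges > matrix.length:
            n_length += 1
        max_len = max(max_len, report.n_edges)
    return VerificationSummary(
        n_pairs=n_pairs,
        seed=seed,
        max_path_length=max_len,
        n_class_violations=n_class,
        n_length_violations=n_length,
    )
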