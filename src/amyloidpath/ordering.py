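"""Per-position amyloidogenicity orderings and the MAX/MIN operators.

At every sequence position the 20 residues can be totally ordered by
their effect-matrix contribution, most amyloidogenic first.  Replacing a
residue by one ranked earlier at its position can only raise the linear
score; ranked later can only lower it.  The path construction relies on
two operators over this ordering: ``MAXi(X, X')`` is whichever of the
two residues ranks earlier at position i, ``MINi`` whichever ranks later.

The orderings here are *derived* from the matrix rather than copied from
the published ordering table, because the published row for position 4
is internally inconsistent (C listed twice, V absent).  The printed
table is retained as an audit reference; :func:`compare_to_reference`
reports, and never repairs, its anomalies.

Tie policy: residues with equal contribution are ordered as in the
published row for that position when that row is a valid permutation of
the 20 residues, and alphabetically otherwise.  MAX/MIN compare matrix
values directly, so the tie direction never affects score monotonicity.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .scoring import AMINO_ACIDS, EffectMatrix, PeptideError


def load_published_ordering() -> list[str]:
    """The published per-position ordering rows, verbatim (may contain typos)."""
    text = (
        resources.files("amyloidpath.data")
        .joinpath("published_ordering.txt")
        .read_text()
    )
    rows: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        _, residues = line.split("\t", 1)
        rows.append(residues.replace(" ", ""))
    return rows


def _tie_break_rank(position_row: str | None) -> dict[str, int]:
    """Rank map used only to break exact contribution ties.

    Uses the published row when it is a valid permutation of the 20
    residues, alphabetical order otherwise.
    """
    if position_row is not None and sorted(position_row) == sorted(AMINO_ACIDS):
        return {aa: i for i, aa in enumerate(position_row)}
    return {aa: i for i, aa in enumerate(sorted(AMINO_ACIDS))}


@dataclass(frozen=True)
class PositionOrdering:
    """Total order of residues per position, most amyloidogenic first."""

    ranks: tuple[str, ...]  # one 20-char string per position
    matrix: EffectMatrix

    @property
    def length(self) -> int:
        return len(self.ranks)

    def row(self, position: int) -> str:
        """Ordering at 1-based ``position`` as a 20-character string."""
        self._check_position(position)
        return self.ranks[position - 1]

    def rank(self, position: int, residue: str) -> int:
        """0-based rank of ``residue`` at ``position`` (0 = most amyloidogenic)."""
        r = self.row(position)
        res = residue.strip().upper()
        idx = r.find(res)
        if idx < 0:
            raise PeptideError(f"invalid residue {residue!r}")
        return idx

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= self.length:
            raise PeptideError(
                f"position {position} out of range 1..{self.length}"
            )


def derive_ordering(matrix: EffectMatrix) -> PositionOrdering:
    """Sort residues at each position by decreasing matrix contribution."""
    published = load_published_ordering()
    rows: list[str] = []
    for j in range(matrix.length):
        row_ref = published[j] if j < len(published) else None
        tie_rank = _tie_break_rank(row_ref)
        ordered = sorted(
            AMINO_ACIDS,
            key=lambda aa: (-matrix.values[AMINO_ACIDS.index(aa), j], tie_rank[aa]),
        )
        rows.append("".join(ordered))
    return PositionOrdering(tuple(rows), matrix)


def _pick(
    ordering: PositionOrdering, position: int, r1: str, r2: str, want_max: bool
) -> str:
    m = ordering.matrix
    a = m.contribution(r1, position)
    b = m.contribution(r2, position)
    if a == b:
        # exact tie: defer to the per-position rank so the choice is
        # deterministic; returns r1 when r1 == r2
        if ordering.rank(position, r1) <= ordering.rank(position, r2):
            return (r1 if want_max else r2).strip().upper()
        return (r2 if want_max else r1).strip().upper()
    if (a > b) == want_max:
        return r1.strip().upper()
    return r2.strip().upper()


def max_residue(
    ordering: PositionOrdering, position: int, r1: str, r2: str
) -> str:
    """The more amyloidogenic of two residues at ``position`` (earlier rank)."""
    return _pick(ordering, position, r1, r2, want_max=True)


def min_residue(
    ordering: PositionOrdering, position: int, r1: str, r2: str
) -> str:
    """The less amyloidogenic of two residues at ``position`` (later rank)."""
    return _pick(ordering, position, r1, r2, want_max=False)


@dataclass(frozen=True)
class OrderingAudit:
    """Result of auditing a reference ordering table against the derived one.

    ``mismatches[i]`` lists ``(rank, derived, reference)`` triples where the
    two rows disagree; ``duplicates[i]`` and ``missing[i]`` flag residues
    that occur more than once or not at all in the reference row.
    """

    mismatches: tuple[tuple[tuple[int, str, str], ...], ...]
    duplicates: tuple[tuple[str, ...], ...]
    missing: tuple[tuple[str, ...], ...]

    @property
    def clean(self) -> bool:
        return not any(self.mismatches) and not any(self.duplicates) and not any(
            self.missing
        )


def compare_to_reference(
    ordering: PositionOrdering, reference: list[str] | None = None
) -> OrderingAudit:
    """Audit a reference ordering (default: the published table) per position.

    The reference rows need not be valid permutations — the audit reports
    duplicated and absent residues instead of failing on them.
    """
    if reference is None:
        reference = load_published_ordering()
    mismatches: list[tuple[tuple[int, str, str], ...]] = []
    duplicates: list[tuple[str, ...]] = []
    missing: list[tuple[str, ...]] = []
    for j, ref_row in enumerate(reference):
        ref = ref_row.replace(" ", "").upper()
        derived = ordering.ranks[j]
        mism = tuple(
            (rank, d, r)
            for rank, (d, r) in enumerate(zip(derived, ref))
            if d != r
        )
        dup = tuple(sorted({aa for aa in ref if ref.count(aa) > 1}))
        miss = tuple(sorted(set(AMINO_ACIDS) - set(ref)))
        mismatches.append(mism)
        duplicates.append(dup)
        missing.append(miss)
    return OrderingAudit(tuple(mismatches), tuple(duplicates), tuple(missing))
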