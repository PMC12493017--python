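"""Linear amyloidogenicity scoring of fixed-length peptides.

The predictor is a linear position-weight classifier: each of the 20
proteogenic residues contributes a pre-computed value at each sequence
position, and a peptide's amyloidogenicity value ``A`` is the sum of its
per-position contributions plus an intercept ``b``.  A peptide is
predicted amyloidogenic iff ``A >= 0``.

The default weights are the published Amyloid Effect Matrix of the
Budapest Amyloid Predictor (BAP), a linear SVM trained on the Waltz
hexapeptide database, as printed to two decimals together with
``b = 1.083``.  Because only the rounded weights are public, peptides
with ``|A|`` within roughly 0.03 of zero may be classified differently
by the BAP web server; this package treats the printed values as exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The 20 proteogenic amino acids, in the row order of the published matrix.
AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Ambiguity / non-proteogenic one-letter codes that are rejected outright.
_REJECTED_CODES = set("BJOUXZ")

_INTERCEPT_LABEL = "__intercept__"


class PeptideError(ValueError):
    """An input sequence is not a valid peptide for the given matrix."""


class MatrixFormatError(ValueError):
    """An effect-matrix table is malformed."""


class PredictedClass(str, Enum):
    """Binary amyloidogenicity call of the linear classifier."""

    AMYLOIDOGENIC = "amyloidogenic"
    NON_AMYLOIDOGENIC = "non_amyloidogenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def clean_peptide(sequence: str, length: int = 6) -> str:
    """Validate and normalize a peptide sequence.

    Whitespace is stripped and lowercase letters are accepted; ambiguity
    codes (B, J, O, U, X, Z) and anything outside the 20 canonical
    one-letter codes raise :class:`PeptideError` naming the offending
    position and character.
    """
    seq = sequence.strip().upper()
    if len(seq) != length:
        raise PeptideError(
            f"peptide {seq!r} has length {len(seq)}, expected {length}"
        )
    for pos, ch in enumerate(seq, start=1):
        if ch not in _AA_INDEX:
            kind = "ambiguity code" if ch in _REJECTED_CODES else "invalid residue"
            raise PeptideError(f"{kind} {ch!r} at position {pos} in {seq!r}")
    return seq


@dataclass(frozen=True)
class EffectMatrix:
    """Per-residue, per-position score contributions plus an intercept.

    Parameters
    ----------
    values
        Array of shape ``(20, length)``; row order follows
        :data:`AMINO_ACIDS`, columns are sequence positions 1..length.
    intercept
        The additive constant ``b`` of the linear decision value.
    """

    values: np.ndarray
    intercept: float
    length: int = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != len(AMINO_ACIDS):
            raise MatrixFormatError(
                f"expected a 20 x length array, got shape {arr.shape}"
            )
        if not np.isfinite(arr).all():
            raise MatrixFormatError("matrix contains non-finite contributions")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "length", arr.shape[1])

    def contribution(self, residue: str, position: int) -> float:
        """Contribution of ``residue`` at 1-based ``position``."""
        if not 1 <= position <= self.length:
            raise PeptideError(
                f"position {position} out of range 1..{self.length}"
            )
        res = residue.strip().upper()
        if res not in _AA_INDEX:
            raise PeptideError(f"invalid residue {res!r}")
        return float(self.values[_AA_INDEX[res], position - 1])

    def score(self, peptide: str) -> float:
        """Amyloidogenicity value ``A`` = intercept + sum of contributions."""
        seq = clean_peptide(peptide, self.length)
        idx = [_AA_INDEX[ch] for ch in seq]
        return float(self.values[idx, range(self.length)].sum() + self.intercept)

    def breakdown(self, peptide: str) -> list[float]:
        """Per-position contribution terms of :meth:`score` (no intercept)."""
        seq = clean_peptide(peptide, self.length)
        return [
            float(self.values[_AA_INDEX[ch], j]) for j, ch in enumerate(seq)
        ]

    def predict(self, peptide: str) -> PredictedClass:
        """Classify: amyloidogenic iff ``A >= 0`` (zero counts as positive)."""
        if self.score(peptide) >= 0:
            return PredictedClass.AMYLOIDOGENIC
        return PredictedClass.NON_AMYLOIDOGENIC

    def to_frame(self) -> pd.DataFrame:
        """The matrix as a DataFrame (residue rows, 1-based position columns)."""
        return pd.DataFrame(
            self.values,
            index=list(AMINO_ACIDS),
            columns=range(1, self.length + 1),
        )

    def to_tsv(self, path) -> None:
        """Write the matrix in the package's TSV interchange format."""
        frame = self.to_frame()
        frame.index.name = "res"
        frame.loc[_INTERCEPT_LABEL] = self.intercept
        frame.to_csv(path, sep="\t")


def _frame_to_matrix(frame: pd.DataFrame, source: str) -> EffectMatrix:
    rows = [str(r).strip() for r in frame.index]
    if _INTERCEPT_LABEL not in rows:
        raise MatrixFormatError(f"{source}: missing {_INTERCEPT_LABEL} row")
    intercept_vals = frame.loc[frame.index.str.strip() == _INTERCEPT_LABEL]
    intercept = float(intercept_vals.iloc[0, 0])
    body = frame.loc[frame.index.str.strip() != _INTERCEPT_LABEL]
    seen: set[str] = set()
    for res in body.index:
        r = str(res).strip().upper()
        if r in seen:
            raise MatrixFormatError(f"{source}: duplicate residue row {r!r}")
        seen.add(r)
    missing = [aa for aa in AMINO_ACIDS if aa not in seen]
    if missing:
        raise MatrixFormatError(
            f"{source}: missing residue row(s) {', '.join(missing)}"
        )
    extra = sorted(seen - set(AMINO_ACIDS))
    if extra:
        raise MatrixFormatError(
            f"{source}: unknown residue row(s) {', '.join(extra)}"
        )
    body = body.copy()
    body.index = body.index.str.strip().str.upper()
    try:
        arr = body.loc[list(AMINO_ACIDS)].to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixFormatError(f"{source}: non-numeric cell ({exc})") from exc
    return EffectMatrix(arr, intercept)


def load_effect_matrix(source=None) -> EffectMatrix:
    """Load an effect matrix.

    With no ``source`` the embedded published matrix (20 x 6 contributions,
    intercept 1.083) is returned.  Otherwise ``source`` must be a TSV with
    a ``res`` index column, one column per position, 20 residue rows and a
    final ``__intercept__`` row.
    """
    if source is None:
        text = (
            resources.files("amyloidpath.data")
            .joinpath("effect_matrix.tsv")
            .read_text()
        )
        frame = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
        return _frame_to_matrix(frame, "embedded matrix")
    try:
        frame = pd.read_csv(source, sep="\t", index_col=0)
    except Exception as exc:
        raise MatrixFormatError(f"{source}: cannot parse TSV ({exc})") from exc
    return _frame_to_matrix(frame, str(source))


def score(matrix: EffectMatrix, peptide: str) -> float:
    """Amyloidogenicity value ``A(x)`` of ``peptide`` under ``matrix``."""
    return matrix.score(peptide)


def predict(matrix: EffectMatrix, peptide: str) -> PredictedClass:
    """Predicted class of ``peptide``: amyloidogenic iff ``A(x) >= 0``."""
    return matrix.predict(peptide)


def score_breakdown(matrix: EffectMatrix, peptide: str) -> list[float]:
    """Per-position contribution terms; their sum plus the intercept is A."""
    return matrix.breakdown(peptide)


def score_many(
    matrix: EffectMatrix, peptides: Iterable[str]
) -> pd.DataFrame:
    """Score a batch of peptides into a tidy report.

    Returns a DataFrame with columns ``peptide``, ``score``, ``class``.
    """
    rows = []
    for pep in peptides:
        a = matrix.score(pep)
        cls = (
            PredictedClass.AMYLOIDOGENIC
            if a >= 0
            else PredictedClass.NON_AMYLOIDOGENIC
        )
        rows.append((clean_peptide(pep, matrix.length), a, cls.value))
    return pd.DataFrame(rows, columns=["peptide", "score", "class"])
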