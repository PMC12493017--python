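"""File input/output and synthetic fixtures.

Peptide lists are plain text (one peptide per line, ``#`` comments) or
FASTA; matrices travel in the TSV format of :mod:`amyloidpath.scoring`.
The fixture generator draws random peptides and, optionally, a random
effect matrix so that the path-construction guarantees can be exercised
on arbitrary linear position-weight classifiers, not just the published
weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
from Bio import SeqIO

from .pathfinder import random_peptides
from .scoring import AMINO_ACIDS, EffectMatrix, PeptideError, clean_peptide


@dataclass(frozen=True)
class PeptideRecord:
    """A validated peptide with its source identifier (for reporting)."""

    id: str
    sequence: str


def read_peptides(
    source, format: Literal["list", "fasta"] = "list", length: int = 6
) -> list[PeptideRecord]:
    """Read and validate peptides from a list file or FASTA.

    FASTA sequence lines are concatenated per record; every record must
    have exactly ``length`` residues.  Errors name the offending record.
    """
    path = Path(source)
    records: list[PeptideRecord] = []
    if format == "list":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            try:
                seq = clean_peptide(text, length)
            except PeptideError as exc:
                raise PeptideError(f"{path}:{lineno}: {exc}") from exc
            records.append(PeptideRecord(id=f"line{lineno}", sequence=seq))
    elif format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            try:
                seq = clean_peptide(str(rec.seq), length)
            except PeptideError as exc:
                raise PeptideError(f"{path}: record {rec.id!r}: {exc}") from exc
            records.append(PeptideRecord(id=rec.id, sequence=seq))
    else:
        raise ValueError(f"unknown peptide format {format!r}")
    return records


def random_effect_matrix(
    rng: np.random.Generator,
    length: int = 6,
    low: float = -0.6,
    high: float = 0.3,
    center_sample: int = 1001,
) -> EffectMatrix:
    """A random linear position-weight classifier with both classes populated.

    Contributions are drawn uniformly from ``[low, high]`` (the span of
    the published matrix); the intercept is set to minus the median
    score of ``center_sample`` random peptides, so roughly half of
    sequence space falls on each side of the decision threshold.
    """
    values = rng.uniform(low, high, size=(len(AMINO_ACIDS), length))
    m0 = EffectMatrix(values, intercept=0.0)
    sample = random_peptides(rng, center_sample, length)
    median = float(np.median([m0.score(p) for p in sample]))
    return EffectMatrix(values, intercept=-median)


def make_fixtures(
    seed: int,
    n_peptides: int,
    random_matrix: bool = False,
    length: int = 6,
) -> tuple[EffectMatrix, list[str]]:
    """Seeded random peptides plus a matrix (embedded or random).

    Deterministic for a given seed.
    """
    from .scoring import load_effect_matrix

    if n_peptides < 0:
        raise ValueError("n_peptides must be non-negative")
    rng = np.random.default_rng(seed)
    if random_matrix:
        matrix = random_effect_matrix(rng, length=length)
    else:
        matrix = load_effect_matrix()
    peptides = random_peptides(rng, n_peptides, length)
    return matrix, peptides


def write_peptides(path, peptides: Iterable[str]) -> None:
    """Write a plain peptide list, one per line."""
    Path(path).write_text("".join(f"{p}\n" for p in peptides))
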