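# amyloidpath

Amyloidogenicity scoring for hexapeptides and class-preserving
single-mutation paths through hexapeptide sequence space.

## The problem

Hexapeptides are a standard model system for studying amyloid formation
— the aggregation of peptides into cross-β fibrils. There are
20⁶ = 64,000,000 hexapeptides over the 20 proteogenic amino acids, far
more than any experimental database covers, so computational predictors
are used to label them. The Budapest Amyloid Predictor (BAP) is a linear
SVM whose decision value for a hexapeptide x reduces to a sum of
position-specific residue contributions:

    A(x) = b + Σᵢ₌₁⁶ W(xᵢ, i),        x amyloidogenic  ⇔  A(x) ≥ 0

where W is the published 20×6 "Amyloid Effect Matrix" and b = 1.083.
This package embeds that matrix and builds on the transparency of the
linear form:

- **Scoring & classification** of peptides, with per-position breakdowns.
- **Per-position residue orderings** (most amyloidogenic first) and the
  MAX/MIN operators over them, derived from the matrix and audited
  against the published ordering table (whose row 4 contains a known
  typo: C listed twice, V absent — reported, never repaired).
- **The mutation graph** M: all hexapeptides as vertices, edges between
  peptides differing in exactly one position (114 neighbors each).
- **Path construction**: any two peptides predicted in the same class
  are joined through the coordinate-wise extreme "meet" peptide by a
  path whose every node stays in that class and whose length equals the
  endpoints' Hamming distance — hence at most 6, and provably shortest.
  An independent BFS oracle over a small sub-lattice cross-checks it.
  The guarantee holds for *any* linear position-weight classifier, and
  the test suite exercises it on random matrices.
- **Wildcard patterns** like `CxFLWx` (x = any residue, `[ILV]` = a
  restricted choice): exact min/max of A over all matching peptides in
  closed form, whole-pattern classification, and exact class counts by
  enumeration.

For users: peptide chemists planning single-point substitution series
that must stay aggregation-prone (or stay soluble), and method
developers studying linear sequence classifiers.

## Worked example

```python
>>> import amyloidpath as ap
>>> m = ap.load_effect_matrix()          # embedded published matrix
>>> m.score("YVSTSY")
-0.5569999999999999
>>> m.predict("YVSTSY").value
'non_amyloidogenic'
>>> o = ap.derive_ordering(m)
>>> r = ap.connect(m, o, "CVFFFF", "LYCLCI")
>>> "-".join(r.path)
'CVFFFF-CYFFFF-CYFLFF-CYFLFI-CYFLCI-CYCLCI-LYCLCI'
>>> r.meet, r.n_edges
('CYFLFI', 6)
```

`YVSTSY` scores −0.557 (= −0.23−0.14−0.41−0.23−0.48−0.15+1.083), below
the threshold, so it is predicted non-amyloidogenic. The two
amyloidogenic peptides `CVFFFF` and `LYCLCI` differ at all six
positions; the constructed path substitutes one residue per step, rises
monotonically in A to the meet `CYFLFI` and descends to the far
endpoint, never leaving the amyloidogenic class.

The same is available from a shell:

```sh
$ amyloidpath predict YVSTSY
peptide	score	class
YVSTSY	-0.557	non_amyloidogenic
$ amyloidpath path CVFFFF LYCLCI
CVFFFF-CYFFFF-CYFLFF-CYFLFI-CYFLCI-CYCLCI-LYCLCI
$ amyloidpath pattern CxFLWx --counts
{ ... "class": "all_amyloidogenic", "min_score": 0.063, "n_amyloidogenic": 400 ... }
$ amyloidpath verify --n 1000 --seed 42 --class amyloid
```

`verify` exits non-zero if any constructed path exceeds length 6 or
leaves its class; it never does.

A caveat worth knowing: the public matrix is printed to two decimals, so
patterns and peptides whose extreme |A| is below ≈0.03 are sensitive to
that rounding (e.g. `xxPQxx` reaches +0.003 at VIPQIV and is reported
`mixed` with a `rounding_sensitive` flag).

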