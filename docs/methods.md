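# Methods

## Model

A peptide x = (x₁, …, x_L) over the 20 proteogenic amino acids is scored

    A(x) = b + Σᵢ W(xᵢ, i)

with W a 20×L matrix of per-residue, per-position contributions and b an
intercept. The classification rule is A(x) ≥ 0 → amyloidogenic, A(x) < 0
→ non-amyloidogenic; the boundary A = 0 is classified amyloidogenic, with
no epsilon band. This is exactly the decision function of a linear SVM
whose per-position feature blocks have been collapsed into one lookup per
(residue, position) pair.

The default weights are the published Amyloid Effect Matrix of the
Budapest Amyloid Predictor with b = 1.083, embedded as package data
(`data/effect_matrix.tsv`) and treated as exact. Everything is
parameterized by L (default 6), so the machinery applies unchanged to
shorter or longer k-mers given a matching matrix.

## Orderings and the MAX/MIN operators

At each position the 20 residues are totally ordered by decreasing
contribution. MAXᵢ(X, X′) returns whichever of two residues ranks
earlier at position i, MINᵢ the later; both return X when X = X′.
Replacing a residue by an earlier-ranked one can only raise A, by a
later-ranked one only lower it — the non-strict inequality is what the
path construction rests on.

The working orderings are derived from the matrix, not copied from the
published ordering table, because that table's row 4 is internally
inconsistent (C appears twice, V — the column-4 maximum at 0.14 — is
absent). The printed table ships only as an audit reference;
`compare_to_reference` reports rank mismatches and duplicate/missing
residues per row without attempting a repair, and deliberately tolerates
non-permutation rows.

**Tie policy.** Contribution ties are broken by the published row's
order where that row is a valid permutation of the 20 residues, and
alphabetically otherwise. With this rule the derived rows 1–3 and 5–6
reproduce the published rows character-for-character; row 4 falls back
to alphabetical, so besides the C/V anomaly it swaps the three-way tie
E/H/S (all −0.30) from the printed H-E-S to E-H-S. MAX/MIN compare
matrix values directly rather than list ranks, so the tie direction can
never affect score monotonicity.

## The mutation graph and the path construction

Vertices are all 20^L peptides; edges join peptides at Hamming distance
exactly 1, giving 19·L neighbors per vertex (114 for L = 6) and 20⁶ =
64,000,000 vertices for hexapeptides. The graph is never materialized:
every operation (neighbor enumeration, legs, the BFS oracle) is local.

Given two peptides of the same predicted class, the *meet* is their
coordinate-wise extreme: per position the MAX of the two residues for an
amyloidogenic pair, the MIN for a non-amyloidogenic pair. Each meet
coordinate equals one of the endpoints' residues. The path runs from p₁
to the meet and on to p₂, substituting one differing coordinate at a
time; because the meet dominates both endpoints coordinate-wise, A is
monotone along each leg (non-decreasing toward an xMAX meet,
non-increasing away from it; mirrored for xMIN), so no intermediate node
can cross the threshold. A coordinate changed on one leg is already at
its meet value and is never touched on the other, hence

    edge count = Hamming(p₁, p₂) ≤ L,

which is also a global lower bound for any path between the endpoints —
the constructed path is a shortest path in the whole graph, class
constraint or not. Cross-class pairs are refused with an error citing
both scores: the construction guarantees nothing about them.

**Substitution order.** Within a leg, differing positions are
substituted in ascending index order. The full path is assembled as
leg 1 followed by leg 2 reversed (leg 2 built from the far endpoint
toward the meet). Monotonicity holds under *any* substitution order, so
an alternative `from-meet` mode (substituting outward from the meet,
again ascending) is exposed; the two modes reproduce the two published
example paths respectively.

**Independent oracle.** `bfs_shortest_class_path` runs a breadth-first
search (networkx) over the sub-lattice of peptides whose residue at each
position is drawn from {p₁ᵢ, p₂ᵢ, meetᵢ} (≤ 3^L nodes; since the meet
coordinate equals an endpoint residue this is at most 2^L), restricted
to nodes of the endpoints' class. It reads the per-position extremes
directly off the matrix and shares none of the ordering/leg code, so
agreement between its shortest-path length and the constructive edge
count is a genuine two-route check.

## Pattern extremization

A pattern assigns each position a non-empty allowed-residue set
(singleton, the full 20, or a bracketed subset like `[ILV]`). Because A
is a sum of independent per-position terms, the exact extrema of A over
all matching peptides are

    min/max A = b + Σᵢ min/max over the slot's residues of W(·, i),

computed in closed form; argmin/argmax break residue ties
alphabetically. A pattern is `all_amyloidogenic` iff min A ≥ 0,
`all_non_amyloidogenic` iff max A < 0, else `mixed` — consistent with
the peptide-level threshold. Class counts are exact, by a vectorized
enumeration (broadcast sum of slot contribution arrays) capped at 10⁷
matching peptides; beyond the cap the closed-form bounds are offered
instead.

**Rounding sensitivity.** The public matrix carries two decimals.
Patterns whose decisive extreme lies within 0.03 of the threshold are
flagged `rounding_sensitive`: under the printed weights `xxPQxx` attains
+0.003 at VIPQIV and is therefore `mixed`, although it was originally
reported all-non-amyloidogenic — presumably from unrounded internal
weights. `PxDxxx` (−0.027), `xxKxEx` (−0.017) and `FxFLFx` (+0.013) hold
but by thin margins. The package reports what the printed matrix yields
and does not adjudicate; marginal peptides (|A| ≲ 0.03) may likewise
disagree with the BAP web server.

## Synthetic fixtures and what they show

`random_effect_matrix` draws contributions uniformly from [−0.6, 0.3] —
the span of the published matrix — and sets the intercept to minus the
median score of a 1001-peptide seeded sample, so both classes are
populated roughly evenly. Random peptides are uniform over the alphabet,
with rejection sampling to a target class where needed. This emulates an
arbitrary linear position-weight classifier, which is precisely the
family the path-construction guarantee covers; it does *not* emulate the
correlation structure of real amyloid data, the class imbalance of
curated databases, or predictor accuracy against experiment — passing
tests certify the combinatorial/geometric claims, not biological
validity. All sampling is seeded (`numpy.random.default_rng`) and
bit-for-bit reproducible.

## Numerical choices

- Scores in double precision; comparisons against 3-decimal printed
  values use tolerance 5e−4, definitional identities (breakdown sums,
  substitution deltas, monotonicity) 1e−9.
- Equality of contributions (tie detection) is exact floating-point
  equality — safe because the embedded weights are 2-decimal literals.
- Neighbor order is fixed (position-major, then residue-alphabetical)
  for reproducible output.
- Input normalization accepts lowercase and strips whitespace; the
  ambiguity codes B, J, O, U, X, Z are a hard error, never skipped
  (X would collide with the pattern wildcard).
- Verification sizes: the test suite and the reproduction script use
  1,000 random pairs per class for the length-bound check and 100 pairs
  per class for the BFS cross-check, sizes at which every distinct
  Hamming distance 0–6 is observed many times over.

## Known limitations

- The unrounded SVM weights are not public; all marginal calls inherit
  the 2-decimal rounding (see above).
- No claims about cross-class paths, globally weighted shortest paths,
  or enumeration of *all* single-class patterns; the published row-4
  ordering typo is reported, not resolved.
- Prediction quality (accuracy against experimental labels) is out of
  scope: this package operates on the published weights, it does not
  retrain or evaluate them.
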