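"""Class-preserving path construction: meets, monotone legs, verification."""

import numpy as np
import pytest

from amyloidpath import (
    CrossClassError,
    NotComparableError,
    PredictedClass,
    bfs_shortest_class_path,
    connect,
    derive_ordering,
    format_path,
    hamming,
    meet_peptide,
    monotone_leg,
    random_effect_matrix,
    sample_verify,
    validate_path,
)
from amyloidpath.pathfinder import sample_class_peptides

AMYLOID = PredictedClass.AMYLOIDOGENIC
NON_AMYLOID = PredictedClass.NON_AMYLOIDOGENIC


class TestMeet:
    def test_worked_example_meet(self, ordering):
        assert meet_peptide(ordering, "CVFFFF", "LYCLCI", AMYLOID) == "CYFLFI"

    def test_length6_example_meet(self, ordering):
        assert meet_peptide(ordering, "ILVWIW", "FWLCYL", AMYLOID) == "IWVCIL"

    def test_meet_of_identical_is_identity(self, ordering):
        assert meet_peptide(ordering, "YVSTSY", "YVSTSY", NON_AMYLOID) == "YVSTSY"

    def test_meet_dominates_both(self, matrix, ordering):
        rng = np.random.default_rng(7)
        for cls in (AMYLOID, NON_AMYLOID):
            peps = sample_class_peptides(matrix, cls, 40, rng)
            for a, b in zip(peps[::2], peps[1::2]):
                m = meet_peptide(ordering, a, b, cls)
                s = matrix.score(m)
                if cls is AMYLOID:
                    assert s >= max(matrix.score(a), matrix.score(b)) - 1e-9
                else:
                    assert s <= min(matrix.score(a), matrix.score(b)) + 1e-9
                assert all(m[i] in (a[i], b[i]) for i in range(6))


class TestMonotoneLeg:
    def test_worked_example_leg1(self, matrix, ordering):
        leg = monotone_leg(matrix, ordering, "CVFFFF", "CYFLFI", "non_decreasing")
        assert leg == ["CVFFFF", "CYFFFF", "CYFLFF", "CYFLFI"]

    def test_worked_example_leg2(self, matrix, ordering):
        leg = monotone_leg(matrix, ordering, "LYCLCI", "CYFLFI", "non_decreasing")
        assert leg == ["LYCLCI", "CYCLCI", "CYFLCI", "CYFLFI"]

    def test_trivial_leg(self, matrix, ordering):
        assert monotone_leg(matrix, ordering, "YVSTSY", "YVSTSY",
                            "non_increasing") == ["YVSTSY"]

    def test_incomparable_pair_rejected(self, matrix, ordering):
        # CVFFFF and LYCLCI are not coordinate-wise ordered either way
        with pytest.raises(NotComparableError, match="coordinate-wise"):
            monotone_leg(matrix, ordering, "CVFFFF", "LYCLCI", "non_decreasing")

    def test_scores_monotone_along_leg(self, matrix, ordering):
        leg = monotone_leg(matrix, ordering, "CVFFFF", "CYFLFI", "non_decreasing")
        scores = [matrix.score(p) for p in leg]
        assert all(s1 <= s2 + 1e-9 for s1, s2 in zip(scores, scores[1:]))


class TestConnect:
    def test_reproduces_worked_example_exactly(self, matrix, ordering):
        report = connect(matrix, ordering, "CVFFFF", "LYCLCI")
        assert format_path(report.path) == (
            "CVFFFF-CYFFFF-CYFLFF-CYFLFI-CYFLCI-CYCLCI-LYCLCI"
        )
        assert report.meet == "CYFLFI"
        assert report.n_edges == 6
        assert report.leg1_length == 3 and report.leg2_length == 3
        assert report.path_class is AMYLOID
        assert all(s >= 0 for s in report.node_scores)

    def test_from_meet_order_reproduces_length6_example(self, matrix, ordering):
        report = connect(matrix, ordering, "ILVWIW", "FWLCYL",
                         leg2_order="from-meet")
        assert format_path(report.path) == (
            "ILVWIW-IWVWIW-IWVCIW-IWVCIL-FWVCIL-FWLCIL-FWLCYL"
        )
        assert report.meet == "IWVCIL"

    def test_identical_endpoints(self, matrix, ordering):
        report = connect(matrix, ordering, "ILVWIW", "ILVWIW")
        assert report.path == ("ILVWIW",)
        assert report.n_edges == 0

    def test_cross_class_pair_refused(self, matrix, ordering):
        with pytest.raises(CrossClassError) as err:
            connect(matrix, ordering, "YVSTSY", "ILVWIW")
        # the error cites both scores
        assert "-0.557" in str(err.value)

    def test_meet_index_and_length_bookkeeping(self, matrix, ordering):
        rng = np.random.default_rng(11)
        peps = sample_class_peptides(matrix, NON_AMYLOID, 20, rng)
        for a, b in zip(peps[::2], peps[1::2]):
            report = connect(matrix, ordering, a, b)
            assert report.path[report.leg1_length] == report.meet
            assert report.leg1_length + report.leg2_length == report.n_edges
            assert report.n_edges == hamming(a, b) <= 6

    def test_leg_complementarity(self, matrix, ordering):
        """A coordinate changed on leg 1 is never changed on leg 2."""
        rng = np.random.default_rng(13)
        for cls in (AMYLOID, NON_AMYLOID):
            peps = sample_class_peptides(matrix, cls, 30, rng)
            for a, b in zip(peps[::2], peps[1::2]):
                report = connect(matrix, ordering, a, b)
                meet = report.meet
                changed1 = {i for i in range(6) if a[i] != meet[i]}
                changed2 = {i for i in range(6) if b[i] != meet[i]}
                assert not (changed1 & changed2)

    def test_monotone_scores_along_both_legs(self, matrix, ordering):
        rng = np.random.default_rng(17)
        for cls, sign in ((AMYLOID, 1), (NON_AMYLOID, -1)):
            peps = sample_class_peptides(matrix, cls, 30, rng)
            for a, b in zip(peps[::2], peps[1::2]):
                report = connect(matrix, ordering, a, b)
                k = report.leg1_length
                up = [sign * s for s in report.node_scores[: k + 1]]
                down = [sign * s for s in report.node_scores[k:]]
                assert all(x <= y + 1e-9 for x, y in zip(up, up[1:]))
                assert all(x >= y - 1e-9 for x, y in zip(down, down[1:]))


class TestBfsOracle:
    def test_worked_example_distance(self, matrix):
        assert bfs_shortest_class_path(matrix, "CVFFFF", "LYCLCI") == 6

    def test_adjacent_pair(self, matrix):
        assert matrix.predict("ILVWIW") is matrix.predict("ILVWIL")
        assert bfs_shortest_class_path(matrix, "ILVWIW", "ILVWIL") == 1

    def test_identical_pair(self, matrix):
        assert bfs_shortest_class_path(matrix, "ILVWIW", "ILVWIW") == 0

    def test_cross_class_refused(self, matrix):
        with pytest.raises(CrossClassError):
            bfs_shortest_class_path(matrix, "YVSTSY", "ILVWIW")

    def test_agrees_with_construction_on_random_pairs(self, matrix, ordering):
        rng = np.random.default_rng(23)
        for cls in (AMYLOID, NON_AMYLOID):
            peps = sample_class_peptides(matrix, cls, 30, rng)
            for a, b in zip(peps[::2], peps[1::2]):
                report = connect(matrix, ordering, a, b)
                assert bfs_shortest_class_path(matrix, a, b) == report.n_edges


class TestSampleVerify:
    def test_no_violations_both_classes(self, matrix, ordering):
        for cls in (AMYLOID, NON_AMYLOID):
            summary = sample_verify(matrix, ordering, 200, seed=5, cls=cls)
            assert summary.max_path_length <= 6
            assert summary.n_class_violations == 0
            assert summary.n_length_violations == 0

    def test_deterministic_given_seed(self, matrix, ordering):
        s1 = sample_verify(matrix, ordering, 50, seed=9, cls=AMYLOID)
        s2 = sample_verify(matrix, ordering, 50, seed=9, cls=AMYLOID)
        assert s1 == s2

    def test_empty_run(self, matrix, ordering):
        summary = sample_verify(matrix, ordering, 0, seed=1, cls=AMYLOID)
        assert summary.n_pairs == 0
        assert summary.max_path_length == 0


class TestGeneralLinearClassifier:
    """The construction holds for any linear position-weight classifier."""

    @pytest.mark.parametrize("seed", range(20))
    def test_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = random_effect_matrix(rng)
        o = derive_ordering(m)
        for cls in (AMYLOID, NON_AMYLOID):
            peps = sample_class_peptides(m, cls, 12, rng)
            for a, b in zip(peps[::2], peps[1::2]):
                report = connect(m, o, a, b)
                assert report.n_edges == hamming(a, b) <= 6
                check = validate_path(m, report.path, expected_class=cls)
                assert check.ok
                # meet dominance under the random matrix too
                s = m.score(report.meet)
                if cls is AMYLOID:
                    assert s >= max(m.score(a), m.score(b)) - 1e-9
                else:
                    assert s <= min(m.score(a), m.score(b)) + 1e-9
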