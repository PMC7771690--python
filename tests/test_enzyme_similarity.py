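"""Normalized local-alignment scoring against an independent DP oracle,
and the penalty-aware organism averaging."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from metabotree import (
    ABSENT_BOTH,
    ONE_SIDED,
    AlignmentConfig,
    PenaltyPolicy,
    ReactionScoreTable,
    average_reaction_scores,
    normalized_sw,
    organism_similarity,
    pairwise_sequence_similarity,
    reaction_score,
    table5_fixture,
    table6_fixture,
)
from metabotree.enzyme_similarity import raw_sw_score, read_reaction_subset, score_matrix_max
from metabotree.fixtures import AA20
from metabotree.org_matrix import ConsistencyError, OrgMatrix, ReactionCatalog

BLOSUM50 = substitution_matrices.load("BLOSUM50")


def sw_oracle(a: str, b: str, gap: float = 8.0) -> float:
    """Brute-force Smith–Waterman over the full DP matrix, linear gap cost."""
    h = np.zeros((len(a) + 1, len(b) + 1))
    best = 0.0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            h[i, j] = max(
                0.0,
                h[i - 1, j - 1] + BLOSUM50[a[i - 1], b[j - 1]],
                h[i - 1, j] - gap,
                h[i, j - 1] - gap,
            )
            best = max(best, h[i, j])
    return best


def random_peptides(rng, n, max_len=40, min_len=5):
    return [
        "".join(rng.choice(list(AA20), size=rng.integers(min_len, max_len + 1)))
        for _ in range(n)
    ]


class TestNormalizedSW:
    def test_classic_pair_raw_score(self):
        assert raw_sw_score("HEAGAWGHEE", "PAWHEAE") == 28.0
        assert sw_oracle("HEAGAWGHEE", "PAWHEAE") == 28.0

    def test_identical_sequences_score_one(self):
        assert normalized_sw("MKVAWQH", "MKVAWQH") == 1.0

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(101)
        seqs = random_peptides(rng, 20)
        for a, b in zip(seqs[::2], seqs[1::2]):
            expect = sw_oracle(a, b) / sw_oracle(a, a)
            assert normalized_sw(a, b) == pytest.approx(expect, abs=1e-12)

    def test_direction_asymmetry(self):
        # normalization is by the first argument's self-score
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(list(AA20), size=30))
        b = "".join(rng.choice(list(AA20), size=12))
        assert normalized_sw(a, b) != normalized_sw(b, a)
        assert raw_sw_score(a, b) == raw_sw_score(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            normalized_sw("", "MKV")

    def test_unknown_matrix_rejected(self):
        with pytest.raises(Exception):
            AlignmentConfig(matrix="NOSUCH")

    def test_nonpositive_gap_rejected(self):
        with pytest.raises(ValueError):
            AlignmentConfig(gap_open=0)


class TestReactionScore:
    def test_printed_matrix_max(self):
        assert score_matrix_max(table6_fixture()) == 0.87

    def test_single_identical_sequences(self):
        assert reaction_score(["MKVAW"], ["MKVAW"]) == 1.0

    def test_matches_bruteforce_over_pairs(self):
        rng = np.random.default_rng(77)
        sa = random_peptides(rng, 2, max_len=25)
        sb = random_peptides(rng, 2, max_len=25)
        expect = max(sw_oracle(a, b) / sw_oracle(a, a) for a in sa for b in sb)
        assert reaction_score(sa, sb) == pytest.approx(expect, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(13)
        sa = random_peptides(rng, 3, max_len=20)
        sb = random_peptides(rng, 3, max_len=20)
        assert reaction_score(sa, sb) == reaction_score(sa[::-1], sb[::-1])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            reaction_score([], ["MKV"])


class TestPenaltyAveraging:
    @pytest.mark.parametrize(
        "penalty,expected",
        [(-0.25, 0.305), (-0.1, 0.38), (0.0, 0.43), (0.1, 0.48)],
    )
    def test_worked_example_penalties(self, toy_pair, penalty, expected):
        _, table = toy_pair
        score = average_reaction_scores(table, PenaltyPolicy("value", penalty))
        assert score == pytest.approx(expected, abs=1e-12)

    def test_worked_example_quarter_penalty_printed_precision(self, toy_pair):
        # (3.44 + 4*0.25)/8 = 0.555; the printed two-decimal value is 0.55
        _, table = toy_pair
        score = average_reaction_scores(table, PenaltyPolicy("value", 0.25))
        assert score == pytest.approx(0.555, abs=1e-12)
        assert abs(score - 0.55) <= 0.005

    def test_worked_example_ignore_mode(self, toy_pair):
        _, table = toy_pair
        assert average_reaction_scores(table, PenaltyPolicy.ignore()) == pytest.approx(
            0.86, abs=1e-12
        )

    def test_contributing_counts(self, toy_pair):
        # absent-from-both reactions never contribute: n_R = 8 with penalty, 4 without
        _, table = toy_pair
        assert table.n_contributing(PenaltyPolicy("value", 0.1)) == 8
        assert table.n_contributing(PenaltyPolicy.ignore()) == 4

    def test_affine_in_penalty(self, toy_pair):
        _, table = toy_pair
        s0 = average_reaction_scores(table, PenaltyPolicy("value", 0.0))
        s1 = average_reaction_scores(table, PenaltyPolicy("value", 1.0))
        slope = table.one_sided_count() / table.n_contributing(PenaltyPolicy("value", 0.0))
        assert s1 - s0 == pytest.approx(slope, abs=1e-12)

    def test_ignore_dominates_low_penalties(self, toy_pair):
        _, table = toy_pair
        ignore = average_reaction_scores(table, PenaltyPolicy.ignore())
        low = average_reaction_scores(table, PenaltyPolicy("value", 0.2))
        assert ignore >= low

    def test_hand_summation_negative_penalty(self):
        table = ReactionScoreTable(
            "X", "Y",
            {"r1": 0.9, "r2": 0.4, "r3": ONE_SIDED, "r4": ONE_SIDED,
             "r5": ABSENT_BOTH, "r6": 0.7},
        )
        expect = (0.9 + 0.4 + 0.7 + 2 * -0.1) / 5
        got = average_reaction_scores(table, PenaltyPolicy("value", -0.1))
        assert got == pytest.approx(expect, abs=1e-12)

    def test_no_contributing_reactions_is_an_error(self):
        table = ReactionScoreTable("X", "Y", {"r1": ABSENT_BOTH})
        with pytest.raises(ValueError, match="undefined"):
            average_reaction_scores(table, PenaltyPolicy("value", 0.1))

    def test_penalty_parse(self):
        assert PenaltyPolicy.parse("ignore").mode == "ignore"
        assert PenaltyPolicy.parse("-0.25").value == -0.25


def _sequence_matrix(seqs_by_cell, organisms, reactions):
    presence = np.zeros((len(organisms), len(reactions)), dtype=np.uint8)
    for (org, rxn) in seqs_by_cell:
        presence[organisms.index(org), reactions.index(rxn)] = 1
    return OrgMatrix(
        organisms, ReactionCatalog(reactions), presence,
        {k: list(v) for k, v in seqs_by_cell.items()},
    )


class TestOrganismSimilarity:
    def test_disjoint_pair_scores_exactly_penalty(self):
        m = _sequence_matrix(
            {("X", "r1"): ["MKVAW"], ("Y", "r2"): ["PQRST"]}, ["X", "Y"], ["r1", "r2"]
        )
        score, table = organism_similarity(m, "X", "Y", penalty=PenaltyPolicy("value", 0.3))
        assert score == pytest.approx(0.3)
        assert table.one_sided_count() == 2

    def test_single_shared_identical_sequence_scores_one(self):
        m = _sequence_matrix(
            {("X", "r1"): ["MKVAW"], ("Y", "r1"): ["MKVAW"]}, ["X", "Y"], ["r1", "r2"]
        )
        for penalty in (PenaltyPolicy("value", -0.5), PenaltyPolicy.ignore()):
            score, _ = organism_similarity(m, "X", "Y", penalty=penalty)
            assert score == 1.0

    def test_subset_restricts_scope(self):
        m = _sequence_matrix(
            {("X", "r1"): ["MKVAW"], ("Y", "r1"): ["MKVAW"], ("X", "r2"): ["PQRST"]},
            ["X", "Y"], ["r1", "r2"],
        )
        score, table = organism_similarity(
            m, "X", "Y", reaction_subset=["r1"], penalty=PenaltyPolicy("value", 0.0)
        )
        assert score == 1.0 and list(table.entries) == ["r1"]
        with pytest.raises(ConsistencyError, match="unknown"):
            organism_similarity(m, "X", "Y", reaction_subset=["nope"])

    def test_missing_sequence_for_present_cell(self):
        presence = np.array([[1], [1]], dtype=np.uint8)
        m = OrgMatrix(["X", "Y"], ReactionCatalog(["r1"]), presence,
                      {("X", "r1"): ["MKVAW"]})
        with pytest.raises(ConsistencyError, match="Y"):
            organism_similarity(m, "X", "Y")

    def test_pairwise_matrix_symmetric_and_unit_for_identical(self):
        seqs = {}
        for org in ("X", "Y", "Z"):
            for rxn in ("r1", "r2"):
                seqs[(org, rxn)] = ["MKVAWQHILNDE"]
        m = _sequence_matrix(seqs, ["X", "Y", "Z"], ["r1", "r2"])
        s = pairwise_sequence_similarity(m, penalty=PenaltyPolicy("value", 0.25))
        assert np.array_equal(s.values, s.values.T)
        assert np.allclose(s.values, 1.0)
        assert s.parameters["symmetrization"] == "mean_of_directed"

    def test_reaction_subset_file(self, tmp_path):
        path = tmp_path / "subset.txt"
        path.write_text("# central carbon\nr1\nr2  # inline note\n\n")
        assert read_reaction_subset(path) == ["r1", "r2"]
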