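"""Elo, David's score, DCI, outcome rules and dyad stability."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domsuite.errors import UnmeasurableError, ValidationError
from domsuite.ranking import (
    EloConfig,
    Stability,
    classify_dyad_stability,
    david_scores,
    david_scores_from_alpha,
    dci,
    elo_expected,
    elo_ratings,
    elo_update,
    reward_match_outcome,
    simplify_ranks,
    urine_outcome,
)
from domsuite.records_io import Assay, MatchRecord, Outcome


def brute_force_david(alpha):
    """Independent elementwise evaluation of the David's-score formulas."""
    n = alpha.shape[0]
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            tot = alpha[i, j] + alpha[j, i]
            if i != j and tot > 0:
                p[i, j] = alpha[i, j] / tot
    w = np.array([sum(p[i, j] for j in range(n)) for i in range(n)])
    l = np.array([sum(p[j, i] for j in range(n)) for i in range(n)])
    w2 = np.array([sum(p[i, j] * w[j] for j in range(n)) for i in range(n)])
    l2 = np.array([sum(p[j, i] * l[j] for j in range(n)) for i in range(n)])
    return w + w2 - l - l2


def tube_match(order, id_a, id_b, outcome):
    return MatchRecord(Assay.TUBE, "c0", order, id_a, id_b, outcome)


class TestEloExpected:
    def test_equal_ratings_give_half(self):
        assert elo_expected(1000, 1000) == 0.5

    def test_400_point_gap_gives_ten_to_one_odds(self):
        assert elo_expected(1400, 1000) == pytest.approx(10 / 11)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(500, 1500, allow_nan=False), st.floats(500, 1500, allow_nan=False)
    )
    def test_complements_sum_to_one_and_bounded(self, ra, rb):
        ea, eb = elo_expected(ra, rb), elo_expected(rb, ra)
        assert ea + eb == pytest.approx(1.0)
        assert 0 < ea < 1

    def test_strictly_increasing_in_own_rating(self):
        vals = [elo_expected(r, 1000) for r in (900, 1000, 1100, 1300)]
        assert vals == sorted(vals) and len(set(vals)) == 4


class TestEloUpdate:
    def test_tie_between_equals_changes_nothing(self):
        assert elo_update(1000, 1000, Outcome.TIE) == (1000, 1000)

    def test_win_between_equals_transfers_half_k(self):
        assert elo_update(1000, 1000, Outcome.A_WINS) == (1010, 990)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(500, 1500, allow_nan=False),
        st.floats(500, 1500, allow_nan=False),
        st.sampled_from(list(Outcome)),
    )
    def test_exactly_zero_sum(self, ra, rb, outcome):
        na, nb = elo_update(ra, rb, outcome)
        assert na + nb == pytest.approx(ra + rb, abs=1e-9)


class TestEloRatings:
    def test_no_matches_keeps_everyone_at_baseline(self):
        hist = elo_ratings([], animals=["m0", "m1", "m2", "m3"])
        assert all(v == 1000.0 for v in hist.final.values())

    def test_two_match_fold_matches_hand_computation(self):
        # A beats B from (1000,1000): A=1010, B=990. Then B beats A:
        # E_B = 1/(1+10^((1010-990)/400)); B' = 990 + 20*(1 - E_B).
        e_b = 1.0 / (1.0 + 10.0 ** ((1010 - 990) / 400))
        expected_b = 990 + 20 * (1 - e_b)
        expected_a = 1010 - 20 * (1 - e_b)
        hist = elo_ratings(
            [
                tube_match(0, "A", "B", Outcome.A_WINS),
                tube_match(1, "B", "A", Outcome.A_WINS),
            ]
        )
        assert hist.final["A"] == pytest.approx(expected_a)
        assert hist.final["B"] == pytest.approx(expected_b)
        # frozen from the hand evaluation above
        assert expected_a == pytest.approx(999.4250, abs=1e-4)
        assert expected_b == pytest.approx(1000.5750, abs=1e-4)

    def test_unsorted_matches_rejected(self):
        ms = [tube_match(1, "A", "B", Outcome.A_WINS), tube_match(0, "A", "B", Outcome.B_WINS)]
        with pytest.raises(ValidationError, match="sorted"):
            elo_ratings(ms)

    def test_zero_sum_over_whole_history(self, small_matches):
        hist = elo_ratings(small_matches)
        assert sum(hist.final.values()) == pytest.approx(4 * 1000.0, abs=1e-9)

    def test_deterministic(self, small_matches):
        h1, h2 = elo_ratings(small_matches), elo_ratings(small_matches)
        assert h1.final == h2.final

    def test_config_k_changes_magnitude_not_direction(self, small_matches):
        big = elo_ratings(small_matches, EloConfig(k_factor=40))
        small = elo_ratings(small_matches, EloConfig(k_factor=20))
        assert big.rank == small.rank
        assert big.final["m0"] > small.final["m0"]


class TestDavidScores:
    def test_clean_sweep_two_animals(self):
        ms = [tube_match(i, "A", "B", Outcome.A_WINS) for i in range(3)]
        table = david_scores(ms)
        assert table.score_of("A") == pytest.approx(1.0)
        assert table.score_of("B") == pytest.approx(-1.0)

    def test_even_split_is_symmetric_zero(self):
        ms = [
            tube_match(0, "A", "B", Outcome.A_WINS),
            tube_match(1, "A", "B", Outcome.B_WINS),
        ]
        table = david_scores(ms)
        assert table.score_of("A") == pytest.approx(0.0)
        assert table.score_of("B") == pytest.approx(0.0)

    def test_no_decisive_interactions_unmeasurable(self):
        ms = [tube_match(0, "A", "B", Outcome.TIE)]
        with pytest.raises(UnmeasurableError):
            david_scores(ms)

    def test_matches_brute_force_on_exhaustive_small_matrices(self):
        """All 3-animal win matrices with per-dyad counts ≤ 2."""
        for counts in itertools.product(range(3), repeat=6):
            alpha = np.zeros((3, 3), dtype=int)
            alpha[np.triu_indices(3, 1)] = counts[:3]
            alpha[np.tril_indices(3, -1)] = counts[3:]
            if alpha.sum() == 0:
                continue
            table = david_scores_from_alpha(["a", "b", "c"], alpha)
            np.testing.assert_allclose(table.ds, brute_force_david(alpha), atol=1e-12)

    def test_matches_brute_force_on_random_four_animal_matrices(self, rng):
        for _ in range(200):
            alpha = rng.integers(0, 4, size=(4, 4))
            np.fill_diagonal(alpha, 0)
            if alpha.sum() == 0:
                continue
            table = david_scores_from_alpha(list("abcd"), alpha)
            np.testing.assert_allclose(table.ds, brute_force_david(alpha), atol=1e-12)
            assert table.ds.sum() == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_scaling_all_dyad_counts(self, rng):
        alpha = rng.integers(0, 4, size=(4, 4))
        np.fill_diagonal(alpha, 0)
        alpha[0, 1] += 1  # ensure non-empty
        t1 = david_scores_from_alpha(list("abcd"), alpha)
        t3 = david_scores_from_alpha(list("abcd"), alpha * 3)
        np.testing.assert_allclose(t1.ds, t3.ds, atol=1e-12)

    def test_p_matrix_dyad_rows_complementary(self, small_matches):
        table = david_scores(small_matches)
        for i in range(4):
            for j in range(i + 1, 4):
                if table.alpha[i, j] + table.alpha[j, i] > 0:
                    assert table.p[i, j] + table.p[j, i] == pytest.approx(1.0)


class TestDCI:
    def test_fully_unidirectional_is_one(self, small_matches):
        assert dci(small_matches).value == 1.0

    def test_even_split_is_zero(self):
        ms = [
            tube_match(0, "A", "B", Outcome.A_WINS),
            tube_match(1, "A", "B", Outcome.B_WINS),
        ]
        assert dci(ms).value == 0.0

    def test_mixed_dyads_toy_value(self):
        # dyad AB: 5-1, dyad CD: 2-2 -> H=7, L=3, DCI = 0.4
        ms = [tube_match(i, "A", "B", Outcome.A_WINS) for i in range(5)]
        ms += [tube_match(5, "A", "B", Outcome.B_WINS)]
        ms += [tube_match(6 + i, "C", "D", Outcome.A_WINS) for i in range(2)]
        ms += [tube_match(8 + i, "C", "D", Outcome.B_WINS) for i in range(2)]
        assert dci(ms).value == pytest.approx(0.4)

    def test_invariant_under_relabeling(self, small_matches):
        relabeled = [
            MatchRecord(m.assay, m.cage, m.order, m.id_a.replace("m", "x"),
                        m.id_b.replace("m", "x"), m.outcome)
            for m in small_matches
        ]
        assert dci(relabeled).value == dci(small_matches).value

    def test_all_ties_unmeasurable(self):
        with pytest.raises(UnmeasurableError):
            dci([tube_match(0, "A", "B", Outcome.TIE)])


class TestSimplifyRanks:
    def test_strictly_ordered_scores(self):
        ranks = simplify_ranks({"a": 1100, "b": 1050, "c": 950, "d": 900})
        assert ranks == {"a": 1, "b": 2, "c": 3, "d": 4}

    def test_ties_broken_by_identifier(self):
        ranks = simplify_ranks({"b": 1000.0, "a": 1000.0})
        assert ranks == {"a": 1, "b": 2}

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(800, 1200, allow_nan=False), min_size=1, max_size=8))
    def test_output_is_permutation(self, scores):
        ranks = simplify_ranks({f"m{i}": s for i, s in enumerate(scores)})
        assert sorted(ranks.values()) == list(range(1, len(scores) + 1))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            simplify_ranks({})


class TestUrineOutcome:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (100, 50, Outcome.A_WINS),  # both rules exceeded
            (10, 8, Outcome.TIE),  # 2-spot difference below 5
            (0, 0, Outcome.TIE),  # no information
            (20, 25, Outcome.B_WINS),  # diff 5, exactly 20% of larger: decisive
            (21, 25, Outcome.TIE),  # diff 4 < 5 spots
            (80, 100, Outcome.B_WINS),  # 20% exactly, 20 spots
            (81, 100, Outcome.TIE),  # 19% < 20%
            (0, 5, Outcome.B_WINS),  # 5 spots and 100% difference
            (0, 4, Outcome.TIE),
        ],
    )
    def test_tie_rule_boundaries(self, a, b, expected):
        assert urine_outcome(a, b) is expected

    def test_symmetry(self, rng):
        for _ in range(100):
            a, b = int(rng.integers(0, 200)), int(rng.integers(0, 200))
            fwd, rev = urine_outcome(a, b), urine_outcome(b, a)
            assert (fwd is Outcome.TIE) == (rev is Outcome.TIE)
            if fwd is Outcome.A_WINS:
                assert rev is Outcome.B_WINS


class TestRewardMatchOutcome:
    def test_majority_of_decisive_trials_wins(self):
        winners = ["A"] * 12 + ["B"] * 7 + [None]
        assert reward_match_outcome(winners, "A", "B") is Outcome.A_WINS

    def test_exact_split_assigned_to_lower_identifier(self):
        winners = ["A"] * 5 + ["B"] * 5
        assert reward_match_outcome(winners, "A", "B") is Outcome.A_WINS
        assert reward_match_outcome(winners, "B", "A") is Outcome.B_WINS

    def test_all_tied_is_tie(self):
        assert reward_match_outcome([None, None], "A", "B") is Outcome.TIE

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            reward_match_outcome([], "A", "B")


def dyad(assay, outcomes):
    return [
        MatchRecord(assay, "c0", i, "A", "B", o) for i, o in enumerate(outcomes)
    ]


class TestDyadStability:
    def test_tube_three_quarters_same_winner_is_stable(self):
        ms = dyad(Assay.TUBE, [Outcome.A_WINS] * 6 + [Outcome.B_WINS] * 2)
        s = classify_dyad_stability(ms, Assay.TUBE)
        assert s.status is Stability.STABLE and s.dominant_id == "A"

    def test_tube_below_threshold_unstable(self):
        ms = dyad(Assay.TUBE, [Outcome.A_WINS] * 5 + [Outcome.B_WINS] * 3)
        s = classify_dyad_stability(ms, Assay.TUBE)
        assert s.status is Stability.UNSTABLE and s.dominant_id is None

    def test_agonistic_needs_three_interactions(self):
        ms = dyad(Assay.AGONISTIC, [Outcome.A_WINS] * 2)
        assert (
            classify_dyad_stability(ms, Assay.AGONISTIC).status
            is Stability.UNMEASURABLE
        )

    def test_agonistic_three_interactions_measurable(self):
        ms = dyad(Assay.AGONISTIC, [Outcome.A_WINS] * 3)
        assert classify_dyad_stability(ms, Assay.AGONISTIC).status is Stability.STABLE

    def test_urine_tie_breaks_stability(self):
        ms = dyad(Assay.URINE, [Outcome.A_WINS, Outcome.A_WINS, Outcome.TIE])
        assert classify_dyad_stability(ms, Assay.URINE).status is Stability.UNSTABLE

    def test_urine_consistent_decisive_is_stable(self):
        ms = dyad(Assay.URINE, [Outcome.A_WINS, Outcome.A_WINS])
        s = classify_dyad_stability(ms, Assay.URINE)
        assert s.status is Stability.STABLE and s.dominant_id == "A"

    def test_reward_sixty_percent_of_decisive_inclusive(self):
        # 3 of 5 decisive = 60% exactly; ties excluded from the denominator
        ms = dyad(
            Assay.REWARD,
            [Outcome.A_WINS] * 3 + [Outcome.B_WINS] * 2 + [Outcome.TIE] * 3,
        )
        s = classify_dyad_stability(ms, Assay.REWARD)
        assert s.status is Stability.STABLE
        assert s.same_winner_fraction == pytest.approx(0.6)

    def test_reward_below_sixty_percent_unstable(self):
        ms = dyad(Assay.REWARD, [Outcome.A_WINS] * 4 + [Outcome.B_WINS] * 3)
        assert classify_dyad_stability(ms, Assay.REWARD).status is Stability.UNSTABLE

    def test_no_interactions_unmeasurable(self):
        assert classify_dyad_stability([], Assay.TUBE).status is Stability.UNMEASURABLE

    def test_mixed_assays_rejected(self):
        ms = dyad(Assay.TUBE, [Outcome.A_WINS])
        with pytest.raises(ValidationError):
            classify_dyad_stability(ms, Assay.URINE)
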