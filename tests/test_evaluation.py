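import itertools
import math
import random

import pytest
from scipy import stats

from epareg.eqsort import EqSet, RankedSequence
from epareg.evaluation import (
    disease_cv,
    entropy_rank_sum,
    evaluate,
    evaluation_score,
    pvalue_exact,
    pvalue_monte_carlo,
    rho_e_intervals,
    subsequence_pvalue,
)


def seq_of(queue_sets, lost_sets):
    mk = lambda members, i: EqSet(frozenset(members), is_exchange=False, id=i)
    return RankedSequence(
        queue=[mk(m, i) for i, m in enumerate(queue_sets)],
        lost=[mk(m, 100 + i) for i, m in enumerate(lost_sets)],
    )


class TestEvaluationScore:
    def test_direct_rank_sum(self):
        seq = seq_of([{"a"}, {"b"}, {"c"}], [])
        res = evaluation_score(seq, {"a", "c"})
        assert res.sigma == 4.0
        assert res.d_missing == 0

    def test_no_meaningful_hits_scores_zero(self):
        seq = seq_of([{"a"}, {"b"}], [{"c"}])
        res = evaluation_score(seq, {"zzz"})
        assert res.sigma == 0.0

    def test_empty_meaningful_set_rejected(self):
        seq = seq_of([{"a"}], [])
        with pytest.raises(ValueError):
            evaluation_score(seq, set())

    def test_lost_penalty_matches_expected_tail_rank(self):
        """A sequence shaped like the red-cell result: 8 ranked EqSets with
        meaningful members at ranks 1-6 and 8, one meaningful EqSet among
        the 14 lost ones: 29 + (8 + 7.5) = 44.5."""
        queue = [
            {"m1"}, {"m2"}, {"m3"}, {"m4"}, {"m5"}, {"m6"}, {"x7"}, {"m8"},
        ]
        lost = [{"m_lost"}] + [{f"x{i}"} for i in range(13)]
        meaningful = {"m1", "m2", "m3", "m4", "m5", "m6", "m8", "m_lost"}
        res = evaluation_score(seq_of(queue, lost), meaningful)
        assert res.rank_sum == 29
        assert res.d_missing == 1
        assert res.sigma == pytest.approx(44.5)
        assert res.n_internal == 22 and res.m_meaningful == 8

    def test_statement_h_penalty_equals_tail_expectation(self):
        """Empirical mean of the meaningful rank sum over random orderings of
        the lost tail converges to d (s + (l+1)/2)."""
        rng = random.Random(0)
        s, lost_ids = 5, ["L1", "L2", "L3", "L4"]
        meaningful_lost = {"L2", "L4"}
        sums = []
        for _ in range(20000):
            order = rng.sample(lost_ids, len(lost_ids))
            sums.append(
                sum(s + i + 1 for i, rid in enumerate(order) if rid in meaningful_lost)
            )
        expected = len(meaningful_lost) * (s + (len(lost_ids) + 1) / 2)
        assert sum(sums) / len(sums) == pytest.approx(expected, rel=0.01)


class TestExactPvalue:
    def test_single_meaningful_first_rank(self):
        assert pvalue_exact(1, 3, 1) == pytest.approx(1 / 3)

    def test_certain_event(self):
        assert pvalue_exact(8 * 22, 22, 8) == 1.0

    def test_monotone_in_sigma(self):
        values = [pvalue_exact(s, 12, 4) for s in range(10, 40)]
        assert values == sorted(values)

    def test_matches_exhaustive_enumeration_small_n(self):
        for n in range(2, 10):
            for m in (1, 2, n // 2 or 1, n - 1):
                combos = list(itertools.combinations(range(1, n + 1), m))
                for sigma0 in (m * (m + 1) // 2, n, (m * (n + 1)) // 2, m * n):
                    brute = sum(1 for c in combos if sum(c) <= sigma0) / len(combos)
                    assert pvalue_exact(sigma0, n, m) == pytest.approx(brute)

    def test_non_integer_score_compares_as_floor(self):
        assert pvalue_exact(44.5, 22, 8) == pvalue_exact(44, 22, 8)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            pvalue_exact(10, 3, 4)


class TestMonteCarloPvalue:
    def test_within_three_standard_errors_of_exact(self):
        exact = pvalue_exact(40, 12, 5)
        est, se = pvalue_monte_carlo(40, 12, 5, reps=100_000, seed=2)
        assert abs(est - exact) <= 3 * max(se, 1e-4)

    def test_single_rep_is_binary(self):
        est, _ = pvalue_monte_carlo(30, 10, 3, reps=1, seed=0)
        assert est in (0.0, 1.0)

    def test_seeded_determinism(self):
        a = pvalue_monte_carlo(25, 10, 4, reps=500, seed=9)
        b = pvalue_monte_carlo(25, 10, 4, reps=500, seed=9)
        assert a == b


class TestRankSum:
    def test_identical_groups_not_significant(self):
        p = entropy_rank_sum([1.0, 2.0], [1.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_separated_groups_match_enumeration(self):
        # groups {1,2} vs {5,6}: only 2 of C(4,2)=6 assignments are as extreme
        p = entropy_rank_sum([1.0, 2.0], [5.0, 6.0])
        assert p == pytest.approx(2 / 6)

    def test_matches_scipy_exact_when_untied(self):
        a = [0.31, 0.57, 0.91, 0.42]
        b = [0.12, 0.20, 0.28]
        ours = entropy_rank_sum(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            entropy_rank_sum([], [1.0])


class TestSubsequence:
    def test_subsequence_ranks_are_relative(self):
        seq = seq_of([{"a"}, {"b"}, {"c"}, {"d"}], [])
        sub = [EqSet(frozenset({"b"}), False, 0), EqSet(frozenset({"d"}), False, 1)]
        # in the subsequence, b has rank 1 of 2
        p = subsequence_pvalue(seq, sub, {"b"})
        assert p == pytest.approx(1 / 2)


class TestDiseaseCV:
    @pytest.fixture()
    def small_world(self, hrbc_ctx):
        return hrbc_ctx

    def test_rho_intervals_partition_axis(self, small_world):
        internal = [r.id for r in small_world.net.reactions if r.kind == "internal"]
        intervals = rho_e_intervals(small_world.graph, internal)
        assert intervals[0][0] == 0.0
        assert intervals[-1][1] == math.inf
        for (a, b), (c, d) in zip(intervals, intervals[1:]):
            assert b == c

    def test_all_disease_reactions_give_unit_rate(self, small_world):
        disease = {r.id for r in small_world.net.reactions if r.kind == "internal"}
        report = disease_cv(
            small_world.profile, small_world.graph, small_world.net,
            disease, x=50, repeats=2, seed=1, mu_values=(0.1,),
        )
        assert report.top10_true_positive_rate == 1.0

    def test_seeded_repeatability(self, small_world, hrbc):
        _, regulated, _ = hrbc
        kwargs = dict(x=50, repeats=2, seed=7, mu_values=(0.0, 0.1))
        a = disease_cv(small_world.profile, small_world.graph, small_world.net,
                       regulated, **kwargs)
        b = disease_cv(small_world.profile, small_world.graph, small_world.net,
                       regulated, **kwargs)
        assert a.mean_train_pvalues == b.mean_train_pvalues
        assert a.top10_true_positive_rate == b.top10_true_positive_rate

    def test_planted_labels_beat_background(self, small_world):
        """Labelling the top-ranked EqSets as 'disease' must push the top-10%
        precision above the background proportion."""
        seq = small_world.sort(__import__("epareg.eqsort", fromlist=["Params"]).Params(mu=0.1))
        planted = set()
        for x in seq.queue[:4]:
            planted |= x.members
        report = disease_cv(
            small_world.profile, small_world.graph, small_world.net,
            planted, x=50, repeats=5, seed=3, mu_values=(0.1,),
        )
        assert report.top10_true_positive_rate > report.background_rate

    def test_bad_percentage_rejected(self, small_world):
        with pytest.raises(ValueError):
            disease_cv(small_world.profile, small_world.graph, small_world.net,
                       {"HK"}, x=0, repeats=1, seed=0)
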