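import math

import numpy as np
import pytest
from scipy import stats

from neurochoice.decoding import (
    assign_pseudo_movement_times,
    build_grouping,
    pooled_auroc,
    session_significance,
    shuffle_null_pvalue,
)

from conftest import make_session, make_trial


def brute_force_pooled_auroc(activity, grouping):
    """Independent oracle: exhaustive pair enumeration with 0.5 tie credit."""
    activity = np.asarray(activity, dtype=float)
    u, pairs = 0.0, 0
    for ix, labels in zip(grouping.indices, grouping.labels):
        pos = activity[ix[labels]]
        neg = activity[ix[~labels]]
        for a in pos:
            for b in neg:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        pairs += len(pos) * len(neg)
    return (u / pairs if pairs else math.nan), u, pairs


def random_dataset(rng, max_per_group=20):
    """Random small grouped dataset as (trials, activity) for 'execution'."""
    levels = [0.0, 0.25, 0.5, 1.0]
    trials, activity = [], []
    i = 0
    n_groups = rng.integers(1, 5)
    conds = [
        (levels[rng.integers(4)], levels[rng.integers(4)]) for _ in range(n_groups)
    ]
    for cL, cR in conds:
        for _ in range(rng.integers(1, max_per_group + 1)):
            choice = "NoGo" if rng.random() < 0.4 else "Left"
            trials.append(make_trial(i, cL=cL, cR=cR, choice=choice))
            # integer-ish activity to exercise the tie convention
            activity.append(float(rng.integers(0, 6)))
            i += 1
    return trials, np.array(activity)


class TestGrouping:
    def _full_factorial_trials(self):
        levels = [0.0, 0.25, 0.5, 1.0]
        trials, i = [], 0
        for cL in levels:
            for cR in levels:
                for choice in ("Left", "Right", "NoGo"):
                    for _ in range(2):
                        trials.append(make_trial(i, cL=cL, cR=cR, choice=choice))
                        i += 1
        return trials

    def test_vision_left_has_12_groups(self):
        g = build_grouping(self._full_factorial_trials(), "vision_l")
        assert g.n_groups == 12  # 3 choices x 4 right contrasts

    def test_execution_has_16_groups(self):
        g = build_grouping(self._full_factorial_trials(), "execution")
        assert g.n_groups == 16

    def test_selection_excludes_nogo(self):
        trials = self._full_factorial_trials()
        g = build_grouping(trials, "selection")
        n_go = sum(1 for t in trials if t.choice != "NoGo")
        assert g.n_labeled_trials == n_go

    def test_all_nogo_selection_gives_undefined_auroc(self):
        trials = [make_trial(i, cL=0.5, cR=0.0, choice="NoGo") for i in range(6)]
        g = build_grouping(trials, "selection")
        res = pooled_auroc(np.zeros(6), g)
        assert not res.defined
        assert math.isnan(res.auroc)

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="variable"):
            build_grouping([], "audition")


class TestPooledAuroc:
    def test_perfect_separation(self):
        trials = [
            make_trial(0, choice="Left"), make_trial(1, choice="Left"),
            make_trial(2, choice="NoGo"),
        ]
        g = build_grouping(trials, "execution")
        assert pooled_auroc([2.0, 3.0, 1.0], g).auroc == 1.0

    def test_two_group_pooling(self):
        # group A (cL=0): positives [2, 3] vs negative [1] -> U = 2 of 2 pairs
        # group B (cL=0.5): positive [1] vs negative [2] -> U = 0 of 1 pair
        trials = [
            make_trial(0, cL=0.0, choice="Left"),
            make_trial(1, cL=0.0, choice="Left"),
            make_trial(2, cL=0.0, choice="NoGo"),
            make_trial(3, cL=0.5, choice="Left"),
            make_trial(4, cL=0.5, choice="NoGo"),
        ]
        g = build_grouping(trials, "execution")
        res = pooled_auroc([2.0, 3.0, 1.0, 1.0, 2.0], g)
        assert res.pair_total == 3
        assert res.auroc == pytest.approx(2.0 / 3.0)

    def test_tie_credited_half(self):
        trials = [make_trial(0, choice="Left"), make_trial(1, choice="NoGo")]
        g = build_grouping(trials, "execution")
        assert pooled_auroc([1.0, 1.0], g).auroc == 0.5

    def test_oracle_equivalence_on_random_datasets(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            trials, activity = random_dataset(rng)
            g = build_grouping(trials, "execution")
            res = pooled_auroc(activity, g)
            oracle_auroc, oracle_u, oracle_pairs = brute_force_pooled_auroc(activity, g)
            assert res.pair_total == oracle_pairs
            assert res.u_total == pytest.approx(oracle_u, abs=1e-9)
            if oracle_pairs:
                assert res.auroc == pytest.approx(oracle_auroc, abs=1e-12)

    def test_matches_scipy_mannwhitneyu_single_group(self, rng):
        """Cross-check against an independent library implementation."""
        pos = rng.normal(0.5, 1, 40)
        neg = rng.normal(0.0, 1, 30)
        trials = [make_trial(i, choice="Left") for i in range(40)] + [
            make_trial(40 + i, choice="NoGo") for i in range(30)
        ]
        g = build_grouping(trials, "execution")
        res = pooled_auroc(np.concatenate([pos, neg]), g)
        u_scipy = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert res.u_total == pytest.approx(u_scipy)

    def test_label_swap_antisymmetry(self, rng):
        for _ in range(20):
            trials, activity = random_dataset(rng)
            g = build_grouping(trials, "execution")
            res = pooled_auroc(activity, g)
            if not res.defined:
                continue
            g_swapped = build_grouping(trials, "execution")
            g_swapped.labels = [~lab for lab in g_swapped.labels]
            res_swapped = pooled_auroc(activity, g_swapped)
            assert res.auroc + res_swapped.auroc == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        trials, activity = random_dataset(rng)
        activity = activity + rng.normal(0, 0.01, activity.size)  # break ties
        g = build_grouping(trials, "execution")
        a1 = pooled_auroc(activity, g)
        a2 = pooled_auroc(np.exp(3 * activity) + 7, g)
        if a1.defined:
            assert a1.auroc == pytest.approx(a2.auroc, abs=1e-12)


class TestShuffleNull:
    def _go_nogo_trials(self, n, rng):
        return [
            make_trial(i, cL=0.0, cR=0.0, choice="Left" if rng.random() < 0.5 else "NoGo")
            for i in range(n)
        ]

    def test_constant_activity_gives_p_one(self, rng):
        trials = self._go_nogo_trials(40, rng)
        g = build_grouping(trials, "execution")
        res = shuffle_null_pvalue(np.ones(40), g, n_shuffles=200, seed=0)
        assert res.auroc == 0.5
        assert res.p_value == 1.0

    def test_perfect_separation_gives_minimal_p(self, rng):
        trials = self._go_nogo_trials(60, rng)
        go = np.array([t.choice != "NoGo" for t in trials])
        activity = np.where(go, 1.0, 0.0)
        g = build_grouping(trials, "execution")
        res = shuffle_null_pvalue(activity, g, n_shuffles=2000, seed=1)
        assert res.p_value == pytest.approx(1 / 2001)

    def test_deterministic_given_seed(self, rng):
        trials = self._go_nogo_trials(30, rng)
        activity = rng.normal(size=30)
        g = build_grouping(trials, "execution")
        p1 = shuffle_null_pvalue(activity, g, n_shuffles=500, seed=9).p_value
        p2 = shuffle_null_pvalue(activity, g, n_shuffles=500, seed=9).p_value
        assert p1 == p2

    def test_invalid_shuffle_count_rejected(self, rng):
        trials = self._go_nogo_trials(10, rng)
        g = build_grouping(trials, "execution")
        with pytest.raises(ValueError, match="n_shuffles"):
            shuffle_null_pvalue(np.zeros(10), g, n_shuffles=0)


class TestConfoundControl:
    def test_condition_driven_activity_decodes_at_chance_when_conditioned(self):
        """Activity depends only on the stimulus condition; Go probability
        also depends on the condition.  The naive auROC sees a spurious
        association; the conditioned decoder does not."""
        rng = np.random.default_rng(123)
        levels = [0.0, 0.25, 0.5, 1.0]
        trials, activity = [], []
        for i in range(10_000):
            cL, cR = levels[rng.integers(4)], levels[rng.integers(4)]
            p_go = 0.2 + 0.35 * (cL + cR)
            choice = "Left" if rng.random() < p_go else "NoGo"
            trials.append(make_trial(i, cL=cL, cR=cR, choice=choice))
            activity.append(2.0 * (cL + cR) + rng.normal(0, 0.1))
        activity = np.array(activity)
        conditioned = pooled_auroc(activity, build_grouping(trials, "execution"))
        naive = pooled_auroc(
            activity, build_grouping(trials, "execution", conditioned=False)
        )
        assert 0.48 <= conditioned.auroc <= 0.52
        assert not 0.48 <= naive.auroc <= 0.52


class TestSessionSignificance:
    def test_exact_chance_everywhere_gives_p_one(self):
        F, p = session_significance([0.5] * 6, ["a", "a", "a", "b", "b", "b"])
        assert p == 1.0

    def test_strong_consistent_decoding_oracle(self):
        # subject means nearly identical: low between-subject variance makes
        # the 0.2 deviation from chance decisive despite only 2 subjects
        aurocs = [0.699, 0.700, 0.701, 0.700, 0.700,
                  0.6999, 0.7001, 0.7003, 0.6999, 0.7003]
        subjects = ["a"] * 5 + ["b"] * 5
        F, p = session_significance(aurocs, subjects)
        # independent oracle: the same nested ANOVA arithmetic by hand
        y = np.array(aurocs) - 0.5
        grand = y.mean()
        ms_mean = y.size * grand**2
        subj_means = [y[:5].mean(), y[5:].mean()]
        ms_subj = sum(5 * (m - grand) ** 2 for m in subj_means) / 1
        F_expected = ms_mean / ms_subj
        p_expected = stats.f.sf(F_expected, 1, 1)
        assert F == pytest.approx(F_expected)
        assert p == pytest.approx(p_expected)
        assert p < 0.001

    def test_single_subject_falls_back_to_t_test(self):
        aurocs = [0.68, 0.72, 0.70, 0.71, 0.69]
        with pytest.warns(UserWarning, match="single subject"):
            F, p = session_significance(aurocs, ["a"] * 5)
        t, p_t = stats.ttest_1samp(np.array(aurocs) - 0.5, 0.0)
        assert F == pytest.approx(t * t)
        assert p == pytest.approx(p_t)

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValueError, match="two sessions"):
            session_significance([0.6], ["a"])


class TestPseudoMovementTimes:
    def test_constant_pool_assigns_constant(self):
        nogo = [make_trial(i, choice="NoGo") for i in range(5)]
        times = assign_pseudo_movement_times(nogo, [0.25, 0.25, 0.25], seed=0)
        np.testing.assert_array_equal(times, 0.25)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign_pseudo_movement_times([make_trial(0, choice="NoGo")], [])

    def test_assigned_distribution_matches_pool(self, rng):
        pool = rng.lognormal(np.log(0.25), 0.3, size=400)
        nogo = [make_trial(i, choice="NoGo") for i in range(20_000)]
        times = assign_pseudo_movement_times(nogo, pool, seed=3)
        d = stats.ks_2samp(times, pool).statistic
        assert d < 0.05

    def test_deterministic_given_seed(self, rng):
        pool = rng.normal(0.3, 0.05, 50)
        nogo = [make_trial(i, choice="NoGo") for i in range(100)]
        t1 = assign_pseudo_movement_times(nogo, pool, seed=5)
        t2 = assign_pseudo_movement_times(nogo, pool, seed=5)
        np.testing.assert_array_equal(t1, t2)
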