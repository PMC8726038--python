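import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from promtriage.clinimetrics import (
    ReasonCode,
    SelectionConfig,
    alpha_if_deleted,
    cronbach_alpha,
    distribution_summary,
    floor_effect,
    journey,
    paper_profile,
    responsiveness,
    run_selection,
    signed_rank_test,
    spearman_matrix,
)
from promtriage.instruments import (
    CohortLabel,
    Instrument,
    Timepoint,
)
from promtriage.synthetic_cohort import (
    FixtureSpec,
    apply_fixture_spec,
    default_generator_config,
    generate_cohort,
)
from promtriage.triage_engine import (
    Comparator,
    CriterionGroup,
    ThresholdCriterion,
    load_rule,
)


# ---------------------------------------------------------------------------
# Independent oracles


def average_ranks(values):
    """Hand-rolled average ranks (independent of scipy.rankdata)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_force_signed_rank_p(diffs):
    """Two-sided exact p by enumerating every sign assignment."""
    d = [x for x in diffs if x != 0]
    ranks = average_ranks([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    n = len(d)
    le = ge = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        le += w <= w_obs + 1e-12
        ge += w >= w_obs - 1e-12
    total = 2 ** n
    return min(1.0, 2 * min(le / total, ge / total))


class TestDistribution:
    def test_constant_values_are_degenerate(self):
        s = distribution_summary([4] * 20, item_id="x")
        assert (s.median, s.q1, s.q3) == (4, 4, 4)
        assert s.degenerate

    def test_spread_values_are_not(self):
        assert not distribution_summary(list(range(11))).degenerate

    def test_quartiles_match_order_statistic_interpolation(self):
        # hand-derived: positions (n-1)*p land on order statistics 2, 4, 6
        values = [1, 2, 3, 4, 5, 6, 7, 8, 20]
        s = distribution_summary(values)
        assert (s.q1, s.median, s.q3) == (3.0, 5.0, 7.0)
        # interpolated case: n=4, q1 at position 0.75 between 1 and 2
        s2 = distribution_summary([1, 2, 3, 4])
        assert s2.q1 == pytest.approx(1.75)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            distribution_summary([])


class TestFloorEffect:
    def test_worst_score_follows_direction(self, defs):
        higher_worse = defs[(Instrument.NRS_REST, 0)]
        res = floor_effect([10, 10, 0, 0], higher_worse)
        assert res.n_worst == 2
        higher_better = defs[(Instrument.OHS, 1)]
        res2 = floor_effect([0, 0, 4, 4], higher_better)
        assert res2.n_worst == 2

    def test_strictly_above_cutoff_flags(self, defs):
        d = defs[(Instrument.OHS, 1)]
        fifteen = [0] * 15 + [4] * 85
        sixteen = [0] * 16 + [4] * 84
        assert not floor_effect(fifteen, d).flagged
        assert floor_effect(sixteen, d).flagged

    def test_small_floor_proportion(self, defs):
        # 3 worst scores among 703 respondents is a 0.4% floor
        d = defs[(Instrument.NRS_REST, 0)]
        res = floor_effect([10] * 3 + [0] * 700, d)
        assert res.proportion == pytest.approx(3 / 703)
        assert not res.flagged

    def test_counting_oracle(self, defs):
        rng = np.random.default_rng(42)
        d = defs[(Instrument.OHS, 3)]
        values = rng.integers(0, 5, size=500)
        res = floor_effect(values, d)
        assert res.n_worst == sum(1 for v in values if v == 0)
        assert res.proportion == res.n_worst / 500


class TestSpearman:
    def test_identical_and_reflected_columns(self):
        x = [1, 4, 2, 7, 5, 3]
        frame = pd.DataFrame({"a": x, "b": x, "c": [-v for v in x]})
        by_pair = {(f.item_a, f.item_b): f.rho
                   for f in spearman_matrix(frame)}
        assert by_pair[("a", "b")] == pytest.approx(1.0)
        assert by_pair[("a", "c")] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        a = [1, 2, 2, 3, 5, 5]
        b = [2, 1, 4, 4, 6, 7]
        frame = pd.DataFrame({"a": a, "b": b})
        rho = spearman_matrix(frame)[0].rho
        oracle = np.corrcoef(average_ranks(a), average_ranks(b))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=50)
        b = a + rng.normal(size=50)
        f1 = spearman_matrix(pd.DataFrame({"a": a, "b": b}))[0].rho
        f2 = spearman_matrix(pd.DataFrame({"a": np.exp(a), "b": b ** 3}))[0].rho
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_constant_column_reported_undefined(self):
        frame = pd.DataFrame({"a": [1, 1, 1, 1], "b": [1, 2, 3, 4]})
        f = spearman_matrix(frame)[0]
        assert np.isnan(f.rho) and f.note == "constant column"

    def test_pairwise_complete_deletion(self):
        frame = pd.DataFrame({"a": [1, 2, 3, 4, np.nan],
                              "b": [1, 2, 3, 4, 5]})
        assert spearman_matrix(frame)[0].n == 4


class TestSignedRank:
    def test_no_change_gives_p_one(self):
        res = signed_rank_test([3, 4, 5, 6], [3, 4, 5, 6])
        assert res.p_value == 1.0 and res.n_nonzero == 0

    def test_six_pair_example_matches_enumeration(self):
        pre = [0, 0, 0, 0, 0, 0]
        post = [1, 2, 3, 4, 5, -6]
        res = signed_rank_test(pre, post)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(
            brute_force_signed_rank_p([1, 2, 3, 4, 5, -6]), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_p_matches_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        diffs = rng.integers(-4, 5, size=9)
        if not np.any(diffs):
            diffs[0] = 1
        res = signed_rank_test(np.zeros_like(diffs), diffs)
        assert res.p_value == pytest.approx(
            brute_force_signed_rank_p(list(diffs)), abs=1e-12)

    def test_exact_agrees_with_scipy_on_tie_free_data(self):
        diffs = np.array([1.1, -2.2, 3.3, 4.4, -5.5, 6.6, 7.7, 8.8, 9.9,
                          -10.1, 11.2, 12.3])
        ours = signed_rank_test(np.zeros_like(diffs), diffs)
        ref = stats.wilcoxon(diffs, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_uniform_improvement_is_detected(self):
        pre = np.full(30, 6)
        post = pre - np.arange(2, 32) % 5 - 2  # everyone improves by >= 2
        res = signed_rank_test(pre, post)
        assert res.method == "normal"
        assert res.p_value < 1e-3

    def test_rank_sum_conservation(self):
        rng = np.random.default_rng(8)
        diffs = rng.normal(size=40)
        res = signed_rank_test(np.zeros_like(diffs), diffs)
        n = res.n_nonzero
        assert res.w_plus + res.w_minus == pytest.approx(n * (n + 1) / 2)

    def test_responsiveness_threshold_is_inclusive(self):
        res = responsiveness([5, 5, 5, 5], [5, 5, 5, 5], item_id="x")
        assert not res.responsive and res.p_value == 1.0


class TestJourney:
    def _criterion(self, defs):
        return ThresholdCriterion(defs[(Instrument.NRS_ACTIVITY, 0)],
                                  Comparator.GE, 4, CriterionGroup.PAIN)

    def test_persistent_worse_group_not_flagged(self, defs):
        c = self._criterion(defs)
        m3 = [6, 7, 8, 9, 5, 1, 0, 2, 1, 0]
        m12 = [5, 6, 7, 8, 4, 0, 0, 1, 1, 0]
        res = journey(m3, m12, c)
        assert not res.flagged
        assert res.n_worse_group == 5 and res.n_better_group == 5

    def test_recovered_worse_group_flagged(self, defs):
        c = self._criterion(defs)
        m3 = [6, 7, 8, 9, 5, 1, 0, 2]
        m12 = [0, 1, 0, 2, 1, 0, 0, 1]  # the crossers scored well later
        assert journey(m3, m12, c).flagged

    def test_groups_partition_complete_pairs(self, defs):
        c = self._criterion(defs)
        m3 = [6, np.nan, 2, 9, 0]
        m12 = [5, 3, np.nan, 8, 0]
        res = journey(m3, m12, c)
        assert res.n_worse_group + res.n_better_group == 3

    def test_tiny_group_warns(self, defs):
        c = self._criterion(defs)
        res = journey([6, 0, 1, 2, 0, 1], [6, 0, 1, 2, 0, 1], c)
        assert res.small_group_warning and res.n_worse_group == 1

    def test_empty_worse_group_has_no_flag(self, defs):
        c = self._criterion(defs)
        res = journey([0, 1, 2], [0, 1, 2], c)
        assert res.worse_12m is None and not res.flagged


class TestCronbachAlpha:
    def test_identical_columns_are_perfectly_consistent(self):
        x = np.array([[1, 1], [2, 2], [4, 4], [3, 3]], dtype=float)
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_fixed_matrix_matches_variance_formula_and_pingouin(self):
        m = np.array([[0, 1, 2], [1, 1, 3], [2, 3, 3], [4, 2, 1]], dtype=float)
        ours = cronbach_alpha(m)
        k = 3
        oracle = k / (k - 1) * (1 - m.var(axis=0, ddof=1).sum()
                                / m.sum(axis=1).var(ddof=1))
        assert ours == pytest.approx(oracle, abs=1e-12)
        pingouin = pytest.importorskip("pingouin")
        ref = pingouin.cronbach_alpha(data=pd.DataFrame(m))[0]
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_independent_columns_have_near_zero_alpha(self):
        rng = np.random.default_rng(12)
        m = rng.normal(size=(1000, 3))
        assert abs(cronbach_alpha(m)) < 0.1

    def test_invariances(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(50, 1))
        m = base + rng.normal(scale=0.5, size=(50, 4))
        a1 = cronbach_alpha(m)
        shifted = m.copy()
        shifted[:, 2] += 7.0
        assert cronbach_alpha(shifted) == pytest.approx(a1, abs=1e-12)
        assert cronbach_alpha(m[:, ::-1]) == pytest.approx(a1, abs=1e-12)

    def test_zero_total_variance_is_undefined(self):
        m = np.array([[1, -1], [2, -2], [3, -3]], dtype=float)
        assert np.isnan(cronbach_alpha(m))

    def test_listwise_deletion(self):
        m = np.array([[1, 1], [2, 2], [np.nan, 3], [4, 4]])
        assert cronbach_alpha(m) == pytest.approx(1.0)


class TestAlphaIfDeleted:
    def test_two_item_group_cannot_lose_an_item(self):
        m = np.array([[1, 2], [2, 3], [3, 4], [4, 4]], dtype=float)
        res = alpha_if_deleted(m, ["a", "b"])
        assert res.alpha_if_deleted == {} and res.removal_candidates == ()

    def test_noise_column_is_the_unique_candidate(self):
        rng = np.random.default_rng(7)
        latent = rng.normal(size=400)
        m = np.column_stack([
            latent + rng.normal(scale=0.4, size=400),
            latent + rng.normal(scale=0.4, size=400),
            rng.normal(size=400),
        ])
        res = alpha_if_deleted(m, ["a", "b", "noise"])
        assert res.removal_candidates == ("noise",)
        # direct recomputation agrees
        assert res.alpha_if_deleted["noise"] == pytest.approx(
            cronbach_alpha(m[:, :2]), abs=1e-12)

    def test_identical_columns_produce_no_candidate(self):
        col = np.array([1.0, 2, 4, 3, 5])
        m = np.column_stack([col, col, col])
        res = alpha_if_deleted(m, ["a", "b", "c"])
        assert res.removal_candidates == ()  # no strict increase over 1.0


def clean_generator_config(n=400, seed=None):
    """Generator conditions with the engineered pathologies switched off."""
    cfg = default_generator_config(n, CohortLabel.TRAINING, (2016, 2017))
    keys = cfg.item_order
    R = cfg.residual_matrix().copy()
    for a, b in [((Instrument.NRS_REST, 0), (Instrument.NRS_ACTIVITY, 0)),
                 ((Instrument.NRS_ACTIVITY, 0), (Instrument.OHS, 1))]:
        i, j = keys.index(a), keys.index(b)
        R[i, j] = R[j, i] = 0.10
    cfg.residual_corr = R
    q10 = cfg.items[(Instrument.OHS, 10)]
    q10.probs[Timepoint.M3] = q10.probs[Timepoint.M12] = \
        cfg.items[(Instrument.OHS, 2)].probs[Timepoint.M3]
    return cfg


class TestRunSelection:
    def test_clean_cohort_retains_everything(self, rule9):
        cohort = generate_cohort(clean_generator_config(), seed=21)
        res = run_selection(cohort, rule9, paper_profile())
        assert res.removed == {}
        assert len(res.retained) == 9

    def test_unchanged_item_removed_as_not_responsive(self, rule9):
        cfg = clean_generator_config()
        cfg = apply_fixture_spec(cfg, FixtureSpec(
            nonresponsive_item=(Instrument.NRS_REST, 0)))
        cohort = generate_cohort(cfg, seed=30)
        res = run_selection(cohort, rule9, paper_profile())
        assert res.removed.get("NRS_REST") == (ReasonCode.NOT_RESPONSIVE,)

    def test_degenerate_item_removed_first(self, rule9):
        cfg = clean_generator_config()
        cfg = apply_fixture_spec(cfg, FixtureSpec(
            degenerate_item=(Instrument.OHS, 10)))
        cohort = generate_cohort(cfg, seed=31)
        res = run_selection(cohort, rule9, paper_profile())
        assert res.removed.get("OHS_Q10") == (
            ReasonCode.DEGENERATE_DISTRIBUTION,)

    def test_selection_is_idempotent_on_the_retained_rule(self, paperlike):
        training, _ = paperlike
        first = run_selection(training, load_rule("candidate_9item"),
                              paper_profile())
        second = run_selection(training, first.final_rule, paper_profile())
        assert second.removed == {}
        assert second.retained == first.retained

    def test_removal_reasons_record_the_earliest_stage(self, paperlike):
        training, _ = paperlike
        res = run_selection(training, load_rule("candidate_9item"),
                            paper_profile())
        for decision in res.decisions:
            if decision.status == "REMOVED":
                assert len(decision.reasons) == 1

    def test_stated_profile_uses_stricter_correlation_cutoff(self):
        assert SelectionConfig().correlation_cutoff == 0.7
        assert paper_profile().correlation_cutoff == 0.6
        assert paper_profile().keep_list == ("NRS_ACTIVITY",)
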