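import math

import pytest
from hypothesis import given, settings, strategies as st

from forumrwe import (
    CombinationStats,
    FeatureMention,
    SentimentLabel,
    UserVerdict,
    Verdict,
    combination_stats,
    confidence_interval,
    flag_combination,
    format_rr,
    invert_counts,
    overall_sentiment_ratios,
    risk_ratio,
)
from forumrwe.stats import (
    AmbiguousCountsError,
    NoCountsSolutionError,
    log_rr_standard_error,
    round_half_away,
)


class TestRiskRatio:
    def test_printed_example(self):
        assert round_half_away(risk_ratio(83, 16)) == 5.19

    def test_zero_denominator_is_infinite(self):
        assert risk_ratio(107, 0) == math.inf
        assert format_rr(risk_ratio(107, 0)) == "inf"

    def test_zero_numerator_is_zero(self):
        assert risk_ratio(0, 45) == 0.0
        assert format_rr(risk_ratio(0, 45)) == "0"

    def test_symmetry_at_equal_counts(self):
        assert risk_ratio(12, 12) == 1.0

    def test_both_zero_is_domain_error(self):
        with pytest.raises(ValueError, match="both counts"):
            risk_ratio(0, 0)

    @given(st.integers(1, 500), st.integers(1, 500))
    @settings(max_examples=100, derandomize=True)
    def test_reciprocal_product_is_one(self, a, b):
        assert risk_ratio(a, b) * risk_ratio(b, a) == pytest.approx(1.0)


class TestConfidenceInterval:
    @pytest.mark.parametrize(
        "n_I,n_W,low,high",
        [
            (17, 4, 1.72, 10.51),
            (2, 31, 0.02, 0.25),
            (83, 16, 3.28, 8.19),
            (67, 2, 8.54, 131.34),
        ],
    )
    def test_printed_intervals(self, n_I, n_W, low, high):
        lo, hi = confidence_interval(n_I, n_W)
        assert round_half_away(lo) == pytest.approx(low, abs=0.005)
        assert round_half_away(hi) == pytest.approx(high, abs=0.005)

    def test_log_symmetric_about_one_at_equal_counts(self):
        lo, hi = confidence_interval(30, 30)
        assert lo * hi == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_bounds_bracket_rr(self):
        lo, hi = confidence_interval(25, 1)
        assert lo <= 25.0 <= hi

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval(0, 5)
        with pytest.raises(ValueError):
            confidence_interval(5, 0)

    @given(st.integers(2, 300), st.integers(2, 300))
    @settings(max_examples=100, derandomize=True)
    def test_log_width_shrinks_with_counts(self, a, b):
        # More evidence tightens the interval: strictly when both counts grow,
        # and when the scarcer side grows.  (Growing only the already-dominant
        # count can widen it, because the variance term 1/n_I + 1/n_W −
        # 2/(n_I+n_W) is driven by the smaller count.)
        assert log_rr_standard_error(a + 1, b + 1) < log_rr_standard_error(a, b)
        lo, hi = sorted((a, b))
        assert log_rr_standard_error(lo + 1, hi) < log_rr_standard_error(lo, hi)


class TestInvertCounts:
    @pytest.mark.parametrize(
        "rr,n,expected",
        [
            (5.19, 99, (83, 16)),
            (33.50, 69, (67, 2)),
            (4.25, 21, (17, 4)),
            (15.08, 209, (196, 13)),
            (0.06, 33, (2, 31)),
        ],
    )
    def test_printed_pairs_invert_uniquely(self, rr, n, expected):
        assert invert_counts(rr, n) == expected

    def test_no_solution(self):
        with pytest.raises(NoCountsSolutionError):
            invert_counts(1.00, 3)  # no split of 3 has ratio 1.00

    def test_ambiguity_lists_candidates(self):
        with pytest.raises(AmbiguousCountsError) as exc:
            invert_counts(1.00, 1000)  # (500,500) and (501,499) both print 1.00
        assert (500, 500) in exc.value.candidates

    @given(st.integers(1, 200), st.integers(1, 200))
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_recovers_counts(self, n_I, n_W):
        printed = round_half_away(risk_ratio(n_I, n_W))
        if printed == 0.0:
            return  # printed as 0.00: not invertible as a positive ratio
        try:
            assert invert_counts(printed, n_I + n_W) == (n_I, n_W)
        except AmbiguousCountsError as exc:
            assert (n_I, n_W) in exc.candidates


class TestFlags:
    def _stats(self, n_I, n_W):
        ci = confidence_interval(n_I, n_W) if n_I and n_W else None
        return CombinationStats(
            "t", "s", n_I, n_W, risk_ratio(n_I, n_W),
            ci[0] if ci else None, ci[1] if ci else None,
        )

    def test_inclusion_is_strictly_more_than_threshold(self):
        assert not flag_combination(self._stats(10, 10)).included  # n = 20
        assert flag_combination(self._stats(11, 10)).included      # n = 21

    def test_significance_requires_ci_excluding_one(self):
        below = CombinationStats("t", "s", 10, 21, 10 / 21, 0.25, 0.88)
        assert flag_combination(below).significant
        spanning = CombinationStats("t", "s", 20, 20, 1.0, 0.9, 1.1)
        assert not flag_combination(spanning).significant

    def test_one_sided_counts_never_significant(self):
        one_sided = flag_combination(self._stats(107, 0))
        assert one_sided.ci_low is None and not one_sided.significant


class TestCombinationStats:
    def test_counts_and_flags_from_verdicts(self):
        verdicts = (
            [UserVerdict(f"u{i}", "metformin", "acne", Verdict.IMPROVED) for i in range(30)]
            + [UserVerdict(f"w{i}", "metformin", "acne", Verdict.WORSENED) for i in range(5)]
            + [UserVerdict("n0", "metformin", "acne", Verdict.NEUTRAL)]
            + [UserVerdict("x0", "metformin", "acne", Verdict.EXCLUDED)]
        )
        (c,) = combination_stats(verdicts)
        assert (c.n_I, c.n_W, c.n) == (30, 5, 35)
        assert c.n_neutral == 1 and c.n_excluded == 1
        assert c.rr == 6.0 and c.included and c.significant
        lo, hi = confidence_interval(30, 5)
        assert (c.ci_low, c.ci_high) == (lo, hi)

    def test_all_neutral_combination_has_nan_rr(self):
        (c,) = combination_stats([UserVerdict("u", "t", "s", Verdict.NEUTRAL)])
        assert math.isnan(c.rr) and not c.included and not c.significant


class TestOverallSentimentRatios:
    def _mentions(self, feature, n_users, sentiment):
        return [
            FeatureMention("d", 0, feature, f"u{i}", sentiment, True)
            for i in range(n_users)
        ]

    def test_all_improving_gives_unit_ratio(self, catalog):
        (r,) = overall_sentiment_ratios(
            self._mentions("inositol", 7, SentimentLabel.IMPROVING), catalog
        )
        assert r.proportions == (1.0, 0.0, 0.0)
        assert r.total_users == 7

    def test_treatment_threshold_is_strict(self, catalog):
        (r100,) = overall_sentiment_ratios(
            self._mentions("inositol", 100, SentimentLabel.NEUTRAL), catalog
        )
        (r101,) = overall_sentiment_ratios(
            self._mentions("inositol", 101, SentimentLabel.NEUTRAL), catalog
        )
        assert not r100.included and r101.included

    def test_symptoms_have_no_threshold(self, catalog):
        (r,) = overall_sentiment_ratios(
            self._mentions("acne", 3, SentimentLabel.WORSENING), catalog
        )
        assert r.included

    def test_user_contributes_once_per_sentiment(self, catalog):
        ms = self._mentions("acne", 1, SentimentLabel.IMPROVING) * 3
        (r,) = overall_sentiment_ratios(ms, catalog)
        assert r.n_improving == 1 and r.total_users == 1

    def test_proportions_sum_to_one(self, catalog, small_corpus):
        corpus, _ = small_corpus
        for r in overall_sentiment_ratios(corpus.gold_mentions, corpus.catalog):
            assert sum(r.proportions) == pytest.approx(1.0)

    def test_sentiment_mix_matches_binomial_oracle(self, catalog):
        from scipy.stats import binom

        from forumrwe import GeneratorConfig, PairGroundTruth, generate_corpus
        from forumrwe.tagging import filter_first_person

        truth = PairGroundTruth("dieting", "body_weight", 1.0, 0.6, 0.3)
        cfg = GeneratorConfig(
            seed=31, n_users=400, pair_truths=[truth], combo_truths=[],
            distance_distribution=(0.3, 0.4, 0.3, 0.0),
            conflict_rate=0.0, third_person_rate=0.0,
        )
        corpus, _ = generate_corpus(cfg, catalog)
        ratios = {
            r.feature_id: r
            for r in overall_sentiment_ratios(
                filter_first_person(corpus.gold_mentions), catalog
            )
        }
        r = ratios["dieting"]
        lo, hi = binom.ppf([0.005, 0.995], cfg.n_users, truth.p_improving)
        assert lo <= r.n_improving <= hi
        lo, hi = binom.ppf([0.005, 0.995], cfg.n_users, truth.p_worsening)
        assert lo <= r.n_worsening <= hi


def test_round_half_away_from_zero():
    assert round_half_away(5.195) == 5.20
    assert round_half_away(5.1875) == 5.19
    assert round_half_away(-0.125) == -0.13
    assert round_half_away(2.0) == 2.0
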