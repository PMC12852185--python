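"""Simple-weighted and empirical-Bayes pooling of colony trends."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonytrend.aggregation import (
    abundance_weights,
    aggregate_eb,
    aggregate_simple,
    eb_shrink,
    simple_weights,
)
from colonytrend.errors import AlignmentError, DegenerateInputError, ValidationError
from colonytrend.trend_estimation import TrendEstimate, fit_all
from colonytrend.synthetic_data import SimulationConfig, simulate_metapopulation

from conftest import make_series


def trend(colony_id, r, var_r=None):
    return TrendEstimate(
        colony_id=colony_id,
        method="log_linear" if var_r is not None else "two_point",
        r=r,
        lam=math.exp(r),
        n_records=3 if var_r is not None else 2,
        n_years_span=10,
        var_r=var_r,
    )


class TestSimpleWeights:
    def test_weight_is_mean_abundance_times_years(self):
        (w,) = simple_weights([make_series([2000, 2005], [100, 300], "A")])
        assert w.mean_abundance == 200
        assert w.n_years == 2
        assert w.weight == 400

    def test_identical_colonies_get_identical_weights(self):
        a = make_series([2000, 2005, 2011], [10, 40, 90], "A")
        b = make_series([2000, 2005, 2011], [10, 40, 90], "B")
        wa, wb = simple_weights([a, b])
        assert wa.weight == wb.weight

    def test_brute_force_recomputation(self):
        dataset = simulate_metapopulation(SimulationConfig(seed=5, n_colonies=20))
        usable = [s for s in dataset.observed if s.n_records >= 2]
        weights = {w.colony_id: w.weight for w in simple_weights(usable)}
        for ser in usable:
            counts = [rec.breeding_pairs for rec in ser.records]
            assert weights[ser.colony_id] == pytest.approx(
                sum(counts) / len(counts) * len(counts), rel=1e-12
            )

    def test_single_record_colony_rejected(self):
        with pytest.raises(ValidationError):
            simple_weights([make_series([2000], [5], "A")])


class TestAggregateSimple:
    def test_hand_computed_weighted_mean(self):
        trends = [trend("A", 0.1), trend("B", -0.1)]
        weights = simple_weights(
            [
                make_series([2000, 2001], [150, 250], "A"),  # w = 400
                make_series([2000, 2001, 2002], [100, 200, 300], "B"),  # w = 600
            ]
        )
        agg = aggregate_simple(trends, weights)
        # (0.1*400 - 0.1*600) / 1000 = -0.02
        assert agg.r_general == pytest.approx(-0.02, abs=1e-15)
        assert agg.lambda_general == pytest.approx(math.exp(-0.02), rel=1e-15)

    def test_all_zero_rates_pool_to_lambda_one(self):
        trends = [trend("A", 0.0), trend("B", 0.0)]
        weights = simple_weights(
            [make_series([2000, 2001], [1, 3], "A"), make_series([2000, 2002], [9, 9], "B")]
        )
        assert aggregate_simple(trends, weights).lambda_general == 1.0

    def test_single_colony_weights_cancel(self):
        trends = [trend("A", 0.0321)]
        weights = simple_weights([make_series([2000, 2001], [5, 6], "A")])
        assert aggregate_simple(trends, weights).r_general == pytest.approx(0.0321)

    def test_mismatched_colony_sets_raise_alignment_error(self):
        trends = [trend("A", 0.1)]
        weights = simple_weights([make_series([2000, 2001], [1, 2], "B")])
        with pytest.raises(AlignmentError, match="A"):
            aggregate_simple(trends, weights)

    def test_bootstrap_interval_is_seeded_and_reproducible(self):
        trends = [trend(c, r) for c, r in [("A", 0.1), ("B", -0.05), ("C", 0.02)]]
        weights = simple_weights(
            [
                make_series([2000, 2001], [10, 12], "A"),
                make_series([2000, 2001], [100, 90], "B"),
                make_series([2000, 2001], [50, 51], "C"),
            ]
        )
        a = aggregate_simple(trends, weights, n_boot=500, seed=9)
        b = aggregate_simple(trends, weights, n_boot=500, seed=9)
        assert a.ci_lambda == b.ci_lambda
        assert a.ci_lambda[0] < a.lambda_general < a.ci_lambda[1]


class TestEmpiricalBayes:
    def two_colony_inputs(self):
        trends = [trend("A", 0.10, 0.001), trend("B", -0.02, 0.003)]
        series = [
            make_series([2000, 2001, 2002], [100, 100, 100], "A"),
            make_series([2000, 2001, 2002], [300, 300, 300], "B"),
        ]
        return trends, series

    def test_hand_computed_two_colony_oracle(self):
        # frozen hand computation from the moment formulas:
        # V_t = 0.0072, vbar = 0.002, tau2 = 0.0052
        # w_A = 0.001/0.0062, w_B = 0.003/0.0082
        # t_bA = 0.04*w_A + 0.10*(1-w_A) = 0.09032258064516128
        # t_bB = 0.04*w_B - 0.02*(1-w_B) = 0.001951219512195129
        trends, series = self.two_colony_inputs()
        comps = eb_shrink(trends, series)
        assert comps.among_var == pytest.approx(0.0072, abs=1e-15)
        assert comps.mean_within_var == pytest.approx(0.002, abs=1e-15)
        assert comps.tau2 == pytest.approx(0.0052, abs=1e-15)
        df = comps.per_colony.set_index("colony_id")
        assert df.loc["A", "bayes_weight"] == pytest.approx(0.16129032258064516, abs=1e-12)
        assert df.loc["B", "bayes_weight"] == pytest.approx(0.36585365853658536, abs=1e-12)
        assert df.loc["A", "shrunk_trend"] == pytest.approx(0.09032258064516128, abs=1e-12)
        assert df.loc["B", "shrunk_trend"] == pytest.approx(0.001951219512195129, abs=1e-12)

    def test_pooling_with_equal_abundance_shares(self):
        trends, series = self.two_colony_inputs()
        # constant counts 100 vs 300 -> abundance weights 0.25 / 0.75
        comps = eb_shrink(trends, series)
        df = comps.per_colony.set_index("colony_id")
        assert df.loc["A", "abundance_weight"] == pytest.approx(0.25, abs=1e-12)
        assert df.loc["B", "abundance_weight"] == pytest.approx(0.75, abs=1e-12)
        agg = aggregate_eb(comps)
        expected = 0.25 * 0.09032258064516128 + 0.75 * 0.001951219512195129
        assert agg.r_general == pytest.approx(expected, abs=1e-12)
        assert agg.lambda_general == pytest.approx(math.exp(expected), rel=1e-12)
        assert agg.variance == pytest.approx(
            0.25 * 0.16129032258064516 * 0.0052 + 0.75 * 0.36585365853658536 * 0.0052,
            abs=1e-15,
        )

    def test_degenerate_identical_colonies_shrink_fully_to_mean(self):
        trends = [trend("A", 0.05, 0.002), trend("B", 0.05, 0.002)]
        series = [
            make_series([2000, 2001, 2002], [10, 10, 10], "A"),
            make_series([2000, 2001, 2002], [10, 10, 10], "B"),
        ]
        comps = eb_shrink(trends, series)
        assert comps.tau2 == 0.0
        assert (comps.per_colony["bayes_weight"] == 1.0).all()
        assert (comps.per_colony["shrunk_trend"] == 0.05).all()

    def test_perfectly_measured_trend_is_not_shrunk(self):
        trends = [trend("A", 0.10, 0.0), trend("B", -0.02, 0.001)]
        series = [
            make_series([2000, 2001, 2002], [10, 10, 10], "A"),
            make_series([2000, 2001, 2002], [10, 10, 10], "B"),
        ]
        comps = eb_shrink(trends, series)
        df = comps.per_colony.set_index("colony_id")
        assert df.loc["A", "bayes_weight"] == 0.0
        assert df.loc["A", "shrunk_trend"] == 0.10

    def test_noisier_of_two_equal_trends_shrinks_more(self):
        trends = [trend("A", 0.08, 0.004), trend("B", 0.08, 0.001), trend("C", -0.04, 0.001)]
        series = [
            make_series([2000, 2001, 2002], [10, 10, 10], c) for c in ("A", "B", "C")
        ]
        comps = eb_shrink(trends, series)
        df = comps.per_colony.set_index("colony_id")
        shift_a = abs(df.loc["A", "shrunk_trend"] - 0.08)
        shift_b = abs(df.loc["B", "shrunk_trend"] - 0.08)
        assert shift_a > shift_b

    def test_two_point_trends_rejected(self):
        trends = [trend("A", 0.1), trend("B", 0.0, 0.001)]
        series = [
            make_series([2000, 2001], [1, 2], "A"),
            make_series([2000, 2001, 2002], [1, 2, 3], "B"),
        ]
        with pytest.raises(ValidationError, match="A"):
            eb_shrink(trends, series)

    def test_single_colony_rejected(self):
        with pytest.raises(DegenerateInputError):
            eb_shrink([trend("A", 0.1, 0.001)], [make_series([2000, 2001, 2002], [1, 2, 3], "A")])

    def test_abundance_weights_ignore_unobserved_years(self):
        # A observed 2000 and 2001; B observed 2001 only: B's share uses the
        # 2001 total (A+B), A's 2000 share is 1
        series = [
            make_series([2000, 2001], [100, 100], "A"),
            make_series([2001, 2002], [300, 300], "B"),
        ]
        w = abundance_weights(series)
        raw_a = (1.0 + 100 / 400) / 2
        raw_b = (300 / 400 + 1.0) / 2
        assert w["A"] == pytest.approx(raw_a / (raw_a + raw_b), abs=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestAggregateProperties:
    @settings(deadline=None, max_examples=60)
    @given(
        rates=st.lists(st.floats(min_value=-0.4, max_value=0.6), min_size=2, max_size=8),
        weights=st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=2, max_size=8),
    )
    def test_simple_aggregate_is_a_convex_combination(self, rates, weights):
        n = min(len(rates), len(weights))
        rates, weights = rates[:n], weights[:n]
        trends = [trend(f"C{i}", r) for i, r in enumerate(rates)]
        series = []
        for i, w in enumerate(weights):
            # two equal counts -> weight = 2 * count; choose count = w / 2
            series.append(make_series([2000, 2001], [w / 2, w / 2], f"C{i}"))
        agg = aggregate_simple(trends, simple_weights(series))
        assert min(rates) - 1e-9 <= agg.r_general <= max(rates) + 1e-9

    def test_eb_aggregate_within_trend_range_and_permutation_invariant(self):
        rng = np.random.default_rng(31)
        trends = [trend(f"C{i}", rng.normal(0, 0.1), rng.uniform(1e-4, 1e-2)) for i in range(6)]
        series = [
            make_series([2000, 2001, 2002], rng.uniform(10, 1e4, 3).tolist(), f"C{i}")
            for i in range(6)
        ]
        agg = aggregate_eb(eb_shrink(trends, series))
        rs = [t.r for t in trends]
        assert min(rs) <= agg.r_general <= max(rs)
        perm = aggregate_eb(eb_shrink(trends[::-1], series[::-1]))
        assert perm.r_general == pytest.approx(agg.r_general, abs=1e-14)

    def test_methods_agree_when_all_colonies_share_a_rate(self):
        trends3 = [trend(f"C{i}", 0.03, 0.001) for i in range(3)]
        series = [
            make_series([2000, 2001, 2002], [10 * (i + 1)] * 3, f"C{i}") for i in range(3)
        ]
        simple = aggregate_simple(trends3, simple_weights(series))
        eb = aggregate_eb(eb_shrink(trends3, series))
        assert simple.r_general == pytest.approx(0.03, abs=1e-14)
        assert eb.r_general == pytest.approx(0.03, abs=1e-14)

    def test_increasing_a_colony_weight_pulls_the_mean_toward_it(self):
        trends = [trend("A", 0.2), trend("B", -0.1)]
        light = simple_weights(
            [make_series([2000, 2001], [10, 10], "A"), make_series([2000, 2001], [100, 100], "B")]
        )
        heavy = simple_weights(
            [make_series([2000, 2001], [500, 500], "A"), make_series([2000, 2001], [100, 100], "B")]
        )
        assert (
            aggregate_simple(trends, heavy).r_general
            > aggregate_simple(trends, light).r_general
        )

    def test_removing_the_dominant_decliner_raises_the_pooled_rate(self):
        dataset = simulate_metapopulation(SimulationConfig(seed=17, n_colonies=40))
        usable = [s for s in dataset.observed if s.n_records >= 2]
        trends = fit_all(usable)
        with_dom = aggregate_simple(trends, simple_weights(usable))
        kept_s = [s for s in usable if s.colony_id != "IM"]
        kept_t = [t for t in trends if t.colony_id != "IM"]
        without_dom = aggregate_simple(kept_t, simple_weights(kept_s))
        assert without_dom.lambda_general > with_dom.lambda_general
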