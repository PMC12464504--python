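import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clustercea import (
    CEDraws,
    ValidationError,
    ce_summary,
    ceac,
    cluster_bootstrap,
    icer,
    one_way_dsa,
)

from test_effects import frame_from_village_means


def draws_from(d_cost, d_effect, seed=0):
    d_cost = np.asarray(d_cost, dtype=float)
    d_effect = np.asarray(d_effect, dtype=float)
    return CEDraws(
        d_cost=d_cost,
        d_effect=d_effect,
        point=(float(d_cost.mean()), float(d_effect.mean())),
        seed=seed,
        B=len(d_cost),
    )


class TestICER:
    def test_published_style_ratio_northeast(self):
        r = icer(23.3, 2.8)
        assert r.value == pytest.approx(8.321, abs=0.001)
        assert r.quadrant == "NE"
        assert r.interpretable and not r.dominant and not r.dominated

    def test_dominant_cheaper_more_effective(self):
        r = icer(-10.0, 0.1)
        assert r.quadrant == "SE"
        assert r.dominant
        assert r.value == pytest.approx(-100.0)

    def test_zero_effect_non_interpretable_not_an_exception(self):
        r = icer(10.0, 0.0)
        assert not r.interpretable
        assert np.isnan(r.value)

    @pytest.mark.parametrize(
        "d_cost, d_effect, quadrant",
        [(5, 2, "NE"), (5, -2, "NW"), (-5, 2, "SE"), (-5, -2, "SW")],
    )
    def test_quadrants(self, d_cost, d_effect, quadrant):
        assert icer(d_cost, d_effect).quadrant == quadrant


class TestClusterBootstrap:
    def test_zero_variance_data_reproduces_point(self):
        df = frame_from_village_means(
            {"intervention": (4, 7.0), "control": (4, 3.0)}, townships=2
        )
        df["cost"] = np.where(df["arm"] == "intervention", 30.0, 10.0)
        df["age"] = 65.0
        df["sex"] = 0
        draws = cluster_bootstrap(df, "cost", "y", B=50, seed=1)
        assert np.allclose(draws.d_cost, 20.0, atol=1e-8)
        assert np.allclose(draws.d_effect, 4.0, atol=1e-8)
        assert draws.point == (pytest.approx(20.0), pytest.approx(4.0))

    def test_same_seed_identical_draws(self, small_frame):
        a = cluster_bootstrap(
            small_frame, "total_cost", "sbp_reduction", B=20, seed=9,
            effect_baseline="sbp0",
        )
        b = cluster_bootstrap(
            small_frame, "total_cost", "sbp_reduction", B=20, seed=9,
            effect_baseline="sbp0",
        )
        np.testing.assert_array_equal(a.d_cost, b.d_cost)
        np.testing.assert_array_equal(a.d_effect, b.d_effect)

    def test_bootstrap_mean_consistent_with_point(self, small_frame):
        draws = cluster_bootstrap(
            small_frame, "total_cost", "sbp_reduction", B=400, seed=2,
            effect_baseline="sbp0",
        )
        for vals, point in ((draws.d_cost, draws.point[0]), (draws.d_effect, draws.point[1])):
            mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - point) < max(2 * vals.std(ddof=1) / 5, 4 * mc_se)

    def test_invalid_replication_count_rejected(self, small_frame):
        with pytest.raises(ValidationError, match="B"):
            cluster_bootstrap(small_frame, "total_cost", "sbp_reduction", B=0, seed=1)


class TestCEAC:
    def test_all_dominant_draws_give_probability_one(self):
        draws = draws_from([-5, -1, -2], [0.1, 0.2, 0.3])
        curve = ceac(draws, [0, 100, 1000])
        assert np.all(curve.p_ce == 1.0)

    def test_lambda_zero_is_fraction_cost_saving(self):
        d_cost = np.array([-1.0, 2.0, 0.0, 5.0])
        draws = draws_from(d_cost, np.ones(4))
        curve = ceac(draws, [0.0, 10.0])
        assert curve.p_ce[0] == pytest.approx((d_cost <= 0).mean())

    def test_negative_lambda_rejected(self):
        draws = draws_from([1.0], [1.0])
        with pytest.raises(ValidationError):
            ceac(draws, [-1.0, 0.0])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_monotone_and_bounded_for_nonnegative_effects(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        draws = draws_from(rng.normal(20, 50, n), np.abs(rng.normal(0.03, 0.02, n)))
        curve = ceac(draws, np.linspace(0, 5000, 40))
        assert np.all((curve.p_ce >= 0) & (curve.p_ce <= 1))
        assert np.all(np.diff(curve.p_ce) >= 0)

    def test_limit_at_large_wtp(self):
        d_cost = np.array([5.0, -3.0, 4.0, 1.0])
        d_eff = np.array([0.1, 0.0, -0.2, 0.3])
        draws = draws_from(d_cost, d_eff)
        curve = ceac(draws, [1e12])
        expected = np.mean((d_eff > 0) | ((d_eff == 0) & (d_cost <= 0)))
        assert curve.p_ce[0] == pytest.approx(expected)


class TestCESummary:
    def test_all_northeast(self):
        s = ce_summary(draws_from([1, 2, 3], [0.1, 0.2, 0.3]))
        assert s["quadrant_proportions"]["NE"] == 1.0

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        s = ce_summary(draws_from(rng.normal(0, 1, 500), rng.normal(0, 1, 500)))
        assert sum(s["quadrant_proportions"].values()) == pytest.approx(1.0)

    def test_symmetric_effect_draws_split_evenly(self):
        rng = np.random.default_rng(1)
        eff = rng.normal(0, 1, 4000)
        s = ce_summary(draws_from(rng.normal(5, 1, 4000), eff))
        east = s["quadrant_proportions"]["NE"] + s["quadrant_proportions"]["SE"]
        assert east == pytest.approx(0.5, abs=0.03)

    def test_percentile_ci_invariant_to_draw_order(self):
        rng = np.random.default_rng(2)
        c, e = rng.normal(20, 5, 300), np.abs(rng.normal(2, 0.5, 300))
        s1 = ce_summary(draws_from(c, e))
        perm = rng.permutation(300)
        s2 = ce_summary(draws_from(c[perm], e[perm]))
        assert s1["icer_ci95"] == pytest.approx(s2["icer_ci95"])
        assert s1["d_cost_ci95"] == pytest.approx(s2["d_cost_ci95"])


class TestOneWayDSA:
    def test_empty_ranges_empty_table(self):
        assert one_way_dsa({"x": 1.0}, {}, lambda p: p["x"]) == []

    def test_ignored_parameter_leaves_icer_flat(self):
        rows = one_way_dsa(
            {"x": 1.0, "unused": 5.0},
            {"unused": (1.0, 10.0)},
            lambda p: 42.0 * p["x"],
        )
        assert rows[0].icer_low == rows[0].icer_high == 42.0

    def test_toy_evaluator_hand_values(self):
        # ICER = (C_fixed + x) / E with C_fixed=10, E=0.03
        rows = one_way_dsa(
            {"x": 10.0},
            {"x": (5.0, 15.0)},
            lambda p: (10.0 + p["x"]) / 0.03,
        )
        assert rows[0].icer_low == pytest.approx(500.0)
        assert rows[0].icer_high == pytest.approx(833.33, abs=0.01)

    def test_tornado_ordering_by_spread(self):
        rows = one_way_dsa(
            {"a": 1.0, "b": 1.0},
            {"a": (0.9, 1.1), "b": (0.1, 2.0)},
            lambda p: 100 * p["a"] * p["b"],
        )
        assert [r.parameter for r in rows] == ["b", "a"]

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError, match="ghost"):
            one_way_dsa({"x": 1.0}, {"ghost": (0, 1)}, lambda p: 1.0)

    def test_evaluator_failure_names_parameter(self):
        def bad(p):
            raise ZeroDivisionError("effect is zero")

        with pytest.raises(RuntimeError, match="x=0.5"):
            one_way_dsa({"x": 1.0}, {"x": (0.5, 2.0)}, bad)
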