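import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nemquant.errors import ValidationError
from nemquant.stats import (
    area_to_radius,
    dunn_test,
    gated_multi_group,
    gated_two_group,
    normalize_measure,
    ols_rate,
    pearson_fit,
    significance_stars,
)


class TestNormalize:
    def test_to_t0_first_element_is_one(self, rng):
        x = rng.random(10) + 0.5
        out, meta = normalize_measure(x, "to_t0")
        assert out[0] == 1.0
        assert meta["scheme"] == "to_t0"

    def test_control_schemes_divide_by_reference(self):
        out, _ = normalize_measure([3.0], "to_iso_control", reference=2.0)
        assert out[0] == pytest.approx(1.5)
        out, _ = normalize_measure([0.4], "to_reference_signal", reference=0.8)
        assert out[0] == pytest.approx(0.5)

    def test_metadata_distinguishes_schemes(self):
        _, m1 = normalize_measure([1.0, 2.0], "to_t0")
        _, m2 = normalize_measure([1.0, 2.0], "to_iso_control", reference=1.0)
        assert m1 != m2  # outputs under different schemes are not comparable

    def test_bad_scheme_and_bad_reference_raise(self):
        with pytest.raises(ValidationError):
            normalize_measure([1.0], "to_nothing")
        with pytest.raises(ValidationError):
            normalize_measure([1.0], "to_iso_control", reference=0.0)
        with pytest.raises(ValidationError):
            normalize_measure([1.0], "to_iso_control")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=2**16))
    def test_commutes_with_positive_rescaling(self, scale, seed):
        x = np.random.default_rng(seed).random(6) + 0.1
        base, _ = normalize_measure(x, "to_t0")
        scaled, _ = normalize_measure(x * scale, "to_t0")
        np.testing.assert_allclose(scaled, base, rtol=1e-9)


class TestTwoGroupGate:
    def test_normal_data_routed_to_t_family(self):
        hits = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            r = gated_two_group(g.normal(0, 1, 30), g.normal(0, 1, 30))
            if r.test_name in ("student_t", "welch_t"):
                hits += 1
        # both groups pass Shapiro-Wilk with probability ~0.95^2 = 0.90;
        # 85/100 keeps the check well clear of binomial noise
        assert hits >= 85

    def test_heavy_tailed_data_routed_to_mann_whitney(self):
        hits = 0
        for seed in range(50):
            g = np.random.default_rng(seed)
            r = gated_two_group(g.standard_cauchy(30), g.standard_cauchy(30))
            if r.test_name == "mann_whitney_u":
                hits += 1
        assert hits >= 35

    def test_unequal_variance_normals_get_welch(self):
        hits = 0
        for seed in range(50):
            g = np.random.default_rng(seed)
            r = gated_two_group(g.normal(0, 1, 40), g.normal(0, 6, 40))
            if r.test_name == "welch_t":
                hits += 1
        assert hits >= 35

    def test_gate_trace_explains_the_route(self):
        g = np.random.default_rng(0)
        r = gated_two_group(g.normal(0, 1, 30), g.normal(0, 1, 30))
        assert "shapiro_p_group0" in r.gate_trace
        assert "shapiro_p_group1" in r.gate_trace
        if r.test_name in ("student_t", "welch_t"):
            assert "levene_p" in r.gate_trace

    def test_identical_samples_report_p_one(self):
        x = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 100.0])  # non-normal, identical
        r = gated_two_group(x, x.copy())
        assert r.test_name == "mann_whitney_u"
        assert r.p_value == 1.0

    def test_gate_is_deterministic(self):
        g = np.random.default_rng(5)
        a, b = g.normal(0, 1, 20), g.normal(0, 1, 20)
        r1, r2 = gated_two_group(a, b), gated_two_group(a, b)
        assert r1.test_name == r2.test_name and r1.p_value == r2.p_value

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            gated_two_group([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMultiGroupGate:
    def test_normal_groups_get_welch_anova_games_howell(self):
        g = np.random.default_rng(7)  # seed whose three draws all pass Shapiro-Wilk
        r = gated_multi_group([g.normal(0, 1, 25), g.normal(0, 2, 25),
                               g.normal(1, 1, 25)])
        assert r.test_name == "welch_anova+games_howell"
        assert len(r.posthoc) == 3
        assert {"group_a", "group_b", "p_adjusted", "stars"} <= set(r.posthoc.columns)

    def test_skewed_groups_get_kruskal_dunn(self, rng):
        r = gated_multi_group([rng.exponential(1, 25) ** 3 for _ in range(4)])
        assert r.test_name == "kruskal_wallis+dunn"
        assert len(r.posthoc) == 6

    def test_shifted_group_dominates_posthoc(self, rng):
        groups = [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(4, 1, 30)]
        r = gated_multi_group(groups)
        ph = r.posthoc
        involving_2 = ph[(ph.group_a.astype(str) == "2") | (ph.group_b.astype(str) == "2")]
        others = ph[~ph.index.isin(involving_2.index)]
        assert involving_2["p_adjusted"].max() < others["p_adjusted"].min()

    def test_constant_group_rejected(self):
        with pytest.raises(ValidationError):
            gated_multi_group([[1.0] * 5, [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]])

    def test_fewer_than_three_groups_rejected(self, rng):
        with pytest.raises(ValidationError):
            gated_multi_group([rng.normal(size=5), rng.normal(size=5)])


class TestDunn:
    def test_symmetric_null_gives_large_p(self, rng):
        groups = [rng.normal(0, 1, 200) for _ in range(3)]
        df = dunn_test(groups)
        assert (df["p_unadjusted"] > 0.01).all()

    def test_separated_groups_give_small_p(self, rng):
        df = dunn_test([rng.normal(0, 1, 40), rng.normal(10, 1, 40)])
        assert df["p_unadjusted"].iloc[0] < 1e-6

    def test_bonferroni_and_holm_never_decrease_p(self, rng):
        groups = [rng.normal(m, 1, 15) for m in (0, 0.5, 1.0)]
        plain = dunn_test(groups)["p_unadjusted"]
        for adjust in ("bonferroni", "holm"):
            adj = dunn_test(groups, adjust=adjust)["p_adjusted"]
            assert (adj >= plain - 1e-15).all()


class TestOlsRate:
    @staticmethod
    def _series(slope, noise_sd, n_cells, seed=0, times=(4.0, 4.5, 5.0)):
        g = np.random.default_rng(seed)
        rows = [{"time_min": t, "S": 1.0 + slope * t + g.normal(0, noise_sd)}
                for _ in range(n_cells) for t in times]
        return pd.DataFrame(rows)

    def test_noiseless_series_gives_exact_slope_and_unit_r2(self):
        fit = ols_rate(self._series(0.3, 0.0, 5))
        assert fit.slope == pytest.approx(0.3, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_points_outside_window_ignored(self):
        df = self._series(0.3, 0.0, 5)
        spoiled = pd.concat([df, pd.DataFrame([{"time_min": 10.0, "S": 99.0}])])
        fit = ols_rate(spoiled, window=(4.0, 5.0))
        assert fit.slope == pytest.approx(0.3, abs=1e-12)

    def test_heteroscedastic_noise_triggers_robust_errors(self):
        robust = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            rows = [{"time_min": t, "S": 1 + 0.3 * t + g.normal(0, 0.01 + 0.3 * (t - 4))}
                    for _ in range(25) for t in (4.0, 4.5, 5.0)]
            if ols_rate(pd.DataFrame(rows)).robust_se_used:
                robust += 1
        assert robust >= 18

    def test_slope_bias_small_at_realistic_n(self):
        slopes = [ols_rate(self._series(0.3, 0.03, 25, seed=s)).slope for s in range(50)]
        assert abs(np.mean(slopes) / 0.3 - 1.0) < 0.02

    def test_diagnostics_reported(self):
        fit = ols_rate(self._series(0.3, 0.02, 10, seed=1))
        assert set(fit.diagnostics) == {"breusch_pagan_p", "shapiro_resid_p", "durbin_watson"}
        assert 0 < fit.diagnostics["durbin_watson"] < 4

    def test_zero_variance_response_rejected(self):
        df = pd.DataFrame({"time_min": [4.0, 4.5, 5.0], "S": [1.0, 1.0, 1.0]})
        with pytest.raises(ValidationError):
            ols_rate(df)

    def test_single_time_point_rejected(self):
        df = pd.DataFrame({"time_min": [4.5, 4.5], "S": [1.0, 1.1]})
        with pytest.raises(ValidationError):
            ols_rate(df)


class TestPearson:
    def test_exact_linear_relation_gives_unit_r(self):
        out = pearson_fit([1, 2, 3, 4], [2, 4, 6, 8])
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)

    def test_independent_normals_give_near_zero_r(self):
        small = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            if abs(pearson_fit(g.normal(size=1000), g.normal(size=1000))["r"]) < 0.1:
                small += 1
        assert small >= 19

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            pearson_fit([1, 2], [1, 2])
        with pytest.raises(ValidationError):
            pearson_fit([1, 1, 1], [1, 2, 3])


class TestSmallDerived:
    @pytest.mark.parametrize("area,expected", [(np.pi, 1.0), (0.0, 0.0), (100 * np.pi, 10.0)])
    def test_area_to_radius(self, area, expected):
        assert area_to_radius(area) == pytest.approx(expected)

    def test_negative_area_rejected(self):
        with pytest.raises(ValidationError):
            area_to_radius(-1.0)

    @pytest.mark.parametrize("p,stars", [
        (0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0009, "***"), (5e-5, "****")])
    def test_significance_stars(self, p, stars):
        assert significance_stars(p) == stars
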