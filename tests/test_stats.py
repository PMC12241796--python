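import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sepnoise.epochs import DomainError, GroupDataset
from sepnoise.simulate import ComponentSpec, GroupSimConfig, NoiseSpec, PhaseResetSpec, \
    gen_participant_epochs
from sepnoise.stats import (
    derived_outcomes,
    effect_size_curve,
    hedges_g,
    mixed_anova_2way,
    ols_regression,
)


def g_from_samples(a, b, **kw):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return hedges_g(a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size, **kw)


group_samples = st.lists(st.floats(-100, 100), min_size=3, max_size=10).filter(
    lambda v: np.std(v, ddof=1) > 1e-6
)


class TestHedgesG:
    @pytest.mark.parametrize(
        "hc,ts,printed",
        [
            ((15.8, 1.65), (15.6, 1.29), 0.15),   # N1 timing
            ((41.2, 2.02), (42.2, 1.45), -0.55),  # P1 timing
            ((64.9, 2.89), (65.5, 2.84), -0.2),   # N2 timing
            ((284.3, 6.65), (285.1, 6.38), -0.13),  # P3 timing
        ],
    )
    def test_published_component_timing_rows(self, hc, ts, printed):
        g = hedges_g(hc[0], hc[1], 19, ts[0], ts[1], 19)
        assert g == pytest.approx(printed, abs=0.02)

    def test_equal_means_give_zero(self):
        assert hedges_g(5.0, 1.0, 10, 5.0, 2.0, 10) == 0.0

    @given(group_samples, group_samples)
    def test_antisymmetry(self, a, b):
        assert g_from_samples(a, b) == pytest.approx(-g_from_samples(b, a), abs=1e-10)

    @given(group_samples, group_samples,
           st.floats(-50, 50), st.floats(0.1, 20))
    def test_location_scale_invariance(self, a, b, shift, scale):
        base = g_from_samples(a, b)
        moved = g_from_samples(scale * (np.array(a) + shift), scale * (np.array(b) + shift))
        assert moved == pytest.approx(base, rel=1e-6, abs=1e-8)

    def test_zero_pooled_sd_is_undefined(self):
        with pytest.raises(DomainError, match="pooled SD"):
            hedges_g(1.0, 0.0, 5, 2.0, 0.0, 5)

    def test_small_sample_correction_against_gamma_oracle(self):
        for n1, n2 in ((10, 10), (19, 19), (30, 25)):
            df = n1 + n2 - 2
            j_exact = math.gamma(df / 2) / (math.sqrt(df / 2) * math.gamma((df - 1) / 2))
            j_approx = 1 - 3 / (4 * df - 1)
            if n1 + n2 >= 20:
                assert abs(j_exact - j_approx) < 1e-3
            g_flagged = hedges_g(1.0, 1.0, n1, 0.0, 1.0, n2, exact_correction=True)
            assert g_flagged == pytest.approx(j_exact * 1.0, abs=1e-12)


class TestEffectSizeCurve:
    def test_identical_groups_zero_everywhere(self, rng):
        curves = rng.normal(size=(6, 40))
        out = effect_size_curve(curves, curves.copy())
        np.testing.assert_allclose(out.g, 0.0, atol=1e-12)
        assert not out.mask.any()

    def test_two_point_toy_matches_scalar(self):
        a = np.array([[1.0, 10.0], [2.0, 12.0], [3.0, 14.0]])
        b = np.array([[4.0, 9.0], [5.0, 11.0], [6.0, 13.0]])
        out = effect_size_curve(a, b)
        for point in range(2):
            expected = g_from_samples(a[:, point], b[:, point])
            assert out.g[point] == pytest.approx(expected, abs=1e-12)
        assert out.mask[0] and (np.abs(out.g) > 0.5)[0]

    def test_degenerate_points_unmarked(self):
        a = np.ones((3, 2))
        b = np.ones((3, 2))
        out = effect_size_curve(a, b)
        assert np.isnan(out.g).all() and not out.mask.any()

    def test_mismatched_abscissa_errors(self, rng):
        with pytest.raises(DomainError):
            effect_size_curve(rng.normal(size=(3, 5)), rng.normal(size=(3, 6)))


def brute_force_mixed_anova(y, groups):
    """Sums of squares via explicit model-comparison loops (oracle)."""
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    n, k = y.shape
    labels = list(dict.fromkeys(groups))
    grand = y.mean()
    ss = {}
    ss["total"] = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    subj = [y[i].mean() for i in range(n)]
    ss["between_subj"] = sum(k * (m - grand) ** 2 for m in subj)
    gmean = {g: y[groups == g].mean() for g in labels}
    ss["group"] = sum(k * (gmean[groups[i]] - grand) ** 2 for i in range(n))
    ss["subj_within"] = ss["between_subj"] - ss["group"]
    lmean = [y[:, j].mean() for j in range(k)]
    ss["within"] = sum(n * (m - grand) ** 2 for m in lmean)
    cell = {(g, j): y[groups == g, j].mean() for g in labels for j in range(k)}
    ss["cells"] = sum((cell[(groups[i], j)] - grand) ** 2 for i in range(n) for j in range(k))
    ss["interaction"] = ss["cells"] - ss["group"] - ss["within"]
    ss["error_within"] = ss["total"] - ss["cells"] - ss["subj_within"]
    return ss


class TestMixedAnova:
    def toy(self):
        y = np.array(
            [
                [3.1, 2.8, 2.2, 1.9],
                [2.9, 2.6, 2.1, 2.0],
                [3.4, 3.1, 2.5, 2.3],
                [3.8, 3.5, 2.9, 2.4],
                [3.6, 3.2, 2.7, 2.6],
                [4.0, 3.8, 3.0, 2.7],
            ]
        )
        groups = np.array(["HC"] * 3 + ["TS"] * 3)
        return y, groups

    def test_matches_brute_force_oracle(self):
        y, groups = self.toy()
        table = mixed_anova_2way(y, groups).set_index("source")
        oracle = brute_force_mixed_anova(y, groups)
        assert table.loc["Group", "ss"] == pytest.approx(oracle["group"], abs=1e-10)
        assert table.loc["Subjects(Group)", "ss"] == pytest.approx(oracle["subj_within"], abs=1e-10)
        assert table.loc["Within", "ss"] == pytest.approx(oracle["within"], abs=1e-10)
        assert table.loc["Group x Within", "ss"] == pytest.approx(oracle["interaction"], abs=1e-10)
        assert table.loc["Within x Subjects", "ss"] == pytest.approx(oracle["error_within"], abs=1e-10)

    def test_sum_of_components_conserves_total(self, rng):
        y = rng.normal(size=(10, 4))
        groups = np.array(["HC"] * 5 + ["TS"] * 5)
        table = mixed_anova_2way(y, groups)
        assert table["ss"].sum() == pytest.approx(((y - y.mean()) ** 2).sum(), abs=1e-9)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.normal(size=(12, 3)) + np.array([0.0, 0.5, 1.0])
        groups = np.array(["HC"] * 6 + ["TS"] * 6)
        table = mixed_anova_2way(y, groups).set_index("source")
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "group": np.repeat(groups, 3),
                "level": list("abc") * 12,
                "value": y.ravel(),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = pingouin.mixed_anova(long, dv="value", within="level",
                                       between="group", subject="subject").set_index("Source")
        assert table.loc["Group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert table.loc["Within", "F"] == pytest.approx(ref.loc["level", "F"], rel=1e-6)
        assert table.loc["Group x Within", "F"] == pytest.approx(ref.loc["Interaction", "F"], rel=1e-6)

    def test_constant_table_is_degenerate(self):
        table = mixed_anova_2way(np.ones((6, 3)), ["HC"] * 3 + ["TS"] * 3)
        assert table["F"].isna().all()

    def test_missing_cells_error(self):
        y = np.ones((4, 3))
        y[1, 2] = np.nan
        with pytest.raises(DomainError, match="missing"):
            mixed_anova_2way(y, ["HC", "HC", "TS", "TS"])


class TestOlsRegression:
    def test_exact_linear_predictor(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": rng.normal(size=30)})
        res = ols_regression(3.0 * x + 1.0, X)
        row = res.univariate.set_index("predictor").loc["a"]
        assert row["r2"] == pytest.approx(1.0, abs=1e-12)
        assert row["p"] < 1e-12

    def test_null_model_r2_matches_expectation(self, rng):
        k, n, reps = 3, 20, 1000
        r2s = [
            ols_regression(
                rng.normal(size=n), pd.DataFrame(rng.normal(size=(n, k)), columns=list("abc"))
            ).r2
            for _ in range(reps)
        ]
        assert np.mean(r2s) == pytest.approx(k / (n - 1), abs=0.02)

    def test_coefficients_match_normal_equations(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6], "b": [2.0, 1, 4, 3, 6, 5]})
        y = np.array([1.0, 3, 2, 5, 4, 6])
        res = ols_regression(y, X)
        design = np.column_stack([np.ones(6), X["a"], X["b"]])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)

    def test_r2_equals_squared_correlation_with_fit(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(size=25)
        res = ols_regression(y, X)
        design = np.column_stack([np.ones(25), X.to_numpy()])
        fitted = design @ np.linalg.lstsq(design, y, rcond=None)[0]
        assert res.r2 == pytest.approx(np.corrcoef(fitted, y)[0, 1] ** 2, abs=1e-10)

    def test_constant_column_named_in_error(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10), "flat": np.ones(10)})
        with pytest.raises(DomainError, match="flat"):
            ols_regression(rng.normal(size=10), X)

    def test_collinear_columns_named_in_error(self, rng):
        a = rng.normal(size=10)
        X = pd.DataFrame({"a": a, "twice_a": 2 * a, "b": rng.normal(size=10)})
        with pytest.raises(DomainError, match="collinear"):
            ols_regression(rng.normal(size=10), X)

    def test_too_few_rows_error(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 3)), columns=list("abc"))
        with pytest.raises(DomainError):
            ols_regression(rng.normal(size=4), X)


class TestDerivedOutcomes:
    def test_noiseless_participant_limits(self):
        cfg = GroupSimConfig(
            n_trials=10,
            components=(ComponentSpec("P2", 98.0, 12.0, 5.0),),
            noise=NoiseSpec(0.0, 1.0),
            phase_reset=PhaseResetSpec(pre_amp_uv=0.0),
            between_participant_scale_sd=0.0,
        )
        es = gen_participant_epochs(cfg, 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = derived_outcomes(GroupDataset([es]))
        row = table.iloc[0]
        assert row["mean_sd_uv"] < 1e-12
        # identical trials: ITPC is 1 throughout, so onset changes vanish
        assert row["alpha_itpc_post_minus_pre"] == pytest.approx(0.0, abs=1e-9)
        assert row["gamma_itpc_post_minus_pre"] == pytest.approx(0.0, abs=1e-9)
        assert row["p2_amplitude_uv"] == pytest.approx(5.0, abs=0.05)
        assert row["alpha_itpc_pre_minus_post"] == -row["alpha_itpc_post_minus_pre"]

    def test_window_mean_differences_hand_checked(self, rng):
        cfg = GroupSimConfig(
            n_trials=20,
            noise=NoiseSpec(2.0, 1.0),
            between_participant_scale_sd=0.0,
            seed=3,
        )
        es = gen_participant_epochs(cfg, 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = derived_outcomes(GroupDataset([es]))
        row = table.iloc[0]
        # mean SD over the epoch recomputed directly
        expected_sd = es.data.std(axis=1, ddof=1).mean()
        assert row["mean_sd_uv"] == pytest.approx(expected_sd, abs=1e-12)
        assert row["cv_post_minus_pre"] == pytest.approx(-row["cv_pre_minus_post"], abs=1e-12)
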