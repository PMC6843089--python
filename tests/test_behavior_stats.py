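"""RT preprocessing, robust correlations, regression, fit comparison."""

import numpy as np
import pandas as pd
import pytest

from madc._exceptions import InvalidDataError
from madc.behavior_stats import (
    compare_fits_linear_quadratic,
    incremental_r2,
    jackknife_se,
    motor_bias_check,
    partial_correlation,
    percentage_bend_correlation,
    preprocess_rt,
    rt_regression,
)


def make_rt_trials(rng, n_subj=6, n_per=120, scale=1.0):
    rows = []
    for s in range(n_subj):
        base = rng.uniform(700, 1100)
        for i in range(n_per):
            rows.append(
                {
                    "subject_id": f"S{s}",
                    "block": i // 20 + 1,
                    "trial_index": i + 1,
                    "cue_location": "cued",
                    "event_location": "cued",
                    "magnitude_deg": 10.0,
                    "response_location": rng.choice(
                        ["cued", "opposite", "adjacent", "none"]
                    ),
                    "rt_ms": scale * base * np.exp(0.2 * rng.standard_normal()),
                    "excluded": 0,
                }
            )
    return pd.DataFrame(rows)


class TestPreprocessRT:
    def test_gross_outlier_excluded(self):
        rng = np.random.default_rng(0)
        t = make_rt_trials(rng)
        mean = t.loc[t.subject_id == "S0", "rt_ms"].mean()
        sd = t.loc[t.subject_id == "S0", "rt_ms"].std()
        idx = t.index[t.subject_id == "S0"][0]
        t.loc[idx, "rt_ms"] = mean + 10 * sd
        res = preprocess_rt(t)
        assert bool(res["trials"].loc[idx, "rt_outlier"])

    def test_scale_invariance_of_normalized_rt(self):
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
        a = preprocess_rt(make_rt_trials(rng1, scale=1.0))
        b = preprocess_rt(make_rt_trials(rng2, scale=2.7))
        pd.testing.assert_series_equal(
            a["trials"]["normalized_rt"], b["trials"]["normalized_rt"]
        )

    def test_median_cued_normalized_mean_is_one(self):
        res = preprocess_rt(make_rt_trials(np.random.default_rng(2)))
        cued = res["summary"].query("response_location == 'cued'")
        assert cued["mean_normalized_rt"].median() == pytest.approx(1.0)

    def test_no_rt_rejected(self):
        t = make_rt_trials(np.random.default_rng(3))
        t["rt_ms"] = np.nan
        with pytest.raises(InvalidDataError):
            preprocess_rt(t)


class TestPercentageBend:
    def test_perfect_line(self):
        x = np.linspace(0, 1, 30)
        rho, p = percentage_bend_correlation(x, x)
        assert rho == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-10

    def test_bivariate_gaussian_recovery(self):
        rng = np.random.default_rng(4)
        n = 10_000
        x = rng.standard_normal(n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        rho, _ = percentage_bend_correlation(x, y)
        assert 0.45 <= rho <= 0.55

    def test_outlier_robustness_vs_pearson(self):
        """A gross outlier flips Pearson but not the percentage bend."""
        rng = np.random.default_rng(5)
        n = 40
        x = rng.standard_normal(n)
        y = 0.8 * x + 0.6 * rng.standard_normal(n)
        x[0], y[0] = 40.0, -60.0
        assert np.corrcoef(x, y)[0, 1] < 0
        rho, _ = percentage_bend_correlation(x, y)
        assert rho > 0.3

    def test_matches_pingouin_reference(self):
        """Independent cross-check against pingouin's percbend estimator."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        x = rng.standard_normal(60)
        y = 0.4 * x + rng.standard_normal(60)
        x[3] = 9.0
        rho, p = percentage_bend_correlation(x, y, bend=0.2)
        ref = pingouin.corr(x, y, method="percbend")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_small_bend_approaches_pearson_on_clean_data(self):
        rng = np.random.default_rng(7)
        n = 1000
        x = rng.standard_normal(n)
        y = 0.6 * x + rng.standard_normal(n)
        rho, _ = percentage_bend_correlation(x, y, bend=0.01)
        assert abs(rho - np.corrcoef(x, y)[0, 1]) < 0.01

    def test_constant_input_flagged(self):
        with pytest.raises(InvalidDataError):
            percentage_bend_correlation(np.ones(10), np.arange(10))


class TestPartialCorrelation:
    def test_independent_control_leaves_rho(self):
        rng = np.random.default_rng(8)
        n = 5000
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        z = rng.standard_normal(n)
        rho_p, _ = partial_correlation(x, y, z)
        assert rho_p == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.03)

    def test_control_identical_to_y_flagged(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        with pytest.raises(InvalidDataError):
            partial_correlation(x, y, y)

    def test_two_route_equivalence(self):
        """Closed form equals the residual-regression route to 1e-10."""
        rng = np.random.default_rng(10)
        n = 1000
        z = rng.standard_normal(n)
        x = 0.4 * z + rng.standard_normal(n)
        y = -0.3 * z + 0.5 * x + rng.standard_normal(n)
        rho_p, _ = partial_correlation(x, y, z)
        zz = np.column_stack([np.ones(n), z])
        rx = x - zz @ np.linalg.lstsq(zz, x, rcond=None)[0]
        ry = y - zz @ np.linalg.lstsq(zz, y, rcond=None)[0]
        assert rho_p == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)


class TestRtRegression:
    def make_data(self, rng, bias_effect=0.0, noise=1.0, n_subj=15):
        rows = []
        for s in range(n_subj):
            for loc in ("cued", "opposite", "adjacent"):
                d = rng.uniform(0.5, 2.5)
                b = rng.uniform(0.3, 2.0)
                mag = rng.uniform(5, 60)
                rt = 1.0 + bias_effect * (-b) + noise * 0.1 * rng.standard_normal()
                rows.append(
                    {"subject_id": s, "location": loc, "rt": rt,
                     "d_prime_av": d, "b_lr": b, "magnitude": mag}
                )
        return pd.DataFrame(rows)

    def test_exact_linear_dependence_recovered(self):
        rng = np.random.default_rng(11)
        d = self.make_data(rng, bias_effect=0.0, noise=0.0)
        d["rt"] = 2.0 * d["d_prime_av"]
        rep = rt_regression(d, n_perm=49, seed=0)
        # standardized response: coefficient on d' is 1, others 0
        assert rep.coefficients["d_prime_av"] == pytest.approx(1.0, abs=1e-8)
        assert rep.coefficients["b_lr"] == pytest.approx(0.0, abs=1e-8)

    def test_bias_only_dependence_detected(self):
        rng = np.random.default_rng(12)
        d = self.make_data(rng, bias_effect=0.5, noise=0.3, n_subj=30)
        rep = rt_regression(d, n_perm=199, seed=0)
        assert rep.coefficients["b_lr"] < -0.3
        assert abs(rep.coefficients["d_prime_av"]) < 0.2
        assert rep.p_difference < 0.05

    def test_null_p_not_extreme(self):
        rng = np.random.default_rng(13)
        d = self.make_data(rng, bias_effect=0.0, noise=1.0)
        rep = rt_regression(d, n_perm=99, seed=1)
        assert rep.p_difference > 0.05


class TestFitComparison:
    def test_linear_data_prefers_linear(self):
        rng = np.random.default_rng(14)
        x = np.linspace(-2, 2, 40)
        y = 1.5 * x + 0.3
        res = compare_fits_linear_quadratic(x, y + 0.01 * rng.standard_normal(40))
        assert res["linear"]["normalized_sse"] < res["quadratic"]["normalized_sse"]

    def test_quadratic_data_prefers_quadratic(self):
        x = np.linspace(-2, 2, 40)
        y = x**2 - 0.5 * x
        res = compare_fits_linear_quadratic(x, y)
        assert res["quadratic"]["normalized_sse"] < res["linear"]["normalized_sse"]
        assert res["quadratic"]["adjusted_r2"] > res["linear"]["adjusted_r2"]

    def test_incremental_r2_nonpositive_for_irrelevant_factor(self):
        rng = np.random.default_rng(15)
        n = 200
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)  # irrelevant
        y = 0.8 * a + 0.5 * rng.standard_normal(n)
        inc = incremental_r2(y, {"a": a, "b": b})
        assert inc["a"] > 0.2
        assert inc["b"] <= 0.01


class TestJackknife:
    def test_estimator_route_matches_bootstrap_scale(self):
        """Smooth nonlinear estimator: jackknife within 20% of bootstrap SE."""
        rng = np.random.default_rng(16)
        x = rng.exponential(size=100)
        est = lambda d: float(np.log(np.mean(d)))
        jk = jackknife_se(estimator=est, data=x)
        boots = [est(rng.choice(x, size=len(x))) for _ in range(2000)]
        assert jk == pytest.approx(np.std(boots), rel=0.2)

    def test_needs_two_values(self):
        with pytest.raises(InvalidDataError):
            jackknife_se(values=[1.0])


class TestMotorBias:
    def make_blocks(self, rng, coupling=0.0, n_subj=12, n_blocks=6):
        rows = []
        for s in range(n_subj):
            for b in range(n_blocks):
                for loc in ("cued", "opposite"):
                    fa = rng.uniform(0.05, 0.3)
                    rt = 1.0 + coupling * fa + 0.05 * rng.standard_normal()
                    rows.append(
                        {"subject_id": s, "block": b, "location": loc,
                         "mean_rt_fa": rt, "fa_rate": fa}
                    )
        return pd.DataFrame(rows)

    def test_null_coupling_not_detected(self):
        rng = np.random.default_rng(17)
        res = motor_bias_check(self.make_blocks(rng, coupling=0.0))
        assert all(abs(v["rho"]) < 0.35 for v in res["per_location"].values())

    def test_injected_coupling_detected(self):
        rng = np.random.default_rng(18)
        res = motor_bias_check(self.make_blocks(rng, coupling=1.5))
        assert res["per_location"]["cued"]["p"] < 0.05
        assert res["anova_fa_p"] < 0.05

    def test_single_block_rejected(self):
        rng = np.random.default_rng(19)
        blocks = self.make_blocks(rng, n_blocks=1)
        with pytest.raises(InvalidDataError):
            motor_bias_check(blocks)
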