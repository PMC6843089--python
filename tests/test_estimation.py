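"""MLE fitting, goodness of fit, subset prediction, model comparison."""

import numpy as np
import pytest

from madc._exceptions import InvalidDataError
from madc.design import TaskDesign
from madc.core import (
    ContingencyTable,
    ModelParams,
    build_contingency_table,
    response_probabilities,
    simulate_observer_trials,
)
from madc.estimation import (
    FitResult,
    compare_models,
    count_free_parameters,
    count_independent_observations,
    fit_madc,
    gof_randomization,
    predict_from_subset,
)


class TestParameterCounts:
    def test_model_variant_parameter_counts(self):
        d4 = TaskDesign.predictive()
        d3 = TaskDesign.collapsed()
        assert count_free_parameters(d4) == 28
        assert count_free_parameters(d3) == 21
        assert count_free_parameters(d3, "eq_d_uncued") == 15
        assert count_free_parameters(d3, "eq_c_uncued") == 20
        assert count_free_parameters(d3, parametric="naka_rushton") == 9

    def test_independent_observation_decomposition(self):
        obs = count_independent_observations(TaskDesign.predictive())
        assert obs == {
            "hits": 24, "mislocalizations": 72, "false_alarms": 4, "total": 100
        }

    def test_overall_cue_validity(self):
        assert TaskDesign.predictive().overall_cue_validity == pytest.approx(0.5)


class TestFit:
    def test_recovery_at_high_counts(self, collapsed_design, generating_params, large_table):
        """d′ and c recovered within ±0.05 at 2e4 trials per condition."""
        fit = fit_madc(large_table, collapsed_design, seed=1, n_restarts=1)
        assert np.max(np.abs(fit.params.d_prime - generating_params.d_prime)) < 0.05
        assert np.max(np.abs(fit.params.criteria - generating_params.criteria)) < 0.05
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.log_likelihood)
        # likelihood dominance: MLE beats the generating parameters
        p_gen = response_probabilities(generating_params, collapsed_design).p
        ll_gen = float((large_table.counts * np.log(p_gen)).sum())
        assert fit.log_likelihood >= ll_gen - 1e-6

    def test_null_sensitivity_limit(self):
        d = TaskDesign(("cued", "opposite"), (10.0, 30.0), (0.7, 0.3), 0.25)
        gen = ModelParams(np.zeros((2, 2)), [1.0, 1.0])
        trials = simulate_observer_trials(gen, d, 20_000, seed=4)
        fit = fit_madc(build_contingency_table(trials, d), d, seed=0, n_restarts=1)
        assert np.max(fit.params.d_prime) < 0.15

    def test_parametric_fit_recovers_naka_rushton(self, collapsed_design):
        gen = ModelParams.from_naka_rushton(
            [(2.5, 15.0), (1.5, 20.0), (1.2, 25.0)],
            collapsed_design.magnitudes, [1.0, 1.2, 1.3],
        )
        trials = simulate_observer_trials(gen, collapsed_design, 150_000, seed=6)
        tab = build_contingency_table(trials, collapsed_design)
        fit = fit_madc(tab, collapsed_design, parametric="naka_rushton",
                       seed=0, n_restarts=1)
        nr = np.array(fit.params.naka_rushton)
        assert np.max(np.abs(nr[:, 0] - [2.5, 1.5, 1.2])) < 0.1
        assert np.max(np.abs(nr[:, 1] / [15.0, 20.0, 25.0] - 1)) < 0.10
        assert fit.n_params == 9

    def test_all_zero_table_rejected(self, collapsed_design):
        n_cond = len(collapsed_design.conditions)
        tab = ContingencyTable(
            collapsed_design, np.zeros((n_cond, 4))
        )
        with pytest.raises(InvalidDataError):
            fit_madc(tab, collapsed_design)


class TestGof:
    def test_perfect_fit_gives_p_one(self, single_mag_design):
        p = ModelParams([[1.5], [1.0], [0.8]], [0.6, 0.9, 1.1])
        probs = response_probabilities(p, single_mag_design)
        counts = np.round(probs.p * 1000)
        tab = ContingencyTable(single_mag_design, counts)
        # use exact expected = observed by matching fitted probabilities
        tab = ContingencyTable(
            single_mag_design, probs.p * 1000
        )
        g = gof_randomization(tab, probs, n_rand=99, seed=0)
        assert g.chi2_observed == pytest.approx(0.0, abs=1e-9)
        assert g.p_value == 1.0

    def test_gross_misfit_detected(self, single_mag_design):
        sharp = ModelParams([[3.5], [3.0], [2.5]], [0.4, 0.5, 0.6])
        trials = simulate_observer_trials(sharp, single_mag_design, 5000, seed=8)
        tab = build_contingency_table(trials, single_mag_design)
        uniform = response_probabilities(
            ModelParams([[0.01], [0.01], [0.01]], [0.0, 0.0, 0.0]),
            single_mag_design,
        )
        g = gof_randomization(tab, uniform, n_rand=199, seed=1)
        assert g.p_value == pytest.approx(1 / 200)

    def test_null_calibration_and_uniformity(self, single_mag_design):
        """Under the null the GOF p-values are uniform (KS < 0.1, level held)."""
        p = ModelParams([[1.5], [1.0], [0.8]], [0.6, 0.9, 1.1])
        probs = response_probabilities(p, single_mag_design)
        totals = np.full(len(single_mag_design.conditions), 120)
        rng = np.random.default_rng(77)
        n_rep = 500
        ps = []
        for r in range(n_rep):
            counts = np.vstack(
                [rng.multinomial(totals[i], probs.p[i]) for i in range(len(totals))]
            )
            tab = ContingencyTable(single_mag_design, counts)
            ps.append(gof_randomization(tab, probs, n_rand=99, seed=r).p_value)
        ps = np.sort(ps)
        rate = (ps <= 0.05).mean()
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= ci + 0.01
        ks = np.max(np.abs(ps - np.arange(1, n_rep + 1) / n_rep))
        assert ks < 0.1


@pytest.fixture(scope="module")
def observer_table(collapsed_design, generating_params):
    trials = simulate_observer_trials(
        generating_params, collapsed_design, 288 * 8, seed=12
    )
    return build_contingency_table(trials, collapsed_design)


class TestSubsetPrediction:
    def test_hits_fa_predicts_held_out(self, observer_table, collapsed_design):
        res = predict_from_subset(
            observer_table, collapsed_design, "hits_fa", seed=0,
            n_rand=199, n_restarts=1,
        )
        assert res.gof.p_value > 0.05
        # held-out cells exclude everything the subset saw
        assert not res.held_out_mask[-1].any()
        L, M = 3, 6
        for loc in range(L):
            assert not res.held_out_mask[loc * M:(loc + 1) * M, loc].any()

    def test_hits_misses_predicts_false_alarms(
        self, observer_table, collapsed_design, generating_params
    ):
        res = predict_from_subset(
            observer_table, collapsed_design, "hits_misses", seed=0,
            n_rand=99, n_restarts=1,
        )
        gen_fa = response_probabilities(generating_params, collapsed_design).catch_row
        n_catch = observer_table.row_totals[-1]
        se = np.sqrt(gen_fa * (1 - gen_fa) / n_catch)
        assert np.all(np.abs(res.predicted.catch_row[:3] - gen_fa[:3]) <= 3 * se[:3] + 0.02)

    def test_full_subset_equals_ordinary_fit(self, observer_table, collapsed_design):
        """The degenerate "full" subset reproduces the unconstrained fit."""
        res = predict_from_subset(
            observer_table, collapsed_design, "full", seed=0,
            n_rand=19, n_restarts=0,
        )
        full = fit_madc(observer_table, collapsed_design, seed=0, n_restarts=0)
        assert np.allclose(
            res.predicted.p, full.fitted_probabilities.p, atol=1e-3
        )

    def test_hits_fa_cohort_mostly_consistent(self, collapsed_design, generating_params):
        """Held-out GOF is unsuspicious for >=90% of study-scale subjects."""
        ok = 0
        n_subj = 30
        for s in range(n_subj):
            trials = simulate_observer_trials(
                generating_params, collapsed_design, 288, seed=800 + s
            )
            res = predict_from_subset(
                build_contingency_table(trials, collapsed_design),
                collapsed_design, "hits_fa", seed=s, n_rand=99, n_restarts=0,
            )
            ok += res.gof.p_value > 0.05
        assert ok >= 0.9 * n_subj

    def test_zero_count_subset_rejected(self, collapsed_design):
        n_cond = len(collapsed_design.conditions)
        counts = np.zeros((n_cond, 4))
        counts[:-1, 3] = 10  # only misses
        tab = ContingencyTable(collapsed_design, counts)
        with pytest.raises(InvalidDataError):
            predict_from_subset(tab, collapsed_design, "hits_fa")


class TestCompareModels:
    def _fake_fit(self, design, ll, k, constraint, checksum=1.0):
        return FitResult(
            params=ModelParams(np.ones((3, 6)), np.zeros(3)),
            log_likelihood=ll, n_params=k, aic=2 * k - 2 * ll,
            bic=k * np.log(288) - 2 * ll, constraint=constraint,
            parametric=None, design=design, n_trials=288,
            table_checksum=checksum,
        )

    def test_aic_arithmetic(self, collapsed_design):
        a = self._fake_fit(collapsed_design, -250.0, 21, "none")
        b = self._fake_fit(collapsed_design, -250.0, 15, "eq_d_uncued")
        ranked = compare_models([a, b])
        assert ranked.iloc[0]["constraint"] == "eq_d_uncued"
        assert ranked.iloc[1]["delta_aic"] == pytest.approx(12.0)

    def test_single_model_identity(self, collapsed_design):
        a = self._fake_fit(collapsed_design, -250.0, 21, "none")
        ranked = compare_models([a])
        assert len(ranked) == 1
        assert ranked.iloc[0]["delta_aic"] == 0.0

    def test_mismatched_tables_rejected(self, collapsed_design):
        a = self._fake_fit(collapsed_design, -250.0, 21, "none", checksum=1.0)
        b = self._fake_fit(collapsed_design, -250.0, 15, "eq_d_uncued", checksum=2.0)
        with pytest.raises(InvalidDataError):
            compare_models([a, b])

    def test_eq_d_recovered_when_true(self, collapsed_design):
        """Generating equal uncued d′: AIC should prefer eq_d for most subjects."""
        gen = ModelParams.from_naka_rushton(
            [(2.5, 12.0), (1.3, 22.0), (1.3, 22.0)],
            collapsed_design.magnitudes, [1.0, 1.2, 1.3],
        )
        wins = 0
        n_subj = 12
        for s in range(n_subj):
            trials = simulate_observer_trials(gen, collapsed_design, 288, seed=100 + s)
            tab = build_contingency_table(trials, collapsed_design)
            f_full = fit_madc(tab, collapsed_design, seed=s, n_restarts=1)
            f_eqd = fit_madc(tab, collapsed_design, "eq_d_uncued", seed=s, n_restarts=1)
            ranked = compare_models([f_full, f_eqd])
            wins += ranked.iloc[0]["constraint"] == "eq_d_uncued"
        assert wins > n_subj / 2
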