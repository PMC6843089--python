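"""Decision-model math: choice probabilities, simulation, risk, optima."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from madc._exceptions import DimensionError, InvalidDataError
from madc.design import CostMatrix, TaskDesign
from madc.core import (
    ContingencyTable,
    ModelParams,
    build_contingency_table,
    collapse_table_adjacent,
    expected_risk,
    optimal_criteria,
    response_probabilities,
    simulate_observer_trials,
)
from conftest import mc_choice_probabilities


def design_of(n_loc, mags=(10.0,), catch=0.25):
    return TaskDesign(
        tuple(f"l{i}" for i in range(n_loc)),
        tuple(mags),
        tuple([1.0 / n_loc] * n_loc),
        catch,
    )


class TestResponseProbabilities:
    def test_one_location_reduces_to_yes_no_sdt(self):
        """m=1 must reproduce the Φ(d′−c)/Φ(−c) closed form to 1e-10."""
        d = design_of(1)
        t = response_probabilities(ModelParams([[2.0]], [1.0]), d)
        assert t.row(0, 0)[0] == pytest.approx(norm.cdf(2.0 - 1.0), abs=1e-10)
        assert t.catch_row[0] == pytest.approx(norm.cdf(-1.0), abs=1e-10)

    def test_two_location_symmetric_catch_row(self):
        d = design_of(2)
        t = response_probabilities(ModelParams([[0.0], [0.0]], [0.0, 0.0]), d)
        assert t.catch_row[2] == pytest.approx(0.25, abs=1e-10)
        assert t.catch_row[0] == pytest.approx(0.375, abs=1e-10)
        assert t.catch_row[1] == pytest.approx(0.375, abs=1e-10)

    def test_matches_adaptive_quadrature(self):
        """Fixed-order quadrature agrees with scipy adaptive to 1e-10."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            L = int(rng.integers(2, 5))
            dp = rng.uniform(0, 4, (L, 1))
            c = rng.uniform(-1.5, 2.5, L)
            d = design_of(L)
            p = response_probabilities(ModelParams(dp, c), d).p
            mu = np.zeros(L)
            mu[0] = dp[0, 0]
            for j in range(L):
                ref, _ = quad(
                    lambda u: norm.pdf(u + c[j] - mu[j])
                    * np.prod([norm.cdf(u + c[k] - mu[k])
                               for k in range(L) if k != j]),
                    0, np.inf, epsabs=1e-13,
                )
                assert p[0, j] == pytest.approx(ref, abs=1e-10)

    def test_matches_monte_carlo_oracle(self):
        """3-location row within 3 MC SE of the brute-force argmax rule."""
        d = design_of(3)
        dp, c = 1.5, np.array([0.5, 0.8, 0.8])
        p = response_probabilities(ModelParams([[dp], [0.0], [0.0]], c), d)
        n = 10**6
        mc = mc_choice_probabilities(dp, c, [dp, 0, 0], n, seed=5)
        se = np.sqrt(np.maximum(mc * (1 - mc), 1e-12) / n)
        assert np.all(np.abs(p.row(0, 0) - mc) <= 3 * se + 1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.integers(2, 4),
        st.integers(0, 10**6),
    )
    def test_rows_normalized_and_permutation_equivariant(self, L, seed):
        rng = np.random.default_rng(seed)
        dp = rng.uniform(0, 5, (L, 2))
        c = rng.uniform(-2, 3, L)
        d = design_of(L, mags=(5.0, 20.0))
        t = response_probabilities(ModelParams(dp, c), d)
        assert np.max(np.abs(t.p.sum(axis=1) - 1)) < 1e-8
        # permuting location indices permutes rows/columns identically
        perm = rng.permutation(L)
        t2 = response_probabilities(ModelParams(dp[perm], c[perm]), d)
        M = 2
        for loc in range(L):
            for m in range(M):
                row_orig = t.row(perm[loc], m)
                row_perm = t2.row(loc, m)
                assert row_perm[L] == pytest.approx(row_orig[L], abs=1e-9)
                assert np.allclose(row_perm[:L], row_orig[perm], atol=1e-9)

    def test_hit_rate_monotone_in_d_and_criterion(self):
        d = design_of(2)
        hits = [
            response_probabilities(ModelParams([[dp], [1.0]], [0.7, 0.7]), d).row(0, 0)[0]
            for dp in (0.5, 1.0, 2.0, 3.0)
        ]
        assert np.all(np.diff(hits) > 0)
        hits_c = [
            response_probabilities(ModelParams([[1.5], [1.0]], [c, 0.7]), d).row(0, 0)[0]
            for c in (0.0, 0.5, 1.0, 2.0)
        ]
        assert np.all(np.diff(hits_c) < 0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            response_probabilities(ModelParams([[1.0]], [0.5]), design_of(2))
        with pytest.raises(ValueError):
            ModelParams([[np.inf]], [0.5])


class TestSimulator:
    def test_zero_trials_gives_empty_table(self):
        d = design_of(2)
        t = simulate_observer_trials(ModelParams([[1.0], [1.0]], [0.5, 0.5]), d, 0, seed=0)
        assert len(t) == 0

    def test_negative_trials_rejected(self):
        d = design_of(2)
        with pytest.raises(ValueError):
            simulate_observer_trials(ModelParams([[1.0], [1.0]], [0.5, 0.5]), d, -1, seed=0)

    def test_deterministic_under_seed(self):
        d = design_of(3, mags=(5.0, 20.0))
        p = ModelParams(np.array([[0.5, 2.0], [0.3, 1.5], [0.2, 1.0]]), [0.6, 0.9, 1.1])
        a = simulate_observer_trials(p, d, 500, seed=42)
        b = simulate_observer_trials(p, d, 500, seed=42)
        assert a.equals(b)

    def test_empirical_proportions_match_analytic(self):
        """Law of large numbers: every cell within 3 binomial SE at 1e5 trials."""
        d = design_of(3, mags=(5.0, 20.0))
        p = ModelParams(np.array([[0.5, 2.0], [0.3, 1.5], [0.2, 1.0]]), [0.6, 0.9, 1.1])
        trials = simulate_observer_trials(p, d, 100_000, seed=9)
        tab = build_contingency_table(trials, d)
        probs = response_probabilities(p, d).p
        tot = tab.row_totals[:, None]
        emp = tab.counts / tot
        se = np.sqrt(np.maximum(probs * (1 - probs), 1e-12) / tot)
        assert np.all(np.abs(emp - probs) <= 3 * se + 1e-9)


class TestContingency:
    def test_single_hit(self):
        d = design_of(2)
        p = ModelParams([[3.0], [3.0]], [0.5, 0.5])
        t = simulate_observer_trials(p, d, 1, seed=0).copy()
        t.loc[:, ["event_location", "response_location"]] = "l0"
        t.loc[:, "magnitude_deg"] = 10.0
        tab = build_contingency_table(t, d)
        assert tab.counts[0, 0] == 1
        assert tab.counts.sum() == 1

    def test_collapse_adds_adjacent_counts(self):
        d = TaskDesign.predictive(magnitudes=(10.0,))
        counts = np.zeros((5, 5))
        counts[2, 2] = 3  # adjacent_ipsi hits
        counts[3, 3] = 5  # adjacent_contra hits
        tab = ContingencyTable(d, counts)
        merged = collapse_table_adjacent(tab)
        assert merged.design.location_labels == ("cued", "opposite", "adjacent")
        assert merged.counts[2, 2] == 8

    def test_row_sums_conserved_on_random_cohort(self):
        d = TaskDesign.predictive(magnitudes=(5.0, 20.0))
        p = ModelParams(np.tile([[0.5, 1.5]], (4, 1)), [0.8] * 4)
        trials = simulate_observer_trials(p, d, 2000, seed=3)
        tab = build_contingency_table(trials, d)
        assert tab.counts.sum() == 2000
        merged = build_contingency_table(trials, d, collapse_adjacent=True)
        assert merged.counts.sum() == 2000
        assert merged.row_totals[-1] == tab.row_totals[-1]

    def test_unknown_response_label_rejected_with_row(self):
        d = design_of(2)
        p = ModelParams([[1.0], [1.0]], [0.5, 0.5])
        t = simulate_observer_trials(p, d, 5, seed=0)
        t.loc[t.index[2], "response_location"] = "elsewhere"
        with pytest.raises(InvalidDataError, match="row 2"):
            build_contingency_table(t, d)


class TestRisk:
    def test_zero_costs_zero_risk(self, single_mag_design):
        p = ModelParams([[1.0], [1.0], [1.0]], [0.5, 0.5, 0.5])
        costs = CostMatrix(np.zeros((4, 4)), single_mag_design)
        assert expected_risk(p, single_mag_design, costs) == 0.0

    def test_matches_explicit_enumeration(self):
        """Risk equals the hand-computed prior × probability × cost sum."""
        d = design_of(2, catch=0.3)
        p = ModelParams([[1.2], [0.8]], [0.4, 0.9])
        rng = np.random.default_rng(2)
        cost = rng.uniform(0, 2, (3, 3))
        costs = CostMatrix(cost, d)
        probs = response_probabilities(p, d).p
        priors = np.array([0.35, 0.35, 0.3])
        event = [0, 1, 2]
        manual = sum(
            priors[i] * probs[i, j] * cost[event[i], j]
            for i in range(3)
            for j in range(3)
        )
        assert expected_risk(p, d, costs) == pytest.approx(manual, abs=1e-12)

    def test_high_sensitivity_risk_vanishes(self):
        d = design_of(2)
        p = ModelParams([[10.0], [10.0]], [0.0, 0.0])
        costs = CostMatrix.from_beta(d, beta=1.0)
        c_opt = optimal_criteria(p, d, costs)
        assert expected_risk(p, d, costs, criteria_override=c_opt) < 1e-3


class TestOptimalCriteria:
    def test_unbiased_yes_no_optimum(self):
        d = design_of(1, catch=0.5)
        costs = CostMatrix.from_beta(d, beta=1.0)
        c = optimal_criteria(ModelParams([[2.0]], [0.0]), d, costs)
        assert c[0] == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("beta,p_n,dp", [(1.7, 0.4, 1.4), (0.6, 0.25, 2.2)])
    def test_one_location_closed_form_and_grid_search(self, beta, p_n, dp):
        """c_opt = d′/2 + ln(β·p_n/p_s)/d′, cross-checked by grid search."""
        d = design_of(1, catch=p_n)
        costs = CostMatrix.from_beta(d, beta=beta)
        params = ModelParams([[dp]], [0.0])
        c = optimal_criteria(params, d, costs)[0]
        ref = dp / 2 + np.log(beta * p_n / (1 - p_n)) / dp
        assert c == pytest.approx(ref, abs=1e-4)
        grid = np.linspace(ref - 1, ref + 1, 2001)
        risks = [expected_risk(params, d, costs, criteria_override=[g]) for g in grid]
        assert grid[int(np.argmin(risks))] == pytest.approx(ref, abs=2e-3)

    def test_higher_prior_lowers_criterion(self):
        """Equal d′, unequal priors: the likelier location gets the lower c."""
        d = TaskDesign.two_location(prior_ratio=3.0)
        costs = CostMatrix.from_beta(d, beta=1.0)
        c = optimal_criteria(ModelParams([[1.0], [1.0]], [0.0, 0.0]), d, costs)
        assert c[0] < c[1]
        # grid-search oracle on the 2-D risk surface confirms the ordering
        grid = np.linspace(-1, 2.5, 36)
        surf = np.array(
            [[expected_risk(ModelParams([[1.0], [1.0]], [0.0, 0.0]), d, costs,
                            criteria_override=[a, b]) for b in grid] for a in grid]
        )
        i, j = np.unravel_index(np.argmin(surf), surf.shape)
        assert grid[i] < grid[j]

    def test_returned_point_is_local_minimum(self, single_mag_design):
        p = ModelParams([[1.8], [1.2], [1.0]], [0.0, 0.0, 0.0])
        costs = CostMatrix.from_beta(single_mag_design, beta=1.3)
        c = optimal_criteria(p, single_mag_design, costs)
        r0 = expected_risk(p, single_mag_design, costs, criteria_override=c)
        for k in range(3):
            for s in (0.05, -0.05):
                trial = c.copy()
                trial[k] += s
                assert expected_risk(
                    p, single_mag_design, costs, criteria_override=trial
                ) >= r0 - 1e-9

    def test_zero_sensitivity_rejected(self, single_mag_design):
        costs = CostMatrix.from_beta(single_mag_design, beta=1.0)
        with pytest.raises(ValueError):
            optimal_criteria(
                ModelParams([[0.0], [1.0], [1.0]], [0.0, 0.0, 0.0]),
                single_mag_design, costs,
            )
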