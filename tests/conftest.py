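import numpy as np
import pytest

from madc.design import TaskDesign
from madc.core import ModelParams, build_contingency_table, simulate_observer_trials


@pytest.fixture(scope="session")
def collapsed_design():
    return TaskDesign.collapsed()


@pytest.fixture(scope="session")
def single_mag_design():
    """3-location, one-magnitude design used for fast risk computations."""
    return TaskDesign(
        ("cued", "opposite", "adjacent"), (10.0,), (2 / 3, 1 / 6, 1 / 6), 0.25
    )


@pytest.fixture(scope="session")
def generating_params(collapsed_design):
    """A plausible observer: spotlight d′, graded criteria."""
    return ModelParams.from_naka_rushton(
        [(2.5, 12.0), (1.4, 20.0), (1.2, 24.0)],
        collapsed_design.magnitudes,
        criteria=[1.0, 1.15, 1.35],
    )


@pytest.fixture(scope="session")
def large_table(collapsed_design, generating_params):
    """High-count table for recovery tests (2e4 trials per condition)."""
    n = 20_000 * (len(collapsed_design.conditions))
    trials = simulate_observer_trials(
        generating_params, collapsed_design, n, seed=20240501
    )
    return build_contingency_table(trials, collapsed_design)


def mc_choice_probabilities(d_prime, criteria, mu, n_draws, seed):
    """Independent brute-force oracle: raw argmax decision rule on draws.

    Deliberately re-implements the decision rule with plain numpy (no calls
    into the package) so quadrature and simulator can both be checked
    against it.
    """
    rng = np.random.default_rng(seed)
    L = len(criteria)
    psi = rng.standard_normal((n_draws, L)) + np.asarray(mu)[None, :]
    slack = psi - np.asarray(criteria)[None, :]
    best = np.argmax(slack, axis=1)
    resp = np.where(slack[np.arange(n_draws), best] > 0, best, L)
    return np.bincount(resp, minlength=L + 1) / n_draws
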