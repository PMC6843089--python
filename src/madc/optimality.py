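"""Bayesian-risk optimality of observed criteria.

An observer minimizing Bayes risk with cost ratio β (β = (C_CR − C_FA)/
(C_Hit − C_Miss)) at a location should hold a criterion at which the
likelihood-ratio bias matches the prior odds divided by β. Inverting that
relationship gives the observed cost ratio

    β_obs(j) = [p_j / p_∅] / b_LR(j)

(the prior odds of a change at location j against no change, divided by the
fitted likelihood-ratio bias there): the cost ratio an optimal observer with
those criteria must have assumed. β_obs = 1 corresponds to maximizing percent
correct.

The subjective optimal cost ratio β^s_opt is the single β, common to all
locations, whose optimal policy comes closest (in risk) to the observer's
actual policy; three suboptimality indices summarize the deviations:
SI_O = |ln(β^s_opt/β_opt)|, SI_G = ΔRisk(obs − opt), and per-location
SI_L = |ln(β_obs/β^s_opt)|. Logs are natural.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._exceptions import InvalidDataError
from .core import ModelParams, expected_risk, optimal_criteria
from .design import CostMatrix, TaskDesign
from .estimation import FitResult

DEFAULT_BETA_GRID = tuple(np.geomspace(0.25, 4.0, 50))
DEFAULT_COST_RATIO_GRID = tuple(np.linspace(0.5, 2.0, 20))


@dataclass(frozen=True)
class OptimalityReport:
    """Decision-optimality summary for one observer."""

    beta_obs: np.ndarray
    beta_s_opt: float
    beta_opt: float
    si_o: float
    si_g: float
    si_l: np.ndarray
    risk_observed: float
    risk_optimal: float
    delta_risk: float


def observed_cost_ratio(design: TaskDesign, b_lr) -> np.ndarray:
    """β_obs per location: prior odds (change vs no change) over b_LR."""
    b_lr = np.asarray(b_lr, float)
    if np.any(b_lr <= 0):
        raise ValueError("b_LR must be positive")
    priors = design.event_priors
    if design.catch_fraction <= 0 or np.any(priors <= 0):
        raise InvalidDataError("observed_cost_ratio needs positive priors")
    odds = priors / design.catch_fraction
    if len(b_lr) != design.n_locations:
        raise InvalidDataError("one b_LR per location required")
    return odds / b_lr


def observed_cost_ratio_exact(
    params: ModelParams, design: TaskDesign, step: float = 1e-5
) -> np.ndarray:
    """β_obs per location from the exact risk-stationarity condition.

    The criteria of a β-optimal observer satisfy, for every location j,
    ∂/∂c_j [Σ_i p_i P(hit_i)] + β·p_∅·∂P(CR)/∂c_j = 0; inverting this at the
    observed criteria gives the cost ratio each criterion is consistent with.
    For one location this reduces to the prior-odds/b_LR form of
    :func:`observed_cost_ratio`; with several locations it additionally
    accounts for the coupling between criteria (the overlap of decision
    zones), making the round trip criteria = optimal(β) → β_obs = β exact.
    Derivatives are central finite differences with the given step.
    """
    from .core import response_probabilities

    marg = params.marginal()
    design_m = design.with_magnitudes((design.magnitudes[0],))
    priors = design.event_priors
    p_catch = design.catch_fraction
    L = design.n_locations
    if p_catch <= 0 or np.any(priors <= 0):
        raise InvalidDataError("observed_cost_ratio needs positive priors")

    def correct_terms(criteria):
        p = response_probabilities(marg.with_criteria(criteria), design_m).p
        hits = np.array([p[i, i] for i in range(L)])
        return float(priors @ hits), float(p[-1, L])

    out = np.empty(L)
    c0 = marg.criteria
    for j in range(L):
        e = np.zeros(L)
        e[j] = step
        hit_hi, cr_hi = correct_terms(c0 + e)
        hit_lo, cr_lo = correct_terms(c0 - e)
        d_hit = (hit_hi - hit_lo) / (2 * step)
        d_cr = (cr_hi - cr_lo) / (2 * step)
        if d_cr <= 0:
            raise InvalidDataError(
                f"degenerate criterion at location {j}: P(CR) not increasing"
            )
        out[j] = -d_hit / (p_catch * d_cr)
    return out


def _delta_risk(params_obs: ModelParams, design: TaskDesign,
                beta: float, cost_ratio: float) -> tuple[float, float, float]:
    """(risk_obs, risk_opt, Δ) for costs built from (β, |C_FA|/|C_CR|).

    Correct responses are rewarded (negative cost, magnitude |C_CR| = 1,
    |C_Hit| = 1/β) and errors penalized (C_FA = cost_ratio, C_Miss =
    cost_ratio/β): with both signs the same the effective weight
    C_FA − C_CR would vanish at cost_ratio = 1 and flip sign below it,
    making the surface degenerate. The criterion-relevant ratio
    (C_CR − C_FA)/(C_Hit − C_Miss) equals β either way.
    """
    costs = CostMatrix.from_beta(
        design, beta=beta, cost_fa=cost_ratio, cost_cr=-1.0
    )
    marg = params_obs.marginal()
    design_m = design.with_magnitudes((design.magnitudes[0],))
    c_opt = optimal_criteria(marg, design_m, costs)
    r_obs = expected_risk(marg, design_m, costs)
    r_opt = expected_risk(marg, design_m, costs, criteria_override=c_opt)
    return r_obs, r_opt, r_obs - r_opt


def estimate_subjective_beta(
    fit: FitResult | ModelParams,
    design: TaskDesign,
    beta_grid=DEFAULT_BETA_GRID,
    cost_ratio_grid=DEFAULT_COST_RATIO_GRID,
    refine: bool = True,
) -> dict:
    """β^s_opt and the ΔRisk(β, C_FA/C_CR) surface for one observer.

    For each candidate β and false-alarm/correct-rejection cost ratio, builds
    the cost matrix (C_Hit = C_CR/β, C_Miss = C_FA/β, mislocalizations costed
    as misses), computes ΔRisk = Risk(observed criteria) − Risk(optimal
    criteria at that β), and finds the minimizing β. ΔRisk ≥ 0 and vanishes
    exactly when the observer's criteria are optimal for that β, so the
    surface is minimized at the cost ratio the observer behaves as if holding.
    β^s_opt is the median of the per-cost-ratio minimizers (optionally refined
    by bounded continuous minimization around the grid minimum).
    """
    from .core import response_probabilities

    if len(beta_grid) == 0 or len(cost_ratio_grid) == 0:
        raise InvalidDataError("beta_grid and cost_ratio_grid must be non-empty")
    params = fit.params if isinstance(fit, FitResult) else fit
    betas = np.asarray(beta_grid, float)
    ratios = np.asarray(cost_ratio_grid, float)

    marg = params.marginal()
    design_m = design.with_magnitudes((design.magnitudes[0],))
    p_obs = response_probabilities(marg, design_m).p
    priors = design_m.condition_priors
    L = design_m.n_locations
    event = np.array(
        [c[0] if c[0] is not None else L for c in design_m.conditions]
    )

    # the β-optimal criteria do not depend on the C_FA/C_CR ratio (the risk
    # is affine in the weighted-correct term with a positive ratio-dependent
    # factor), so one criterion optimization per β serves the whole column
    surface = np.empty((len(ratios), len(betas)))
    x0 = None
    for j, b in enumerate(betas):
        costs_ref = CostMatrix.from_beta(design_m, beta=b, cost_fa=1.0,
                                         cost_cr=-1.0)
        c_opt = optimal_criteria(marg, design_m, costs_ref, x0=x0)
        x0 = c_opt
        p_opt = response_probabilities(marg.with_criteria(c_opt), design_m).p
        diff = priors[:, None] * (p_obs - p_opt)
        for i, r in enumerate(ratios):
            cost = CostMatrix.from_beta(design_m, beta=b, cost_fa=r,
                                        cost_cr=-1.0).cost
            surface[i, j] = float((diff * cost[event, :]).sum())

    minimizers = []
    refined: dict[int, float] = {}
    for i, r in enumerate(ratios):
        j = int(np.argmin(surface[i]))
        b_star = betas[j]
        if refine:
            if j not in refined:
                lo = betas[max(j - 1, 0)]
                hi = betas[min(j + 1, len(betas) - 1)]
                if hi > lo:
                    res = minimize_scalar(
                        lambda b: _delta_risk(params, design, float(b), r)[2],
                        bounds=(lo, hi), method="bounded",
                        options={"xatol": 1e-4},
                    )
                    refined[j] = float(res.x)
                else:
                    refined[j] = b_star
            b_star = refined[j]
        minimizers.append(b_star)
    beta_s_opt = float(np.median(minimizers))

    table = pd.DataFrame(surface, index=pd.Index(ratios, name="cost_ratio_fa_cr"),
                         columns=pd.Index(betas, name="beta"))
    return {
        "beta_s_opt": beta_s_opt,
        "per_ratio_minimizers": np.asarray(minimizers),
        "surface": table,
    }


def suboptimality_indices(
    beta_obs,
    beta_s_opt: float,
    risk_observed: float,
    risk_optimal: float,
    beta_opt: float = 1.0,
) -> OptimalityReport:
    """SI_O, SI_G and per-location SI_L from betas and risks (natural log)."""
    beta_obs = np.asarray(beta_obs, float)
    if np.any(beta_obs <= 0) or beta_s_opt <= 0 or beta_opt <= 0:
        raise ValueError("all cost ratios must be positive")
    delta = risk_observed - risk_optimal
    return OptimalityReport(
        beta_obs=beta_obs,
        beta_s_opt=float(beta_s_opt),
        beta_opt=float(beta_opt),
        si_o=float(abs(np.log(beta_s_opt / beta_opt))),
        si_g=float(delta),
        si_l=np.abs(np.log(beta_obs / beta_s_opt)),
        risk_observed=float(risk_observed),
        risk_optimal=float(risk_optimal),
        delta_risk=float(delta),
    )


def optimality_report(
    fit: FitResult,
    design: TaskDesign,
    beta_grid=DEFAULT_BETA_GRID,
    cost_ratio_grid=DEFAULT_COST_RATIO_GRID,
    cost_ratio_for_risk: float = 1.0,
    refine: bool = True,
    subjective: dict | None = None,
) -> OptimalityReport:
    """Full optimality analysis of one fitted observer.

    ``subjective`` may carry a precomputed :func:`estimate_subjective_beta`
    result to avoid recomputing the ΔRisk surface.
    """
    from .psychometrics import bias_metrics_from_fit

    b_lr = np.array([b.b_lr for b in bias_metrics_from_fit(fit)])
    beta_obs = observed_cost_ratio(design, b_lr)
    est = subjective if subjective is not None else estimate_subjective_beta(
        fit, design, beta_grid, cost_ratio_grid, refine=refine
    )
    r_obs, r_opt, _ = _delta_risk(
        fit.params, design, est["beta_s_opt"], cost_ratio_for_risk
    )
    return suboptimality_indices(beta_obs, est["beta_s_opt"], r_obs, r_opt)


# ---------------------------------------------------------------------------
# expectation-strategy falsification tests
# ---------------------------------------------------------------------------

def expectation_strategy_tests(
    false_alarm_counts,
    task_priors,
    perceived_priors,
    n_rand: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Test expectation-only accounts of the false-alarm distribution.

    False alarms on catch trials index choice bias in the absence of sensory
    evidence. Three nulls are tested with a multinomial χ² randomization test
    (add-one p-values): (1) maximization — all false alarms at the
    highest-prior location; (2) probability matching on the task priors;
    (3) probability matching on the perceived priors (each subject's share of
    change-trial responses per location). Small p rejects the strategy.
    Hypothesis 1 places probability 0 on non-maximal locations, so any false
    alarm elsewhere is an exact rejection (p = 0).
    """
    k = np.asarray(false_alarm_counts, float)
    if np.any(k < 0) or k.sum() <= 0:
        raise InvalidDataError("false-alarm counts must be >=0 with positive total")
    task_p = np.asarray(task_priors, float)
    perc_p = np.asarray(perceived_priors, float)
    if not (len(k) == len(task_p) == len(perc_p)):
        raise InvalidDataError("counts and priors must have equal lengths")
    task_p = task_p / task_p.sum()
    perc_p = perc_p / perc_p.sum()
    rng = np.random.default_rng(seed)
    n = int(k.sum())

    def rand_test(p):
        exp = n * p
        chi2_obs = float((((k - exp) ** 2) / exp).sum())
        n_ge = 0
        for _ in range(n_rand):
            sim = rng.multinomial(n, p)
            if float((((sim - exp) ** 2) / exp).sum()) >= chi2_obs:
                n_ge += 1
        return (1 + n_ge) / (1 + n_rand)

    # maximization: degenerate point-mass null
    jmax = int(np.argmax(task_p))
    off_mass = k.sum() - k[jmax]
    p_max = 1.0 if off_mass == 0 else 0.0

    return {
        "maximization": p_max,
        "matching_task_priors": rand_test(task_p),
        "matching_perceived_priors": rand_test(perc_p),
        "n_randomizations": n_rand,
        "seed": seed,
    }
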