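"""Risk curvature: an expectation-free measure of spatial choice bias.

The Bayes risk, as a function of one location's criterion (others held at
their optimum), is locally convex around the optimal criterion. Its second
derivative there — the risk curvature R_C — measures how sharply an observer
is penalized for misplacing that criterion; locations that matter more for
decisions carry higher curvature. The cued-minus-uncued difference ΔR_C
therefore indexes attentional bias without reference to the observer's
expectations, and σ(b_CC) — the jackknife variability of the choice-criterion
bias across blocks — provides a companion data-driven index (sharper risk
should force more precise criterion placement).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._exceptions import DimensionError, InvalidDataError
from .core import ModelParams, expected_risk, optimal_criteria
from .design import CostMatrix, TaskDesign
from .estimation import FitResult


@dataclass(frozen=True)
class RiskCurve:
    """Risk along one location's criterion axis around the optimum."""

    location: int
    criterion_grid: np.ndarray
    risk: np.ndarray
    r_c: float
    optimal_criterion: float

    def __post_init__(self):
        g = np.asarray(self.criterion_grid, float)
        r = np.asarray(self.risk, float)
        if g.shape != r.shape:
            raise DimensionError("grid and risk must have the same shape")
        object.__setattr__(self, "criterion_grid", g)
        object.__setattr__(self, "risk", r)


@dataclass(frozen=True)
class CurvatureReport:
    """Per-location curvature and cued-vs-uncued contrast for one observer."""

    r_c: np.ndarray
    delta_r_c: float
    sigma_b_cc: np.ndarray | None = None
    location_labels: tuple[str, ...] = ()


def risk_sweep(
    params: ModelParams,
    design: TaskDesign,
    costs: CostMatrix,
    location: int,
    span: float = 1.0,
    n_grid: int = 21,
    criteria: np.ndarray | None = None,
    risk_fn: Callable[[np.ndarray], float] | None = None,
) -> RiskCurve:
    """Sweep one location's criterion ±span about its optimum.

    All other criteria stay at the optimum; the curvature R_C is the central
    second difference at the grid center (exact for quadratic risk at any
    step). ``criteria`` overrides the optimum (e.g. a subject's fitted
    criteria); ``risk_fn`` substitutes the risk evaluation (used for testing
    with analytically known risk shapes).
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if n_grid < 5 or n_grid % 2 == 0:
        raise ValueError("n_grid must be odd and >= 5")
    marg = params.marginal()
    design_m = design.with_magnitudes((design.magnitudes[0],))
    if risk_fn is None:
        base = optimal_criteria(marg, design_m, costs) if criteria is None \
            else np.asarray(criteria, float)
        risk_fn_ = lambda c: expected_risk(marg, design_m, costs, criteria_override=c)
    else:
        base = np.asarray(
            criteria if criteria is not None else marg.criteria, float
        )
        risk_fn_ = risk_fn

    grid = base[location] + np.linspace(-span, span, n_grid)
    risks = np.empty(n_grid)
    for i, c_j in enumerate(grid):
        c = base.copy()
        c[location] = c_j
        risks[i] = risk_fn_(c)
    if not np.all(np.isfinite(risks)):
        raise InvalidDataError("non-finite risk encountered during sweep")
    h = grid[1] - grid[0]
    mid = n_grid // 2
    r_c = (risks[mid + 1] - 2 * risks[mid] + risks[mid - 1]) / h**2
    return RiskCurve(
        location=location, criterion_grid=grid, risk=risks,
        r_c=float(r_c), optimal_criterion=float(base[location]),
    )


def delta_risk_curvature(
    curves: Sequence[RiskCurve],
    design: TaskDesign,
    cued_index: int = 0,
) -> CurvatureReport:
    """ΔR_C = R_C(cued) − R_C(uncued summary).

    With more than one uncued location the uncued curvature is summarized by
    the prior-weighted mean across uncued locations.
    """
    by_loc = {c.location: c for c in curves}
    if cued_index not in by_loc:
        raise InvalidDataError("cued risk curve is missing")
    uncued = [i for i in range(design.n_locations) if i != cued_index]
    missing = [i for i in uncued if i not in by_loc]
    if missing:
        raise InvalidDataError(f"missing uncued risk curves for locations {missing}")
    r_c = np.array([by_loc[i].r_c if i in by_loc else np.nan
                    for i in range(design.n_locations)])
    w = design.event_priors[uncued]
    uncued_rc = float(np.average(r_c[uncued], weights=w))
    return CurvatureReport(
        r_c=r_c,
        delta_r_c=float(r_c[cued_index] - uncued_rc),
        location_labels=design.location_labels,
    )


def subject_delta_r_c(
    fit: FitResult,
    design: TaskDesign,
    beta: float | None = None,
    span: float = 1.0,
    n_grid: int = 21,
) -> CurvatureReport:
    """ΔR_C for a fitted observer.

    Costs use the observer-specific subjective cost ratio β^s_opt by default
    (β = 1 is available as the configurable alternative by passing ``beta``).
    """
    if beta is None:
        from .optimality import estimate_subjective_beta

        beta = estimate_subjective_beta(fit, design)["beta_s_opt"]
    costs = CostMatrix.from_beta(design, beta=float(beta))
    curves = [
        risk_sweep(fit.params, design, costs, loc, span=span, n_grid=n_grid)
        for loc in range(design.n_locations)
    ]
    return delta_risk_curvature(curves, design)


# ---------------------------------------------------------------------------
# criterion variability
# ---------------------------------------------------------------------------

def criterion_variability(
    jackknife_fits: Sequence[FitResult], design: TaskDesign | None = None
) -> dict:
    """σ(b_CC) per location from leave-one-block-out fits.

    ``jackknife_fits`` holds one m-ADC fit per left-out block; the jackknife
    SD of b_CC is sqrt((n−1)/n · Σ (b_(i) − b̄)²) per location. The AMI of
    σ(b_CC) (cued vs mean uncued) is reported alongside.
    """
    from .psychometrics import bias_metrics_from_fit, modulation_indices

    if len(jackknife_fits) < 2:
        raise InvalidDataError("need at least 2 usable blocks")
    design = design or jackknife_fits[0].design
    b_cc = np.array(
        [[b.b_cc for b in bias_metrics_from_fit(f)] for f in jackknife_fits]
    )  # (n_blocks, n_locations)
    n = b_cc.shape[0]
    sigma = np.sqrt((n - 1) / n * ((b_cc - b_cc.mean(axis=0)) ** 2).sum(axis=0))
    ami = modulation_indices(sigma[0], sigma[1:], parameter="sigma_b_cc")
    return {
        "sigma_b_cc": sigma,
        "ami_sigma_b_cc": ami.ami,
        "adi_sigma_b_cc": ami.adi,
        "location_labels": design.location_labels,
        "n_blocks": n,
    }


def leave_one_block_out_fits(
    trials: pd.DataFrame, design: TaskDesign, **fit_kwargs
) -> list[FitResult]:
    """Refit the m-ADC model leaving out each block in turn."""
    from .core import build_contingency_table
    from .estimation import fit_madc

    blocks = sorted(trials["block"].unique())
    if len(blocks) < 2:
        raise InvalidDataError("need at least 2 blocks")
    fits = []
    for b in blocks:
        sub = trials[trials["block"] != b]
        fits.append(fit_madc(build_contingency_table(sub, design), design, **fit_kwargs))
    return fits


# ---------------------------------------------------------------------------
# simulated curvature profiles (2-location task)
# ---------------------------------------------------------------------------

def simulate_curvature_profiles(
    d_pairs: Sequence[tuple[float, float]] = ((1.0, 1.0), (2.0, 1.0)),
    prior_ratio_grid: Sequence[float] = (1.0, 2.0, 4.0, 8.0),
    d_cued_grid: Sequence[float] = tuple(np.linspace(1.0, 5.0, 9)),
    beta: float = 1.0,
    catch_fraction: float = 0.25,
    n_grid: int = 21,
    span: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Deterministic curvature tables for the simulated 2-location task.

    Reproduces the structure of the simulation analyses: R_C at the cued and
    uncued locations as the signal priors vary, ΔR_C as a function of the
    cued/uncued prior ratio for each d′ pair, and ΔR_C over a grid of
    (prior ratio × d′_cued) with the associated ADI of b_CC and of d′
    (cross-sections: ΔR_C is monotone in ADI b_CC at equal d′, and
    non-monotone — rising then falling — in ADI d′).
    """
    from .psychometrics import bias_metrics

    def one_point(d_cued, d_uncued, ratio):
        design = TaskDesign.two_location(
            prior_ratio=ratio, catch_fraction=catch_fraction
        )
        costs = CostMatrix.from_beta(design, beta=beta)
        params = ModelParams([[d_cued], [d_uncued]], [0.0, 0.0])
        c_opt = optimal_criteria(params, design, costs)
        p_opt = params.with_criteria(c_opt)
        curves = [
            risk_sweep(p_opt, design, costs, loc, span=span, n_grid=n_grid,
                       criteria=c_opt)
            for loc in range(2)
        ]
        b = [bias_metrics(d, c) for d, c in zip([d_cued, d_uncued], c_opt)]
        return {
            "p_s_cued": design.event_priors[0],
            "p_s_uncued": design.event_priors[1],
            "prior_ratio": ratio,
            "d_cued": d_cued,
            "d_uncued": d_uncued,
            "c_opt_cued": c_opt[0],
            "c_opt_uncued": c_opt[1],
            "r_c_cued": curves[0].r_c,
            "r_c_uncued": curves[1].r_c,
            "delta_r_c": curves[0].r_c - curves[1].r_c,
            "adi_b_cc": b[0].b_cc - b[1].b_cc,
            "adi_d": d_cued - d_uncued,
        }

    rows_ratio = [
        one_point(dc, du, r)
        for (dc, du) in d_pairs
        for r in prior_ratio_grid
    ]
    delta_vs_ratio = pd.DataFrame(rows_ratio)

    rows_grid = [
        one_point(dc, 1.0, r)
        for r in prior_ratio_grid
        for dc in d_cued_grid
    ]
    grid = pd.DataFrame(rows_grid)

    rc_vs_ps = delta_vs_ratio[
        ["p_s_cued", "p_s_uncued", "d_cued", "d_uncued",
         "r_c_cued", "r_c_uncued"]
    ].copy()
    return {
        "rc_vs_ps": rc_vs_ps,
        "delta_rc_vs_ratio": delta_vs_ratio,
        "delta_rc_grid": grid,
    }
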