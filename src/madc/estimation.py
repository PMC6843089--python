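"""Maximum-likelihood fitting of the m-ADC model to contingency tables.

The likelihood is multinomial per stimulus condition: each change condition
(location × magnitude) contributes counts over the m+1 response categories,
the catch condition contributes false alarms and correct rejections. Free
parameters are one d′ per (location, magnitude) — or a Naka-Rushton profile
(d_max, θ50; exponent fixed at 2) per location when ``parametric`` — plus one
criterion per location, uniform across magnitudes (subjects cannot anticipate
the magnitude, so the threshold cannot depend on it).

Constrained variants fix uncued parameters equal across uncued locations
(``eq_d_uncued``: shared uncued d′ profile; ``eq_c_uncued``: shared uncued
criterion), used for AIC/BIC model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtri, xlogy

from ._exceptions import ConvergenceError, DimensionError, InvalidDataError
from .core import (
    ContingencyTable,
    ModelParams,
    ResponseProbabilityTable,
    _choice_probabilities,
    _condition_means,
    naka_rushton,
)
from .design import TaskDesign

D_BOUNDS = (0.0, 8.0)
C_BOUNDS = (-5.0, 5.0)
DMAX_BOUNDS = (0.0, 8.0)
THETA50_BOUNDS = (0.5, 300.0)

CONSTRAINTS = ("none", "eq_d_uncued", "eq_c_uncued")
SUBSETS = ("hits_fa", "fa_misses", "hits_misses", "full")


@dataclass(frozen=True)
class FitResult:
    """An m-ADC maximum-likelihood fit and its information criteria."""

    params: ModelParams
    log_likelihood: float
    n_params: int
    aic: float
    bic: float
    constraint: str
    parametric: str | None
    design: TaskDesign = field(repr=False)
    n_trials: float = 0.0
    converged: bool = True
    n_iterations: int = 0
    table_checksum: float = 0.0

    @property
    def fitted_probabilities(self) -> ResponseProbabilityTable:
        from .core import response_probabilities

        return response_probabilities(self.params, self.design)


@dataclass(frozen=True)
class GofResult:
    """Randomization goodness-of-fit based on the χ² statistic.

    ``p_value`` follows the add-one rule
    (1 + #{randomized χ² ≥ observed}) / (1 + n_randomizations); a small value
    signals that the model deviates from the observed counts.
    """

    chi2_observed: float
    p_value: float
    n_randomizations: int
    seed: int


def count_free_parameters(
    design: TaskDesign, constraint: str = "none", parametric: str | None = None
) -> int:
    """Number of free parameters of a model variant on a given design.

    Unconstrained: L·M sensitivities + L criteria (28 for 4 locations and 6
    magnitudes; 21 for the collapsed 3-location table). ``eq_d_uncued`` shares
    one uncued d′ profile (15 on the collapsed design); ``eq_c_uncued`` shares
    one uncued criterion (20). Parametric Naka-Rushton fits replace each
    location's M sensitivities with (d_max, θ50).
    """
    L, M = design.n_locations, design.n_magnitudes
    per_loc = 2 if parametric == "naka_rushton" else M
    if constraint == "none":
        n_d, n_c = L * per_loc, L
    elif constraint == "eq_d_uncued":
        n_d, n_c = 2 * per_loc, L
    elif constraint == "eq_c_uncued":
        n_d, n_c = L * per_loc, 2
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    return n_d + n_c


def count_independent_observations(design: TaskDesign) -> dict[str, int]:
    """Independent response proportions in the contingency table.

    Each of the L·M change conditions has L free proportions (one is fixed by
    normalization); the catch condition has L free false-alarm proportions.
    The breakdown separates hits (one diagonal cell per change condition),
    the remaining free change-trial proportions (mislocalizations), and false
    alarms. For the 4-location, 6-magnitude table this gives
    24 + 72 + 4 = 100.
    """
    L, M = design.n_locations, design.n_magnitudes
    hits = L * M
    mislocalizations = L * M * (L - 1)
    false_alarms = L
    return {
        "hits": hits,
        "mislocalizations": mislocalizations,
        "false_alarms": false_alarms,
        "total": hits + mislocalizations + false_alarms,
    }


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

class _Packing:
    """Maps the optimizer vector to ModelParams for a given model variant."""

    def __init__(self, design: TaskDesign, constraint: str, parametric: str | None):
        if constraint not in CONSTRAINTS:
            raise ValueError(f"unknown constraint {constraint!r}")
        if parametric not in (None, "none", "naka_rushton"):
            raise ValueError(f"unknown parametric option {parametric!r}")
        self.design = design
        self.constraint = constraint
        self.parametric = "naka_rushton" if parametric == "naka_rushton" else None
        self.L, self.M = design.n_locations, design.n_magnitudes
        self.per_loc = 2 if self.parametric else self.M
        self.n_d_groups = 2 if constraint == "eq_d_uncued" else self.L
        self.n_c = 2 if constraint == "eq_c_uncued" else self.L
        self.n_free = self.n_d_groups * self.per_loc + self.n_c

    def bounds(self) -> list[tuple[float, float]]:
        if self.parametric:
            d_b = [DMAX_BOUNDS, THETA50_BOUNDS] * self.n_d_groups
        else:
            d_b = [D_BOUNDS] * (self.n_d_groups * self.per_loc)
        return d_b + [C_BOUNDS] * self.n_c

    def unpack(self, x: np.ndarray) -> ModelParams:
        nd = self.n_d_groups * self.per_loc
        d_raw = np.asarray(x[:nd], float).reshape(self.n_d_groups, self.per_loc)
        c_raw = np.asarray(x[nd:], float)
        # expand d groups: group 0 = cued, group 1 (if shared) = all uncued
        if self.n_d_groups == self.L:
            groups = d_raw
        else:
            groups = np.vstack([d_raw[0:1]] + [d_raw[1:2]] * (self.L - 1))
        if self.parametric:
            mags = np.asarray(self.design.magnitudes, float)
            d = np.vstack(
                [naka_rushton(mags, g[0], g[1], 2.0) for g in groups]
            )
            nr = tuple((float(g[0]), float(g[1]), 2.0) for g in groups)
        else:
            d = groups
            nr = None
        c = c_raw if self.n_c == self.L else np.concatenate(
            [c_raw[0:1], np.repeat(c_raw[1], self.L - 1)]
        )
        return ModelParams(d_prime=d, criteria=c, naka_rushton=nr)

    def pack_init(self, params: ModelParams) -> np.ndarray:
        if self.parametric:
            mags = np.asarray(self.design.magnitudes, float)
            rows = []
            for loc in range(self.n_d_groups):
                d_row = params.d_prime[min(loc, params.n_locations - 1)]
                d_max = max(float(d_row.max()), 0.1)
                half = d_max / 2
                above = np.nonzero(d_row >= half)[0]
                theta50 = float(mags[above[0]]) if len(above) else float(mags[-1])
                rows.extend([d_max, np.clip(theta50, *THETA50_BOUNDS)])
            d_part = np.asarray(rows)
        elif self.n_d_groups == params.n_locations:
            d_part = params.d_prime.ravel()
        else:
            d_part = np.concatenate(
                [params.d_prime[0], params.d_prime[1:].mean(axis=0)]
            )
        if self.n_c == params.n_locations:
            c_part = params.criteria
        else:
            c_part = np.array(
                [params.criteria[0], params.criteria[1:].mean()]
            )
        return np.concatenate([d_part, c_part])


def _warm_start(table: ContingencyTable) -> ModelParams:
    """Inverse-Gaussian SDT warm start from hit and false-alarm rates."""
    design = table.design
    L, M = design.n_locations, design.n_magnitudes
    k = table.counts
    catch_total = max(k[-1].sum(), 1.0)
    fa_rate = np.clip(k[-1, :L] / catch_total, 0.02, 0.7)
    c0 = np.clip(-ndtri(fa_rate), *C_BOUNDS)
    d0 = np.zeros((L, M))
    for loc in range(L):
        for m in range(M):
            row = k[loc * M + m]
            tot = max(row.sum(), 1.0)
            hit = np.clip(row[loc] / tot, 0.02, 0.98)
            d0[loc, m] = np.clip(ndtri(hit) + c0[loc], *D_BOUNDS)
    return ModelParams(d_prime=d0, criteria=c0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _negloglik(x, packing: _Packing, counts: np.ndarray) -> float:
    params = packing.unpack(x)
    mu = _condition_means(params, packing.design)
    p = _choice_probabilities(mu, params.criteria)
    return -float(xlogy(counts, np.clip(p, 1e-300, None)).sum())


def fit_madc(
    table: ContingencyTable,
    design: TaskDesign | None = None,
    constraint: str = "none",
    parametric: str | None = None,
    init: ModelParams | None = None,
    seed: int = 0,
    n_restarts: int = 2,
) -> FitResult:
    """Maximum-likelihood m-ADC fit of a contingency table.

    Multi-start bounded quasi-Newton (L-BFGS-B): one start from the SDT warm
    start (or ``init`` if given) plus ``n_restarts`` seeded random restarts;
    the best optimum is reported. AIC = 2k − 2ln L, BIC = k·ln n − 2ln L.
    """
    design = design or table.design
    if design.location_labels != table.design.location_labels:
        raise DimensionError("table and design disagree on locations")
    if table.n_trials <= 0:
        raise InvalidDataError("cannot fit an all-zero contingency table")
    if np.any(table.row_totals[:-1] < 0):
        raise InvalidDataError("negative row totals")

    packing = _Packing(design, constraint, parametric)
    counts = table.counts
    rng = np.random.default_rng(seed)

    x0s = [packing.pack_init(init if init is not None else _warm_start(table))]
    lo, hi = np.array(packing.bounds()).T
    for _ in range(n_restarts):
        x0s.append(lo + (hi - lo) * rng.uniform(0.15, 0.85, packing.n_free))

    best, n_it, any_ok = None, 0, False
    for x0 in x0s:
        res = minimize(
            _negloglik,
            np.clip(x0, lo, hi),
            args=(packing, counts),
            method="L-BFGS-B",
            bounds=packing.bounds(),
            options={"maxiter": 500, "ftol": 1e-11},
        )
        n_it += res.nit
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    if not any_ok and not np.isfinite(best.fun):
        raise ConvergenceError(
            "no optimizer start converged",
            best=packing.unpack(best.x),
            diagnostics={"message": best.message, "fun": best.fun},
        )

    params = packing.unpack(best.x)
    ll = -float(best.fun)
    k = packing.n_free
    n = table.n_trials
    return FitResult(
        params=params,
        log_likelihood=ll,
        n_params=k,
        aic=2 * k - 2 * ll,
        bic=k * np.log(n) - 2 * ll,
        constraint=constraint,
        parametric=packing.parametric,
        design=design,
        n_trials=n,
        converged=bool(any_ok),
        n_iterations=int(n_it),
        table_checksum=float(counts.sum() + (counts * np.arange(counts.size).reshape(counts.shape)).sum()),
    )


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def _chi2(observed: np.ndarray, expected: np.ndarray, mask: np.ndarray) -> float:
    """χ² over masked cells, pooling cells with expected < 1 into the row max."""
    obs = observed.astype(float).copy()
    exp = expected.astype(float).copy()
    use = mask.copy()
    for i in range(obs.shape[0]):
        row_use = np.nonzero(use[i])[0]
        if len(row_use) < 2:
            continue
        small = [j for j in row_use if exp[i, j] < 1.0]
        if small:
            big = row_use[np.argmax(exp[i, row_use])]
            for j in small:
                if j == big:
                    continue
                exp[i, big] += exp[i, j]
                obs[i, big] += obs[i, j]
                use[i, j] = False
    sel = use & (exp > 0)
    return float((((obs - exp) ** 2) / np.where(sel, exp, 1.0))[sel].sum())


def gof_randomization(
    observed: ContingencyTable,
    fitted: ResponseProbabilityTable,
    n_rand: int = 1000,
    seed: int = 0,
    cell_mask: np.ndarray | None = None,
) -> GofResult:
    """Randomization goodness-of-fit of fitted probabilities to counts.

    The null distribution is built by drawing ``n_rand`` multinomial tables
    (row totals preserved) from the fitted probabilities and recomputing χ²;
    ``cell_mask`` restricts the statistic to a subset of cells (used for
    held-out prediction scoring). Cells with expected count < 1 are pooled
    into their row's largest expected cell.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if observed.design.location_labels != fitted.design.location_labels:
        raise DimensionError("table and fitted probabilities disagree on design")
    k = observed.counts
    p = fitted.p
    totals = np.round(observed.row_totals).astype(int)
    expected = observed.row_totals[:, None] * p
    mask = np.ones_like(k, bool) if cell_mask is None else np.asarray(cell_mask, bool)
    chi2_obs = _chi2(k, expected, mask)

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_rand):
        sim = np.vstack(
            [rng.multinomial(totals[i], p[i]) for i in range(len(totals))]
        )
        if _chi2(sim, expected, mask) >= chi2_obs:
            n_ge += 1
    return GofResult(
        chi2_observed=chi2_obs,
        p_value=(1 + n_ge) / (1 + n_rand),
        n_randomizations=n_rand,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# subset fitting / prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionResult:
    """Held-out prediction of a subset fit."""

    fit: FitResult
    predicted: ResponseProbabilityTable
    expected_counts: np.ndarray
    held_out_mask: np.ndarray
    gof: GofResult


def _subset_masks(design: TaskDesign, subset: str):
    """(fit-cells mask, held-out mask) over the full table layout."""
    L, M = design.n_locations, design.n_magnitudes
    n_cond = L * M + 1
    fit_mask = np.zeros((n_cond, L + 1), bool)
    if subset == "full":
        fit_mask[:] = True
    elif subset == "hits_fa":
        for loc in range(L):
            fit_mask[loc * M:(loc + 1) * M, loc] = True
        fit_mask[-1, :] = True  # FA cells + CR implicitly
    elif subset == "fa_misses":
        fit_mask[:-1, L] = True  # misses
        fit_mask[-1, :] = True
    elif subset == "hits_misses":
        for loc in range(L):
            fit_mask[loc * M:(loc + 1) * M, loc] = True
        fit_mask[:-1, L] = True
        fit_mask[-1, L] = True  # CR explicitly; FAs pooled as complement
    else:
        raise ValueError(f"unknown subset {subset!r}")
    held_out = ~fit_mask
    held_out[-1, L] = False  # CR is never scored as held out
    return fit_mask, held_out


def _subset_negloglik(x, packing: _Packing, counts, fit_mask) -> float:
    """Multinomial likelihood over subset cells, complement cells pooled."""
    params = packing.unpack(x)
    mu = _condition_means(params, packing.design)
    p = np.clip(_choice_probabilities(mu, params.criteria), 1e-300, None)
    ll = 0.0
    for i in range(counts.shape[0]):
        cells = np.nonzero(fit_mask[i])[0]
        if len(cells) == 0:
            continue
        row_tot = counts[i].sum()
        p_in = p[i, cells]
        ll += float(xlogy(counts[i, cells], p_in).sum())
        rest = row_tot - counts[i, cells].sum()
        p_rest = max(1.0 - p_in.sum(), 1e-300)
        if rest > 0:
            ll += float(xlogy(rest, p_rest))
    return -ll


def predict_from_subset(
    table: ContingencyTable,
    design: TaskDesign | None = None,
    subset: str = "hits_fa",
    seed: int = 0,
    n_rand: int = 1000,
    n_restarts: int = 2,
) -> PredictionResult:
    """Fit a contingency subset, predict the rest, and score the prediction.

    Subsets mirror the three prediction analyses: hits + false alarms
    (correct rejections enter implicitly as the catch-row complement),
    false alarms + misses, or hits + misses (correct rejections explicit,
    false alarms pooled). ``"full"`` is the degenerate case using every
    cell, equivalent to an ordinary fit. The returned goodness-of-fit is
    computed only on the held-out cells.
    """
    design = design or table.design
    if subset not in SUBSETS:
        raise ValueError(f"subset must be one of {SUBSETS}")
    fit_mask, held_out = _subset_masks(design, subset)
    if table.counts[fit_mask].sum() <= 0:
        raise InvalidDataError("subset has zero total counts")

    packing = _Packing(design, "none", None)
    rng = np.random.default_rng(seed)
    x0s = [packing.pack_init(_warm_start(table))]
    lo, hi = np.array(packing.bounds()).T
    for _ in range(n_restarts):
        x0s.append(lo + (hi - lo) * rng.uniform(0.15, 0.85, packing.n_free))
    best = None
    for x0 in x0s:
        res = minimize(
            _subset_negloglik, np.clip(x0, lo, hi),
            args=(packing, table.counts, fit_mask),
            method="L-BFGS-B", bounds=packing.bounds(),
            options={"maxiter": 500, "ftol": 1e-11},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = packing.unpack(best.x)
    ll = -float(best.fun)
    k = packing.n_free
    fit = FitResult(
        params=params, log_likelihood=ll, n_params=k,
        aic=2 * k - 2 * ll, bic=k * np.log(table.n_trials) - 2 * ll,
        constraint="none", parametric=None, design=design,
        n_trials=table.n_trials, converged=True, n_iterations=int(best.nit),
    )
    predicted = fit.fitted_probabilities
    expected = table.row_totals[:, None] * predicted.p
    gof = gof_randomization(
        table, predicted, n_rand=n_rand, seed=seed, cell_mask=held_out
    )
    return PredictionResult(
        fit=fit, predicted=predicted, expected_counts=expected,
        held_out_mask=held_out, gof=gof,
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def compare_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits of the same table by AIC (ties: fewer parameters).

    Returns a DataFrame ordered best-first with ΔAIC and ΔBIC relative to the
    winner.
    """
    if not fits:
        raise ValueError("need at least one fit")
    checksums = {f.table_checksum for f in fits}
    trials = {f.n_trials for f in fits}
    if len(checksums) > 1 or len(trials) > 1:
        raise InvalidDataError("fits were not computed on the same table")
    rows = pd.DataFrame(
        {
            "constraint": [f.constraint for f in fits],
            "parametric": [f.parametric or "none" for f in fits],
            "n_params": [f.n_params for f in fits],
            "log_likelihood": [f.log_likelihood for f in fits],
            "aic": [f.aic for f in fits],
            "bic": [f.bic for f in fits],
        }
    )
    rows = rows.sort_values(["aic", "n_params"], kind="stable").reset_index(drop=True)
    rows["delta_aic"] = rows["aic"] - rows["aic"].iloc[0]
    rows["delta_bic"] = rows["bic"] - rows["bic"].iloc[0]
    return rows
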