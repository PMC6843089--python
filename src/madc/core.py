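"""The m-ADC decision model: response probabilities, simulation, and Bayes risk.

The model places one Gaussian decision variable per location (unit variance,
independent components). On a change trial of magnitude θ at location k the
k-th component's mean shifts by the sensitivity d′_k(θ); on catch trials all
means are zero. The observer holds one criterion c_k per location and responds
at the location maximizing Ψ_k − c_k when that maximum is positive, otherwise
"no change". The induced choice probabilities are

    P(respond j | μ) = ∫_0^∞ φ(u + c_j − μ_j) Π_{k≠j} Φ(u + c_k − μ_k) du
    P(no change | μ) = Π_k Φ(c_k − μ_k)

which this module evaluates by high-order Gauss–Legendre quadrature on (0, U),
U = max(8, max|c − μ| + 8); the integrand has a Gaussian tail so the fixed
rule is accurate to ~1e-12 (verified against adaptive quadrature in tests).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from ._exceptions import ConvergenceError, DimensionError, InvalidDataError
from .design import NO_CHANGE, CostMatrix, TaskDesign

_SQRT_2PI = np.sqrt(2.0 * np.pi)
_N_NODES = 160

#: Columns of a trial table, one row per trial.
TRIAL_COLUMNS = [
    "subject_id",
    "block",
    "trial_index",
    "cue_location",
    "event_location",
    "magnitude_deg",
    "response_location",
    "rt_ms",
    "excluded",
]


def naka_rushton(theta, d_max, theta50, n=2.0):
    """Saturating sensitivity function d(θ) = d_max·θⁿ/(θⁿ + θ50ⁿ)."""
    theta = np.asarray(theta, float)
    tn = theta**n
    return d_max * tn / (tn + theta50**n)


@dataclass(frozen=True)
class ModelParams:
    """Sensitivities and criteria of an m-ADC observer.

    ``d_prime`` has shape (n_locations, n_magnitudes) in noise-SD units;
    ``criteria`` has one detection threshold per location. A parametric
    observer can be built from per-location Naka-Rushton profiles with
    :meth:`from_naka_rushton`, which also records the generating
    (d_max, θ50, n) triplets in ``naka_rushton``.
    """

    d_prime: np.ndarray
    criteria: np.ndarray
    naka_rushton: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.d_prime, float))
        c = np.atleast_1d(np.asarray(self.criteria, float))
        if d.shape[0] != c.shape[0]:
            raise DimensionError(
                f"d_prime has {d.shape[0]} locations but criteria has {c.shape[0]}"
            )
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(c))):
            raise ValueError("parameters must be finite")
        if np.any(d < 0):
            raise ValueError("d_prime must be non-negative")
        object.__setattr__(self, "d_prime", d)
        object.__setattr__(self, "criteria", c)

    @property
    def n_locations(self) -> int:
        return self.d_prime.shape[0]

    @property
    def n_magnitudes(self) -> int:
        return self.d_prime.shape[1]

    @property
    def d_av(self) -> np.ndarray:
        """Unweighted mean of d′ across magnitudes, per location."""
        return self.d_prime.mean(axis=1)

    def marginal(self) -> "ModelParams":
        """Single-effective-magnitude observer with the magnitude-mean d′."""
        return ModelParams(d_prime=self.d_av[:, None], criteria=self.criteria)

    def with_criteria(self, criteria) -> "ModelParams":
        return replace(self, criteria=np.asarray(criteria, float))

    @classmethod
    def from_naka_rushton(
        cls,
        profiles: Sequence[tuple[float, float] | tuple[float, float, float]],
        magnitudes: Sequence[float],
        criteria,
        n: float = 2.0,
    ) -> "ModelParams":
        """Build d′(θ) per location from (d_max, θ50[, n]) profiles."""
        mags = np.asarray(magnitudes, float)
        rows, kept = [], []
        for prof in profiles:
            d_max, theta50 = prof[0], prof[1]
            exp_n = prof[2] if len(prof) > 2 else n
            if d_max < 0 or theta50 <= 0 or exp_n <= 0:
                raise ValueError("require d_max >= 0, theta50 > 0, n > 0")
            rows.append(naka_rushton(mags, d_max, theta50, exp_n))
            kept.append((float(d_max), float(theta50), float(exp_n)))
        return cls(
            d_prime=np.vstack(rows), criteria=criteria, naka_rushton=tuple(kept)
        )

    def check_design(self, design: TaskDesign) -> None:
        if self.n_locations != design.n_locations:
            raise DimensionError(
                f"params have {self.n_locations} locations, design has "
                f"{design.n_locations}"
            )
        if self.n_magnitudes not in (1, design.n_magnitudes):
            raise DimensionError(
                f"params have {self.n_magnitudes} magnitudes, design has "
                f"{design.n_magnitudes}"
            )


@dataclass(frozen=True)
class ResponseProbabilityTable:
    """P(response | stimulus condition); rows sum to one.

    Rows follow :attr:`TaskDesign.conditions` order ((location, magnitude)
    row-major, catch last); columns are response locations in design order
    with "no change" last.
    """

    design: TaskDesign
    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, float)
        n_cond = len(self.design.conditions)
        n_resp = self.design.n_locations + 1
        if p.shape != (n_cond, n_resp):
            raise DimensionError(f"probability table must be {(n_cond, n_resp)}")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("each condition's probabilities must sum to 1")
        object.__setattr__(self, "p", p)

    def row(self, location: int, magnitude_index: int) -> np.ndarray:
        return self.p[location * self.design.n_magnitudes + magnitude_index]

    @property
    def catch_row(self) -> np.ndarray:
        return self.p[-1]


@dataclass(frozen=True)
class ContingencyTable:
    """Stimulus-response counts for one session (or pool of sessions).

    Same row/column layout as :class:`ResponseProbabilityTable`. Diagonal
    change-row cells are hits, the last column misses, the catch row holds
    false alarms and (last cell) correct rejections; remaining change-row
    cells are mislocalizations.
    """

    design: TaskDesign
    counts: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.counts)
        n_cond = len(self.design.conditions)
        n_resp = self.design.n_locations + 1
        if k.shape != (n_cond, n_resp):
            raise DimensionError(f"counts must be {(n_cond, n_resp)}")
        if np.any(k < 0):
            raise InvalidDataError("counts must be non-negative")
        object.__setattr__(self, "counts", np.asarray(k, float))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_trials(self) -> float:
        return float(self.counts.sum())

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        if other.design.location_labels != self.design.location_labels:
            raise DimensionError("cannot add tables with different designs")
        return ContingencyTable(self.design, self.counts + other.counts)


# ---------------------------------------------------------------------------
# response probabilities
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w  # mapped to [0, 1]


def _choice_probabilities(mu: np.ndarray, criteria: np.ndarray) -> np.ndarray:
    """Rows of choice probabilities for mean vectors ``mu`` (n_cond, L)."""
    mu = np.atleast_2d(np.asarray(mu, float))
    c = np.asarray(criteria, float)
    n_cond, n_loc = mu.shape
    a = c[None, :] - mu  # shifts c_k − μ_k
    upper = max(8.0, float(np.abs(a).max()) + 8.0)
    t, w = _gl_nodes(_N_NODES)
    u = upper * t
    wu = upper * w
    z = u[None, None, :] + a[:, :, None]  # (n_cond, L, nodes)
    phi = np.exp(-0.5 * z * z) / _SQRT_2PI
    logPhi = log_ndtr(z)
    out = np.empty((n_cond, n_loc + 1), float)
    for j in range(n_loc):
        others = [k for k in range(n_loc) if k != j]
        log_prod = logPhi[:, others, :].sum(axis=1) if others else 0.0
        out[:, j] = (phi[:, j, :] * np.exp(log_prod)) @ wu
    out[:, n_loc] = np.exp(log_ndtr(a).sum(axis=1))
    # quadrature leaves ~1e-12 slack; renormalize exactly
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=1, keepdims=True)
    return out


def _condition_means(params: ModelParams, design: TaskDesign) -> np.ndarray:
    """Mean vector per condition in table order (catch last)."""
    L, M = design.n_locations, design.n_magnitudes
    d = params.d_prime
    if d.shape[1] == 1 and M > 1:
        d = np.repeat(d, M, axis=1)
    mu = np.zeros((L * M + 1, L))
    for loc in range(L):
        for m in range(M):
            mu[loc * M + m, loc] = d[loc, m]
    return mu


def response_probabilities(
    params: ModelParams, design: TaskDesign
) -> ResponseProbabilityTable:
    """Analytic choice probabilities of an m-ADC observer for every condition."""
    params.check_design(design)
    mu = _condition_means(params, design)
    return ResponseProbabilityTable(
        design=design, p=_choice_probabilities(mu, params.criteria)
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _stratified_counts(priors: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder allocation of n trials to conditions."""
    ideal = priors * n
    counts = np.floor(ideal).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(ideal - counts))
        counts[order[:short]] += 1
    return counts


def simulate_observer_trials(
    params: ModelParams,
    design: TaskDesign,
    n_trials: int,
    seed: int | np.random.Generator,
    subject_id: str = "sim",
) -> pd.DataFrame:
    """Monte-Carlo trials from the m-ADC decision rule.

    Event types are allocated to trials by stratified (largest-remainder)
    counts matching the design priors, then shuffled; per trial the decision
    variable is drawn as N(μ, I) and the argmax rule applied (ties, a
    measure-zero event, resolve to the lowest location index). Deterministic
    for a fixed seed.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    params.check_design(design)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    L, M = design.n_locations, design.n_magnitudes
    conditions = design.conditions
    counts = _stratified_counts(design.condition_priors, n_trials)
    cond_idx = np.repeat(np.arange(len(conditions)), counts)
    rng.shuffle(cond_idx)

    mu_all = _condition_means(params, design)
    mu = mu_all[cond_idx]
    psi = rng.standard_normal((n_trials, L)) + mu
    slack = psi - params.criteria[None, :]
    best = np.argmax(slack, axis=1) if L else np.zeros(n_trials, int)
    resp = np.where(slack[np.arange(n_trials), best] > 0, best, L)

    event_loc = np.array(
        [design.location_labels[c[0]] if c[0] is not None else NO_CHANGE
         for c in conditions]
    )[cond_idx] if n_trials else np.array([], dtype=object)
    mags = np.array(
        [c[1] if c[1] is not None else np.nan for c in conditions], float
    )[cond_idx] if n_trials else np.array([])
    resp_labels = np.array(list(design.location_labels) + [NO_CHANGE])[resp] \
        if n_trials else np.array([], dtype=object)

    idx = np.arange(n_trials)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "block": idx // design.trials_per_block + 1,
            "trial_index": idx + 1,
            "cue_location": design.location_labels[0],
            "event_location": event_loc,
            "magnitude_deg": mags,
            "response_location": resp_labels,
            "rt_ms": np.nan,
            "excluded": 0,
        },
        columns=TRIAL_COLUMNS,
    )


def build_contingency_table(
    trials: pd.DataFrame, design: TaskDesign, collapse_adjacent: bool = False
) -> ContingencyTable:
    """Aggregate a trial table into stimulus-response counts.

    With ``collapse_adjacent`` the two adjacent roles are merged — a
    count-level merge of both rows and response columns — and the returned
    table lives on :meth:`TaskDesign.collapse_adjacent`.
    """
    use = trials[trials["excluded"].fillna(0).astype(int) == 0]
    L, M = design.n_locations, design.n_magnitudes
    counts = np.zeros((L * M + 1, L + 1))
    resp_index = {lab: i for i, lab in enumerate(design.location_labels)}
    resp_index[NO_CHANGE] = L
    mag_index = {float(m): i for i, m in enumerate(design.magnitudes)}

    col = use["response_location"].map(resp_index)
    if col.isna().any():
        bad = int(np.flatnonzero(col.isna().to_numpy())[0])
        raise InvalidDataError(
            f"unknown response label "
            f"{use['response_location'].iloc[bad]!r} at trial row {bad}"
        )
    ev = use["event_location"].fillna(NO_CHANGE)
    is_catch = (ev == NO_CHANGE).to_numpy()
    ev_loc = ev.map(resp_index)
    if ev_loc[~is_catch].isna().any() or (ev_loc[~is_catch] == L).any():
        bad = int(np.flatnonzero((ev_loc.isna() | (ev_loc == L)).to_numpy()
                                 & ~is_catch)[0])
        raise InvalidDataError(
            f"unknown event label {ev.iloc[bad]!r} at trial row {bad}"
        )
    mag = use["magnitude_deg"].astype(float).map(mag_index)
    if mag[~is_catch].isna().any():
        bad = int(np.flatnonzero(mag.isna().to_numpy() & ~is_catch)[0])
        raise InvalidDataError(
            f"magnitude {use['magnitude_deg'].iloc[bad]} not in design "
            f"at trial row {bad}"
        )
    row = np.where(
        is_catch,
        L * M,
        ev_loc.fillna(0).to_numpy(dtype=int) * M + mag.fillna(0).to_numpy(dtype=int),
    )
    np.add.at(counts, (row, col.to_numpy(dtype=int)), 1)

    table = ContingencyTable(design=design, counts=counts)
    return collapse_table_adjacent(table) if collapse_adjacent else table


def collapse_table_adjacent(table: ContingencyTable) -> ContingencyTable:
    """Count-level merge of the adjacent-ipsi/contra rows and columns."""
    design = table.design
    new_design = design.collapse_adjacent()
    adj = [i for i, lab in enumerate(design.location_labels)
           if lab.startswith("adjacent")]
    keep = [i for i in range(design.n_locations) if i not in adj]
    M = design.n_magnitudes
    k = table.counts
    # columns: kept locations, merged adjacent, no-change
    cols = [k[:, i] for i in keep] + [k[:, adj].sum(axis=1), k[:, -1]]
    k2 = np.column_stack(cols)
    rows = [k2[i * M:(i + 1) * M] for i in keep]
    rows.append(sum(k2[i * M:(i + 1) * M] for i in adj))
    rows.append(k2[-1:])
    return ContingencyTable(design=new_design, counts=np.vstack(rows))


# ---------------------------------------------------------------------------
# risk and optimal criteria
# ---------------------------------------------------------------------------

def expected_risk(
    params: ModelParams,
    design: TaskDesign,
    costs: CostMatrix,
    criteria_override=None,
) -> float:
    """Bayes risk Σ_i Σ_j prior(i)·C^i_j·P(j|i) of the observer's policy."""
    if costs.design.n_locations != design.n_locations:
        raise DimensionError("cost matrix and design disagree on locations")
    p = params if criteria_override is None else params.with_criteria(criteria_override)
    probs = response_probabilities(p, design).p
    priors = design.condition_priors
    L = design.n_locations
    event = np.array(
        [c[0] if c[0] is not None else L for c in design.conditions]
    )
    return float(np.sum(priors[:, None] * probs * costs.cost[event, :]))


def optimal_criteria(
    params: ModelParams,
    design: TaskDesign,
    costs: CostMatrix,
    x0=None,
    perturbation: float = 0.05,
) -> np.ndarray:
    """Criteria minimizing Bayes risk within the planar-boundary family.

    Multi-magnitude observers are reduced to their magnitude-marginal d′ (one
    effective sensitivity per location) before minimizing. The returned vector
    is verified to be a local minimum: risk must be non-decreasing under
    ±``perturbation`` moves of any single criterion.
    """
    from scipy.optimize import minimize

    marg = params.marginal()
    if np.any(marg.d_prime <= 0):
        raise ValueError("optimal_criteria requires d_prime > 0 at every location")
    design_m = design.with_magnitudes((design.magnitudes[0],))

    def risk_of(c):
        return expected_risk(marg, design_m, costs, criteria_override=c)

    if x0 is None:
        x0 = marg.d_prime[:, 0] / 2.0
    best = None
    for method in ("L-BFGS-B", "Nelder-Mead"):
        res = minimize(
            risk_of, x0, method=method,
            bounds=[(-5.0, 5.0)] * design.n_locations,
            options={"xatol": 1e-9, "fatol": 1e-13}
            if method == "Nelder-Mead"
            else {"ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
        c_opt = np.asarray(best.x, float)
        r0 = best.fun
        # verify local optimality within the feasible box (an optimum may sit
        # on a bound when one policy dominates, e.g. never responding)
        ok = True
        for k in range(design.n_locations):
            for sign in (+1.0, -1.0):
                trial = c_opt.copy()
                trial[k] = trial[k] + sign * perturbation
                if not -5.0 <= trial[k] <= 5.0:
                    continue
                if risk_of(trial) < r0 - 1e-9:
                    ok = False
        if ok:
            return c_opt
    raise ConvergenceError(
        "optimal criteria search did not reach a verified local minimum",
        best=np.asarray(best.x, float),
        diagnostics={"risk": best.fun, "message": best.message},
    )
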