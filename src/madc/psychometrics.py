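"""Raw performance curves, bias metrics, and attention modulation indices.

Two measures of spatial choice bias are derived from each location's fitted
detection threshold c and magnitude-averaged sensitivity d′_av:

* choice-criterion bias  b_CC = c − d′_av/2 — deviation of the threshold from
  the unbiased midpoint of the signal and noise distributions (lower = more
  biased toward reporting change there);
* likelihood-ratio bias  b_LR = exp(−d′_av · b_CC) — the density ratio at the
  criterion for equal-variance Gaussians (higher = more biased).

Cue-induced modulation of any parameter is summarized by the attention
difference index ADI = cued − mean(uncued) and the attention modulation index
AMI = (cued − uncued)/(cued + uncued).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._exceptions import InvalidDataError
from .core import ContingencyTable, naka_rushton
from .design import TaskDesign
from .estimation import FitResult, fit_madc


@dataclass(frozen=True)
class BiasMetrics:
    """Per-location bias pair (b_CC, b_LR) with the d′_av that produced it."""

    d_prime_av: float
    criterion: float
    b_cc: float
    b_lr: float


@dataclass(frozen=True)
class ModulationIndices:
    parameter: str
    adi: float
    ami: float
    undefined: bool = False


@dataclass(frozen=True)
class SigmoidFit:
    """Three-parameter logistic fit of percent correct vs magnitude.

    y(θ) = asymptote / (1 + exp(−(θ − midpoint)/slope)); floor fixed at 0.
    """

    asymptote: float
    midpoint: float
    slope: float
    degenerate: bool = False

    def __call__(self, theta):
        return logistic3(np.asarray(theta, float),
                         self.asymptote, self.midpoint, self.slope)


@dataclass(frozen=True)
class NakaRushtonFit:
    """Naka-Rushton psychophysical fit d(θ) = d_max·θⁿ/(θⁿ + θ50ⁿ), n fixed."""

    d_max: float
    theta50: float
    n: float = 2.0
    degenerate: bool = False
    se_d_max: float = np.nan
    se_theta50: float = np.nan

    def __call__(self, theta):
        return naka_rushton(np.asarray(theta, float), self.d_max, self.theta50, self.n)


def logistic3(theta, asymptote, midpoint, slope):
    return asymptote / (1.0 + np.exp(-(theta - midpoint) / slope))


# ---------------------------------------------------------------------------
# bias and modulation
# ---------------------------------------------------------------------------

def bias_metrics(d_prime_av: float, criterion: float) -> BiasMetrics:
    """b_CC = c − d′_av/2 and b_LR = exp(−d′_av·b_CC)."""
    if d_prime_av < 0:
        raise ValueError("d_prime_av must be non-negative")
    b_cc = criterion - d_prime_av / 2.0
    return BiasMetrics(
        d_prime_av=float(d_prime_av),
        criterion=float(criterion),
        b_cc=float(b_cc),
        b_lr=float(np.exp(-d_prime_av * b_cc)),
    )


def bias_metrics_from_fit(fit: FitResult) -> list[BiasMetrics]:
    """Bias metrics per location of an m-ADC fit, in design order."""
    return [
        bias_metrics(d_av, c)
        for d_av, c in zip(fit.params.d_av, fit.params.criteria)
    ]


def modulation_indices(
    value_cued: float, values_uncued: Sequence[float], parameter: str = ""
) -> ModulationIndices:
    """ADI = cued − mean(uncued); AMI = (cued − uncued)/(cued + uncued)."""
    if len(values_uncued) == 0:
        raise ValueError("need at least one uncued value")
    uncued = float(np.mean(values_uncued))
    adi = value_cued - uncued
    total = value_cued + uncued
    if total == 0:
        return ModulationIndices(parameter, adi=adi, ami=np.nan, undefined=True)
    return ModulationIndices(parameter, adi=adi, ami=adi / total)


# ---------------------------------------------------------------------------
# psychometric (percent correct) curves
# ---------------------------------------------------------------------------

def percent_correct(table: ContingencyTable) -> pd.DataFrame:
    """Hit rate (correct detection AND localization) per location × magnitude."""
    design = table.design
    L, M = design.n_locations, design.n_magnitudes
    rows = []
    for loc in range(L):
        for m in range(M):
            row = table.counts[loc * M + m]
            tot = row.sum()
            rows.append(
                {
                    "location": design.location_labels[loc],
                    "magnitude_deg": design.magnitudes[m],
                    "n_trials": tot,
                    "proportion_correct": row[loc] / tot if tot else np.nan,
                }
            )
    return pd.DataFrame(rows)


def fit_psychometric(
    table: ContingencyTable, design: TaskDesign | None = None
) -> dict[str, SigmoidFit]:
    """Least-squares logistic fit of percent correct vs magnitude per location."""
    design = design or table.design
    if design.n_magnitudes < 3:
        raise InvalidDataError("need at least 3 magnitudes for a sigmoid fit")
    pc = percent_correct(table)
    mags = np.asarray(design.magnitudes, float)
    out = {}
    for loc in design.location_labels:
        y = pc.loc[pc["location"] == loc, "proportion_correct"].to_numpy()
        ok = np.isfinite(y)
        if ok.sum() < 3:
            raise InvalidDataError(f"location {loc!r} has <3 magnitudes with trials")
        x, yy = mags[ok], y[ok]
        if np.ptp(yy) < 1e-12:
            out[loc] = SigmoidFit(
                asymptote=float(yy.mean()), midpoint=float(np.median(x)),
                slope=0.0, degenerate=True,
            )
            continue
        p0 = (min(max(yy.max(), 0.05), 1.0), float(np.median(x)), float(np.ptp(x)) / 4)
        try:
            popt, _ = curve_fit(
                logistic3, x, yy, p0=p0,
                bounds=([0.0, 1e-6, 1e-6], [1.0, 10 * x.max(), 10 * x.max()]),
                maxfev=20000,
            )
            out[loc] = SigmoidFit(*map(float, popt))
        except RuntimeError:
            out[loc] = SigmoidFit(p0[0], p0[1], p0[2], degenerate=True)
    return out


# ---------------------------------------------------------------------------
# psychophysical (sensitivity) curves
# ---------------------------------------------------------------------------

def fit_psychophysical(
    d_prime_by_magnitude: Sequence[float],
    magnitudes: Sequence[float],
    n: float = 2.0,
    theta50_max: float | None = None,
) -> NakaRushtonFit:
    """Least-squares Naka-Rushton fit to per-magnitude sensitivities.

    The exponent n is fixed (default 2), leaving d_max and θ50 free. All-zero
    sensitivities give a flagged fit with d_max = 0 (θ50 unidentifiable).
    θ50 is bounded at 1.5× the largest sampled magnitude by default: beyond
    the sampled range the half-saturation point trades off freely against
    d_max, so an unbounded fit can run away on noisy, non-saturating data.
    """
    d = np.asarray(d_prime_by_magnitude, float)
    mags = np.asarray(magnitudes, float)
    if len(d) != len(mags) or len(d) < 3:
        raise InvalidDataError("need >=3 (magnitude, d') pairs of equal length")
    if np.all(d <= 1e-12):
        return NakaRushtonFit(d_max=0.0, theta50=float(np.median(mags)),
                              n=n, degenerate=True)
    f = lambda th, dm, t50: naka_rushton(th, dm, t50, n)
    half = d.max() / 2
    above = np.nonzero(d >= half)[0]
    p0 = (float(d.max()), float(mags[above[0]] if len(above) else np.median(mags)))
    # d_max capped at 10: d' itself is bounded well below this, and an
    # unsaturated curve otherwise trades d_max off against theta50 freely
    t50_hi = 1.5 * float(mags.max()) if theta50_max is None else float(theta50_max)
    popt, _ = curve_fit(
        f, mags, d, p0=(min(p0[0], 10.0), min(p0[1], t50_hi)),
        bounds=([0.0, 1e-3], [10.0, t50_hi]), maxfev=20000,
    )
    return NakaRushtonFit(d_max=float(popt[0]), theta50=float(popt[1]), n=n)


def pooled_psychophysical_fit(
    tables: Sequence[ContingencyTable],
    design: TaskDesign,
    n: float = 2.0,
    seed: int = 0,
    jackknife: bool = True,
    **fit_kwargs,
) -> dict[str, NakaRushtonFit]:
    """Naka-Rushton fit on the pooled contingency table, with jackknife SEs.

    The pooled table is fit with the m-ADC model; per-location d′(θ) values
    are then fit with the Naka-Rushton form. Jackknife SEs are
    leave-one-subject-out over the pooled fit.
    """
    pooled = tables[0]
    for t in tables[1:]:
        pooled = pooled + t

    def nr_by_location(table):
        fit = fit_madc(table, design, seed=seed, **fit_kwargs)
        return {
            lab: fit_psychophysical(fit.params.d_prime[i], design.magnitudes, n=n)
            for i, lab in enumerate(design.location_labels)
        }

    full = nr_by_location(pooled)
    if not jackknife or len(tables) < 2:
        return full
    loo = []
    for i in range(len(tables)):
        rest = pooled.counts - tables[i].counts
        loo.append(nr_by_location(ContingencyTable(design, rest)))
    m = len(tables)
    out = {}
    for lab, fit in full.items():
        dm = np.array([x[lab].d_max for x in loo])
        t50 = np.array([x[lab].theta50 for x in loo])
        se_dm = np.sqrt((m - 1) / m * ((dm - dm.mean()) ** 2).sum())
        se_t50 = np.sqrt((m - 1) / m * ((t50 - t50.mean()) ** 2).sum())
        out[lab] = NakaRushtonFit(
            d_max=fit.d_max, theta50=fit.theta50, n=fit.n,
            degenerate=fit.degenerate, se_d_max=float(se_dm),
            se_theta50=float(se_t50),
        )
    return out


# ---------------------------------------------------------------------------
# permutation test across locations
# ---------------------------------------------------------------------------

def permutation_test_locations(
    trials_by_subject: Sequence[pd.DataFrame],
    design: TaskDesign,
    parameter: str = "d_max",
    locations: tuple[str, str] = ("cued", "opposite"),
    n_perm: int = 1000,
    seed: int = 0,
    **fit_kwargs,
) -> dict:
    """Two-sided permutation test of a pooled psychophysical parameter.

    The null is built by shuffling change-event location labels across change
    trials (within subject), rebuilding the pooled contingency table, refitting,
    and recomputing the parameter difference between the two named locations.
    P-value uses the add-one rule.
    """
    from .core import NO_CHANGE, build_contingency_table

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    def param_diff(trials_list):
        tabs = [build_contingency_table(t, design) for t in trials_list]
        fits = pooled_psychophysical_fit(tabs, design, jackknife=False, **fit_kwargs)
        a, b = fits[locations[0]], fits[locations[1]]
        return getattr(a, parameter) - getattr(b, parameter)

    obs = param_diff(trials_by_subject)
    n_ge = 0
    for _ in range(n_perm):
        shuffled = []
        for t in trials_by_subject:
            t = t.copy()
            change = (t["event_location"] != NO_CHANGE).to_numpy()
            labels = t.loc[change, "event_location"].to_numpy().copy()
            rng.shuffle(labels)
            t.loc[change, "event_location"] = labels
            shuffled.append(t)
        if abs(param_diff(shuffled)) >= abs(obs):
            n_ge += 1
    return {
        "parameter": parameter,
        "locations": locations,
        "observed_difference": float(obs),
        "p_value": (1 + n_ge) / (1 + n_perm),
        "n_perm": n_perm,
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# split-half covariation of sensitivity and bias
# ---------------------------------------------------------------------------

def split_half_covariation(
    trials_by_subject: Sequence[pd.DataFrame],
    design: TaskDesign,
    bias_measure: str = "b_lr",
    seed: int = 0,
    **fit_kwargs,
) -> dict:
    """Within-subject covariation of bias with sensitivity across session halves.

    Each subject's session is split into first/second half by trial order and
    fit separately; the chosen bias ADI is regressed on the d′ ADI with
    subject as a random intercept (statsmodels MixedLM). Subjects whose half
    has an empty condition are flagged and excluded. With a single subject
    the model degenerates to ordinary regression (flagged).
    """
    from .core import build_contingency_table

    rows, flagged = [], []
    for s, t in enumerate(trials_by_subject):
        half = len(t) // 2
        for h, part in enumerate((t.iloc[:half], t.iloc[half:])):
            tab = build_contingency_table(part, design)
            if np.any(tab.row_totals == 0):
                flagged.append(s)
                break
            fit = fit_madc(tab, design, seed=seed, **fit_kwargs)
            bm = bias_metrics_from_fit(fit)
            d_adi = modulation_indices(
                fit.params.d_av[0], fit.params.d_av[1:]).adi
            bias_vals = [getattr(b, bias_measure) for b in bm]
            b_adi = modulation_indices(bias_vals[0], bias_vals[1:]).adi
            rows.append({"subject": s, "half": h, "d_adi": d_adi, "bias_adi": b_adi})
    df = pd.DataFrame(rows)
    df = df[~df["subject"].isin(flagged)]
    if df["subject"].nunique() < 1 or len(df) < 2:
        raise InvalidDataError("not enough usable subjects for the regression")

    single = df["subject"].nunique() == 1
    fallback_ols = single
    if not single:
        import statsmodels.formula.api as smf

        try:
            md = smf.mixedlm("bias_adi ~ d_adi", df, groups=df["subject"])
            res = md.fit(reml=True, method="lbfgs")
            slope, p = float(res.params["d_adi"]), float(res.pvalues["d_adi"])
        except (np.linalg.LinAlgError, ValueError):
            # singular random-effect covariance (no between-subject spread)
            fallback_ols = True
    if fallback_ols:
        import statsmodels.api as sm

        X = sm.add_constant(df["d_adi"])
        res = sm.OLS(df["bias_adi"], X).fit()
        slope = float(res.params.iloc[1])
        p = float(res.pvalues.iloc[1]) if len(df) > 2 else np.nan
    return {
        "slope": slope,
        "p_value": p,
        "n_subjects": int(df["subject"].nunique()),
        "flagged_subjects": flagged,
        "degenerate_single_subject": single,
        "used_ols_fallback": fallback_ols,
        "table": df,
    }
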