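"""RT preprocessing and the robust statistical toolkit.

Reaction times are outlier-trimmed per subject (±3 SD about the subject mean)
and normalized by the across-subject median of per-subject mean cued-location
RT, so the normalized cued mean RT has median 1 across subjects by
construction. Associations involving psychophysical parameters use the
percentage-bend correlation (Wilcox), which bends a fixed fraction of extreme
marginal values before correlating; regression analyses standardize
predictors to zero mean, unit variance and compare coefficient magnitudes
against permutation nulls built by shuffling location labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._exceptions import InvalidDataError


# ---------------------------------------------------------------------------
# RT preprocessing
# ---------------------------------------------------------------------------

def preprocess_rt(
    trials: pd.DataFrame, cued_label: str = "cued"
) -> dict:
    """Outlier-trim and normalize reaction times across a cohort.

    Per subject, trials with RT beyond mean ± 3 SD are flagged
    ``rt_outlier``. The normalization divisor is the across-subject median of
    each subject's mean RT at the cued location (cue-relative role of the
    response); ``normalized_rt`` = rt / divisor. Subjects with no
    cued-location responses are flagged and excluded from the divisor.
    """
    t = trials.copy()
    if t["rt_ms"].isna().all():
        raise InvalidDataError("no reaction times present")
    t = t[np.isfinite(t["rt_ms"])]
    if np.any(t["rt_ms"] <= 0):
        raise InvalidDataError("reaction times must be positive")

    grp = t.groupby("subject_id")["rt_ms"]
    center = grp.transform("mean")
    spread = grp.transform("std").fillna(0.0)
    t["rt_outlier"] = (t["rt_ms"] - center).abs() > 3 * spread
    clean = t[~t["rt_outlier"]]

    cued_means = (
        clean[clean["response_location"] == cued_label]
        .groupby("subject_id")["rt_ms"].mean()
    )
    flagged = sorted(
        set(clean["subject_id"].unique()) - set(cued_means.index)
    )
    if len(cued_means) == 0:
        raise InvalidDataError("no subject has cued-location responses")
    divisor = float(cued_means.median())
    t["normalized_rt"] = t["rt_ms"] / divisor

    summary = (
        clean.assign(normalized_rt=clean["rt_ms"] / divisor)
        .groupby(["subject_id", "response_location"])["normalized_rt"]
        .mean().rename("mean_normalized_rt").reset_index()
    )
    return {
        "trials": t,
        "summary": summary,
        "divisor_ms": divisor,
        "flagged_subjects": flagged,
    }


# ---------------------------------------------------------------------------
# robust correlation
# ---------------------------------------------------------------------------

def _bend_weights(x: np.ndarray, bend: float) -> np.ndarray:
    """Wilcox ψ-transformed deviations for the percentage-bend estimator."""
    n = len(x)
    med = np.median(x)
    w = np.sort(np.abs(x - med))
    m = int(np.floor((1.0 - bend) * n + 0.5))
    omega = w[m - 1]
    if omega <= 0:
        raise InvalidDataError("constant input: percentage-bend undefined")
    z = (x - _bend_location(x, omega)) / omega
    return np.clip(z, -1.0, 1.0)


def _bend_location(x: np.ndarray, omega: float) -> float:
    """The percentage-bend measure of location φ̂."""
    med = np.median(x)
    z = (x - med) / omega
    i1 = int((z < -1).sum())
    i2 = int((z > 1).sum())
    sx = x[(z >= -1) & (z <= 1)].sum()
    return (omega * (i2 - i1) + sx) / (len(x) - i1 - i2)


def percentage_bend_correlation(
    x, y, bend: float = 0.2
) -> tuple[float, float]:
    """Percentage-bend correlation (Wilcox) with t-approximation p-value.

    The bend constant is the fraction of extreme marginal deviations clipped
    before correlating (default 0.2). Returns (rho, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise InvalidDataError("x and y must have equal length >= 4")
    if not 0 < bend < 0.5:
        raise ValueError("bend must be in (0, 0.5)")
    a = _bend_weights(x, bend)
    b = _bend_weights(y, bend)
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise InvalidDataError("degenerate input: zero bend variance")
    rho = float((a * b).sum() / denom)
    n = len(x)
    rho_c = min(max(rho, -1 + 1e-15), 1 - 1e-15)
    tstat = rho_c * np.sqrt((n - 2) / (1 - rho_c**2))
    p = float(2 * sps.t.sf(abs(tstat), n - 2))
    return rho, p


def partial_correlation(x, y, control) -> tuple[float, float]:
    """Pearson partial correlation of x and y controlling for one covariate.

    Closed form ρ_xy·z = (ρ_xy − ρ_xz ρ_yz)/√((1−ρ_xz²)(1−ρ_yz²)); p from the
    t-approximation with n−3 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(control, float)
    if not (len(x) == len(y) == len(z)) or len(x) < 5:
        raise InvalidDataError("need equal lengths >= 5")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if min(1 - r_xz**2, 1 - r_yz**2) <= 1e-12:
        raise InvalidDataError("control is collinear with an input; undefined")
    rho = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    n = len(x)
    rho_c = min(max(rho, -1 + 1e-15), 1 - 1e-15)
    tstat = rho_c * np.sqrt((n - 3) / (1 - rho_c**2))
    p = float(2 * sps.t.sf(abs(tstat), n - 3))
    return float(rho), p


# ---------------------------------------------------------------------------
# RT regression with permutation comparison of coefficients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionReport:
    coefficients: dict[str, float]
    coefficient_difference: float
    p_difference: float
    n_perm: int
    seed: int


def rt_regression(
    data: pd.DataFrame,
    response: str = "rt",
    sensitivity: str = "d_prime_av",
    bias: str = "b_lr",
    extra_predictors: tuple[str, ...] = ("magnitude",),
    subject: str = "subject_id",
    location: str = "location",
    n_perm: int = 10_000,
    seed: int = 0,
) -> RegressionReport:
    """OLS of RT on standardized predictors + permutation coefficient test.

    ``data`` has one row per (subject, location[, magnitude]) with the RT
    response and predictor columns. All predictors are standardized to zero
    mean and unit variance. The difference |β_bias| − |β_d′| is tested
    against a null built by shuffling location labels of the d′ and bias
    values randomly and independently within subject (add-one p).
    """
    import statsmodels.api as sm

    predictors = [sensitivity, bias, *extra_predictors]
    d = data.dropna(subset=[response, *predictors]).reset_index(drop=True)
    if len(d) < len(predictors) + 2:
        raise InvalidDataError("not enough rows for the regression")

    def standardize(v):
        s = v.std(ddof=0)
        if s == 0:
            raise InvalidDataError(f"constant predictor {v.name!r}")
        return (v - v.mean()) / s

    def fit_ols(frame):
        X = sm.add_constant(
            np.column_stack([standardize(frame[p]) for p in predictors])
        )
        cond = np.linalg.cond(X)
        if cond > 1e8:
            raise InvalidDataError(f"rank-deficient design (cond={cond:.2e})")
        res = sm.OLS(standardize(frame[response]), X).fit()
        return dict(zip(predictors, res.params[1:]))

    coefs = fit_ols(d)
    obs_diff = abs(coefs[bias]) - abs(coefs[sensitivity])

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        shuffled = d.copy()
        for col in (sensitivity, bias):
            shuffled[col] = (
                shuffled.groupby(subject)[col]
                .transform(lambda v: rng.permutation(v.to_numpy()))
            )
        c = fit_ols(shuffled)
        if abs(abs(c[bias]) - abs(c[sensitivity])) >= abs(obs_diff):
            n_ge += 1
    return RegressionReport(
        coefficients={k: float(v) for k, v in coefs.items()},
        coefficient_difference=float(obs_diff),
        p_difference=(1 + n_ge) / (1 + n_perm),
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# model-fit comparison and jackknife
# ---------------------------------------------------------------------------

def compare_fits_linear_quadratic(x, y) -> dict:
    """Linear vs quadratic polynomial fit comparison.

    Reports per model the normalized SSE = sse/(n − m − 1) (m = polynomial
    order) and adjusted R², plus the incremental adjusted R² of the quadratic
    term (its gain when added to the linear model).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y) or n < 5:
        raise InvalidDataError("need equal lengths >= 5")

    out = {}
    ss_tot = ((y - y.mean()) ** 2).sum()
    adj = {}
    for m, name in ((1, "linear"), (2, "quadratic")):
        if n <= m + 1:
            raise InvalidDataError(f"n={n} too small for order {m}")
        coef = np.polyfit(x, y, m)
        resid = y - np.polyval(coef, x)
        sse = float((resid**2).sum())
        r2 = 1 - sse / ss_tot if ss_tot > 0 else np.nan
        adj_r2 = 1 - (1 - r2) * (n - 1) / (n - m - 1)
        adj[name] = adj_r2
        out[name] = {
            "coefficients": coef.tolist(),
            "sse": sse,
            "normalized_sse": sse / (n - m - 1),
            "adjusted_r2": float(adj_r2),
        }
    out["incremental_adjusted_r2_quadratic"] = float(
        adj["quadratic"] - adj["linear"]
    )
    return out


def incremental_r2(y, factors: dict[str, np.ndarray]) -> dict[str, float]:
    """Adjusted-R² gain of each factor when added to the full regression."""
    import statsmodels.api as sm

    y = np.asarray(y, float)
    names = list(factors)
    cols = {k: np.asarray(v, float) for k, v in factors.items()}

    def adj_r2(keys):
        if not keys:
            return 0.0
        X = sm.add_constant(np.column_stack([cols[k] for k in keys]))
        return float(sm.OLS(y, X).fit().rsquared_adj)

    full = adj_r2(names)
    return {
        k: full - adj_r2([n for n in names if n != k]) for k in names
    }


def jackknife_se(values=None, estimator=None, data=None) -> float:
    """Leave-one-out jackknife standard error.

    Either pass ``values`` (the statistic is the mean, for which the
    jackknife SE equals s/√n exactly) or an ``estimator`` callable applied to
    ``data`` with one row deleted at a time.
    """
    if values is not None:
        x = np.asarray(values, float)
        n = len(x)
        if n < 2:
            raise InvalidDataError("need n >= 2")
        loo = (x.sum() - x) / (n - 1)
    else:
        data = np.asarray(data)
        n = len(data)
        if n < 2:
            raise InvalidDataError("need n >= 2")
        loo = np.array(
            [estimator(np.delete(data, i, axis=0)) for i in range(n)]
        )
    return float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))


# ---------------------------------------------------------------------------
# motor-bias control
# ---------------------------------------------------------------------------

def motor_bias_check(
    blocks: pd.DataFrame,
    rt_col: str = "mean_rt_fa",
    fa_col: str = "fa_rate",
    subject: str = "subject_id",
    location: str = "location",
    bend: float = 0.2,
) -> dict:
    """Block-wise RT vs false-alarm-rate association, motor-bias control.

    ``blocks`` has one row per (subject, block, location) with the mean RT on
    false-alarm trials and the block's false-alarm rate. Values are
    subject-mean-centered, then correlated (percentage-bend) per location; a
    companion random-effects ANOVA (RT ~ FA with subject random intercepts)
    is reported. A positive association would indicate that fast guesses, not
    choice bias, drive false alarms.
    """
    import statsmodels.formula.api as smf

    d = blocks.dropna(subset=[rt_col, fa_col]).copy()
    n_blocks = d.groupby(subject)["block"].nunique()
    if (n_blocks < 2).any() or len(n_blocks) == 0:
        raise InvalidDataError("every subject needs >= 2 blocks")
    for col in (rt_col, fa_col):
        d[col + "_c"] = d[col] - d.groupby([subject, location])[col].transform("mean")

    per_loc = {}
    for loc, g in d.groupby(location):
        rho, p = percentage_bend_correlation(
            g[rt_col + "_c"], g[fa_col + "_c"], bend=bend
        )
        per_loc[loc] = {"rho": rho, "p": p, "n": len(g)}

    md = smf.mixedlm(
        f"{rt_col} ~ {fa_col}", d, groups=d[subject]
    ).fit(reml=True, method="lbfgs")
    return {
        "per_location": per_loc,
        "anova_fa_coefficient": float(md.params[fa_col]),
        "anova_fa_p": float(md.pvalues[fa_col]),
    }
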