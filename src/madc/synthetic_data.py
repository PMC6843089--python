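"""Synthetic observer cohorts for exercising the full analysis pipeline.

The generator emulates the probabilistic structure of the cued change-
detection session: 288 trials in 6 blocks of 48, 25% catch trials, and
conditional cue validities 2/3 : 1/6 : 1/12 : 1/12, which force per-session
event counts of exactly (72 catch, 144 cued, 36 opposite, 18 + 18 adjacent).
Subject-level parameters are drawn around cohort means: per-location
Naka-Rushton sensitivity profiles (spotlight-like: clearly higher d_max and
lower θ50 at the cued location, similar across uncued locations) and graded
criteria (most liberal at the cued location, then opposite, then adjacent —
the graded-bias pattern the analyses are designed to detect). Reaction times
follow a deliberately simple linear-in-parameters model with multiplicative
lognormal noise — synthetic scaffolding able to exercise every RT analysis,
not a process model of real latencies.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import InvalidDataError
from .core import NO_CHANGE, ModelParams, simulate_observer_trials
from .design import TaskDesign
from .psychometrics import bias_metrics


@dataclass(frozen=True)
class RTModel:
    """Linear RT model: rt = (a + b_bias·(−b_LR) + b_d·(−d′_av))·exp(σZ).

    Faster responses at locations with higher bias and higher sensitivity —
    the direction of coupling the RT analyses are designed to detect.
    Coefficients in milliseconds; ``noise_sd`` is the lognormal σ
    (dimensionless).
    """

    intercept_ms: float = 900.0
    coef_bias_ms: float = 120.0
    coef_d_ms: float = 60.0
    noise_sd: float = 0.18

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("RT noise SD must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Generating distributions for a cohort of simulated observers.

    ``d_max_mean``/``theta50_mean`` hold one value per location role;
    between-subject spread is Gaussian with the given SDs (truncated at
    positivity). Criterion means may alternatively be derived from a target
    b_CC profile via :meth:`with_target_b_cc`.
    """

    n_subjects: int = 30
    design: TaskDesign = field(default_factory=TaskDesign.collapsed)
    d_max_mean: tuple[float, ...] = (2.6, 1.5, 1.3)
    d_max_sd: float = 0.35
    theta50_mean: tuple[float, ...] = (12.0, 20.0, 22.0)
    theta50_sd: float = 3.0
    nr_exponent: float = 2.0
    criterion_mean: tuple[float, ...] = (1.0, 1.15, 1.35)
    criterion_sd: float = 0.12
    rt_model: RTModel = field(default_factory=RTModel)
    rt_coef_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        L = self.design.n_locations
        for name in ("d_max_mean", "theta50_mean", "criterion_mean"):
            if len(getattr(self, name)) != L:
                raise InvalidDataError(f"{name} must have {L} entries")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if min(self.d_max_sd, self.theta50_sd, self.criterion_sd,
               self.rt_coef_sd) < 0:
            raise ValueError("SDs must be >= 0")

    def scaled(self, factor: int) -> "CohortConfig":
        """Same design proportions with ``factor``× the trials per subject."""
        return replace(
            self,
            design=replace(self.design, n_blocks=self.design.n_blocks * factor),
        )

    def with_target_b_cc(self, b_cc_targets: Sequence[float]) -> "CohortConfig":
        """Derive criterion means from a target b_CC profile.

        Uses c = b_CC + d′_av/2 with d′_av from the cohort-mean Naka-Rushton
        profiles, so the mean subject realizes the requested bias profile.
        """
        if len(b_cc_targets) != self.design.n_locations:
            raise InvalidDataError("need one b_CC target per location")
        mean_params = ModelParams.from_naka_rushton(
            list(zip(self.d_max_mean, self.theta50_mean)),
            self.design.magnitudes, np.zeros(self.design.n_locations),
            n=self.nr_exponent,
        )
        criteria = tuple(
            float(b + d / 2) for b, d in zip(b_cc_targets, mean_params.d_av)
        )
        return replace(self, criterion_mean=criteria)


@dataclass(frozen=True)
class SubjectTruth:
    subject_id: str
    params: ModelParams
    rt_model: RTModel

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "d_prime": self.params.d_prime.tolist(),
            "criteria": self.params.criteria.tolist(),
            "naka_rushton": self.params.naka_rushton,
            "rt_model": asdict(self.rt_model),
        }


def generate_ground_truth(config: CohortConfig) -> list[SubjectTruth]:
    """Sample subject-level generating parameters; deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    design = config.design
    L = design.n_locations
    out = []
    for s in range(config.n_subjects):
        d_max = np.maximum(
            np.asarray(config.d_max_mean)
            + config.d_max_sd * rng.standard_normal(L),
            0.05,
        )
        theta50 = np.maximum(
            np.asarray(config.theta50_mean)
            + config.theta50_sd * rng.standard_normal(L),
            1.0,
        )
        criteria = (
            np.asarray(config.criterion_mean)
            + config.criterion_sd * rng.standard_normal(L)
        )
        params = ModelParams.from_naka_rushton(
            list(zip(d_max, theta50)), design.magnitudes, criteria,
            n=config.nr_exponent,
        )
        rt = config.rt_model
        if config.rt_coef_sd > 0:
            rt = replace(
                rt,
                coef_bias_ms=rt.coef_bias_ms
                + config.rt_coef_sd * rng.standard_normal(),
                coef_d_ms=rt.coef_d_ms
                + config.rt_coef_sd * rng.standard_normal(),
            )
        out.append(SubjectTruth(f"S{s + 1:03d}", params, rt))
    return out


def _exact_event_counts(design: TaskDesign) -> np.ndarray:
    """Per-condition counts realizing the design proportions exactly."""
    n = design.n_trials
    ideal = design.condition_priors * n
    counts = np.round(ideal).astype(int)
    if np.max(np.abs(counts - ideal)) > 1e-9 or counts.sum() != n:
        # smallest n making every condition count integral
        from math import gcd

        frac = design.condition_priors
        denom = 1
        for f in frac:
            r = f
            d = 1
            while abs(round(r * d) - r * d) > 1e-9 and d < 10**6:
                d += 1
            denom = denom * d // gcd(denom, d)
        raise InvalidDataError(
            f"{n} trials cannot realize the design proportions exactly; "
            f"smallest compatible count is {denom}"
        )
    return counts


def _assign_rts(
    trials: pd.DataFrame,
    truth: SubjectTruth,
    design: TaskDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    params = truth.params
    b_lr = np.array(
        [bias_metrics(d, c).b_lr
         for d, c in zip(params.d_av, params.criteria)]
    )
    d_av = params.d_av
    # no-change responses take the across-location mean drive
    base_by_resp = {
        lab: truth.rt_model.intercept_ms
        + truth.rt_model.coef_bias_ms * (-b_lr[i])
        + truth.rt_model.coef_d_ms * (-d_av[i])
        for i, lab in enumerate(design.location_labels)
    }
    base_by_resp[NO_CHANGE] = (
        truth.rt_model.intercept_ms
        + truth.rt_model.coef_bias_ms * (-b_lr.mean())
        + truth.rt_model.coef_d_ms * (-d_av.mean())
    )
    base = trials["response_location"].map(base_by_resp).to_numpy(float)
    base = np.maximum(base, 150.0)
    noise = np.exp(truth.rt_model.noise_sd * rng.standard_normal(len(trials)))
    t = trials.copy()
    t["rt_ms"] = base * noise
    return t


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectTruth], dict[str, pd.DataFrame]]:
    """Simulate a cohort of sessions: trial tables with responses and RTs.

    Per subject the event schedule realizes the design proportions exactly
    (e.g. 288 trials → 72 catch, 144 cued / 36 opposite / 18+18 adjacent
    change trials, spread evenly over magnitudes), shuffled by the seeded
    stream; responses follow the m-ADC decision rule and RTs the configured
    linear model. Deterministic under ``config.seed``.
    """
    _exact_event_counts(config.design)  # raises if not realizable
    truths = generate_ground_truth(config)
    root = np.random.default_rng(config.seed + 1)
    tables = {}
    for truth in truths:
        rng = np.random.default_rng(root.integers(2**31))
        t = simulate_observer_trials(
            truth.params, config.design, config.design.n_trials,
            seed=rng, subject_id=truth.subject_id,
        )
        tables[truth.subject_id] = _assign_rts(t, truth, config.design, rng)
    return truths, tables


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_cohort(
    out_dir: str | Path,
    truths: Sequence[SubjectTruth],
    tables: dict[str, pd.DataFrame],
) -> None:
    """Write per-subject trial CSVs plus the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, t in tables.items():
        t.to_csv(out / f"{sid}_trials.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump([t.to_dict() for t in truths], fh, indent=1)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial-table CSV, validating the schema."""
    from .core import TRIAL_COLUMNS

    t = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in t.columns]
    if missing:
        raise InvalidDataError(f"trial table missing columns {missing}")
    return t
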