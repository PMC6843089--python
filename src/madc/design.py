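"""Task designs and cost (payoff) matrices for cued multialternative change detection.

A design describes the probabilistic structure of a session: the spatial roles
relative to the cue (cued, opposite, adjacent...), the set of change magnitudes
(orientation change, degrees), the conditional probability of a change at each
role given a change trial, and the fraction of no-change (catch) trials.
Everything downstream — the decision model, the simulator, the fitters — is
expressed in cue-relative roles, not screen coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._exceptions import DimensionError

NO_CHANGE = "none"

#: Conditional cue validities of the predictive task: changes occur at the cued
#: location on 2/3 of change trials, opposite on 1/6, each adjacent on 1/12.
PREDICTIVE_VALIDITIES = (2 / 3, 1 / 6, 1 / 12, 1 / 12)

#: Magnitudes of orientation change (degrees) used for the psychometric curves.
DEFAULT_MAGNITUDES = (2.0, 10.0, 15.0, 25.0, 45.0, 90.0)


@dataclass(frozen=True)
class TaskDesign:
    """Probabilistic structure of a cued change-detection session.

    Parameters
    ----------
    location_labels
        Ordered cue-relative roles, e.g. ``("cued", "opposite",
        "adjacent_ipsi", "adjacent_contra")`` or the collapsed 3-role set.
    magnitudes
        Change magnitudes in degrees, strictly positive and increasing.
    prior_change_given_location
        P(change at role | change trial); sums to 1.
    catch_fraction
        P(no-change trial); in [0, 1).
    n_blocks, trials_per_block
        Session structure (288 trials = 6 blocks of 48 in the reference task).
    cueing_mode
        ``"predictive"`` or ``"neutral"``.
    """

    location_labels: tuple[str, ...]
    magnitudes: tuple[float, ...]
    prior_change_given_location: tuple[float, ...]
    catch_fraction: float = 0.25
    n_blocks: int = 6
    trials_per_block: int = 48
    cueing_mode: str = "predictive"

    def __post_init__(self):
        if len(self.location_labels) < 1:
            raise DimensionError("need at least one location")
        if len(self.prior_change_given_location) != len(self.location_labels):
            raise DimensionError(
                "prior_change_given_location must have one entry per location"
            )
        p = np.asarray(self.prior_change_given_location, float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("prior_change_given_location must be >=0 and sum to 1")
        if not 0.0 <= self.catch_fraction < 1.0:
            raise ValueError("catch_fraction must be in [0, 1)")
        m = np.asarray(self.magnitudes, float)
        if np.any(m <= 0) or np.any(np.diff(m) <= 0):
            raise ValueError("magnitudes must be strictly positive and increasing")
        if self.cueing_mode not in ("predictive", "neutral"):
            raise ValueError(f"unknown cueing_mode {self.cueing_mode!r}")

    # -- basic dimensions -------------------------------------------------
    @property
    def n_locations(self) -> int:
        return len(self.location_labels)

    @property
    def n_magnitudes(self) -> int:
        return len(self.magnitudes)

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    # -- probabilities ----------------------------------------------------
    @property
    def event_priors(self) -> np.ndarray:
        """Unconditional P(change at each role), length ``n_locations``."""
        return (1.0 - self.catch_fraction) * np.asarray(
            self.prior_change_given_location, float
        )

    @property
    def condition_priors(self) -> np.ndarray:
        """Prior of each stimulus condition in table order.

        Conditions are ordered (location, magnitude) row-major with the catch
        condition last; magnitudes are equiprobable within a location.
        """
        per_loc = self.event_priors / self.n_magnitudes
        rows = np.repeat(per_loc, self.n_magnitudes)
        return np.concatenate([rows, [self.catch_fraction]])

    @property
    def conditions(self) -> list[tuple[int | None, float | None]]:
        """(location index, magnitude) per condition; (None, None) = catch."""
        out: list[tuple[int | None, float | None]] = [
            (loc, mag)
            for loc in range(self.n_locations)
            for mag in self.magnitudes
        ]
        out.append((None, None))
        return out

    @property
    def overall_cue_validity(self) -> float:
        """P(change at the cued location) including catch trials."""
        return float(self.event_priors[0])

    def location_index(self, label: str) -> int:
        try:
            return self.location_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown location label {label!r}") from None

    # -- constructors -----------------------------------------------------
    @classmethod
    def predictive(cls, magnitudes: Sequence[float] = DEFAULT_MAGNITUDES) -> "TaskDesign":
        """The 4-location predictive design (2/3 : 1/6 : 1/12 : 1/12)."""
        return cls(
            location_labels=("cued", "opposite", "adjacent_ipsi", "adjacent_contra"),
            magnitudes=tuple(float(m) for m in magnitudes),
            prior_change_given_location=PREDICTIVE_VALIDITIES,
        )

    @classmethod
    def collapsed(cls, magnitudes: Sequence[float] = DEFAULT_MAGNITUDES) -> "TaskDesign":
        """3-role design with both adjacent locations merged (2/3 : 1/6 : 1/6)."""
        return cls(
            location_labels=("cued", "opposite", "adjacent"),
            magnitudes=tuple(float(m) for m in magnitudes),
            prior_change_given_location=(2 / 3, 1 / 6, 1 / 6),
        )

    @classmethod
    def neutral(cls, magnitudes: Sequence[float] = DEFAULT_MAGNITUDES) -> "TaskDesign":
        """Neutral-cue variant: changes equally likely at all four locations."""
        return cls(
            location_labels=("cued", "opposite", "adjacent_ipsi", "adjacent_contra"),
            magnitudes=tuple(float(m) for m in magnitudes),
            prior_change_given_location=(0.25, 0.25, 0.25, 0.25),
            cueing_mode="neutral",
        )

    @classmethod
    def two_location(
        cls,
        prior_ratio: float = 1.0,
        catch_fraction: float = 0.25,
        magnitudes: Sequence[float] = (10.0,),
    ) -> "TaskDesign":
        """2-location (cued/uncued) design used for the risk-curvature simulations.

        ``prior_ratio`` is p(change cued)/p(change uncued) given a change trial.
        """
        r = float(prior_ratio)
        if r <= 0:
            raise ValueError("prior_ratio must be positive")
        return cls(
            location_labels=("cued", "uncued"),
            magnitudes=tuple(float(m) for m in magnitudes),
            prior_change_given_location=(r / (1 + r), 1 / (1 + r)),
            catch_fraction=catch_fraction,
        )

    def collapse_adjacent(self) -> "TaskDesign":
        """Merge the two adjacent roles into a single "adjacent" role."""
        adj = [i for i, lab in enumerate(self.location_labels) if lab.startswith("adjacent")]
        if len(adj) != 2:
            raise DimensionError("design has no adjacent_ipsi/adjacent_contra pair to collapse")
        keep = [i for i in range(self.n_locations) if i not in adj]
        labels = tuple(self.location_labels[i] for i in keep) + ("adjacent",)
        p = np.asarray(self.prior_change_given_location, float)
        priors = tuple(p[keep]) + (float(p[adj].sum()),)
        return replace(
            self, location_labels=labels, prior_change_given_location=priors
        )

    def with_magnitudes(self, magnitudes: Sequence[float]) -> "TaskDesign":
        return replace(self, magnitudes=tuple(float(m) for m in magnitudes))


@dataclass(frozen=True)
class CostMatrix:
    """Costs C^i_j of responding j when the true event was i.

    Indexing: rows are true events, columns are responses; locations first in
    design order, the no-change event/response last. Lower cost is better
    (risk is minimized).
    """

    cost: np.ndarray
    design: TaskDesign = field(repr=False)

    def __post_init__(self):
        c = np.asarray(self.cost, float)
        n = self.design.n_locations + 1
        if c.shape != (n, n):
            raise DimensionError(
                f"cost matrix must be {(n, n)} for {self.design.n_locations} locations"
            )
        if not np.all(np.isfinite(c)):
            raise ValueError("costs must be finite")
        object.__setattr__(self, "cost", c)

    @property
    def n(self) -> int:
        return self.design.n_locations

    @property
    def c_hit(self) -> np.ndarray:
        return np.diagonal(self.cost)[: self.n].copy()

    @property
    def c_miss(self) -> np.ndarray:
        return self.cost[: self.n, self.n].copy()

    @property
    def c_fa(self) -> np.ndarray:
        return self.cost[self.n, : self.n].copy()

    @property
    def c_cr(self) -> float:
        return float(self.cost[self.n, self.n])

    @classmethod
    def from_beta(
        cls,
        design: TaskDesign,
        beta: float = 1.0,
        cost_fa: float = 1.0,
        cost_cr: float = 0.0,
    ) -> "CostMatrix":
        """Cost matrix parameterized by the cost ratio β.

        β = (C_CR − C_FA)/(C_Hit − C_Miss); the construction sets
        C_Hit = C_CR/β, C_Miss = C_FA/β, and gives mislocalizations the same
        cost as misses (C^j_i = C^j_0 for i ≠ j, j ≠ 0). β = 1 with zero cost
        for correct responses and unit cost for errors corresponds to
        maximizing percent correct.
        """
        if beta <= 0:
            raise ValueError("beta must be positive")
        n = design.n_locations
        c = np.empty((n + 1, n + 1), float)
        c_hit = cost_cr / beta
        c_miss = cost_fa / beta
        c[:n, :] = c_miss          # misses and mislocalizations
        np.fill_diagonal(c[:n, :n], c_hit)
        c[n, :n] = cost_fa
        c[n, n] = cost_cr
        return cls(cost=c, design=design)
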