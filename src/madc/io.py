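"""Serialization of contingency tables, fits, and configuration files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from ._exceptions import InvalidDataError
from .core import ContingencyTable
from .design import TaskDesign
from .estimation import FitResult


def contingency_to_json(table: ContingencyTable, path: str | Path) -> None:
    design = table.design
    payload = {
        "location_labels": list(design.location_labels),
        "magnitudes": list(design.magnitudes),
        "prior_change_given_location": list(design.prior_change_given_location),
        "catch_fraction": design.catch_fraction,
        "conditions": [
            {"location": (design.location_labels[c[0]] if c[0] is not None else None),
             "magnitude_deg": c[1]}
            for c in design.conditions
        ],
        "responses": list(design.location_labels) + ["none"],
        "counts": table.counts.astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def contingency_from_json(path: str | Path) -> ContingencyTable:
    payload = json.loads(Path(path).read_text())
    design = TaskDesign(
        location_labels=tuple(payload["location_labels"]),
        magnitudes=tuple(payload["magnitudes"]),
        prior_change_given_location=tuple(payload["prior_change_given_location"]),
        catch_fraction=payload["catch_fraction"],
    )
    counts = np.asarray(payload["counts"], float)
    return ContingencyTable(design=design, counts=counts)


def fit_to_json(fit: FitResult, path: str | Path, seed: int | None = None) -> None:
    """Persist a fit with full provenance (options, seed, package version)."""
    from . import __version__

    payload = {
        "version": __version__,
        "seed": seed,
        "constraint": fit.constraint,
        "parametric": fit.parametric,
        "location_labels": list(fit.design.location_labels),
        "magnitudes": list(fit.design.magnitudes),
        "d_prime": fit.params.d_prime.tolist(),
        "criteria": fit.params.criteria.tolist(),
        "naka_rushton": fit.params.naka_rushton,
        "log_likelihood": fit.log_likelihood,
        "n_params": fit.n_params,
        "aic": fit.aic,
        "bic": fit.bic,
        "n_trials": fit.n_trials,
        "converged": fit.converged,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_design(path: str | Path) -> TaskDesign:
    """Load a TaskDesign from a YAML/JSON config file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise InvalidDataError("design config must be a mapping")
    return TaskDesign(
        location_labels=tuple(cfg["location_labels"]),
        magnitudes=tuple(cfg["magnitudes"]),
        prior_change_given_location=tuple(cfg["prior_change_given_location"]),
        catch_fraction=float(cfg.get("catch_fraction", 0.25)),
        n_blocks=int(cfg.get("n_blocks", 6)),
        trials_per_block=int(cfg.get("trials_per_block", 48)),
        cueing_mode=cfg.get("cueing_mode", "predictive"),
    )
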