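"""Shared setup for the numbered analysis drivers.

Every driver regenerates the same deterministic 30-subject cohort so the
scripts can run in any order; 01_simulate_cohort.py additionally writes the
trial tables to scratch/ for inspection.
"""

from pathlib import Path

from madc.design import TaskDesign
from madc.synthetic_data import CohortConfig, generate_cohort

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

COHORT_SEED = 20190703
DESIGN = TaskDesign.collapsed()


def cohort_config(n_subjects: int = 30) -> CohortConfig:
    return CohortConfig(n_subjects=n_subjects, design=DESIGN, seed=COHORT_SEED)


def load_cohort(n_subjects: int = 30):
    """(truths, trial tables) for the canonical cohort."""
    return generate_cohort(cohort_config(n_subjects))


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
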