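"""Shared cohort setup for the numbered analysis drivers.

One seeded configuration produces the development cohort (full design grid,
194 applications — the bench study's size) and the validation cohort
(boundary-adjacent design, 111 applications at a fixed 60-s duration).
"""

import dataclasses
from pathlib import Path

from bipolar_rf.simulate import GeneratorConfig, generate_cohort, read_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
N_DEVELOPMENT = 194
N_VALIDATION = 111


def study_cohorts(seed: int = 20260919):
    """(development, validation) tables at the bench-study sample sizes."""
    cfg = GeneratorConfig(seed=seed)
    dev = generate_cohort(cfg, n_total=N_DEVELOPMENT)
    vcfg = dataclasses.replace(cfg, design="boundary_adjacent")
    val = generate_cohort(vcfg, n_total=N_VALIDATION, cohort="validation",
                          seed=seed + 1)
    return cfg, dev, val


def load_or_simulate(seed: int = 20260919):
    """Use the CSVs written by 01_simulate_cohorts.py when present (so every
    driver sees the same tables), else regenerate them deterministically."""
    dev_path = RESULTS / "cohorts" / "development.csv"
    val_path = RESULTS / "cohorts" / "validation.csv"
    if dev_path.exists() and val_path.exists():
        return GeneratorConfig(seed=seed), read_cohort(dev_path), read_cohort(val_path)
    return study_cohorts(seed)
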