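"""Shared fixtures.

The two parameter-recovery suites (paediatric n=200, adult n=40, ten
seeded replicates each) are expensive, so they are computed once per
session and shared by the recovery, covariate-search and acceptance
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ratiopkpd import (AdultDesign, DEFAULT_ADULT_INIT, DEFAULT_PAED_INIT,
                       FitSettings, PaediatricDesign, TruthSpec,
                       apply_adult_inclusion_rules, fit_population,
                       generate_adult_study, generate_paediatric_study)

#: pre-registered replicate seeds for the recovery experiments
RECOVERY_SEEDS = tuple(range(1000, 1010))


@pytest.fixture(scope="session")
def adult_truth() -> TruthSpec:
    return TruthSpec.adult()


@pytest.fixture(scope="session")
def paediatric_truth() -> TruthSpec:
    return TruthSpec.paediatric()


@pytest.fixture(scope="session")
def adult_study_n9(adult_truth):
    """One paper-design adult study (9 subjects, 9 missing samples)."""
    return generate_adult_study(AdultDesign(), adult_truth, seed=42)


@pytest.fixture(scope="session")
def paed_study_n27(paediatric_truth):
    """One study-plan paediatric dataset (87 records, tags injected)."""
    return generate_paediatric_study(PaediatricDesign(), paediatric_truth,
                                     seed=42)


@pytest.fixture(scope="session")
def paed_recovery_fits(paediatric_truth):
    """Ten seeded n=200 paediatric recovery (dataset, fit) pairs."""
    runs = []
    for i, seed in enumerate(RECOVERY_SEEDS):
        ds = generate_paediatric_study(PaediatricDesign(n_subjects=200),
                                       paediatric_truth, seed=seed)
        runs.append((ds, fit_population(ds, "paed_direct",
                                        DEFAULT_PAED_INIT,
                                        FitSettings(seed=i))))
    return runs


@pytest.fixture(scope="session")
def adult_recovery_fits(adult_truth):
    """Ten seeded n=40 adult recovery (dataset, fit) pairs (SAEM)."""
    runs = []
    for i, seed in enumerate(RECOVERY_SEEDS):
        ds = generate_adult_study(
            AdultDesign(n_subjects=40, missing_plan={}), adult_truth,
            seed=seed)
        ds, _ = apply_adult_inclusion_rules(ds)
        runs.append((ds, fit_population(ds, "adult_pkpd",
                                        DEFAULT_ADULT_INIT,
                                        FitSettings(seed=i))))
    return runs
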