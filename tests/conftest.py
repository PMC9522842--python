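"""Shared fixtures.

The expensive experiment fixtures (fitted cohorts) are session-scoped so
the per-module tests and the acceptance checks reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from kuznefit import FitConfig, ScaleConstants
from kuznefit.fitting import fit_patient
from kuznefit.synthetic import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def scales() -> ScaleConstants:
    return ScaleConstants()


@pytest.fixture(scope="session")
def clean_cohort(scales):
    """10 noise-free virtual patients, 9 visits each."""
    spec = SyntheticSpec(n_patients=10, ld_noise_sd=0.0, seed=42, n_visits=(9, 9))
    return generate_cohort(spec, scales)


@pytest.fixture(scope="session")
def recovery_fit_cfg() -> FitConfig:
    # reduced budget: 2e4 evaluations per start, 3 starts; the stop target
    # is the solver's effective convergence floor on noise-free data
    return FitConfig(n_starts=3, max_evals=20_000, max_time=60.0, seed=1,
                     target_objective=1e-9)


@pytest.fixture(scope="session")
def clean_fits(clean_cohort, recovery_fit_cfg, scales):
    """Full-data fits of the noise-free cohort."""
    cohort, _ = clean_cohort
    return {rec.patient_id: fit_patient(rec, recovery_fit_cfg, scales) for rec in cohort}


@pytest.fixture(scope="session")
def noisy_cohort(scales):
    """20 virtual patients with the 1 mm manual-measurement noise."""
    spec = SyntheticSpec(n_patients=20, ld_noise_sd=1.0, seed=7)
    return generate_cohort(spec, scales)


@pytest.fixture(scope="session")
def noisy_fits(noisy_cohort, scales):
    cohort, _ = noisy_cohort
    cfg = FitConfig(n_starts=2, max_evals=5_000, max_time=30.0, seed=1)
    return {rec.patient_id: fit_patient(rec, cfg, scales) for rec in cohort}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
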