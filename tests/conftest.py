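import dataclasses

import numpy as np
import pytest

from inflamr import generate_cohort
from inflamr.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate default-config cohort reused across read-only tests."""
    cfg = dataclasses.replace(SimulationConfig(), n_participants=20_000, seed=11)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with every genetic, causal and confounder effect switched off."""
    cfg = dataclasses.replace(
        SimulationConfig(),
        n_participants=30_000,
        alpha_crp=(0.0, 0.0, 0.0, 0.0),
        gamma_il6r=(0.0, 0.0, 0.0),
        delta_il6_to_crp=0.0,
        theta_il6_dep=0.0,
        theta_crp_dep=0.0,
        theta_il6_anx=0.0,
        theta_crp_anx=0.0,
        confounder_effects={
            k: {c: 0.0 for c in v}
            for k, v in SimulationConfig().confounder_effects.items()
        },
        seed=13,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
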