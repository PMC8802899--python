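"""Shared fixtures.

The expensive artefacts — the eight condition-preset simulations, the two
diagnostic runs, and cohort statistics — are session-scoped so the acceptance
suite and property tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from spinalsynergy import (
    ANGLES,
    POSITIONS,
    build_default_network,
    generate_cohort,
)
from spinalsynergy.cohort import CohortConfig
from spinalsynergy.experiment import (
    ExperimentConfig,
    run_condition,
    run_custom_afferents,
)
from spinalsynergy.stats import cohort_condition_means

ACC_SEED = 7


@pytest.fixture(scope="session")
def acc_cfg() -> ExperimentConfig:
    """Production-profile configuration at the reduced ensemble size used for
    the multi-condition sweeps."""
    return ExperimentConfig(ensemble_size=200, seed=ACC_SEED, write_cohort=False)


@pytest.fixture(scope="session")
def preset_sims(acc_cfg):
    """All eight (position, angle) afferent presets, full drive profile."""
    return {
        (p, a): run_condition(acc_cfg, p, a)
        for p in POSITIONS
        for a in ANGLES
    }


@pytest.fixture(scope="session")
def flip_sim(acc_cfg):
    """senFlInt = 0, senExtInt = 15 Hz: the agonist-bias diagnostic."""
    return run_custom_afferents(acc_cfg, senflint=0.0, senextint=15.0)


@pytest.fixture(scope="session")
def equal_sim(acc_cfg):
    """senFlInt = senExtInt = 75 Hz: the cancellation diagnostic."""
    return run_custom_afferents(acc_cfg, senflint=75.0, senextint=75.0)


@pytest.fixture(scope="session")
def ablation_sims(acc_cfg):
    """Position-2 runs with senInhRF forced to zero (third-input ablation)."""
    return {
        (2, 20): run_condition(acc_cfg, 2, 20, seninhrf_override=0.0),
        (2, 90): run_condition(acc_cfg, 2, 90, seninhrf_override=0.0),
    }


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_cohort_means(default_cohort):
    return cohort_condition_means(default_cohort)


@pytest.fixture()
def tiny_cohort():
    """Four subjects, short bursts — fast unit-test material."""
    return generate_cohort(
        CohortConfig(
            n_subjects=4,
            bursts_per_condition=3,
            plateau_ms=2000.0,
            gap_ms=1000.0,
            seed=11,
        )
    )


@pytest.fixture()
def small_net():
    """Small, short-horizon network for engine unit tests."""
    return build_default_network(ensemble_size=50, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
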