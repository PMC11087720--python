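"""Shared fixtures: synthetic cohorts at the study's default conditions and
a cheap small cohort for unit tests."""

import numpy as np
import pandas as pd
import pytest

from episig.pipeline import RunConfig, run_discovery
from episig.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Discovery-scale cohort at the default study conditions (seed 1):
    60 cases vs 85 controls, 20,000 probes, 200 planted probes at
    |delta beta| = 0.10, 70% hypermethylated."""
    config = SimulationConfig(seed=1)
    beta, sheet, truth = simulate_cohort(config)
    return beta, sheet, truth


@pytest.fixture(scope="session")
def default_run(default_cohort):
    """Full discovery run (pruning, selection, training) on the default
    cohort; cross-validation is exercised separately."""
    beta, sheet, truth = default_cohort
    config = RunConfig(seed=1, run_cv=False, outdir="")
    artifacts = run_discovery(config, beta=beta, sheet=sheet, outdir=None)
    return beta, sheet, truth, artifacts


@pytest.fixture(scope="session")
def small_cohort():
    """Small but signal-bearing cohort for fast unit tests."""
    config = SimulationConfig(
        seed=7, n_probes=3000, n_cases=16, n_controls=20, n_true_dmps=80
    )
    beta, sheet, truth = simulate_cohort(config)
    return beta, sheet, truth


@pytest.fixture()
def tiny_sheet():
    """Hand-built 8-sample sheet for design-matrix tests."""
    rng = np.random.default_rng(3)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(8)],
            "group": ["case"] * 4 + ["control"] * 4,
            "age": rng.uniform(5, 30, 8).round(1),
            "sex": ["F", "M"] * 4,
            "cohort": "toy",
        }
    )
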