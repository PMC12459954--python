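"""Shared fixtures: the heavier simulated populations are session-scoped so
the alignment, value-error, and TD-RPE-pattern tests reuse the same runs."""

from __future__ import annotations

import numpy as np
import pytest

from ovrnn.runner import run_choice_population, run_population
from ovrnn.tasks import TaskSpec
from ovrnn.true_values import dp_true_values

MASTER_SEED = 1


@pytest.fixture(scope="session")
def pav_spec():
    return TaskSpec(kind="pavlovian", delay=3)


@pytest.fixture(scope="session")
def pav_table(pav_spec):
    return dp_true_values(pav_spec)


@pytest.fixture(scope="session")
def rf7_pop(pav_spec):
    """100 sims of the 7-unit random-feedback agent, 1000 Pavlovian trials."""
    return run_population("oVRNNrf", 7, pav_spec, 1000, 100, MASTER_SEED,
                          record_angle=True, probe_trials=[1000])


@pytest.fixture(scope="session")
def bio12_pop(pav_spec):
    """100 sims of the biologically constrained 12-unit agent, 1500 trials."""
    return run_population("oVRNNrf-bio", 12, pav_spec, 1500, 100, MASTER_SEED,
                          record_angle=True, probe_trials=[1500])


@pytest.fixture(scope="session")
def msve_pops(pav_spec, rf7_pop):
    """Trained vs untrained populations for the value-error ordering."""
    pops = {("oVRNNrf", 7): rf7_pop}
    for n in (7, 12):
        for variant in ("oVRNNbp", "oVRNNrf", "untrained-naive"):
            if (variant, n) in pops:
                continue
            pops[(variant, n)] = run_population(
                variant, n, pav_spec, 1000, 100, MASTER_SEED,
                probe_trials=[1000])
    return pops


@pytest.fixture(scope="session")
def prob_pops():
    """20-unit revised agents on the probabilistic-timing tasks (2000 trials)."""
    pops = {}
    for variant in ("oVRNNbp-rev", "oVRNNrf-bio"):
        for kind in ("prob-task1", "prob-task2"):
            pops[(variant, kind)] = run_population(
                variant, 20, TaskSpec(kind=kind), 2000, 100, MASTER_SEED)
    return pops


@pytest.fixture(scope="session")
def choice_logs():
    """Actor-critic runs on both choice tasks (beta=2, 3000 trials)."""
    return {kind: run_choice_population("oVRNNbp-rev", 12, kind, 3000, 100,
                                        MASTER_SEED, beta=2.0)
            for kind in ("choice-1", "choice-2")}


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)
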