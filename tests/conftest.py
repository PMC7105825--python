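"""Shared fixtures: one full default-conditions run plus small truths.

The expensive end-to-end result (default study conditions: 2 chromosomes x
250 kb per subgenome, 7% homoeologous divergence, 30x capture depth, 0.1%
sequencing error, fixed seed) is computed once per session and shared by the
integration and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tetrasnp.simcore import SimConfig, simulate_tetraploid
from tetrasnp.workflow import WorkflowConfig, run_all

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_config() -> WorkflowConfig:
    return WorkflowConfig(sim=SimConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def run_result(default_config):
    """Full default run: simulate -> design -> sequence -> call -> map."""
    return run_all(default_config)


@pytest.fixture(scope="session")
def small_truth():
    """One-chromosome truth for cheap unit tests."""
    return simulate_tetraploid(
        SimConfig(n_chromosomes_per_subgenome=1, chromosome_length=250_000, seed=DEFAULT_SEED)
    )


@pytest.fixture(scope="session")
def megabase_truth():
    """A 1 Mb single-chromosome truth for statistical checks."""
    return simulate_tetraploid(
        SimConfig(n_chromosomes_per_subgenome=1, chromosome_length=1_000_000, seed=3)
    )


@pytest.fixture(scope="session")
def tiny_workflow_config() -> WorkflowConfig:
    """Laptop-second-scale workflow for smoke/CLI tests."""
    sim = SimConfig(
        n_chromosomes_per_subgenome=1,
        chromosome_length=100_000,
        n_class1_per_chromosome=4,
        n_class2_per_chromosome=6,
        n_resistance_per_chromosome=1,
        seed=7,
    )
    return WorkflowConfig(sim=sim, n_array_markers=60, merge_distance=20_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
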