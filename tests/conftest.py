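"""Shared fixtures.

The expensive session fixtures simulate reduced fast-regime islets
(260 cells, the size used for the reduced fast-model comparisons) once
and share them across the qualitative-reproduction tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from isletnet.funcnet import identify_hubs, threshold_network, tune_threshold
from isletnet.islet import build_islet
from isletnet.metrics import duty_cycles, pearson_matrix
from isletnet.simulate import SimulationConfig, simulate_islet

BATCH_SEEDS = (1, 2, 3, 4, 5)
BATCH_N_CELLS = 260


@pytest.fixture(scope="session")
def small_islet():
    return build_islet(30, model_tag="fast", seed=7)


@pytest.fixture(scope="session")
def sim_small():
    """A 10-cell simulated islet for integration-level checks."""
    islet = build_islet(10, model_tag="fast", seed=3)
    traces = simulate_islet(islet, config=SimulationConfig(seed=3))
    return islet, traces


@pytest.fixture(scope="session")
def coupling_sweep():
    """Reference/half/quarter coupling sweep with full-size ER nulls."""
    from isletnet.topology import coupling_sweep_analysis

    return coupling_sweep_analysis(
        n_cells=BATCH_N_CELLS, seeds=BATCH_SEEDS, null_size=1000
    )


@pytest.fixture(scope="session")
def fast_batch():
    """Five simulated 260-cell fast-regime islets with tuned networks."""
    out = []
    for seed in BATCH_SEEDS:
        islet = build_islet(BATCH_N_CELLS, model_tag="fast", seed=seed)
        traces = simulate_islet(islet, config=SimulationConfig(seed=seed))
        R = pearson_matrix(traces)
        tuning = tune_threshold(R)
        fnet = threshold_network(R, tuning.R_th)
        out.append(
            {
                "seed": seed,
                "islet": islet,
                "traces": traces,
                "R": R,
                "tuning": tuning,
                "fnet": fnet,
                "hubs": identify_hubs(fnet, method="threshold60"),
                "duty": duty_cycles(traces),
            }
        )
    return out
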