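"""Shared fixtures.

The stochastic network properties (K-switch irreversibility, resection
outcomes, response-delay ordering) are all assessed on one shared ensemble
of pathological-expansion runs so the suite integrates each condition only
once.
"""

from __future__ import annotations

import pytest

from epinmm.params import default_params
from epinmm.simulator import (integrate, expansion_protocol,
                              resection_protocol, matured_state)

N_SEEDS = 10
KB_VALUES = (8.0, 9.0, 10.0)
EXPANSION_DURATION = 500.0
RESECTION_DURATION = 300.0


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def expansion_runs():
    """Pathological-expansion time series per (k_B, seed).

    k_B in {8, 9, 10}, k_G = 20, 500 s from the consolidated-potentiated
    state, shared p(t)/B-noise streams per seed across k_B.
    """
    out = {}
    for kb in KB_VALUES:
        for seed in range(N_SEEDS):
            p, proto = expansion_protocol(k_B=kb, k_G=20.0, seed=seed,
                                          duration=EXPANSION_DURATION)
            out[(kb, seed)] = (p, integrate(p, proto))
    return out


@pytest.fixture(scope="session")
def resection_runs():
    """Post-resection continuations (A^(1) = 0) from quiescent matured
    states, per (k_B, seed) for k_B in {9, 10}."""
    out = {}
    for kb in (9.0, 10.0):
        for seed in range(N_SEEDS):
            p, st = matured_state(kb, 20.0, seed=seed,
                                  duration=EXPANSION_DURATION)
            out[(kb, seed)] = (p, resection_protocol(
                st, p, duration=RESECTION_DURATION, seed=seed + 1000))
    return out


@pytest.fixture(scope="session")
def gate_closed_runs():
    """Expansion-style runs in which the synapse never potentiates (high
    potentiation threshold, depressed start), so Us stays below the
    spillover gate throughout."""
    out = []
    for seed in range(N_SEEDS):
        p, proto = expansion_protocol(k_B=9.0, k_G=20.0, seed=seed,
                                      duration=EXPANSION_DURATION,
                                      theta=(0.3, 1.5), potentiated=False)
        out.append((p, integrate(p, proto)))
    return out


@pytest.fixture(scope="session")
def nmm1_branch(params):
    """Continuation of the primary focus's fast subsystem over B in [0, 60]."""
    from epinmm.analysis import trace_branch, detect_bifurcations
    branch = trace_branch(params.pop1.fast, (0.0, 60.0))
    return branch, detect_bifurcations(branch)
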