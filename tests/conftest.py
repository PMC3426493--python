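from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import parasym as ps

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: power-scenario tree: outgroup four times the duplicate branches, the
#: regime where parsimony ancestors remain informative
POWER_TREE = {"copy1": 0.45, "copy2": 0.45, "outgroup": 1.8}


def make_trio(seq1, seq2, seqo, pair_id="t"):
    return ps.CodonTrioAlignment(pair_id, seq1, seq2, seqo)


@pytest.fixture(scope="session")
def null_trio():
    """One 2,000-codon trio from the default (neutral, symmetric) null
    scenario."""
    scen = ps.SimulationScenario(n_codons=2000, seed=8)
    trio, _ = ps.simulate_trio(scen, pair_id="null")
    return trio


@pytest.fixture(scope="session")
def asymmetric_trio():
    """Strongly asymmetric pair (omega 1.5 vs 0.2) on the power tree."""
    scen = ps.SimulationScenario(
        n_codons=1000, seed=11, t_by_branch=POWER_TREE,
        omega_by_branch={"copy1": 1.5, "copy2": 0.2, "outgroup": 0.5},
    )
    trio, _ = ps.simulate_trio(scen, pair_id="asym")
    return trio


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
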