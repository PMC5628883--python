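"""Shared fixtures: the calibrated default model and derived reference doses.

Session-scoped so the (cheap but non-trivial) vehicle pre-equilibration and
EC50 bisections run once per test session.
"""

import numpy as np
import pytest

from mapkdual import (FeedbackConfig, ViabilityLink, build_network,
                      default_inhibitors, load_default_parameters)
from mapkdual.network import DrugTarget, output_ec50


@pytest.fixture(scope="session")
def params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def inhibitors():
    return default_inhibitors()


@pytest.fixture(scope="session")
def kras_network(params, inhibitors):
    """Calibrated KRAS-mutant (RAS-coupled, all feedbacks on) network."""
    net = build_network(params, FeedbackConfig(), inhibitors)
    net.vehicle_steady_state()  # warm the cache
    return net


@pytest.fixture(scope="session")
def reference_doses(kras_network):
    """Single-agent output-EC50s of the calibrated model (nM)."""
    return {
        "mek": output_ec50(kras_network, DrugTarget.MEK),
        "erk": output_ec50(kras_network, DrugTarget.ERK),
    }


@pytest.fixture(scope="session")
def link():
    return ViabilityLink()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
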