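"""Shared fixtures: tiny hand-built networks and planted synthetic ones."""

from pathlib import Path

import numpy as np
import pytest

from netsplitter import StoichiometricNetwork, SyntheticSpec, generate_synthetic

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


def make_net(mets, rxns, S, reversible=None, external=None, names=None):
    S = np.asarray(S, float)
    return StoichiometricNetwork(
        list(mets),
        list(rxns),
        S,
        np.zeros(S.shape[1], bool) if reversible is None else np.asarray(reversible, bool),
        np.zeros(S.shape[0], bool) if external is None else np.asarray(external, bool),
        names,
    )


@pytest.fixture
def ab_net():
    """A -> B, both internal."""
    return make_net(["A", "B"], ["r1"], [[-1], [1]])


@pytest.fixture
def chain_net():
    """A -> B -> C, all internal."""
    return make_net(["A", "B", "C"], ["r1", "r2"], [[-1, 0], [1, -1], [0, 1]])


@pytest.fixture
def two_module_net():
    """Planted 2-module network with one bridge and two currency metabolites."""
    net, truth = generate_synthetic(SyntheticSpec(module_count=2, module_size=10, seed=1))
    return net, truth
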