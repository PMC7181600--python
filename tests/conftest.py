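"""Shared fixtures and graph factories for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cranionet import BoneNetwork, SkullTemplate, SpecimenMeta, make_skull

# keep hypothesis fully deterministic and file-free
settings.register_profile("repro", database=None, deadline=None,
                          derandomize=True)
settings.load_profile("repro")


def net_from_adjacency(adj, labels=None, allow_disconnected=False,
                       specimen_id="test"):
    """Build a BoneNetwork from a 0/1 matrix with generic midline labels."""
    from cranionet.netio import BoneLabel, Side

    adj = np.asarray(adj, dtype=int)
    n = adj.shape[0]
    if labels is None:
        labels = [f"b{i:02d}_M" for i in range(n)]
    parsed = [BoneLabel.parse(l) for l in labels]
    return BoneNetwork(parsed, adj, SpecimenMeta(specimen_id=specimen_id),
                       allow_disconnected=allow_disconnected)


def complete_graph(n):
    a = np.ones((n, n), dtype=int)
    np.fill_diagonal(a, 0)
    return a


def path_graph(n):
    a = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


def random_connected_adjacency(n, rng, p=0.35):
    """Random G(n, p) conditioned on connectivity via a random spanning tree."""
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, k=1)
    a = a + a.T
    order = rng.permutation(n)
    for i in range(1, n):  # spanning tree guarantees connectivity
        j = order[rng.integers(i)]
        a[order[i], j] = a[j, order[i]] = 1
    np.fill_diagonal(a, 0)
    return a


@pytest.fixture(scope="session")
def skull():
    return make_skull(SkullTemplate(seed=1))


@pytest.fixture(scope="session")
def skull_template():
    return SkullTemplate(seed=1)
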