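import itertools

import numpy as np
import pytest

from pyroclean import (
    ReferenceAlignment,
    build_consensus,
    simulate_reads,
    simulate_templates,
)


@pytest.fixture(scope="session")
def templates():
    """Default 27-template community (220 nt, pairwise divergence 1-60)."""
    return simulate_templates(seed=11)


@pytest.fixture(scope="session")
def template_consensus(templates):
    """Inclusive ambiguity consensus over the template set."""
    return build_consensus(ReferenceAlignment(tuple(templates.values())))


@pytest.fixture(scope="session")
def small_simulation(templates):
    """A modest noisy read set with numts, shared across tests for speed."""
    reads, truth = simulate_reads(templates, n_reads=3000, seed=12)
    return reads, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def pairwise_distances(seqs):
    return [
        sum(a != b for a, b in zip(x, y))
        for x, y in itertools.combinations(seqs, 2)
    ]
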