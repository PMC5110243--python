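"""Shared fixtures: one default synthetic dataset reused across suites."""

from __future__ import annotations

import pytest

from cortexdev import FetalReference, SimConfig, gen_expression


@pytest.fixture(scope="session")
def default_sim():
    """Default-config simulation: (matrix, meta, truth)."""
    return gen_expression(SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_truth(default_sim):
    return default_sim[2]


@pytest.fixture(scope="session")
def default_matrix(default_sim):
    return default_sim[0]


@pytest.fixture(scope="session")
def fetal_reference():
    """Independent default-config draw standing in for a labelled reference."""
    matrix, _, truth = gen_expression(SimConfig(seed=1000))
    return FetalReference(matrix=matrix, types=truth.true_type)


@pytest.fixture(scope="session")
def marker_genes(default_truth):
    """NSPC + neuron + BP marker genes of the default simulation."""
    t = default_truth
    return t.signature_genes["NSPC"] + t.signature_genes["neuron"] + t.bp_genes


@pytest.fixture(scope="session")
def trajectory_genes(default_truth, marker_genes):
    """Marker genes plus the species-shifted progenitor genes."""
    return marker_genes + list(default_truth.species_shift_genes.index)
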