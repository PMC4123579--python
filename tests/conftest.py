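"""Shared fixtures: a scaled-down synthetic bundle and derived objects.

The session bundle uses the generator defaults (two 15-vs-15 cell-type
contrasts, 20 planted reporter enzymes at a 2-SD shift, six compartments)
with a fixed seed, so every test sees the same study-like inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

from enzynet.io import gene_pvalues_from_expression
from enzynet.localization import CompartmentScheme, partition_enzymes
from enzynet.network import build_enzyme_network
from enzynet.synthetic import SyntheticConfig, generate_bundle

SESSION_SEED = 11


@pytest.fixture(scope="session")
def bundle():
    return generate_bundle(SyntheticConfig(seed=SESSION_SEED))


@pytest.fixture(scope="session")
def overall_net(bundle):
    return build_enzyme_network(
        bundle.reactions, currency_compounds=bundle.currency_compounds
    )


@pytest.fixture(scope="session")
def pvalues(bundle):
    return {
        cell_type: gene_pvalues_from_expression(ds)
        for cell_type, ds in bundle.expression.items()
    }


@pytest.fixture(scope="session")
def partition(bundle, overall_net):
    return partition_enzymes(
        overall_net,
        bundle.annotations,
        bundle.gene_map,
        bundle.ontology,
        CompartmentScheme(),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
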