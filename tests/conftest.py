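"""Shared fixtures: small featurized molecule sets and synthetic studies.

Conformer embedding dominates featurization cost, so featurized graph sets
are session-scoped and reused across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import semiquant as sq


@pytest.fixture(scope="session")
def molecules40():
    """40 grammar molecules with β targets (noise_sd 0.1)."""
    mols = sq.generate_molecules(40, seed=11)
    return sq.assign_beta(mols, 0.1, seed=12)


@pytest.fixture(scope="session")
def graphs40(molecules40):
    return [sq.featurize_smiles(m.smiles, m.molecule_id) for m in molecules40]


@pytest.fixture(scope="session")
def targets40(molecules40):
    return np.array([m.target for m in molecules40])


@pytest.fixture(scope="session")
def counts40(molecules40):
    return sq.count_descriptor_table(
        [m.smiles for m in molecules40], [m.molecule_id for m in molecules40]
    )


@pytest.fixture(scope="session")
def zero_noise_study():
    """Noise-free dilution study: preprocessing must recover β exactly."""
    spec = sq.SyntheticSpec(
        n_molecules=25, signal_noise_cv=0.0, beta_noise_sd=0.2, outlier_fraction=0.0, seed=5
    )
    return spec, sq.simulate_study(spec)


def permute_graph(graph: sq.MolGraph, perm: np.ndarray) -> sq.MolGraph:
    """Relabel nodes by ``perm`` (node i -> perm[i]), consistently."""
    n = graph.n_nodes
    feats = np.empty_like(graph.node_features)
    feats[perm] = graph.node_features
    edges = [(min(perm[i], perm[j]), max(perm[i], perm[j])) for i, j in graph.edges]
    return sq.MolGraph(
        molecule_id=graph.molecule_id,
        n_nodes=n,
        edges=sorted(edges),
        node_features=feats,
        node_order=[int(perm[i]) for i in graph.node_order],
        smiles=graph.smiles,
    )
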