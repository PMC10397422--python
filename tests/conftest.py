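import numpy as np
import pytest

import dtismooth as dm
from dtismooth.features import (
    DrugFeatureConfig,
    assemble_initial_features,
    encode_drug_structures,
    encode_protein_sequences,
    l2_normalize_rows,
    reduce_dimensionality,
)


@pytest.fixture
def two_node():
    """Smallest nontrivial network: one drug, one target, one interaction."""
    return dm.build_hbin(["d1"], ["t1"], [("d1", "t1")])


@pytest.fixture
def path3():
    """3-node path d1 - t1 - d2 (node order: d1, d2, t1)."""
    return dm.build_hbin(["d1", "d2"], ["t1"], [("d1", "t1"), ("d2", "t1")])


@pytest.fixture
def random_hbin():
    """Connected random bipartite fixture for oracle comparisons."""
    return dm.generate_connected_hbin(12, 10, extra_edge_prob=0.2, seed=7)


def dense_abar(hbin, r=0.5):
    """Independent dense construction of the normalized operator."""
    a = hbin.adjacency.toarray()
    atil = a + np.eye(a.shape[0])
    dtil = a.sum(axis=1) + 1.0
    return np.diag(dtil ** (r - 1.0)) @ atil @ np.diag(dtil ** (-r))


def dense_stationary(hbin, r=0.5):
    """Closed-form limit computed naively, node pair by node pair."""
    a = hbin.adjacency.toarray()
    n = a.shape[0]
    dtil = a.sum(axis=1) + 1.0
    # component labels by BFS on A + I
    labels = -np.ones(n, dtype=int)
    label = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        stack = [start]
        labels[start] = label
        while stack:
            u = stack.pop()
            for v in np.nonzero(a[u])[0]:
                if labels[v] < 0:
                    labels[v] = label
                    stack.append(v)
        label += 1
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                z = dtil[labels == labels[i]].sum()
                out[i, j] = dtil[i] ** r * dtil[j] ** (1 - r) / z
    return out


def synthetic_features(hbin, seqs_seed=1, reducer="truncated-svd", groups=None):
    """Initial feature matrix for a synthetic network (normalized rows)."""
    n_d, n_t = hbin.catalog.n_drugs, hbin.catalog.n_targets
    smiles = dm.toy_smiles_catalog(min(n_d, 72))
    smiles = [smiles[i % len(smiles)] for i in range(n_d)]
    seqs = dm.generate_sequences(n_t, seed=seqs_seed, groups=groups)
    cfg = DrugFeatureConfig(reducer=reducer, seed=0)
    c_d = reduce_dimensionality(encode_drug_structures(smiles, cfg), cfg)
    c_t = encode_protein_sequences(seqs)
    C = assemble_initial_features(c_d, c_t, hbin.catalog)
    return l2_normalize_rows(C.values)
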