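"""Bipartite drug-target interaction networks and their propagation operators.

The heterogeneous biological information network (HBIN) used here is a
bipartite graph: drug nodes on one side, protein-target nodes on the other,
edges are known drug-target interactions (DTIs). Feature propagation runs on
the self-loop-augmented, degree-normalized adjacency

    Abar = (D + I)^(r-1) (A + I) (D + I)^(-r),      r in [0, 1],

whose powers converge, per connected component, to a closed-form stationary
matrix with entries proportional to (d_i + 1)^r (d_j + 1)^(1-r).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "NodeCatalog",
    "Hbin",
    "PropagationOperator",
    "StationaryMatrix",
    "build_hbin",
    "operator_from_adjacency",
    "normalize_operator",
    "stationary_matrix",
]


@dataclass(frozen=True)
class NodeCatalog:
    """Global node indexing: drugs occupy 0..n_drugs-1, targets follow."""

    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.drug_ids:
            raise ValueError("drug id list is empty")
        if not self.target_ids:
            raise ValueError("target id list is empty")
        all_ids = self.drug_ids + self.target_ids
        if len(set(all_ids)) != len(all_ids):
            seen: set[str] = set()
            dup = next(i for i in all_ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate node id: {dup!r}")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_drugs + self.n_targets

    def drug_index(self, drug_id: str) -> int:
        return self.drug_ids.index(drug_id)

    def target_index(self, target_id: str) -> int:
        """Global index of a target (offset by the drug block)."""
        return self.n_drugs + self.target_ids.index(target_id)

    def node_id(self, index: int) -> str:
        if index < self.n_drugs:
            return self.drug_ids[index]
        return self.target_ids[index - self.n_drugs]


@dataclass(frozen=True)
class Hbin:
    """Bipartite interaction network with a symmetric 0/1 adjacency.

    ``edges`` hold global-index pairs (drug_index, target_index); the
    drug-drug and target-target blocks of ``adjacency`` are structurally
    zero, and the diagonal is zero (self-loops live in the operator only).
    """

    catalog: NodeCatalog
    edges: frozenset[tuple[int, int]]
    adjacency: sp.csr_matrix = field(repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


def build_hbin(
    drug_ids: list[str],
    target_ids: list[str],
    interactions: list[tuple[str, str]],
) -> Hbin:
    """Assemble the bipartite network from id lists and an interaction list.

    Duplicate interactions are collapsed; an interaction naming an unknown
    drug or target is rejected with the offending pair.
    """
    catalog = NodeCatalog(tuple(drug_ids), tuple(target_ids))
    d_index = {d: i for i, d in enumerate(catalog.drug_ids)}
    t_index = {t: catalog.n_drugs + j for j, t in enumerate(catalog.target_ids)}

    edges: set[tuple[int, int]] = set()
    for drug_id, target_id in interactions:
        if drug_id not in d_index or target_id not in t_index:
            raise ValueError(
                f"interaction references unknown node: ({drug_id!r}, {target_id!r})"
            )
        edges.add((d_index[drug_id], t_index[target_id]))

    n = catalog.n_nodes
    if edges:
        rows, cols = zip(*edges)
        rows = np.fromiter(rows, dtype=np.int64, count=len(edges))
        cols = np.fromiter(cols, dtype=np.int64, count=len(edges))
        data = np.ones(len(edges), dtype=np.float64)
        upper = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
        adjacency = (upper + upper.T).tocsr()
    else:
        adjacency = sp.csr_matrix((n, n), dtype=np.float64)
    return Hbin(catalog=catalog, edges=frozenset(edges), adjacency=adjacency)


@dataclass(frozen=True)
class PropagationOperator:
    """Normalized operator Abar = (D+I)^(r-1) (A+I) (D+I)^(-r).

    ``degrees`` are degrees in A (no self-loop); ``components`` labels the
    connected components of A+I (same partition as A, isolated nodes are
    singleton components).
    """

    r: float
    abar: sp.csr_matrix = field(repr=False)
    degrees: np.ndarray = field(repr=False)
    components: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return self.abar.shape[0]


def operator_from_adjacency(a: sp.spmatrix, r: float = 0.5) -> PropagationOperator:
    """Normalized operator from a symmetric 0/1 adjacency matrix.

    r = 0.5 gives the symmetric normalization (Abar symmetric); r = 1 gives
    the row-stochastic random-walk operator.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"convolutional coefficient r must be in [0, 1], got {r}")
    a = sp.csr_matrix(a, dtype=np.float64)
    n = a.shape[0]
    deg = np.asarray(a.sum(axis=1)).ravel()
    dtil = deg + 1.0
    atil = (a + sp.identity(n, format="csr")).tocsr()
    left = sp.diags(dtil ** (r - 1.0))
    right = sp.diags(dtil ** (-r))
    abar = (left @ atil @ right).tocsr()
    _, labels = connected_components(atil, directed=False)
    return PropagationOperator(r=r, abar=abar, degrees=deg, components=labels)


def normalize_operator(hbin: Hbin, r: float = 0.5) -> PropagationOperator:
    """Build the self-loop-augmented normalized propagation operator."""
    return operator_from_adjacency(hbin.adjacency, r=r)


@dataclass(frozen=True)
class StationaryMatrix:
    """Closed-form limit of Abar^k.

    Within a connected component c, the limiting entry is
    (d_i+1)^r (d_j+1)^(1-r) / Z_c with Z_c = sum over the component of
    (d_v+1); across components it is zero. For a connected graph
    Z = 2|E| + |V|. An isolated node's row is its own indicator.
    """

    r: float
    degrees: np.ndarray = field(repr=False)
    components: np.ndarray = field(repr=False)
    z_by_component: np.ndarray = field(repr=False)

    def row(self, i: int) -> np.ndarray:
        dtil = self.degrees + 1.0
        mask = self.components == self.components[i]
        out = np.zeros_like(dtil)
        z = self.z_by_component[self.components[i]]
        out[mask] = (dtil[i] ** self.r) * (dtil[mask] ** (1.0 - self.r)) / z
        return out

    def toarray(self) -> np.ndarray:
        dtil = self.degrees + 1.0
        n = dtil.size
        same = self.components[:, None] == self.components[None, :]
        z = self.z_by_component[self.components]
        mat = (dtil[:, None] ** self.r) * (dtil[None, :] ** (1.0 - self.r)) / z[:, None]
        mat[~same] = 0.0
        return mat


def stationary_matrix(op: PropagationOperator) -> StationaryMatrix:
    """Per-component stationary influence distribution of the operator."""
    dtil = op.degrees + 1.0
    n_comp = int(op.components.max()) + 1
    z = np.zeros(n_comp)
    np.add.at(z, op.components, dtil)
    return StationaryMatrix(
        r=op.r, degrees=op.degrees, components=op.components, z_by_component=z
    )
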