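"""Node-dependent local smoothing (NDLS) of node features.

Each node i receives its own propagation depth

    k_i = min{ k >= k_min : || Qbar_i^(inf) - Qbar_i^(k) ||_2 < epsilon },

where Qbar_i^(k) is row i of Abar^k (the influence distribution reaching i
after k propagation steps) and Qbar_i^(inf) its closed-form stationary
limit. The smoothed embedding of node i is the running average of its
feature vector over depths 0..k_i — deep enough to absorb neighborhood
context, shallow enough to stop before the stationary collapse that causes
over-smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .hbin import (
    Hbin,
    PropagationOperator,
    StationaryMatrix,
    normalize_operator,
    operator_from_adjacency,
    stationary_matrix,
)

__all__ = [
    "NdlsConfig",
    "DepthAssignment",
    "SmoothedEmbeddings",
    "NDLSSmoother",
    "propagate",
    "influence_row",
    "ndls_depth",
    "assign_depths",
    "smooth_embeddings",
    "smooth_all",
]


@dataclass(frozen=True)
class NdlsConfig:
    """Tolerance and depth bounds for the per-node depth search.

    epsilon: distance-to-stationarity tolerance (smaller -> deeper).
    k_min: floor of 1 — depth 0 would return raw, unpropagated features.
    k_max: truncation guard against slow-mixing components.
    """

    epsilon: float = 1e-4
    k_max: int = 200
    k_min: int = 1

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")


@dataclass(frozen=True)
class DepthAssignment:
    depths: np.ndarray
    epsilon: float
    truncated: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class SmoothedEmbeddings:
    """Per-node averaged embeddings X with the depth each row used."""

    X: np.ndarray
    depths: np.ndarray


def propagate(
    C: np.ndarray, op: PropagationOperator, k: int, return_all: bool = False
):
    """X^(k) = Abar^k C by repeated sparse products; X^(0) = C.

    With return_all=True the whole trajectory [X^(0), ..., X^(k)] is
    returned.
    """
    C = np.asarray(C, dtype=np.float64)
    if k < 0:
        raise ValueError("depth k must be non-negative")
    if C.shape[0] != op.n_nodes:
        raise ValueError(
            f"feature matrix has {C.shape[0]} rows for {op.n_nodes} nodes"
        )
    x = C
    trajectory = [x]
    for _ in range(k):
        x = op.abar @ x
        if return_all:
            trajectory.append(x)
    return trajectory if return_all else x


def influence_row(op: PropagationOperator, i: int, k: int) -> np.ndarray:
    """Row i of Abar^k via k sparse vector-matrix products.

    Abar^k itself is never materialized: q_k = q_{k-1} Abar starting from
    the one-hot vector at i.
    """
    if not 0 <= i < op.n_nodes:
        raise ValueError(f"node index {i} out of range")
    if k < 0:
        raise ValueError("depth k must be non-negative")
    q = np.zeros(op.n_nodes)
    q[i] = 1.0
    for _ in range(k):
        q = q @ op.abar
    return q


def ndls_depth(
    op: PropagationOperator,
    stationary: StationaryMatrix,
    i: int,
    cfg: NdlsConfig | None = None,
) -> tuple[int, bool]:
    """Minimal depth at which node i's influence row is epsilon-close to
    its stationary limit. Returns (depth, truncated)."""
    cfg = cfg or NdlsConfig()
    target = stationary.row(i)
    q = np.zeros(op.n_nodes)
    q[i] = 1.0
    for k in range(1, cfg.k_max + 1):
        q = q @ op.abar
        if k >= cfg.k_min and np.linalg.norm(target - q) < cfg.epsilon:
            return k, False
    return cfg.k_max, True


def assign_depths(
    op: PropagationOperator,
    stationary: StationaryMatrix,
    cfg: NdlsConfig | None = None,
) -> DepthAssignment:
    """Depths for every node in one shared power sweep.

    Iterates P_k = Abar P_{k-1} from the identity, recording for each node
    the first k >= k_min at which its row is within epsilon of the
    stationary row.
    """
    cfg = cfg or NdlsConfig()
    n = op.n_nodes
    target = stationary.toarray()
    depths = np.zeros(n, dtype=np.int64)
    p = np.eye(n)
    unresolved = np.ones(n, dtype=bool)
    for k in range(1, cfg.k_max + 1):
        p = op.abar @ p
        if k < cfg.k_min:
            continue
        if unresolved.any():
            dist = np.linalg.norm(target[unresolved] - p[unresolved], axis=1)
            hit = dist < cfg.epsilon
            idx = np.flatnonzero(unresolved)[hit]
            depths[idx] = k
            unresolved[idx] = False
        if not unresolved.any():
            break
    truncated = unresolved.copy()
    depths[truncated] = cfg.k_max
    return DepthAssignment(depths=depths, epsilon=cfg.epsilon, truncated=truncated)


def smooth_embeddings(
    C: np.ndarray, op: PropagationOperator, depths: DepthAssignment
) -> SmoothedEmbeddings:
    """X_i = mean of X_i^(0..k_i), in a single sweep to max(k_i).

    The running sum is frozen row-by-row as each node reaches its assigned
    depth, so no per-node propagation is repeated.
    """
    C = np.asarray(C, dtype=np.float64)
    if C.shape[0] != op.n_nodes:
        raise ValueError(
            f"feature matrix has {C.shape[0]} rows for {op.n_nodes} nodes"
        )
    k_arr = depths.depths
    if k_arr.shape[0] != op.n_nodes:
        raise ValueError("depth assignment does not cover all nodes")
    x = C
    acc = C.copy()
    for k in range(1, int(k_arr.max()) + 1):
        x = op.abar @ x
        active = k_arr >= k
        acc[active] += x[active]
    X = acc / (k_arr[:, None] + 1.0)
    return SmoothedEmbeddings(X=X, depths=k_arr.copy())


def smooth_all(
    hbin: Hbin,
    C: np.ndarray,
    cfg: NdlsConfig | None = None,
    r: float = 0.5,
) -> tuple[SmoothedEmbeddings, DepthAssignment]:
    """Full smoothing stage: operator -> stationary -> depths -> averages."""
    cfg = cfg or NdlsConfig()
    op = normalize_operator(hbin, r=r)
    stat = stationary_matrix(op)
    depths = assign_depths(op, stat, cfg)
    emb = smooth_embeddings(C, op, depths)
    return emb, depths


class NDLSSmoother(BaseEstimator, TransformerMixin):
    """Transformer view of NDLS smoothing for a fixed graph.

    The graph (sparse symmetric 0/1 adjacency) is a parameter; the data are
    node feature matrices aligned with it. ``fit`` builds the operator and
    assigns per-node depths; ``transform`` averages the propagation
    trajectory of its input per node.

    Attributes after fit: operator_, stationary_, depths_, truncated_.
    """

    def __init__(
        self,
        adjacency: sp.spmatrix | None = None,
        r: float = 0.5,
        epsilon: float = 1e-4,
        k_max: int = 200,
        k_min: int = 1,
    ):
        self.adjacency = adjacency
        self.r = r
        self.epsilon = epsilon
        self.k_max = k_max
        self.k_min = k_min

    def _config(self) -> NdlsConfig:
        return NdlsConfig(epsilon=self.epsilon, k_max=self.k_max, k_min=self.k_min)

    def fit(self, X, y=None):
        if self.adjacency is None:
            raise ValueError("NDLSSmoother requires an adjacency matrix")
        a = sp.csr_matrix(self.adjacency, dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] != a.shape[0]:
            raise ValueError("feature rows must match adjacency size")
        self.operator_ = operator_from_adjacency(a, r=self.r)
        self.stationary_ = stationary_matrix(self.operator_)
        assignment = assign_depths(self.operator_, self.stationary_, self._config())
        self.depths_ = assignment.depths
        self.truncated_ = assignment.truncated
        self._assignment = assignment
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return smooth_embeddings(
            np.asarray(X, dtype=np.float64), self.operator_, self._assignment
        ).X
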