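"""Correlation network of aerobic features and Newman modularity clustering.

Each of the 51 aerobic features is a node; the Spearman rank correlation of
two features across subjects weighs the edge between them.  Keeping only the
top 30% of pairwise correlations (by absolute value) yields a sparse
network whose community structure is found by Newman's leading-eigenvector
method: the modularity

    Q = (1/4m) * sum_ij (A_ij - k_i k_j / 2m) (S_i S_j + 1)

is maximized by recursive spectral bisection, each split accepted only when
its modularity gain dQ (computed from the generalized subgroup modularity
matrix) is positive.  Edge weights are absolute correlations (modularity
assumes non-negative weights); ``k`` is node strength and ``m`` total edge
weight in the weighted mode, plain degree/edge count in the binary mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConstantColumnError, DataValidationError, UndefinedModularityError
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "FeatureNetwork",
    "Partition",
    "correlation_matrix",
    "build_network",
    "modularity",
    "modularity_from_labels",
    "spectral_bisect",
    "cluster",
    "ModularityClustering",
]

#: dQ below this is treated as "no positive split".
DEFAULT_TOL = 1e-10


def correlation_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation matrix of the feature columns.

    Requires at least 4 subjects and no missing values; constant columns
    make the rank correlation undefined and raise a named error.  The
    result is symmetric with an exact unit diagonal.
    """
    if len(features) < 4:
        raise DataValidationError("need at least 4 subjects for a correlation matrix")
    if features.isna().any().any():
        bad = features.columns[features.isna().any()].tolist()
        raise DataValidationError(f"missing values in column(s): {bad}")
    constant = features.columns[features.nunique() <= 1].tolist()
    if constant:
        raise ConstantColumnError(constant)
    corr = features.corr(method="spearman")
    np.fill_diagonal(corr.values, 1.0)
    return (corr + corr.T) / 2.0


@dataclass
class FeatureNetwork:
    """Weighted undirected feature graph.

    ``adjacency`` is symmetric, non-negative, zero diagonal; ``strengths``
    are its row sums and ``total_weight`` m = (1/2) sum_ij A_ij.
    """

    names: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.shape != (len(self.names), len(self.names)):
            raise DataValidationError("adjacency shape does not match node count")
        if not np.allclose(A, A.T):
            raise DataValidationError("adjacency must be symmetric")
        if (A < 0).any():
            raise DataValidationError("adjacency weights must be non-negative")
        np.fill_diagonal(A, 0.0)
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def strengths(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def total_weight(self) -> float:
        return float(self.adjacency.sum() / 2.0)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    def edges(self) -> list[tuple[str, str, float]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return [(self.names[a], self.names[b], float(self.adjacency[a, b]))
                for a, b in zip(i, j)]


def build_network(
    corr: pd.DataFrame,
    top_fraction: float = 0.30,
    *,
    weighted: bool = True,
) -> FeatureNetwork:
    """Threshold a correlation matrix into a feature network.

    The C(n,2) off-diagonal pairs are ranked by absolute correlation and the
    top ``ceil(top_fraction * C(n,2))`` become edges (weight = |rho|, or 1 in
    binary mode).  Ties at the cutoff are broken by lexical order of the
    feature-name pair, so the construction is deterministic.  All nodes are
    retained, isolated or not.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise DataValidationError("top_fraction must lie in (0, 1]")
    names = [str(c) for c in corr.columns]
    n = len(names)
    C = corr.to_numpy(dtype=float)
    iu, ju = np.triu_indices(n, k=1)
    weights = np.abs(C[iu, ju])
    n_pairs = len(iu)
    n_keep = int(np.ceil(top_fraction * n_pairs))
    pairs = sorted(
        range(n_pairs),
        key=lambda k: (-weights[k], names[iu[k]], names[ju[k]]),
    )[:n_keep]
    A = np.zeros((n, n))
    for k in pairs:
        w = 1.0 if not weighted else weights[k]
        A[iu[k], ju[k]] = A[ju[k], iu[k]] = w
    return FeatureNetwork(names=names, adjacency=A)


def _modularity_matrix(net: FeatureNetwork) -> np.ndarray:
    k = net.strengths
    m = net.total_weight
    if m <= 0:
        raise UndefinedModularityError("network has zero total edge weight")
    return net.adjacency - np.outer(k, k) / (2.0 * m)


def modularity(net: FeatureNetwork, S: np.ndarray) -> float:
    """Two-group modularity Q for a +/-1 membership vector S."""
    S = np.asarray(S, dtype=float)
    if S.shape != (net.n_nodes,) or not np.all(np.isin(S, (-1.0, 1.0))):
        raise DataValidationError("S must be a +/-1 vector over all nodes")
    B = _modularity_matrix(net)
    m = net.total_weight
    return float((S @ B @ S + B.sum()) / (4.0 * m))


def modularity_from_labels(net: FeatureNetwork, labels: np.ndarray) -> float:
    """Multi-group modularity: Q = (1/2m) sum_ij (A_ij - k_i k_j/2m) d(c_i,c_j)."""
    labels = np.asarray(labels)
    B = _modularity_matrix(net)
    m = net.total_weight
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum() / (2.0 * m))


def _fine_tune(Bg: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Vertex-moving refinement of a bisection sign vector.

    Repeated sweeps: each sweep moves every vertex exactly once, always the
    one whose side change most increases (least decreases) the quadratic
    form S'BgS, and keeps the best intermediate state; sweeps repeat while
    they improve.  This is the fine-tuning stage of the leading-eigenvector
    method; without it the raw eigenvector sign split can miss the optimal
    bisection even on small graphs.
    """
    n = len(S)
    S = S.copy()
    quad = float(S @ Bg @ S)
    improved = True
    while improved:
        improved = False
        moved = np.zeros(n, dtype=bool)
        best_quad, best_S = quad, S.copy()
        cur_S, cur_quad = S.copy(), quad
        Bs = Bg @ cur_S
        for _ in range(n):
            # gain of flipping each unmoved vertex i: -4*S_i*(Bs_i - Bg_ii*S_i)
            gains = -4.0 * cur_S * (Bs - np.diag(Bg) * cur_S)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            cur_quad += gains[i]
            Bs = Bs - 2.0 * cur_S[i] * Bg[:, i]
            cur_S[i] = -cur_S[i]
            moved[i] = True
            if cur_quad > best_quad + 1e-12:
                best_quad, best_S = cur_quad, cur_S.copy()
        if best_quad > quad + 1e-12:
            S, quad = best_S, best_quad
            improved = True
    return S


def spectral_bisect(
    net: FeatureNetwork,
    nodes: np.ndarray | None = None,
    *,
    tol: float = DEFAULT_TOL,
    fine_tune: bool = True,
) -> tuple[np.ndarray, float]:
    """Leading-eigenvector bisection of a (sub)group.

    The generalized subgroup modularity matrix restricted to ``nodes``
    subtracts the restricted row sums on the diagonal, so splitting a group
    mid-recursion scores exactly its contribution dQ to the global Q.  The
    split sign vector follows the leading eigenvector (zero entries join the
    +1 side) and is then refined by the vertex-moving fine-tuning sweep;
    when the leading eigenvalue or the resulting dQ is not positive the
    group is declared indivisible and an all-ones vector with dQ = 0 is
    returned.
    """
    if nodes is None:
        nodes = np.arange(net.n_nodes)
    nodes = np.asarray(nodes, dtype=int)
    if len(nodes) < 2:
        return np.ones(len(nodes)), 0.0
    B = _modularity_matrix(net)
    m = net.total_weight
    Bg = B[np.ix_(nodes, nodes)].copy()
    Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
    evals, evecs = np.linalg.eigh(Bg)
    lead = int(np.argmax(evals))
    if evals[lead] <= tol:
        return np.ones(len(nodes)), 0.0
    v = evecs[:, lead]
    S = np.where(v >= 0.0, 1.0, -1.0)  # zero entries -> +1 side
    if fine_tune:
        S = _fine_tune(Bg, S)
    dq = float(S @ Bg @ S) / (4.0 * m)
    if dq <= tol or np.all(S == S[0]):
        return np.ones(len(nodes)), 0.0
    return S, dq


@dataclass
class Partition:
    """Community assignment of the feature network."""

    names: list[str]
    labels: np.ndarray
    q: float
    tree: list[dict] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(np.unique(self.labels))

    def groups(self) -> list[list[str]]:
        out = []
        for g in sorted(np.unique(self.labels)):
            out.append([self.names[i] for i in np.nonzero(self.labels == g)[0]])
        return out

    def to_dict(self) -> dict:
        return {
            "groups": self.groups(),
            "Q": self.q,
            "tree": self.tree,
        }


def cluster(net: FeatureNetwork, *, tol: float = DEFAULT_TOL) -> Partition:
    """Recursive spectral bisection until no group divides with dQ > tol.

    Returns the final labels, the total modularity Q (recomputed from the
    labels; it equals the accumulated sum of accepted dQ up to numerical
    tolerance), and the division tree.
    """
    n = net.n_nodes
    labels = np.zeros(n, dtype=int)
    next_label = 1
    stack: list[np.ndarray] = [np.arange(n)]
    tree: list[dict] = []
    while stack:
        group = stack.pop()
        S, dq = spectral_bisect(net, group, tol=tol)
        if dq <= tol:
            tree.append({
                "nodes": [net.names[i] for i in group],
                "dQ": 0.0,
                "split": False,
            })
            continue
        left = group[S > 0]
        right = group[S < 0]
        labels[right] = next_label
        next_label += 1
        tree.append({
            "nodes": [net.names[i] for i in group],
            "dQ": dq,
            "split": True,
            "sizes": [int(len(left)), int(len(right))],
        })
        stack.append(right)
        stack.append(left)
    # relabel compactly in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    q = modularity_from_labels(net, labels)
    return Partition(names=list(net.names), labels=labels, q=q, tree=tree)


class ModularityClustering(BaseEstimator, ClusterMixin):
    """Cluster *features* of a cohort matrix by correlation-network modularity.

    ``fit(X)`` expects a subjects x features DataFrame: it computes the
    Spearman correlation matrix, keeps the top ``top_fraction`` of pairwise
    correlations as edges, and recursively bisects the network by the
    leading-eigenvector method.  ``labels_`` assigns a community to each
    *column* of ``X`` (this estimator clusters variables, not samples).

    Attributes (after fit): ``labels_``, ``modularity_``, ``network_``,
    ``partition_``, ``correlation_``.
    """

    def __init__(self, top_fraction: float = 0.30, weighted: bool = True,
                 tol: float = DEFAULT_TOL):
        self.top_fraction = top_fraction
        self.weighted = weighted
        self.tol = tol

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"f{i + 1}" for i in range(X.shape[1])]
        self.correlation_ = correlation_matrix(X)
        self.network_ = build_network(
            self.correlation_, self.top_fraction, weighted=self.weighted
        )
        self.partition_ = cluster(self.network_, tol=self.tol)
        self.labels_ = self.partition_.labels
        self.modularity_ = self.partition_.q
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
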