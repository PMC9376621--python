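"""Gaussian-affinity graph over normalized subject vectors.

Subjects become nodes of a fully connected edge-weighted undirected graph;
the weight between subjects i and j is exp(-d_ij^2 / sigma^2) with d the
Euclidean distance over the (normalized) attributes. The diagonal is zero:
no self-loops. The bandwidth sigma^2 defaults to the variance of the
pairwise Euclidean distances over the upper triangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["AffinityGraph", "pairwise_sq_distances", "gaussian_affinity",
           "export_affinity"]


@dataclass
class AffinityGraph:
    """Symmetric nonnegative affinity matrix with zero diagonal.

    Attributes
    ----------
    A : (M, M) ndarray
        Edge weights in [0, 1], a_ii = 0.
    sigma2 : float
        Kernel bandwidth actually used (the sigma^2 in the exponent).
    node_ids : (M,) ndarray
        Row indices into the source table.
    """

    A: np.ndarray
    sigma2: float
    node_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("affinity matrix must be square")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.node_ids is None:
            self.node_ids = np.arange(self.A.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


def pairwise_sq_distances(X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance matrix: entry (i,j) = sum_k (x_ik - x_jk)^2."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values present; impute before building the graph")
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    D = squareform(pdist(X, metric="sqeuclidean"))
    return D


def gaussian_affinity(X: np.ndarray, sigma2="auto") -> AffinityGraph:
    """Build the Gaussian-kernel affinity graph a_ij = exp(-d_ij^2 / sigma^2).

    Parameters
    ----------
    X : (M, n) ndarray
        Normalized feature rows, M >= 2, no missing values. Binary-encoded
        categoricals enter as ordinary 0/1 coordinates.
    sigma2 : float or {"auto", "auto_dist_var", "auto_sqdist_var"}
        Kernel bandwidth. ``"auto"`` (= ``"auto_dist_var"``) sets sigma^2 to
        the population variance of the M(M-1)/2 upper-triangle Euclidean
        distances; ``"auto_sqdist_var"`` uses the variance of the squared
        distances instead.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 rows")
    D2 = pairwise_sq_distances(X)
    iu = np.triu_indices_from(D2, k=1)
    if isinstance(sigma2, str):
        if sigma2 in ("auto", "auto_dist_var"):
            s2 = float(np.var(np.sqrt(D2[iu])))
        elif sigma2 == "auto_sqdist_var":
            s2 = float(np.var(D2[iu]))
        else:
            raise ValueError(f"unknown bandwidth rule {sigma2!r}")
        if s2 <= 0:
            raise ValueError(
                "pairwise distances have zero variance (identical points?); "
                "pass an explicit numeric bandwidth"
            )
    else:
        s2 = float(sigma2)
        if s2 <= 0:
            raise ValueError("sigma2 must be positive")
    A = np.exp(-D2 / s2)
    np.fill_diagonal(A, 0.0)
    # exact symmetry guards replicator determinism downstream
    A = (A + A.T) / 2.0
    return AffinityGraph(A=A, sigma2=s2)


def export_affinity(graph: AffinityGraph, path, delimiter=",") -> None:
    """Write the dense affinity matrix for external inspection."""
    np.savetxt(path, graph.A, delimiter=delimiter)
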