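"""Dominant-set clustering by replicator dynamics with a peeling-off loop.

A dominant set is a graph-theoretic cluster: a subset S of nodes of an
edge-weighted graph whose internal node weights W_S(i) are all positive
(internal homogeneity) while every external node would join with
non-positive weight (maximality). Dominant sets correspond to (strict)
local maximizers of the quadratic form f(z) = z'Az over the standard
simplex; their supports are found by running the replicator dynamics

    z_i  <-  z_i (Az)_i / (z'Az)

which keeps z on the simplex and monotonically increases f. Clustering
proceeds by *peeling off*: extract a dominant set, delete its nodes from
the graph, repeat. The number of clusters is therefore discovered, not
prescribed, and loosely structured leftovers stay together as a residual
"clutter" group instead of being forced into a coherent cluster.

The combinatorial weights W_S(i) are exponential in |S| and are used only
for verification and diagnostics (and by the brute-force oracle); the
production path is the replicator dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = [
    "CharacteristicVector",
    "DominantSetPartition",
    "relative_similarity",
    "node_weight",
    "set_weight",
    "is_dominant_set",
    "replicator_dynamics",
    "extract_dominant_set",
    "peel_off",
    "brute_force_dominant_sets",
]

#: numerical zero for the strict/non-strict weight sign tests
_SIGN_TOL = 1e-12


def _check_A(A) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("affinity matrix must be square")
    return A


# ---------------------------------------------------------------------------
# Combinatorial weights (Pavan–Pelillo), used in verification and the oracle
# ---------------------------------------------------------------------------

def relative_similarity(A, S, i: int, j: int) -> float:
    """phi_S(i, j) = a_ij - mean_{k in S} a_jk, the similarity of node i to
    j relative to j's average affinity within S. May be negative. j must
    belong to S; i is typically (not necessarily) outside S."""
    A = _check_A(A)
    S = sorted(set(int(s) for s in S))
    if not S:
        raise ValueError("S must be nonempty")
    if j not in S:
        raise ValueError(f"node {j} not in S={S}")
    return float(A[i, j] - A[j, list(S)].sum() / len(S))


class _WeightEngine:
    """Memoized evaluation of W_S(i) over subsets of one affinity matrix."""

    def __init__(self, A):
        self.A = _check_A(A)
        self._cache: dict[tuple[frozenset, int], float] = {}

    def node_weight(self, S, i: int) -> float:
        S = frozenset(int(s) for s in S)
        if i not in S:
            raise ValueError(f"node {i} not in S")
        return self._w(S, int(i))

    def _w(self, S: frozenset, i: int) -> float:
        if len(S) == 1:
            return 1.0
        key = (S, i)
        if key in self._cache:
            return self._cache[key]
        R = S - {i}
        Rl = sorted(R)
        mean_aff = self.A[np.ix_(Rl, Rl)].sum(axis=1) / len(Rl)  # over j in R
        total = 0.0
        for pos, j in enumerate(Rl):
            phi = self.A[i, j] - mean_aff[pos]  # phi_R(i, j), symmetric A
            total += phi * self._w(frozenset(R), j)
        self._cache[key] = total
        return total

    def set_weight(self, S) -> float:
        S = frozenset(int(s) for s in S)
        if not S:
            raise ValueError("S must be nonempty")
        return sum(self._w(S, i) for i in S)


def node_weight(A, S, i: int) -> float:
    """W_S(i): recursive cohesion weight of node i within S (1 if |S| = 1)."""
    return _WeightEngine(A).node_weight(S, i)


def set_weight(A, S) -> float:
    """W(S) = sum over i in S of W_S(i)."""
    return _WeightEngine(A).set_weight(S)


def is_dominant_set(A, S, engine: "_WeightEngine | None" = None):
    """Check the dominant-set conditions for S; returns (bool, diagnostics).

    Conditions: W(T) > 0 for every nonempty T within S, W_S(i) > 0 for all
    internal nodes, and W_{S+{i}}(i) <= 0 for every external node (boundary
    ties count as non-extending, which reproduces maximal-clique behaviour
    on unweighted graphs).
    """
    A = _check_A(A)
    S = sorted(set(int(s) for s in S))
    if not S:
        raise ValueError("S must be nonempty")
    eng = engine or _WeightEngine(A)
    diag = {"internal_violations": [], "subset_violations": [],
            "external_violations": []}
    for i in S:
        if eng.node_weight(S, i) <= _SIGN_TOL:
            diag["internal_violations"].append(i)
    for r in range(1, len(S)):
        for T in combinations(S, r):
            if eng.set_weight(T) <= _SIGN_TOL:
                diag["subset_violations"].append(tuple(T))
    outside = [i for i in range(A.shape[0]) if i not in S]
    for i in outside:
        if eng.node_weight(set(S) | {i}, i) > _SIGN_TOL:
            diag["external_violations"].append(i)
    ok = not (diag["internal_violations"] or diag["subset_violations"]
              or diag["external_violations"])
    return ok, diag


def brute_force_dominant_sets(A, max_nodes: int = 12) -> list[frozenset]:
    """Enumerate every nonempty subset and return all dominant sets.

    Exponential; a test oracle only. Refuses graphs above ``max_nodes``.
    """
    A = _check_A(A)
    M = A.shape[0]
    if M > max_nodes:
        raise ValueError(f"brute force limited to {max_nodes} nodes, got {M}")
    eng = _WeightEngine(A)
    found = []
    nodes = list(range(M))
    for r in range(1, M + 1):
        for S in combinations(nodes, r):
            ok, _ = is_dominant_set(A, S, engine=eng)
            if ok:
                found.append(frozenset(S))
    return found


# ---------------------------------------------------------------------------
# Replicator dynamics on the simplex
# ---------------------------------------------------------------------------

@dataclass
class CharacteristicVector:
    """A point on the standard simplex with its quadratic objective value."""

    z: np.ndarray
    objective: float
    iterations: int = 0
    converged: bool = False
    degenerate: bool = False
    support_eps: float = 1e-5
    trajectory: list = None  # optional per-iteration (z, f) pairs

    @property
    def support(self) -> np.ndarray:
        sup = np.flatnonzero(self.z > self.support_eps)
        return sup

    def check_simplex(self, tol: float = 1e-9) -> bool:
        return bool(np.all(self.z >= -tol) and abs(self.z.sum() - 1.0) <= tol)


def replicator_dynamics(A, z0="barycenter", max_iter: int = 1000,
                        min_increment: float = 1e-8,
                        support_eps: float = 1e-5,
                        record_trajectory: bool = False) -> CharacteristicVector:
    """Iterate z_i <- z_i (Az)_i / (z'Az) until the objective gain per step
    falls below ``min_increment`` or ``max_iter`` is reached.

    Starting from the barycenter (uniform 1/M) makes the trajectory — and
    hence the whole clustering — deterministic. If z'Az hits zero (isolated
    support, e.g. an empty graph) the current vector is returned flagged
    degenerate.
    """
    A = _check_A(A)
    M = A.shape[0]
    if isinstance(z0, str):
        if z0 != "barycenter":
            raise ValueError(f"unknown start {z0!r}")
        z = np.full(M, 1.0 / M)
    else:
        z = np.asarray(z0, dtype=float).copy()
        if z.shape != (M,) or np.any(z < 0) or abs(z.sum() - 1.0) > 1e-9:
            raise ValueError("z0 must lie on the standard simplex")
    f = float(z @ A @ z)
    traj = [(z.copy(), f)] if record_trajectory else None
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        Az = A @ z
        denom = float(z @ Az)
        if denom <= 0.0:
            return CharacteristicVector(z=z, objective=f, iterations=it - 1,
                                        converged=False, degenerate=True,
                                        support_eps=support_eps, trajectory=traj)
        z = z * Az / denom
        # renormalize to kill accumulated rounding on the simplex constraint
        z = z / z.sum()
        f_new = float(z @ A @ z)
        if record_trajectory:
            traj.append((z.copy(), f_new))
        if f_new - f < min_increment:
            f = f_new
            converged = True
            break
        f = f_new
    return CharacteristicVector(z=z, objective=f, iterations=it,
                                converged=converged, support_eps=support_eps,
                                trajectory=traj)


def extract_dominant_set(A, support_eps: float = 1e-5, max_iter: int = 1000,
                         min_increment: float = 1e-8):
    """Run the dynamics from the barycenter; return (support, vector).

    The support {i : z_i > support_eps} identifies the dominant set. If the
    dynamics degenerate (zero objective throughout, e.g. an edgeless graph)
    a singleton with the maximum-degree node is returned, flagged.
    """
    A = _check_A(A)
    if A.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    cv = replicator_dynamics(A, "barycenter", max_iter=max_iter,
                             min_increment=min_increment,
                             support_eps=support_eps)
    if cv.degenerate or cv.objective <= 0.0:
        fallback = int(np.argmax(A.sum(axis=1)))
        cv.degenerate = True
        return np.array([fallback]), cv
    return cv.support, cv


@dataclass
class DominantSetPartition:
    """Ordered disjoint clusters plus a residual (clutter) set."""

    clusters: list = field(default_factory=list)       # list of index arrays
    weights: list = field(default_factory=list)        # support weights per cluster
    residual: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    extraction_log: list = field(default_factory=list)
    n_nodes: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self, include_residual: bool = True) -> np.ndarray:
        """Cluster id per node; the residual gets the last id."""
        lab = np.full(self.n_nodes, -1, dtype=int)
        for cid, idx in enumerate(self.clusters):
            lab[idx] = cid
        if include_residual and self.residual.size:
            lab[self.residual] = len(self.clusters)
        return lab

    def to_csv(self, path) -> None:
        import csv

        lab = self.labels()
        wmap = {}
        for idx, w in zip(self.clusters, self.weights):
            for node, wi in zip(idx, w):
                wmap[int(node)] = float(wi)
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["node_id", "cluster_id", "support_weight"])
            for node in range(self.n_nodes):
                wr.writerow([node, int(lab[node]), wmap.get(node, 0.0)])


def peel_off(A, min_remaining: int = 2, support_eps: float = 1e-5,
             max_iter: int = 1000, min_increment: float = 1e-8) -> DominantSetPartition:
    """Iteratively extract dominant sets, removing their nodes each round.

    Stops when fewer than ``min_remaining`` nodes remain or an extraction
    degenerates; whatever is left becomes the residual clutter set. The
    cluster count is an outcome, never an input.
    """
    A = _check_A(A)
    M = A.shape[0]
    part = DominantSetPartition(n_nodes=M)
    remaining = np.arange(M)
    while remaining.size >= max(min_remaining, 2):
        sub = A[np.ix_(remaining, remaining)]
        support, cv = extract_dominant_set(sub, support_eps=support_eps,
                                           max_iter=max_iter,
                                           min_increment=min_increment)
        if cv.degenerate:
            break
        cluster = remaining[support]
        part.clusters.append(cluster)
        part.weights.append(cv.z[support].copy())
        part.extraction_log.append(
            {"iterations": cv.iterations, "objective": cv.objective,
             "size": int(cluster.size)})
        mask = np.ones(remaining.size, dtype=bool)
        mask[support] = False
        remaining = remaining[mask]
    part.residual = remaining
    return part
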