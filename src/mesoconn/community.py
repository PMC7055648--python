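"""Signed modularity maximization with a uniform null model.

The quality function is Q(gamma, {g_i}) = sum_{i != j} [A_ij - gamma] *
delta(g_i, g_j): the expected weight of every edge under the null is the
constant P_ij = 1 scaled by the resolution parameter gamma, which is the
appropriate null for correlation-derived matrices and sidesteps the
resolution limit of degree-preserving nulls.  The sum runs over ordered
pairs with the diagonal excluded, so the all-singletons partition scores
exactly 0.

Optimization is a generalized Louvain heuristic (greedy node moves plus
aggregation) operating directly on the dense modularity matrix
B = A - gamma (off-diagonal).  Resolution values are sampled from the
network's own weight distribution between the gamma at which a non-trivial
split first appears and the largest off-diagonal weight; the resulting
partition ensemble is summarized by a coassignment matrix and distilled
into a nested hierarchy by recursive, permutation-tested reclustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .connectivity import FCNetwork, SurrogateEnsemble
from .errors import (
    DegenerateBoundsError,
    InvalidPartitionError,
    SamplingError,
)


@dataclass(frozen=True)
class ModularityConfig:
    """Sampling configuration for multiresolution modularity maximization."""

    n_gamma_samples: int = 1000  # full-scale studies use 10,000
    null_model: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gamma_samples < 1:
            raise ValueError("n_gamma_samples must be >= 1")
        if self.null_model != "uniform":
            raise ValueError("only the uniform null model (P_ij = 1) is supported")


@dataclass
class Partition:
    """Module labels g_i for all nodes, canonicalized to 0..C-1."""

    labels: NDArray[np.intp]

    def __post_init__(self) -> None:
        self.labels = canonical_labels(np.asarray(self.labels))

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1 if self.n_nodes else 0

    def module_sizes(self) -> NDArray[np.int64]:
        return np.bincount(self.labels)


@dataclass
class CoassignmentMatrix:
    """Fraction of sampled partitions assigning each node pair together."""

    values: NDArray[np.float64]
    n_partitions: int


@dataclass
class Hierarchy:
    """Nested partitions ordered coarse -> fine with per-level provenance."""

    levels: list[Partition]
    q_values: list[float] = field(default_factory=list)
    gamma_provenance: list[float] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def canonical_labels(labels: NDArray) -> NDArray[np.intp]:
    """Relabel modules by order of first appearance (0-based, contiguous)."""
    labels = np.asarray(labels)
    _, idx = np.unique(labels, return_index=True)
    order = labels[np.sort(idx)]
    mapping = {int(m): i for i, m in enumerate(order)}
    return np.array([mapping[int(m)] for m in labels], dtype=np.intp)


def _check_partition(n_nodes: int, labels: NDArray) -> NDArray[np.intp]:
    labels = np.asarray(labels)
    if labels.shape != (n_nodes,):
        raise InvalidPartitionError(
            f"partition labels shape {labels.shape} != ({n_nodes},)"
        )
    return labels.astype(np.intp)


def modularity_score(
    A: FCNetwork | NDArray[np.float64],
    partition: Partition | NDArray,
    gamma: float,
) -> float:
    """Q = sum over ordered pairs i != j in the same module of (A_ij - gamma)."""
    w = A.weights if isinstance(A, FCNetwork) else np.asarray(A, dtype=float)
    labels = partition.labels if isinstance(partition, Partition) else partition
    labels = _check_partition(w.shape[0], labels)
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    b = w - gamma
    return float(b[same].sum())


def _louvain_engine(
    B: NDArray[np.float64],
    rng: np.random.Generator,
    init: NDArray[np.intp] | None = None,
    tol: float = 1e-12,
) -> NDArray[np.intp]:
    """One greedy Louvain pass on a dense modularity matrix (zero diagonal
    on entry; aggregated diagonals are label-invariant and ignored).

    ``init`` seeds the first move phase (defaults to all singletons);
    multi-start callers pass random coarse initializations to escape local
    optima of the greedy dynamics.
    """
    n0 = B.shape[0]
    node_of = np.arange(n0)  # original node -> current supernode
    M = B.copy()
    first = True
    while True:
        n = M.shape[0]
        if first and init is not None:
            labels = canonical_labels(np.asarray(init, dtype=np.intp)).copy()
        else:
            labels = np.arange(n)
        first = False
        moved_any = False
        improved = True
        while improved:
            improved = False
            for i in rng.permutation(n):
                row = M[i].copy()
                row[i] = 0.0
                # one extra empty slot so a node can always split off into a
                # fresh singleton community (weight 0)
                comm_w = np.bincount(labels, weights=row, minlength=labels.max() + 2)
                current = labels[i]
                best = int(np.argmax(comm_w))
                if comm_w[best] > comm_w[current] + tol:
                    labels[i] = best
                    improved = True
                    moved_any = True
        labels = canonical_labels(labels)
        c = labels.max() + 1
        if not moved_any or c == n:
            return canonical_labels(labels[node_of])
        # aggregation phase
        S = np.zeros((n, c))
        S[np.arange(n), labels] = 1.0
        M = S.T @ M @ S
        node_of = labels[node_of]


def louvain_optimize(
    A: FCNetwork | NDArray[np.float64],
    gamma: float,
    seed: int = 0,
    n_restarts: int = 20,
) -> tuple[Partition, float]:
    """Maximize uniform-null signed modularity with the Louvain heuristic.

    Greedy node moves and aggregation phases on B = A - gamma (zero diagonal)
    until no move increases Q; node visitation order is randomized from
    ``seed`` and the best of ``n_restarts`` starts is returned, guaranteed to
    score at least as well as both trivial partitions (all singletons, one
    module).
    """
    w = A.weights if isinstance(A, FCNetwork) else np.asarray(A, dtype=float)
    n = w.shape[0]
    B = w - gamma
    np.fill_diagonal(B, 0.0)
    rng = np.random.default_rng(seed)
    best_labels = np.arange(n)  # singletons, Q = 0
    best_q = 0.0
    one = float(B.sum())
    if one > best_q:
        best_labels, best_q = np.zeros(n, dtype=np.intp), one
    for r in range(max(1, n_restarts)):
        # first start from singletons, then from random coarse initializations
        init = None if r == 0 else rng.integers(0, rng.integers(2, n + 1), size=n)
        labels = _louvain_engine(B, rng, init=init)
        q = float(B[labels[:, None] == labels[None, :]].sum())
        # diagonal of B is zero, so same-module mask sum is exactly Q
        if q > best_q + 1e-15:
            best_labels, best_q = labels, q
    return Partition(labels=best_labels), best_q


def gamma_bounds(
    A: FCNetwork | NDArray[np.float64],
    seed: int = 0,
    n_bisect: int = 25,
    n_restarts: int = 3,
) -> tuple[float, float]:
    """Resolution range bounding all non-trivial partitions.

    The upper bound is the maximum off-diagonal weight (above it every
    B_ij < 0 and the optimum is all singletons).  The lower bound is the
    smallest gamma at which optimization first yields two or more modules,
    located by bisection with repeated Louvain runs.
    """
    w = A.weights if isinstance(A, FCNetwork) else np.asarray(A, dtype=float)
    n = w.shape[0]
    if n < 2:
        raise DegenerateBoundsError("need at least 2 nodes")
    off = w[~np.eye(n, dtype=bool)]
    if np.ptp(off) == 0:
        raise DegenerateBoundsError("constant weight matrix")
    gamma_max = float(off.max())
    lo = float(off.min())  # at gamma <= min weight all B_ij >= 0: one module
    hi = gamma_max
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        part, _ = louvain_optimize(w, mid, seed=seed, n_restarts=n_restarts)
        if part.n_modules >= 2:
            hi = mid
        else:
            lo = mid
    return hi, gamma_max


def sample_gamma_values(
    A: FCNetwork | NDArray[np.float64],
    n: int,
    bounds: tuple[float, float],
    seed: int = 0,
) -> NDArray[np.float64]:
    """Draw gamma values with replacement from the admissible weights.

    The sampling set is the off-diagonal connection weights falling inside
    ``bounds``, so the gamma distribution follows the network's own weight
    distribution.
    """
    w = A.weights if isinstance(A, FCNetwork) else np.asarray(A, dtype=float)
    off = w[~np.eye(w.shape[0], dtype=bool)]
    gmin, gmax = bounds
    admissible = off[(off >= gmin) & (off <= gmax)]
    if admissible.size == 0:
        raise SamplingError("no connection weights inside the gamma bounds")
    rng = np.random.default_rng(seed)
    return rng.choice(admissible, size=n, replace=True)


def build_coassignment(partitions: list[Partition]) -> CoassignmentMatrix:
    """values[i][j] = fraction of partitions assigning i and j together."""
    if not partitions:
        raise InvalidPartitionError("need at least one partition")
    n = partitions[0].n_nodes
    labels = np.stack([_check_partition(n, p.labels) for p in partitions])
    same = labels[:, :, None] == labels[:, None, :]
    return CoassignmentMatrix(values=same.mean(axis=0), n_partitions=len(partitions))


def _coassignment_from_labels(labels: NDArray[np.intp]) -> NDArray[np.float64]:
    same = labels[:, :, None] == labels[:, None, :]
    return same.mean(axis=0)


def _null_coassignment_mean(labels: NDArray[np.intp]) -> float:
    """Expected pairwise coassignment if each partition's labels were
    randomly permuted across the node set (preserving module sizes)."""
    p, m = labels.shape
    if m < 2:
        return 0.0
    probs = np.empty(p)
    for k in range(p):
        sizes = np.bincount(canonical_labels(labels[k]))
        probs[k] = float(np.sum(sizes * (sizes - 1))) / (m * (m - 1))
    return float(probs.mean())


def consensus_hierarchy(
    partitions: list[Partition],
    alpha: float = 0.05,
    seed: int = 0,
    n_permutations: int = 100,
) -> Hierarchy:
    """Distill a partition ensemble into a nested hierarchy of modules.

    Recursively: within the current node set, test whether the observed
    coassignment structure exceeds a permutation null (each input partition's
    labels shuffled across the node set) at level ``alpha``, using the
    maximum off-diagonal coassignment as the test statistic.  If significant,
    split by Louvain on the null-centered coassignment submatrix and recurse
    into the parts.  Levels are cuts of the resulting tree at increasing
    depth, so every level refines its parent by construction.
    """
    if not partitions:
        raise InvalidPartitionError("need at least one partition")
    n = partitions[0].n_nodes
    all_labels = np.stack([_check_partition(n, p.labels) for p in partitions])
    rng = np.random.default_rng(seed)

    def significant(sub: NDArray[np.intp]) -> bool:
        m = sub.shape[1]
        coas = _coassignment_from_labels(sub)
        iu = np.triu_indices(m, k=1)
        obs = coas[iu].max()
        exceed = 0
        for _ in range(n_permutations):
            idx = np.argsort(rng.random(sub.shape), axis=1)
            perm = np.take_along_axis(sub, idx, axis=1)
            stat = _coassignment_from_labels(perm)[iu].max()
            if stat >= obs:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)
        return p < alpha

    def split(node_set: NDArray[np.intp]) -> list[NDArray[np.intp]] | None:
        sub = all_labels[:, node_set]
        if node_set.size < 2 or not significant(sub):
            return None
        coas = _coassignment_from_labels(sub)
        centered = coas - _null_coassignment_mean(sub)
        np.fill_diagonal(centered, 0.0)
        part, _ = louvain_optimize(centered, 0.0, seed=int(rng.integers(2**31)))
        if part.n_modules < 2:
            return None
        return [node_set[part.labels == c] for c in range(part.n_modules)]

    # build the tree breadth-first, recording the partition at each depth
    levels: list[Partition] = []
    frontier: list[NDArray[np.intp]] = [np.arange(n)]
    current = np.zeros(n, dtype=np.intp)
    while True:
        new_frontier: list[NDArray[np.intp]] = []
        changed = False
        nxt = current.copy()
        next_label = 0
        for node_set in frontier:
            parts = split(node_set)
            if parts is None:
                nxt[node_set] = next_label
                next_label += 1
                new_frontier.append(node_set)
            else:
                changed = True
                for p_set in parts:
                    nxt[p_set] = next_label
                    next_label += 1
                    new_frontier.append(p_set)
        if not changed:
            break
        current = nxt
        levels.append(Partition(labels=current.copy()))
        frontier = new_frontier
    if not levels:  # no significant structure at all: one trivial level
        levels = [Partition(labels=np.zeros(n, dtype=np.intp))]
    return Hierarchy(levels=levels)


def detect_hierarchy(
    A: FCNetwork,
    config: ModularityConfig = ModularityConfig(),
    alpha: float = 0.05,
) -> tuple[Hierarchy, list[Partition], NDArray[np.float64]]:
    """Sample gamma values, optimize at each, and build the consensus hierarchy.

    Returns the hierarchy, the sampled partition ensemble, and the gamma
    values used (one Louvain run per gamma sample).  Each hierarchy level is
    annotated with its Q at the median admissible gamma.
    """
    bounds = gamma_bounds(A, seed=config.seed)
    gammas = sample_gamma_values(A, config.n_gamma_samples, bounds, seed=config.seed + 1)
    rng = np.random.default_rng(config.seed + 2)
    ensemble = []
    for g in gammas:
        part, _ = louvain_optimize(A, float(g), seed=int(rng.integers(2**31)), n_restarts=1)
        ensemble.append(part)
    hier = consensus_hierarchy(ensemble, alpha=alpha, seed=config.seed + 3)
    g_med = float(np.median(gammas))
    hier.q_values = [modularity_score(A, lev, g_med) for lev in hier.levels]
    hier.gamma_provenance = [g_med] * hier.n_levels
    return hier, ensemble, gammas


def modularity_significance(
    A: FCNetwork,
    surrogates: SurrogateEnsemble,
    hierarchy: Hierarchy,
    ensemble: list[Partition],
    gammas: NDArray[np.float64],
    seed: int = 0,
) -> NDArray[np.float64]:
    """Bonferroni-corrected p-values of Q at each hierarchy level vs surrogates.

    For each level, the empirical statistic is the maximum Q among ensemble
    partitions whose module count matches that level (at their own sampled
    gamma); each surrogate network is optimized once at the median of those
    gammas, and p = (1 + #{surrogate Q >= empirical Q}) / (1 + n_surrogates),
    multiplied by the number of levels (capped at 1).
    """
    import warnings

    if surrogates.n_surrogates < 20:
        warnings.warn("fewer than 20 surrogates: p-value resolution is coarse")
    counts = np.array([p.n_modules for p in ensemble])
    qs = np.array(
        [modularity_score(A, p, float(g)) for p, g in zip(ensemble, gammas)]
    )
    pvals = []
    rng = np.random.default_rng(seed)
    for level in hierarchy.levels:
        c = level.n_modules
        sel = counts == c
        if not sel.any():  # fall back to nearest module count
            sel = np.abs(counts - c) == np.abs(counts - c).min()
        q_emp = float(qs[sel].max())
        g_star = float(np.median(gammas[sel]))
        q_surr = np.array(
            [
                louvain_optimize(s, g_star, seed=int(rng.integers(2**31)), n_restarts=1)[1]
                for s in surrogates.networks
            ]
        )
        p = (1 + int(np.sum(q_surr >= q_emp))) / (1 + surrogates.n_surrogates)
        pvals.append(min(1.0, p * hierarchy.n_levels))
    return np.array(pvals)
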