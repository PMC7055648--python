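"""Multilayer modularity maximization across stimulus-condition layers.

Each stimulus condition contributes one layer A_s with modularity block
B_s = A_s - gamma (uniform null); node i in layer s couples to itself in
every other layer with weight omega (categorical, all-to-all).  The
multilayer quality function is

    Q = sum_s sum_{i != j} (A_s,ij - gamma) delta(g_is, g_js)
        + sum_i sum_{s != r} omega delta(g_is, g_ir)

optimized by the same generalized Louvain engine on the supra-modularity
matrix (N*T supra-nodes).  Because module labels live on supra-nodes, labels
are preserved across layers, which makes node flexibility -- the fraction of
layer pairs on which a node's module assignment differs -- well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .community import Partition, _louvain_engine, canonical_labels
from .connectivity import FCNetwork
from .errors import (
    IncompatibleNetworksError,
    InvalidPartitionError,
    InvalidSpecError,
    SamplingError,
    UndefinedFlexibilityError,
)


@dataclass
class MultilayerNetwork:
    """Stack of per-condition FC networks sharing the node set."""

    layers: list[FCNetwork]
    omega: float = 0.1
    layer_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise IncompatibleNetworksError("need at least one layer")
        n = self.layers[0].n_nodes
        if any(l.n_nodes != n for l in self.layers):
            raise IncompatibleNetworksError("layers differ in node count")
        if self.omega < 0:
            raise InvalidSpecError("omega must be >= 0")
        if not self.layer_labels:
            self.layer_labels = [l.condition for l in self.layers]

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class MultilayerPartition:
    """Module labels g_is on the node x layer grid, ids shared across layers."""

    labels: NDArray[np.intp]  # (N, T)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if self.labels.ndim != 2:
            raise InvalidPartitionError("labels must be (n_nodes, n_layers)")

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def n_layers(self) -> int:
        return self.labels.shape[1]

    @property
    def n_modules_mean(self) -> float:
        """Mean number of distinct modules per layer."""
        return float(
            np.mean([len(np.unique(self.labels[:, s])) for s in range(self.n_layers)])
        )


@dataclass
class FlexibilityProfile:
    """Per-node flexibility f_i in [0, 1] with sampling provenance."""

    f: NDArray[np.float64]
    averaged_over: list[tuple[float, float]] = field(default_factory=list)  # (gamma, omega)
    n_modules_mean: float = float("nan")


def multilayer_modularity_score(
    net: MultilayerNetwork, partition: MultilayerPartition, gamma: float
) -> float:
    """Evaluate the multilayer quality function (ordered pairs, zero diagonal)."""
    if partition.labels.shape != (net.n_nodes, net.n_layers):
        raise InvalidPartitionError("partition shape does not match the network")
    g = partition.labels
    q = 0.0
    for s, layer in enumerate(net.layers):
        same = g[:, s][:, None] == g[:, s][None, :]
        np.fill_diagonal(same, False)
        q += float((layer.weights - gamma)[same].sum())
    # interlayer: ordered layer pairs (s != r) for each node
    agree = g[:, :, None] == g[:, None, :]  # (N, T, T)
    t = net.n_layers
    agree_offdiag = agree.sum() - net.n_nodes * t
    q += net.omega * float(agree_offdiag)
    return q


def supra_modularity_matrix(net: MultilayerNetwork, gamma: float) -> NDArray[np.float64]:
    """Dense supra-matrix: intra-layer blocks B_s on the diagonal, omega
    between copies of the same node in different layers; zero diagonal."""
    n, t = net.n_nodes, net.n_layers
    supra = np.zeros((n * t, n * t))
    for s, layer in enumerate(net.layers):
        b = layer.weights - gamma
        np.fill_diagonal(b, 0.0)
        supra[s * n : (s + 1) * n, s * n : (s + 1) * n] = b
    if net.omega > 0:
        for s in range(t):
            for r in range(t):
                if s != r:
                    idx_s = np.arange(n) + s * n
                    idx_r = np.arange(n) + r * n
                    supra[idx_s, idx_r] = net.omega
    return supra


def multilayer_louvain(
    net: MultilayerNetwork,
    gamma: float,
    seed: int = 0,
    n_restarts: int = 30,
) -> tuple[MultilayerPartition, float]:
    """Louvain on the supra-modularity matrix; best of ``n_restarts``.

    Returns labels reshaped to (node, layer), canonicalized, plus the
    attained Q (guaranteed >= the all-singletons score of 0).
    """
    n, t = net.n_nodes, net.n_layers
    supra = supra_modularity_matrix(net, gamma)
    rng = np.random.default_rng(seed)
    best = np.arange(n * t)
    best_q = float(supra[best[:, None] == best[None, :]].sum())  # singletons: 0
    one = float(supra.sum())
    if one > best_q:
        best, best_q = np.zeros(n * t, dtype=np.intp), one
    nt = n * t
    for r in range(max(1, n_restarts)):
        if r == 0:
            init = None
        elif r == 1:
            # columns coupled: start with each node merged across layers
            init = np.tile(np.arange(n), t)
        else:
            init = rng.integers(0, rng.integers(2, nt + 1), size=nt)
        labels = _louvain_engine(supra, rng, init=init)
        q = float(supra[labels[:, None] == labels[None, :]].sum())
        if q > best_q + 1e-15:
            best, best_q = labels, q
    labels = canonical_labels(best).reshape(t, n).T  # supra order is layer-major
    return MultilayerPartition(labels=labels), best_q


def sample_omega_values(
    n: int,
    exponent_range: tuple[float, float] = (-3.0, 1.0),
    seed: int = 0,
) -> NDArray[np.float64]:
    """omega = 10**u with u uniform on ``exponent_range`` (default [-3, 1],
    so omega spans 0.001 to 10)."""
    if n < 1:
        raise SamplingError("n must be >= 1")
    lo, hi = exponent_range
    if lo > hi:
        raise InvalidSpecError("inverted exponent range")
    rng = np.random.default_rng(seed)
    return 10.0 ** rng.uniform(lo, hi, size=n)


def compute_flexibility(partition: MultilayerPartition) -> FlexibilityProfile:
    """f_i = 1 - (2 / (T (T - 1))) sum_{r < s} delta(g_ir, g_is)."""
    t = partition.n_layers
    if t < 2:
        raise UndefinedFlexibilityError("flexibility requires at least 2 layers")
    g = partition.labels
    agree = 0
    for r in range(t):
        for s in range(r + 1, t):
            agree = agree + (g[:, r] == g[:, s]).astype(float)
    f = 1.0 - 2.0 * agree / (t * (t - 1))
    return FlexibilityProfile(f=f, n_modules_mean=partition.n_modules_mean)


def flexibility_summary(
    profiles: list[FlexibilityProfile],
    module_range: tuple[float, float] = (2.0, 25.0),
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Mean flexibility per node over profiles whose mean module count lies
    in ``module_range``; also the rank-transformed variant (mean of per-run
    flexibility ranks, which removes baseline differences induced by omega).
    """
    from scipy.stats import rankdata

    from .errors import EmptySummaryError

    lo, hi = module_range
    keep = [p for p in profiles if lo <= p.n_modules_mean <= hi]
    if not keep:
        raise EmptySummaryError(
            f"no profiles with mean module count in [{lo}, {hi}]"
        )
    mean_f = np.mean([p.f for p in keep], axis=0)
    mean_rank = np.mean([rankdata(p.f) for p in keep], axis=0)
    return mean_f, mean_rank


def multilayer_flexibility_run(
    net_layers: list[FCNetwork],
    n_samples: int = 500,
    gamma_pool: NDArray[np.float64] | None = None,
    exponent_range: tuple[float, float] = (-3.0, 1.0),
    module_range: tuple[float, float] = (2.0, 25.0),
    seed: int = 0,
    n_restarts: int = 1,
) -> tuple[NDArray[np.float64], NDArray[np.float64], list[FlexibilityProfile]]:
    """Joint (gamma, omega) sampling and flexibility averaging.

    gamma is drawn with replacement from ``gamma_pool`` (typically the
    admissible connection weights of the group network); omega from the
    log-uniform sampler.  One Louvain run per (gamma, omega) pair; profiles
    whose mean module count falls outside ``module_range`` are excluded from
    the summary (they are still returned).
    """
    from .community import gamma_bounds, sample_gamma_values

    if gamma_pool is None:
        stack = np.mean([l.weights for l in net_layers], axis=0)
        ref = FCNetwork(weights=stack, coords=net_layers[0].coords)
        bounds = gamma_bounds(ref, seed=seed)
        gammas = sample_gamma_values(ref, n_samples, bounds, seed=seed + 1)
    else:
        rng0 = np.random.default_rng(seed + 1)
        gammas = rng0.choice(np.asarray(gamma_pool, dtype=float), size=n_samples)
    omegas = sample_omega_values(n_samples, exponent_range, seed=seed + 2)
    rng = np.random.default_rng(seed + 3)
    profiles = []
    for g, w in zip(gammas, omegas):
        net = MultilayerNetwork(layers=net_layers, omega=float(w))
        part, _ = multilayer_louvain(
            net, float(g), seed=int(rng.integers(2**31)), n_restarts=n_restarts
        )
        prof = compute_flexibility(part)
        prof.averaged_over = [(float(g), float(w))]
        profiles.append(prof)
    mean_f, mean_rank = flexibility_summary(profiles, module_range)
    return mean_f, mean_rank, profiles
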