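"""Hub metrics, partition similarity, geometry and similarity analyses.

Implements the participation coefficient p_i+ = 1 - sum_c (kappa_ic+/k_i+)^2
over positive connection weights, absolute strength s_i = sum_j |A_ij|, the
z-score of the Rand index for comparing partitions, distance-binned weight
profiles with connection-class proportions, hemispheric similarity of
within-hemisphere connectivity, the Mantel permutation test, and
upper-triangle similarity reports across conditions and subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, pearsonr, rankdata

from .community import Hierarchy, Partition, _check_partition
from .connectivity import FCNetwork
from .errors import (
    IncompatibleNetworksError,
    InvalidSpecError,
    MissingPartnerError,
    UndefinedCorrelationError,
    UndefinedVarianceError,
)
from .multilayer import FlexibilityProfile
from .parcellation import Parcellation


@dataclass
class HubMetrics:
    """Participation per hierarchy level plus summaries, and strength."""

    participation_per_level: NDArray[np.float64]  # (n_nodes, n_levels)
    participation_mean: NDArray[np.float64]
    participation_rank: NDArray[np.float64]
    cross_level_corr: NDArray[np.float64]
    strength: NDArray[np.float64]


@dataclass
class ZRandResult:
    """z-score of the Rand index with its Eq.-4 components."""

    z: float
    w_xy: float  # pairs together in both partitions
    w_x: float  # pairs together in X
    w_y: float  # pairs together in Y
    w_total: float  # all node pairs
    sigma_w: float

    @property
    def p_value(self) -> float:
        """One-sided normal p-value for similarity beyond chance."""
        return float(norm.sf(self.z))


@dataclass
class GeometryProfile:
    bin_edges: NDArray[np.float64]
    mean_weight_within: NDArray[np.float64]
    mean_weight_between: NDArray[np.float64]
    class_proportions: NDArray[np.float64]  # (n_bins, 4), NaN for empty bins
    class_thresholds: tuple[float, float]
    class_names: tuple[str, ...] = (
        "strong_positive",
        "weak_positive",
        "neutral",
        "anticorrelation",
    )


@dataclass
class SimilarityReport:
    labels: list[tuple[str, str]]  # (subject, condition) per network
    pairwise_r: NDArray[np.float64]
    self_similarity: float = float("nan")
    intersubject_similarity: float = float("nan")
    mantel: dict = field(default_factory=dict)


def positive_strengths(
    A: FCNetwork | NDArray[np.float64], labels: NDArray[np.intp]
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """(k_i+, kappa_ic+): total positive strength and its split over modules."""
    w = A.weights if isinstance(A, FCNetwork) else np.asarray(A, dtype=float)
    pos = np.clip(w, 0.0, None)
    np.fill_diagonal(pos, 0.0)
    k = pos.sum(axis=1)
    n_mod = int(labels.max()) + 1
    onehot = np.zeros((w.shape[0], n_mod))
    onehot[np.arange(w.shape[0]), labels] = 1.0
    kappa = pos @ onehot
    return k, kappa


def participation_coefficient(
    A: FCNetwork | NDArray[np.float64], partition: Partition | NDArray
) -> NDArray[np.float64]:
    """p_i+ = 1 - sum_c (kappa_ic+ / k_i+)^2 over positive weights.

    Nodes with zero positive strength get participation 0 by convention.
    """
    w = A.weights if isinstance(A, FCNetwork) else np.asarray(A, dtype=float)
    labels = partition.labels if isinstance(partition, Partition) else partition
    labels = _check_partition(w.shape[0], labels)
    k, kappa = positive_strengths(w, labels)
    out = np.zeros(w.shape[0])
    nz = k > 0
    out[nz] = 1.0 - np.sum((kappa[nz] / k[nz, None]) ** 2, axis=1)
    return out


def absolute_strength(A: FCNetwork | NDArray[np.float64]) -> NDArray[np.float64]:
    """s_i = sum_j |A_ij| (diagonal excluded)."""
    w = A.weights if isinstance(A, FCNetwork) else np.asarray(A, dtype=float)
    a = np.abs(w).copy()
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def hierarchy_participation(A: FCNetwork, hierarchy: Hierarchy) -> HubMetrics:
    """Participation at every hierarchy level, averaged and rank-transformed.

    Also returns the cross-level correlation matrix of the participation
    maps (scale-dependence of hubness) and absolute strength.
    """
    if hierarchy.n_levels == 0:
        raise InvalidSpecError("hierarchy has no levels")
    per_level = np.column_stack(
        [participation_coefficient(A, lev) for lev in hierarchy.levels]
    )
    mean = per_level.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cross = np.corrcoef(per_level.T) if hierarchy.n_levels > 1 else np.ones((1, 1))
    return HubMetrics(
        participation_per_level=per_level,
        participation_mean=mean,
        participation_rank=rankdata(mean),
        cross_level_corr=np.atleast_2d(cross),
        strength=absolute_strength(A),
    )


def _pair_counts(labels: NDArray[np.intp]) -> float:
    sizes = np.bincount(labels)
    return float(np.sum(sizes * (sizes - 1)) / 2)


def zrand_score(X: Partition | NDArray, Y: Partition | NDArray) -> ZRandResult:
    """z-score of the Rand index between two partitions.

    Standardizes the count of co-assigned pairs w_XY against its mean and
    variance under the permutation model that fixes both partitions' module
    sizes; the closed-form variance uses exact integer pair counts.
    """
    lx = X.labels if isinstance(X, Partition) else np.asarray(X, dtype=np.intp)
    ly = Y.labels if isinstance(Y, Partition) else np.asarray(Y, dtype=np.intp)
    if lx.shape != ly.shape:
        raise InvalidSpecError("partitions must share the node set")
    n = lx.shape[0]
    if n < 3:
        raise InvalidSpecError("need at least 3 nodes")
    lx = _check_partition(n, lx)
    ly = _check_partition(n, ly)
    big_w = n * (n - 1) / 2
    w_x = _pair_counts(lx)
    w_y = _pair_counts(ly)
    # contingency table pair count
    joint = lx.astype(np.int64) * (int(ly.max()) + 1) + ly
    w_xy = _pair_counts(np.unique(joint, return_inverse=True)[1])
    m = big_w
    m1, m2 = w_x, w_y
    nx3 = float(np.sum(np.bincount(lx).astype(float) ** 3))
    ny3 = float(np.sum(np.bincount(ly).astype(float) ** 3))
    c1 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * m1 + 4 * nx3
    c2 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * m2 + 4 * ny3
    var = (
        m / 16
        - (4 * m1 - 2 * m) ** 2 * (4 * m2 - 2 * m) ** 2 / (256 * m**2)
        + c1 * c2 / (16 * n * (n - 1) * (n - 2))
        + ((4 * m1 - 2 * m) ** 2 - 4 * c1 - 4 * m)
        * ((4 * m2 - 2 * m) ** 2 - 4 * c2 - 4 * m)
        / (64 * n * (n - 1) * (n - 2) * (n - 3))
    )
    if var <= 0:
        raise UndefinedVarianceError(
            "z-Rand variance undefined (degenerate partition)"
        )
    sigma = float(np.sqrt(var))
    z = (w_xy - m1 * m2 / m) / sigma
    return ZRandResult(z=float(z), w_xy=w_xy, w_x=w_x, w_y=w_y, w_total=big_w, sigma_w=sigma)


def distance_profile(
    A: FCNetwork,
    bin_edges: NDArray[np.float64],
    class_thresholds: tuple[float, float] = (0.1, 0.5),
    hemisphere: NDArray[np.str_] | None = None,
) -> GeometryProfile:
    """Distance-binned mean weight and connection-class proportions.

    Classes (Fisher-z units): anticorrelation w < -t_neutral; neutral
    |w| <= t_neutral; weak positive t_neutral < w <= t_strong; strong
    positive w > t_strong.  Mean weights are reported separately for
    within- and between-hemisphere pairs; hemisphere defaults to the sign of
    the first coordinate.  Empty bins are NaN, not 0.
    """
    t_neutral, t_strong = class_thresholds
    if not 0 <= t_neutral < t_strong:
        raise InvalidSpecError("need 0 <= t_neutral < t_strong")
    n = A.n_nodes
    if hemisphere is None:
        hemisphere = np.where(A.coords[:, 0] < 0, "L", "R")
    iu = np.triu_indices(n, k=1)
    d = squareform(pdist(A.coords))[iu]
    w = A.weights[iu]
    same_hemi = (hemisphere[iu[0]] == hemisphere[iu[1]])
    edges = np.asarray(bin_edges, dtype=float)
    n_bins = len(edges) - 1
    which = np.digitize(d, edges) - 1
    mean_within = np.full(n_bins, np.nan)
    mean_between = np.full(n_bins, np.nan)
    props = np.full((n_bins, 4), np.nan)
    for b in range(n_bins):
        sel = which == b
        if (sel & same_hemi).any():
            mean_within[b] = w[sel & same_hemi].mean()
        if (sel & ~same_hemi).any():
            mean_between[b] = w[sel & ~same_hemi].mean()
        if sel.any():
            wb = w[sel]
            props[b] = [
                np.mean(wb > t_strong),
                np.mean((wb > t_neutral) & (wb <= t_strong)),
                np.mean(np.abs(wb) <= t_neutral),
                np.mean(wb < -t_neutral),
            ]
    return GeometryProfile(
        bin_edges=edges,
        mean_weight_within=mean_within,
        mean_weight_between=mean_between,
        class_proportions=props,
        class_thresholds=(t_neutral, t_strong),
    )


def hemisphere_similarity(A: FCNetwork, parcellation: Parcellation) -> float:
    """Pearson r between left and homotopically reordered right
    within-hemisphere connection weights."""
    hemi = parcellation.hemisphere_of_parcel
    partner = parcellation.homotopic_partner
    left = np.where(hemi == "L")[0]
    if left.size < 2:
        raise MissingPartnerError("fewer than two left-hemisphere parcels")
    right = partner[left]
    if np.any(hemi[right] != "R"):
        raise MissingPartnerError("homotopic partner missing or not in R")
    li, lj = np.triu_indices(left.size, k=1)
    lw = A.weights[left[li], left[lj]]
    rw = A.weights[right[li], right[lj]]
    if np.std(lw) == 0 or np.std(rw) == 0:
        raise UndefinedCorrelationError("constant within-hemisphere weights")
    return float(pearsonr(lw, rw).statistic)


def mantel_test(
    A: NDArray[np.float64],
    B: NDArray[np.float64],
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel permutation test of matrix correspondence.

    r is the Pearson correlation of the upper triangles; the null permutes
    rows and columns of B simultaneously; p is one-sided (greater or equal),
    p = (1 + #{r_perm >= r}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise InvalidSpecError("n_perm must be >= 1")
    a = np.asarray(A, dtype=float)
    b = np.asarray(B, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise IncompatibleNetworksError("matrices must be square and same shape")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    va = a[iu]
    r_obs = float(pearsonr(va, b[iu]).statistic)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = float(pearsonr(va, b[np.ix_(perm, perm)][iu]).statistic)
        if r_p >= r_obs:
            exceed += 1
    return r_obs, (1 + exceed) / (1 + n_perm)


def similarity_report(
    networks: list[FCNetwork],
    mantel_pairs: list[tuple[int, int]] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> SimilarityReport:
    """Pairwise upper-triangle Pearson similarity across networks.

    With both subject and condition labels present, also reports mean
    self-similarity (same subject, different conditions) and mean
    intersubject similarity (different subjects, different conditions).
    ``mantel_pairs`` optionally names network index pairs to test with the
    Mantel permutation test.
    """
    if not networks:
        raise IncompatibleNetworksError("no networks")
    n = networks[0].n_nodes
    if any(net.n_nodes != n for net in networks):
        raise IncompatibleNetworksError("networks differ in node count")
    k = len(networks)
    tri = np.stack([net.upper_triangle() for net in networks])
    r = np.corrcoef(tri) if k > 1 else np.ones((1, 1))
    labels = [(net.subject_id, net.condition) for net in networks]
    subjects = np.array([s for s, _ in labels])
    conditions = np.array([c for _, c in labels])
    self_vals, other_vals = [], []
    for i in range(k):
        for j in range(i + 1, k):
            if conditions[i] == conditions[j]:
                continue
            if subjects[i] == subjects[j]:
                self_vals.append(r[i, j])
            else:
                other_vals.append(r[i, j])
    report = SimilarityReport(
        labels=labels,
        pairwise_r=np.atleast_2d(r),
        self_similarity=float(np.mean(self_vals)) if self_vals else float("nan"),
        intersubject_similarity=float(np.mean(other_vals)) if other_vals else float("nan"),
    )
    if mantel_pairs:
        for i, j in mantel_pairs:
            rm, pm = mantel_test(
                networks[i].weights, networks[j].weights, n_perm=n_perm, seed=seed
            )
            report.mantel[(labels[i], labels[j])] = (rm, pm)
    return report


def flexibility_participation_correlation(
    flex: FlexibilityProfile | NDArray[np.float64],
    participation: HubMetrics | NDArray[np.float64],
) -> float:
    """Pearson r between mean flexibility and mean spontaneous participation."""
    f = flex.f if isinstance(flex, FlexibilityProfile) else np.asarray(flex, dtype=float)
    p = (
        participation.participation_mean
        if isinstance(participation, HubMetrics)
        else np.asarray(participation, dtype=float)
    )
    if f.shape != p.shape:
        raise IncompatibleNetworksError("flexibility and participation differ in size")
    if np.std(f) == 0 or np.std(p) == 0:
        raise UndefinedCorrelationError("constant vector")
    return float(pearsonr(f, p).statistic)
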