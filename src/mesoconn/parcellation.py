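"""Multistage clustering that aggregates cells into network nodes (parcels).

Parcels must be (a) spatially contiguous, (b) functionally homogeneous and
(c) shared across subjects.  The algorithm: spatial k-means on pooled
left-hemisphere cell coordinates; mirroring of the centroids about the
midline so every spatial cluster has a homotopic partner; global-signal
regression of the concatenated traces; k-means with correlation distance on
the group- and hemisphere-averaged spatial-cluster correlation matrix; and a
final spatial subdivision of each functional cluster so that every parcel has
centroid diameter below ``max_diameter`` and spatially disconnected chunks
(>= ``min_gap`` apart) are separated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .errors import (
    DegenerateInputError,
    IllPosedRegressionError,
    InfeasibleClusteringError,
    InvalidSpecError,
)
from .synthetic import StudyDataset


@dataclass(frozen=True)
class ParcellationParams:
    """Tunable knobs of the multistage clustering.

    Full-scale defaults are k_spatial=2500 spatial clusters per hemisphere,
    k_functional=100 functional clusters, 10 k-means replicates, 200 px
    maximum parcel diameter and 60 px minimum within-functional-cluster gap.
    Desk-scale analyses pass smaller k values.
    """

    k_spatial: int = 2500
    k_functional: int = 100
    n_replicates: int = 10
    max_diameter: float = 200.0
    min_gap: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.max_diameter > self.min_gap > 0):
            raise InvalidSpecError("need max_diameter > min_gap > 0")
        if self.k_spatial < 1 or self.k_functional < 1 or self.n_replicates < 1:
            raise InvalidSpecError("cluster counts and replicates must be >= 1")


@dataclass
class SpatialClustering:
    """k-means spatial clusters; after mirroring, both hemispheres.

    ``centroids`` holds k left centroids, or 2k centroids (left then mirrored
    right) after :func:`mirror_assign`.  ``homotopic_map`` pairs cluster i
    with cluster i + k.  ``assignment`` is the cluster index of the points the
    clustering was fitted/assigned on (pooled left, then pooled right).
    """

    centroids: NDArray[np.float64]
    assignment: NDArray[np.intp]
    k: int  # clusters per hemisphere
    midline_axis: int = 0
    inertia: float = float("nan")

    @property
    def both_hemispheres(self) -> bool:
        return self.centroids.shape[0] == 2 * self.k

    def homotopic_map(self) -> NDArray[np.intp]:
        if not self.both_hemispheres:
            raise DegenerateInputError("clustering not yet mirrored")
        return np.concatenate([np.arange(self.k) + self.k, np.arange(self.k)])

    def assign_positions(
        self, positions: NDArray[np.float64], hemisphere: NDArray[np.str_]
    ) -> NDArray[np.intp]:
        """Nearest-centroid assignment, each hemisphere to its own centroids."""
        if not self.both_hemispheres:
            raise DegenerateInputError("clustering not yet mirrored")
        out = np.empty(positions.shape[0], dtype=np.intp)
        left = hemisphere == "L"
        tree_l = cKDTree(self.centroids[: self.k])
        tree_r = cKDTree(self.centroids[self.k :])
        if left.any():
            out[left] = tree_l.query(positions[left])[1]
        if (~left).any():
            out[~left] = tree_r.query(positions[~left])[1] + self.k
        return out


@dataclass
class Parcellation:
    """Cell -> parcel map shared across subjects, with homotopic pairing."""

    parcel_of_cell: dict[str, NDArray[np.intp]]
    parcel_centroids: NDArray[np.float64]  # (N, 3)
    homotopic_partner: NDArray[np.intp]  # (N,)
    n_parcels: int
    functional_of_parcel: NDArray[np.intp]
    members: list[NDArray[np.intp]]  # spatial-cluster indices per parcel
    spatial_centroids: NDArray[np.float64]  # (2k, 3)
    hemisphere_of_parcel: NDArray[np.str_] = field(default_factory=lambda: np.empty(0, dtype=str))
    params: ParcellationParams | None = None
    stats: dict = field(default_factory=dict)

    def diameters(self) -> NDArray[np.float64]:
        """Max pairwise distance between each parcel's member centroids."""
        out = np.zeros(self.n_parcels)
        for p, mem in enumerate(self.members):
            if len(mem) > 1:
                out[p] = pdist(self.spatial_centroids[mem]).max()
        return out

    def within_functional_gaps(self) -> list[tuple[int, int, float]]:
        """Min centroid distance between distinct parcels sharing hemisphere
        and functional cluster."""
        gaps = []
        for p in range(self.n_parcels):
            for q in range(p + 1, self.n_parcels):
                if (
                    self.functional_of_parcel[p] == self.functional_of_parcel[q]
                    and self.hemisphere_of_parcel[p] == self.hemisphere_of_parcel[q]
                ):
                    d = np.min(
                        np.linalg.norm(
                            self.spatial_centroids[self.members[p]][:, None, :]
                            - self.spatial_centroids[self.members[q]][None, :, :],
                            axis=-1,
                        )
                    )
                    gaps.append((p, q, float(d)))
        return gaps


def spatial_kmeans_left(
    left_positions_pooled: NDArray[np.float64], params: ParcellationParams
) -> SpatialClustering:
    """Euclidean k-means of pooled left-hemisphere cell coordinates.

    Best of ``n_replicates`` restarts by within-cluster sum of squares;
    the resulting clusters are Voronoi cells of the centroids, hence
    spatially compact and contiguous.
    """
    pts = np.asarray(left_positions_pooled, dtype=float)
    if pts.shape[0] < params.k_spatial:
        raise InfeasibleClusteringError(
            f"{pts.shape[0]} points < k_spatial={params.k_spatial}"
        )
    km = KMeans(
        n_clusters=params.k_spatial,
        n_init=params.n_replicates,
        random_state=params.seed,
    ).fit(pts)
    return SpatialClustering(
        centroids=km.cluster_centers_.copy(),
        assignment=km.labels_.astype(np.intp),
        k=params.k_spatial,
        inertia=float(km.inertia_),
    )


def mirror_assign(
    left_clustering: SpatialClustering,
    right_positions: NDArray[np.float64],
    midline_axis: int = 0,
) -> SpatialClustering:
    """Mirror left centroids about the midline and assign right cells.

    Right centroids are exact reflections of the left ones, so the homotopic
    map (cluster i <-> cluster i + k) is a bijection by construction.
    """
    right = np.asarray(right_positions, dtype=float)
    if right.shape[0] == 0:
        raise DegenerateInputError("no right-hemisphere positions")
    mirrored = left_clustering.centroids.copy()
    mirrored[:, midline_axis] *= -1.0
    r_assign = cKDTree(mirrored).query(right)[1] + left_clustering.k
    return SpatialClustering(
        centroids=np.vstack([left_clustering.centroids, mirrored]),
        assignment=np.concatenate([left_clustering.assignment, r_assign]),
        k=left_clustering.k,
        midline_axis=midline_axis,
        inertia=left_clustering.inertia,
    )


def global_signal_regression(traces: NDArray[np.float64]) -> NDArray[np.float64]:
    """Regress the mean-over-cells signal out of every trace.

    Per-cell least squares on [intercept, global signal]; the residuals are
    exactly orthogonal to the global signal and to the constant.
    """
    x = np.asarray(traces, dtype=float)
    g = x.mean(axis=0)
    if np.ptp(g) == 0:
        raise IllPosedRegressionError("global signal is constant")
    design = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    return x - (design @ beta).T


def functional_kmeans(
    cluster_corr: NDArray[np.float64], params: ParcellationParams
) -> NDArray[np.intp]:
    """k-means on the rows of a correlation matrix with correlation distance.

    Correlation distance (1 - Pearson r between rows) is realized by
    centering each row and scaling it to unit norm, then running Euclidean
    k-means; labels are therefore invariant to positive affine transforms of
    the rows.
    """
    c = np.asarray(cluster_corr, dtype=float)
    if params.k_functional > c.shape[0]:
        raise InfeasibleClusteringError("k_functional exceeds number of rows")
    rows = c - c.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    rows = rows / norms
    km = KMeans(
        n_clusters=params.k_functional,
        n_init=params.n_replicates,
        random_state=params.seed,
    ).fit(rows)
    return km.labels_.astype(np.intp)


def _split_by_diameter(
    member_idx: NDArray[np.intp],
    centroids: NDArray[np.float64],
    max_diameter: float,
    seed: int,
) -> list[NDArray[np.intp]]:
    """Recursive bisecting 2-means until every group's diameter < max_diameter."""
    if len(member_idx) <= 1 or pdist(centroids[member_idx]).max() < max_diameter:
        return [member_idx]
    km = KMeans(n_clusters=2, n_init=4, random_state=seed).fit(centroids[member_idx])
    out: list[NDArray[np.intp]] = []
    for side in (0, 1):
        sub = member_idx[km.labels_ == side]
        if len(sub) == 0:  # degenerate split; fall back to halving
            order = np.argsort(centroids[member_idx][:, 0])
            half = len(member_idx) // 2
            return [member_idx[order[:half]], member_idx[order[half:]]]
        out.extend(_split_by_diameter(sub, centroids, max_diameter, seed + 1))
    return out


def enforce_spatial_constraints(
    functional_labels: NDArray[np.intp],
    cluster_centroids: NDArray[np.float64],
    params: ParcellationParams,
    midline_axis: int = 0,
) -> Parcellation:
    """Subdivide functional clusters into spatially coherent parcels.

    Within each functional cluster, left-hemisphere spatial clusters are
    grouped by single-linkage agglomeration cut at ``min_gap`` (so distinct
    groups are separated by more than ``min_gap``); any group whose centroid
    diameter reaches ``max_diameter`` is split further by recursive bisecting
    2-means.  The groups, mirrored into both hemispheres, are the parcels;
    the homotopic pairing is a fixed-point-free involution by construction.

    The returned parcellation has no per-subject cell map yet; the pipeline
    fills ``parcel_of_cell`` after mirroring.
    """
    labels = np.asarray(functional_labels)
    cents = np.asarray(cluster_centroids, dtype=float)
    k = cents.shape[0]
    groups: list[NDArray[np.intp]] = []
    group_functional: list[int] = []
    for f in np.unique(labels):
        mem = np.where(labels == f)[0]
        if len(mem) == 1:
            chunks = [mem]
        else:
            link = linkage(cents[mem], method="single")
            cut = fcluster(link, t=params.min_gap, criterion="distance")
            chunks = [mem[cut == c] for c in np.unique(cut)]
        for chunk in chunks:
            for grp in _split_by_diameter(chunk, cents, params.max_diameter, params.seed):
                groups.append(grp)
                group_functional.append(int(f))

    n_left = len(groups)
    n_parcels = 2 * n_left
    mirrored = cents.copy()
    mirrored[:, midline_axis] *= -1.0
    parcel_centroids = np.zeros((n_parcels, 3))
    members: list[NDArray[np.intp]] = []
    functional = np.zeros(n_parcels, dtype=np.intp)
    hemi = np.array(["L"] * n_left + ["R"] * n_left)
    for g, grp in enumerate(groups):
        parcel_centroids[g] = cents[grp].mean(axis=0)
        members.append(grp)
        functional[g] = group_functional[g]
    for g, grp in enumerate(groups):
        c = cents[grp].mean(axis=0).copy()
        c[midline_axis] *= -1.0
        parcel_centroids[n_left + g] = c
        members.append(grp + k)  # right spatial cluster indices
        functional[n_left + g] = group_functional[g]
    partner = np.concatenate([np.arange(n_left) + n_left, np.arange(n_left)])
    spatial_centroids = np.vstack([cents, mirrored])
    return Parcellation(
        parcel_of_cell={},
        parcel_centroids=parcel_centroids,
        homotopic_partner=partner,
        n_parcels=n_parcels,
        functional_of_parcel=functional,
        members=members,
        spatial_centroids=spatial_centroids,
        hemisphere_of_parcel=hemi,
        params=params,
    )


def _concatenated_residual_traces(dataset: StudyDataset, subject: str) -> NDArray[np.float64]:
    """Concatenate a subject's recordings over conditions, then regress the
    global signal once on the concatenated matrix."""
    conds = dataset.conditions
    traces = np.hstack([dataset.recordings[(subject, c)].traces for c in conds])
    return global_signal_regression(traces)


def run_parcellation(dataset: StudyDataset, params: ParcellationParams) -> Parcellation:
    """Full multistage clustering on a study dataset.

    Stages: pooled left-hemisphere spatial k-means; centroid mirroring and
    right-hemisphere assignment; per-subject global-signal regression of the
    concatenated (spontaneous + stimulus) traces; spatial-cluster-averaged
    correlation, averaged over subjects and hemispheres; correlation-distance
    k-means into functional clusters; spatial subdivision into parcels.
    Deterministic given ``params.seed``.
    """
    subjects = dataset.subjects
    left_pool = np.vstack(
        [
            dataset.populations[s].positions[dataset.populations[s].hemisphere == "L"]
            for s in subjects
        ]
    )
    left_cl = spatial_kmeans_left(left_pool, params)
    right_pool = np.vstack(
        [
            dataset.populations[s].positions[dataset.populations[s].hemisphere == "R"]
            for s in subjects
        ]
    )
    midline_axis = dataset.populations[subjects[0]].midline_axis
    clustering = mirror_assign(left_cl, right_pool, midline_axis=midline_axis)

    k = params.k_spatial
    corr_sum = np.zeros((2 * k, 2 * k))
    corr_cnt = np.zeros((2 * k, 2 * k))
    cluster_of_cell: dict[str, NDArray[np.intp]] = {}
    for s in subjects:
        pop = dataset.populations[s]
        assign = clustering.assign_positions(pop.positions, pop.hemisphere)
        cluster_of_cell[s] = assign
        resid = _concatenated_residual_traces(dataset, s)
        tmat = np.zeros((2 * k, resid.shape[1]))
        counts = np.bincount(assign, minlength=2 * k).astype(float)
        np.add.at(tmat, assign, resid)
        present = counts > 0
        tmat[present] /= counts[present, None]
        sd = tmat.std(axis=1)
        valid = present & (sd > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(tmat)
        ok = np.outer(valid, valid)
        corr_sum[ok] += c[ok]
        corr_cnt += ok
    with np.errstate(invalid="ignore"):
        corr = np.where(corr_cnt > 0, corr_sum / np.maximum(corr_cnt, 1), 0.0)
    # hemisphere averaging: a left cluster's correlation block averaged with
    # its homotopic partner's block
    hemi_avg = 0.5 * (corr[:k, :k] + corr[k:, k:])

    functional = functional_kmeans(hemi_avg, params)
    parc = enforce_spatial_constraints(
        functional, clustering.centroids[:k], params, midline_axis=midline_axis
    )

    parcel_of_spatial = np.full(2 * k, -1, dtype=np.intp)
    for p, mem in enumerate(parc.members):
        parcel_of_spatial[mem] = p
    for s in subjects:
        parc.parcel_of_cell[s] = parcel_of_spatial[cluster_of_cell[s]]

    counts = np.zeros(parc.n_parcels, dtype=int)
    all_subj = np.zeros(parc.n_parcels, dtype=int)
    for s in subjects:
        cnt = np.bincount(parc.parcel_of_cell[s], minlength=parc.n_parcels)
        counts += cnt
        all_subj += cnt > 0
    parc.stats = {
        "cells_per_parcel": counts,
        "fraction_all_subjects": float(np.mean(all_subj == len(subjects))),
        "n_parcels": parc.n_parcels,
    }
    return parc
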