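"""Synthetic multi-subject calcium-imaging studies with planted network structure.

The generator emulates the statistical features that the downstream analyses
assume of real whole-brain single-cell recordings: hemispherically symmetric
3-D cell clouds, distance-dependent correlation decay with strong long-range
homotopic connections, a two-level (coarse -> fine) planted module hierarchy, a
shared global signal, condition-specific module reassignment for a designated
flexible cell subset, and independent per-subject noise.

Traces are Gaussian.  Calcium indicator kinetics and spiking are deliberately
not modeled: every analysis downstream uses zero-lag correlation only, so the
second-order structure of the traces is the entire contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .errors import InvalidSpecError, UnknownConditionError

SPONTANEOUS = "spontaneous"
#: Stimulus conditions of the study design: phototaxis, optomotor response,
#: looming response, dark-flash response.
STIMULUS_CONDITIONS = ("PT", "OMR", "Looming", "DF")
ALL_CONDITIONS = (SPONTANEOUS,) + STIMULUS_CONDITIONS


@dataclass(frozen=True)
class SyntheticBrainSpec:
    """Geometry and size of one synthetic brain.

    Parameters
    ----------
    n_cells_per_hemisphere : int
        Number of cells sampled in the left hemisphere (mirrored to the right).
    ellipsoid_semi_axes : tuple of float
        Semi-axes (pixels) of the whole-brain ellipsoid.  The default
        (150, 400, 100) gives a 300 x 800 x 200 px brain, the order of
        magnitude of a registered larval zebrafish volume in pixel units.
    midline_axis : int
        Index of the axis mirrored about the midplane (left-right axis).
    seed : int
        Seed for cell placement.
    """

    n_cells_per_hemisphere: int = 1000
    ellipsoid_semi_axes: tuple[float, float, float] = (150.0, 400.0, 100.0)
    midline_axis: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_hemisphere < 1:
            raise InvalidSpecError("n_cells_per_hemisphere must be >= 1")
        if len(self.ellipsoid_semi_axes) != 3 or min(self.ellipsoid_semi_axes) <= 0:
            raise InvalidSpecError("ellipsoid_semi_axes must be 3 positive reals")
        if self.midline_axis not in (0, 1, 2):
            raise InvalidSpecError("midline_axis must be 0, 1 or 2")


@dataclass
class CellPopulation:
    """Aligned 3-D cell coordinates with hemisphere labels for one subject."""

    positions: NDArray[np.float64]  # (n_cells, 3), pixels
    hemisphere: NDArray[np.str_]  # (n_cells,), "L" or "R"
    subject_id: str
    midline_axis: int = 0

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    def mirror_partner_index(self) -> NDArray[np.intp]:
        """Index of each cell's mirror-image cell (L cell i <-> R cell i+n/2)."""
        half = self.n_cells // 2
        return np.concatenate([np.arange(half) + half, np.arange(half)])


@dataclass
class PlantedStructure:
    """Ground-truth statistical structure planted in the generated traces.

    ``fine_of_cell`` assigns each cell to a fine module; ``coarse_of_fine``
    nests every fine module inside exactly one coarse module.  The three
    correlation targets set the structured correlation between cells in the
    same fine module, same coarse (different fine) module, and different
    coarse modules; they must be ordered decreasing.  ``decay_rate`` adds an
    exp(-decay_rate * distance) spatial correlation kernel on top of the
    module targets; 0 disables it.  ``condition_remap`` maps each stimulus
    condition to the fine-module labels taken by ``flexible_cells`` under that
    condition (the spontaneous condition always uses the base assignment).
    """

    fine_of_cell: NDArray[np.intp] | None
    coarse_of_fine: NDArray[np.intp] | None
    within_fine_corr: float = 0.6
    within_coarse_corr: float = 0.3
    between_corr: float = 0.05
    decay_rate: float = 0.01  # per pixel
    global_amp: float = 0.5
    noise_sd: float = 1.0
    #: Amplitude of per-subject latent signals with smooth spatial loading
    #: maps (drawn once per subject, shared across that subject's
    #: conditions).  This is what makes a subject an individual: it pushes
    #: intersubject FC similarity below self-similarity and strictly between
    #: 0 and 1.  Spatially smooth loadings are essential so the individuality
    #: survives parcel averaging, as regional idiosyncrasies do in real data.
    subject_amp: float = 2.5
    n_subject_modes: int = 80
    subject_mode_length: float = 40.0  # pixels
    flexible_cells: NDArray[np.intp] = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    condition_remap: dict[str, NDArray[np.intp]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ok = (
            0.0 <= self.between_corr <= self.within_coarse_corr
            <= self.within_fine_corr < 1.0
        )
        if not ok:
            raise InvalidSpecError(
                "need within_fine_corr >= within_coarse_corr >= between_corr >= 0, all < 1"
            )
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.global_amp < 0:
            raise InvalidSpecError("global_amp must be >= 0")
        if self.decay_rate < 0:
            raise InvalidSpecError("decay_rate must be >= 0")
        if self.subject_amp < 0:
            raise InvalidSpecError("subject_amp must be >= 0")
        if self.n_subject_modes < 1 or self.subject_mode_length <= 0:
            raise InvalidSpecError("invalid subject-mode parameters")
        for cond, labels in self.condition_remap.items():
            if len(labels) != len(self.flexible_cells):
                raise InvalidSpecError(
                    f"remap for condition {cond!r} must label every flexible cell"
                )

    @property
    def has_modules(self) -> bool:
        return self.fine_of_cell is not None

    def fine_assignment(self, condition: str) -> NDArray[np.intp] | None:
        """Fine-module label of every cell under the given condition."""
        if self.fine_of_cell is None:
            return None
        if condition == SPONTANEOUS:
            return self.fine_of_cell
        if condition not in self.condition_remap:
            raise UnknownConditionError(
                f"condition {condition!r} has no entry in condition_remap"
            )
        labels = self.fine_of_cell.copy()
        labels[self.flexible_cells] = self.condition_remap[condition]
        return labels

    def coarse_assignment(self, condition: str) -> NDArray[np.intp] | None:
        fine = self.fine_assignment(condition)
        if fine is None:
            return None
        return self.coarse_of_fine[fine]


@dataclass
class FluorescenceRecording:
    """Cells x frames fluorescence matrix for one subject and condition."""

    traces: NDArray[np.float64]  # (n_cells, n_frames)
    frame_rate: float  # volumes / second
    condition: str
    subject_id: str

    def __post_init__(self) -> None:
        if self.traces.ndim != 2 or self.traces.shape[1] < 2:
            raise InvalidSpecError("traces must be (n_cells, n_frames >= 2)")
        if not np.all(np.isfinite(self.traces)):
            raise InvalidSpecError("traces contain non-finite values")


@dataclass
class StudyDataset:
    """Everything one synthetic study provides: cells, recordings, ground truth."""

    populations: dict[str, CellPopulation]
    recordings: dict[tuple[str, str], FluorescenceRecording]  # (subject, condition)
    structure: PlantedStructure

    @property
    def subjects(self) -> list[str]:
        return sorted(self.populations)

    @property
    def conditions(self) -> list[str]:
        conds = sorted({c for (_, c) in self.recordings})
        # keep the canonical ordering: spontaneous first
        return [c for c in ALL_CONDITIONS if c in conds] + [
            c for c in conds if c not in ALL_CONDITIONS
        ]


def generate_cells(spec: SyntheticBrainSpec) -> CellPopulation:
    """Sample a hemispherically symmetric cell cloud inside an ellipsoid.

    Cells are rejection-sampled uniformly inside the left half of the
    ellipsoid (coordinate along ``midline_axis`` < 0) and mirrored exactly
    about the midplane, so every L cell has a bit-identical mirror R cell.
    """
    rng = np.random.default_rng(spec.seed)
    axes = np.asarray(spec.ellipsoid_semi_axes, dtype=float)
    n = spec.n_cells_per_hemisphere
    left = np.empty((0, 3))
    while left.shape[0] < n:
        cand = rng.uniform(-1.0, 1.0, size=(max(4 * n, 256), 3))
        inside = np.sum(cand**2, axis=1) < 1.0
        cand = cand[inside]
        # fold onto the left half-ellipsoid; the midline itself has measure zero
        cand[:, spec.midline_axis] = -np.abs(cand[:, spec.midline_axis])
        left = np.vstack([left, cand * axes])
    left = left[:n]
    right = left.copy()
    right[:, spec.midline_axis] *= -1.0
    positions = np.vstack([left, right])
    hemisphere = np.array(["L"] * n + ["R"] * n)
    return CellPopulation(
        positions=positions,
        hemisphere=hemisphere,
        subject_id="synthetic",
        midline_axis=spec.midline_axis,
    )


def default_structure(
    cells: CellPopulation,
    n_coarse: int = 2,
    n_fine: int = 4,
    n_flexible: int = 64,
    conditions: tuple[str, ...] = STIMULUS_CONDITIONS,
    seed: int = 0,
    **corr_kwargs,
) -> PlantedStructure:
    """Build a spatially compact, hemispherically symmetric planted structure.

    Fine modules are spatial k-means clusters of left-hemisphere cells,
    mirrored onto the right hemisphere (so each module is bilateral and its two
    halves are homotopic, giving the planted long-range mirror correlations).
    Fine modules nest into coarse modules by clustering their centroids.  The
    flexible set is the ``n_flexible`` cells nearest the centroid of fine
    module 0; under each stimulus condition they are reassigned to a different
    fine module (cycling through the others), which is what multilayer
    flexibility should recover.
    """
    from sklearn.cluster import KMeans

    if n_fine < n_coarse or n_coarse < 1:
        raise InvalidSpecError("need n_fine >= n_coarse >= 1")
    half = cells.n_cells // 2
    left_pos = cells.positions[:half]
    km = KMeans(n_clusters=n_fine, n_init=4, random_state=seed).fit(left_pos)
    fine_left = km.labels_.astype(np.intp)
    fine = np.concatenate([fine_left, fine_left])  # mirror cells share the module
    if n_coarse == n_fine:
        coarse_of_fine = np.arange(n_fine, dtype=np.intp)
    else:
        km2 = KMeans(n_clusters=n_coarse, n_init=4, random_state=seed + 1).fit(
            km.cluster_centers_
        )
        coarse_of_fine = km2.labels_.astype(np.intp)

    centroid0 = km.cluster_centers_[0]
    d0 = np.linalg.norm(cells.positions - centroid0, axis=1)
    in_mod0 = np.where(fine == 0)[0]
    order = in_mod0[np.argsort(d0[in_mod0])]
    flexible = np.sort(order[: min(n_flexible, len(order))])

    remap = {}
    for i, cond in enumerate(conditions):
        target = (1 + i % max(n_fine - 1, 1)) % n_fine
        remap[cond] = np.full(len(flexible), target, dtype=np.intp)

    return PlantedStructure(
        fine_of_cell=fine,
        coarse_of_fine=coarse_of_fine,
        flexible_cells=flexible,
        condition_remap=remap,
        **corr_kwargs,
    )


def _target_correlation(
    cells: CellPopulation, structure: PlantedStructure, condition: str
) -> NDArray[np.float64] | None:
    """Structured correlation matrix R = T + (1 - T) * exp(-lambda * D).

    T holds the planted module targets (1 on the diagonal); the spatial kernel
    raises nearby cells toward correlation 1 and decays to the module target.
    Returns None when the structure is empty (no modules, no spatial kernel).
    """
    n = cells.n_cells
    fine = structure.fine_assignment(condition)
    if fine is None and structure.decay_rate == 0:
        return None
    if fine is None:
        tree = np.eye(n)
    else:
        coarse = structure.coarse_of_fine[fine]
        same_fine = fine[:, None] == fine[None, :]
        same_coarse = coarse[:, None] == coarse[None, :]
        tree = np.where(
            same_fine,
            structure.within_fine_corr,
            np.where(same_coarse, structure.within_coarse_corr, structure.between_corr),
        )
        np.fill_diagonal(tree, 1.0)
    if structure.decay_rate > 0:
        diff = cells.positions[:, None, :] - cells.positions[None, :, :]
        dist = np.sqrt(np.sum(diff**2, axis=-1))
        kernel = np.exp(-structure.decay_rate * dist)
        r = tree + (1.0 - tree) * kernel
    else:
        r = tree
    return r


def _psd_factor(r: NDArray[np.float64]) -> NDArray[np.float64]:
    """Factor F with F F^T equal to the nearest-PSD projection of ``r``."""
    w, v = np.linalg.eigh(r)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _draw_traces(
    factor: NDArray[np.float64] | None,
    n_cells: int,
    n_frames: int,
    structure: PlantedStructure,
    rng: np.random.Generator,
    subject_loadings: NDArray[np.float64] | None = None,
) -> NDArray[np.float64]:
    traces = np.zeros((n_cells, n_frames))
    if factor is not None:
        traces += factor @ rng.standard_normal((factor.shape[1], n_frames))
    if subject_loadings is not None and structure.subject_amp > 0:
        m = subject_loadings.shape[1]
        z = rng.standard_normal((m, n_frames))
        traces += (structure.subject_amp / np.sqrt(m)) * subject_loadings @ z
    if structure.global_amp > 0:
        traces += structure.global_amp * rng.standard_normal(n_frames)[None, :]
    traces += structure.noise_sd * rng.standard_normal((n_cells, n_frames))
    return traces


def _subject_loading_maps(
    cells: CellPopulation, structure: PlantedStructure, rng: np.random.Generator
) -> NDArray[np.float64] | None:
    """Smooth spatial loading maps (Gaussian bumps at random anchor cells,
    centered and RMS-normalized), one column per subject-specific mode."""
    if structure.subject_amp == 0:
        return None
    m = structure.n_subject_modes
    anchors = cells.positions[rng.integers(0, cells.n_cells, size=m)]
    d2 = np.sum((cells.positions[:, None, :] - anchors[None, :, :]) ** 2, axis=-1)
    u = np.exp(-d2 / (2.0 * structure.subject_mode_length**2))
    u = u - u.mean(axis=0, keepdims=True)
    rms = np.sqrt(np.mean(u**2, axis=0, keepdims=True))
    rms[rms == 0] = 1.0
    return u / rms


def generate_activity(
    cells: CellPopulation,
    structure: PlantedStructure,
    n_frames: int,
    condition: str = SPONTANEOUS,
    seed: int = 0,
    frame_rate: float = 2.0,
) -> FluorescenceRecording:
    """Generate one recording whose correlation structure follows the plant.

    The trace of cell *i* is a structured Gaussian component (with the planted
    module / spatial-kernel correlation), plus ``global_amp`` times a shared
    global signal, plus ``noise_sd`` times independent noise.  With no modules
    and no spatial kernel the structured component is absent and the expected
    off-diagonal correlation is global_amp^2 / (global_amp^2 + noise_sd^2).
    """
    if n_frames < 2:
        raise InvalidSpecError("n_frames must be >= 2")
    r = _target_correlation(cells, structure, condition)
    factor = None if r is None else _psd_factor(r)
    rng = np.random.default_rng(seed)
    traces = _draw_traces(factor, cells.n_cells, n_frames, structure, rng)
    return FluorescenceRecording(
        traces=traces,
        frame_rate=frame_rate,
        condition=condition,
        subject_id=cells.subject_id,
    )


def generate_study(
    spec: SyntheticBrainSpec,
    structure: PlantedStructure,
    n_subjects: int = 3,
    conditions: tuple[str, ...] = ALL_CONDITIONS,
    n_frames: int = 1000,
    seed: int = 0,
    frame_rate: float = 2.0,
) -> StudyDataset:
    """Generate a multi-subject, multi-condition study.

    All subjects share the same (exactly aligned) cell cloud and the same
    planted structure; they differ by independent latent and noise draws, so
    intersubject FC similarity is intermediate between 0 and 1.  Per-subject,
    per-condition seeds are spawned deterministically from the master seed.
    """
    if n_subjects < 1:
        raise InvalidSpecError("n_subjects must be >= 1")
    if len(conditions) == 0:
        raise InvalidSpecError("conditions must be non-empty")
    if SPONTANEOUS not in conditions:
        raise InvalidSpecError("conditions must include the spontaneous condition")

    cells = generate_cells(spec)
    # one structured factor per condition, shared across subjects
    factors: dict[str, NDArray[np.float64] | None] = {}
    for cond in conditions:
        r = _target_correlation(cells, structure, cond)
        factors[cond] = None if r is None else _psd_factor(r)

    root = np.random.SeedSequence(seed)
    child_seeds = root.spawn(n_subjects * (len(conditions) + 1))
    populations: dict[str, CellPopulation] = {}
    recordings: dict[tuple[str, str], FluorescenceRecording] = {}
    k = 0
    for s in range(n_subjects):
        subject_id = f"sub-{s + 1:02d}"
        populations[subject_id] = CellPopulation(
            positions=cells.positions.copy(),
            hemisphere=cells.hemisphere.copy(),
            subject_id=subject_id,
            midline_axis=spec.midline_axis,
        )
        # subject individuality: loading maps drawn once per subject,
        # shared across all of this subject's conditions
        loadings = _subject_loading_maps(
            cells, structure, np.random.default_rng(child_seeds[k])
        )
        k += 1
        for cond in conditions:
            rng = np.random.default_rng(child_seeds[k])
            k += 1
            traces = _draw_traces(
                factors[cond], cells.n_cells, n_frames, structure, rng,
                subject_loadings=loadings,
            )
            recordings[(subject_id, cond)] = FluorescenceRecording(
                traces=traces,
                frame_rate=frame_rate,
                condition=cond,
                subject_id=subject_id,
            )
    return StudyDataset(populations=populations, recordings=recordings, structure=structure)
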