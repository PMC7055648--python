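"""Signed functional networks and phase-randomized surrogate nulls.

Edge weights are Fisher-transformed Pearson correlations between
parcel-averaged traces, giving a fully weighted, signed, symmetric matrix
with zero diagonal.  Surrogate networks are built from traces whose Fourier
amplitude spectra are preserved exactly while their phases are randomized,
destroying cross-correlation structure but keeping the marginal
autocorrelation of every trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.stats import spearmanr

from .errors import (
    IncompatibleNetworksError,
    InvalidSpecError,
    UndefinedCorrelationError,
)
from .parcellation import Parcellation
from .synthetic import FluorescenceRecording

#: correlations numerically at +-1 are clipped here before atanh
_R_CLIP = 1.0 - 1e-12


@dataclass
class FCNetwork:
    """Symmetric signed matrix of Fisher-z correlations plus node geometry."""

    weights: NDArray[np.float64]  # (N, N), zero diagonal
    coords: NDArray[np.float64]  # (N, 3)
    condition: str = "spontaneous"
    subject_id: str = "group"

    def __post_init__(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidSpecError("weights must be square")
        if not np.all(np.isfinite(w)):
            raise InvalidSpecError("weights contain non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def upper_triangle(self) -> NDArray[np.float64]:
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]


@dataclass
class SurrogateEnsemble:
    """Phase-randomized null networks sharing geometry with their source."""

    networks: list[FCNetwork] = field(default_factory=list)

    @property
    def n_surrogates(self) -> int:
        return len(self.networks)


def parcel_average_traces(
    recording: FluorescenceRecording, parcellation: Parcellation
) -> NDArray[np.float64]:
    """Average the traces of each parcel's constituent cells (row = parcel).

    A parcel with no cells for this subject gets a NaN row; callers must
    treat such parcels as missing (the group average drops them per edge).
    """
    assign = parcellation.parcel_of_cell[recording.subject_id]
    n, t = parcellation.n_parcels, recording.traces.shape[1]
    out = np.zeros((n, t))
    counts = np.bincount(assign[assign >= 0], minlength=n).astype(float)
    np.add.at(out, assign[assign >= 0], recording.traces[assign >= 0])
    present = counts > 0
    out[present] /= counts[present, None]
    out[~present] = np.nan
    return out


def compute_fc(
    parcel_traces: NDArray[np.float64],
    coords: NDArray[np.float64] | None = None,
    condition: str = "spontaneous",
    subject_id: str = "group",
) -> FCNetwork:
    """Fisher-z Pearson correlation network of parcel traces.

    A_ij = atanh(r_ij) for i != j; the diagonal is set to 0.  Correlations
    numerically at +-1 are clipped to +-(1 - 1e-12) before the transform.
    """
    x = np.asarray(parcel_traces, dtype=float)
    if x.shape[1] < 3:
        raise InvalidSpecError("need at least 3 frames")
    sd = x.std(axis=1)
    bad = np.where(~np.isfinite(sd) | (sd == 0))[0]
    if bad.size:
        raise UndefinedCorrelationError(
            f"constant or missing trace for parcel(s) {bad.tolist()}"
        )
    r = np.corrcoef(x)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = 0.5 * (z + z.T)
    if coords is None:
        coords = np.zeros((x.shape[0], 3))
    return FCNetwork(weights=z, coords=np.asarray(coords, dtype=float),
                     condition=condition, subject_id=subject_id)


def phase_randomized_surrogates(
    parcel_traces: NDArray[np.float64],
    n_surrogates: int,
    seed: int = 0,
    phases: NDArray[np.float64] | None = None,
) -> list[NDArray[np.float64]]:
    """Fourier phase-randomized surrogates of a traces matrix.

    Each surrogate trace keeps the source trace's amplitude spectrum exactly
    (hence its mean and variance) while its non-DC, non-Nyquist Fourier bins
    get independent uniform phase offsets; conjugate symmetry is implicit in
    the real FFT, so the surrogates are real-valued.

    ``phases`` is a test hook: an array of offsets (radians) applied to every
    trace of every surrogate instead of random draws; all-zero offsets
    reproduce the source exactly.
    """
    if n_surrogates < 1:
        raise InvalidSpecError("n_surrogates must be >= 1")
    x = np.asarray(parcel_traces, dtype=float)
    if x.shape[1] < 4:
        raise InvalidSpecError("need at least 4 frames")
    n, t = x.shape
    spec = np.fft.rfft(x, axis=1)
    n_bins = spec.shape[1]
    # bins whose phase may rotate freely: exclude DC, and Nyquist when T even
    free = slice(1, n_bins - 1 if t % 2 == 0 else n_bins)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_surrogates):
        if phases is None:
            offs = rng.uniform(0.0, 2.0 * np.pi, size=(n, n_bins))
        else:
            offs = np.broadcast_to(np.asarray(phases, dtype=float), (n, n_bins))
        rotated = spec.copy()
        rotated[:, free] = spec[:, free] * np.exp(1j * offs[:, free])
        out.append(np.fft.irfft(rotated, n=t, axis=1))
    return out


def group_average(networks: list[FCNetwork]) -> FCNetwork:
    """Element-wise mean of Fisher-z weights across networks."""
    if not networks:
        raise IncompatibleNetworksError("no networks to average")
    n = networks[0].n_nodes
    coords = networks[0].coords
    for net in networks[1:]:
        if net.n_nodes != n or not np.allclose(net.coords, coords):
            raise IncompatibleNetworksError("networks differ in size or coords")
    w = np.mean([net.weights for net in networks], axis=0)
    conds = {net.condition for net in networks}
    cond = conds.pop() if len(conds) == 1 else "mixed"
    return FCNetwork(weights=w, coords=coords.copy(), condition=cond, subject_id="group")


def surrogate_fc_similarity(
    source: FCNetwork, surrogates: list[FCNetwork] | SurrogateEnsemble
) -> NDArray[np.float64]:
    """Spearman similarity between source FC and each surrogate FC
    (upper-triangle elements)."""
    nets = surrogates.networks if isinstance(surrogates, SurrogateEnsemble) else surrogates
    src = source.upper_triangle()
    return np.array([spearmanr(src, s.upper_triangle()).statistic for s in nets])


def build_surrogate_ensemble(
    parcel_traces: NDArray[np.float64],
    coords: NDArray[np.float64],
    n_surrogates: int,
    seed: int = 0,
    condition: str = "spontaneous",
) -> SurrogateEnsemble:
    """FC networks of phase-randomized surrogate traces."""
    mats = phase_randomized_surrogates(parcel_traces, n_surrogates, seed=seed)
    nets = [
        compute_fc(m, coords=coords, condition=condition, subject_id=f"surrogate-{i}")
        for i, m in enumerate(mats)
    ]
    return SurrogateEnsemble(networks=nets)
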