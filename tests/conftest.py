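"""Shared fixtures: small planted instances used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from mesoconn import FCNetwork, PipelineConfig
from mesoconn.pipeline import simulate_stage
from mesoconn.synthetic import (
    PlantedStructure,
    SyntheticBrainSpec,
    generate_cells,
)


def planted_hierarchy_network(
    seed: int,
    n: int = 64,
    within_fine: float = 0.7,
    within_coarse: float = 0.35,
    between: float = 0.05,
    noise: float = 0.05,
):
    """64-node network with 2 coarse modules nesting 4 fine modules.

    Weights: within-fine 0.7, within-coarse 0.35, between 0.05, plus
    symmetric N(0, 0.05) noise; returns (network, fine labels, coarse labels).
    """
    rng = np.random.default_rng(seed)
    fine = np.repeat(np.arange(4), n // 4)
    coarse = fine // 2
    w = np.where(
        fine[:, None] == fine[None, :],
        within_fine,
        np.where(coarse[:, None] == coarse[None, :], within_coarse, between),
    ).astype(float)
    e = rng.normal(0.0, noise, (n, n))
    w = w + 0.5 * (e + e.T)
    np.fill_diagonal(w, 0.0)
    return FCNetwork(weights=w, coords=np.zeros((n, 3))), fine, coarse


def planted_flexibility_layers(
    seed: int,
    n: int = 64,
    n_modules: int = 4,
    n_flexible: int = 8,
    n_layers: int = 3,
    within: float = 0.6,
    between: float = 0.05,
    noise: float = 0.05,
):
    """Condition layers in which a designated node subset switches modules.

    Layer 0 uses the base 4-module partition; in each later layer the
    flexible nodes move to a different module.  Returns (layers, flexible
    node indices, per-layer ground-truth labels).
    """
    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(n_modules), n // n_modules)
    flexible = np.sort(rng.choice(n, size=n_flexible, replace=False))
    layers, truth = [], []
    for s in range(n_layers):
        lab = base.copy()
        if s > 0:
            lab[flexible] = (base[flexible] + s) % n_modules
        w = np.where(lab[:, None] == lab[None, :], within, between).astype(float)
        e = rng.normal(0.0, noise, (n, n))
        w = w + 0.5 * (e + e.T)
        np.fill_diagonal(w, 0.0)
        layers.append(FCNetwork(weights=w, coords=np.zeros((n, 3)), condition=f"c{s}"))
        truth.append(lab)
    return layers, flexible, truth


@pytest.fixture(scope="session")
def tiny_study():
    """Small planted study: 3 subjects, 3 conditions, 300 cells/hemisphere."""
    cfg = PipelineConfig(
        n_cells_per_hemisphere=300,
        n_subjects=3,
        conditions=("spontaneous", "PT", "OMR"),
        n_frames=400,
        seed=11,
    )
    return simulate_stage(cfg)


@pytest.fixture(scope="session")
def tiny_cells():
    return generate_cells(SyntheticBrainSpec(n_cells_per_hemisphere=150, seed=5))


@pytest.fixture(scope="session")
def two_module_structure(tiny_cells):
    n = tiny_cells.n_cells
    half = n // 2
    fine = np.zeros(n, dtype=np.intp)
    fine[tiny_cells.positions[:, 1] > 0] = 1  # split along the long axis
    return PlantedStructure(
        fine_of_cell=fine,
        coarse_of_fine=np.arange(2, dtype=np.intp),
        within_fine_corr=0.6,
        within_coarse_corr=0.1,
        between_corr=0.1,
        decay_rate=0.0,
        global_amp=0.0,
        noise_sd=1.0,
    )
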