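"""Shared fixtures: synthetic complexes and derived models.

Expensive trajectory generation and per-ligand model building are
session-scoped; individual tests treat them as read-only.
"""

import numpy as np
import pytest

from dynopharm.interaction_analysis import (
    build_model_ensemble,
    select_frequent_models,
)
from dynopharm.pharmacophore_build import build_final_model, merge_models
from dynopharm.synthetic_data import (
    OccupancySchedule,
    default_ligand_schedules,
    generate_complex_trajectory,
)


@pytest.fixture(scope="session")
def clean_complex():
    """A jitter-free 40-frame complex with its ground truth."""
    schedule = OccupancySchedule(n_frames=40, sigma=0.0, seed=11)
    return generate_complex_trajectory(schedule)


@pytest.fixture(scope="session")
def jittered_complex():
    """A 200-frame complex with default jitter and mixed occupancies."""
    schedule = OccupancySchedule(n_frames=200, sigma=0.15, seed=12)
    return generate_complex_trajectory(schedule)


@pytest.fixture(scope="session")
def ligand_models():
    """Per-ligand merged pharmacophore models for five synthetic ligands."""
    models = {}
    for name, schedule in default_ligand_schedules(
            n_frames=120, sigma=0.1, seed=10).items():
        traj, _truth = generate_complex_trajectory(schedule)
        ensemble = build_model_ensemble(traj)
        k = min(4, len(ensemble.histogram))
        merged = merge_models(select_frequent_models(ensemble, k))
        merged.name = name
        models[name] = merged
    return models


@pytest.fixture(scope="session")
def final_model_result(ligand_models):
    return build_final_model(list(ligand_models.values()))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
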