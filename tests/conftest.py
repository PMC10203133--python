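"""Shared fixtures: toy specimens, phantoms, and the session-scale closed loop.

The expensive fixtures (trained desk U-Net, crowded-tomogram benchmark) are
session-scoped so the restoration-quality and picking tests share one
training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from resttomo.structure_dynamics import compute_enm_modes, generate_toy_model
from resttomo.tomo_forward import DensityVolume


def make_phantom(box: int = 64, seed: int = 0) -> DensityVolume:
    """Smooth asymmetric phantom: a few Gaussian blobs, zero near the edge."""
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.meshgrid(*[np.arange(box)] * 3, indexing="ij")
    c = box // 2
    values = np.zeros((box, box, box))
    for _ in range(4):
        pos = c + rng.uniform(-box / 6, box / 6, 3)
        sig = rng.uniform(box / 16, box / 10)
        amp = rng.uniform(0.5, 1.5)
        values += amp * np.exp(
            -((zz - pos[0]) ** 2 + (yy - pos[1]) ** 2 + (xx - pos[2]) ** 2)
            / (2 * sig**2)
        )
    return DensityVolume(values, voxel_A=4.44)


def cc(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


@pytest.fixture(scope="session")
def toy_model():
    return generate_toy_model("disc_with_arms", 200, seed=1).centered()


@pytest.fixture(scope="session")
def toy_modes(toy_model):
    return compute_enm_modes(toy_model, cutoff_A=16.0)


@pytest.fixture()
def phantom():
    return make_phantom(box=64, seed=0)


@pytest.fixture(scope="session")
def closed_loop():
    """One desk-scale simulate→train→restore run shared across the suite."""
    from resttomo.workflows import closed_loop_desk_run

    return closed_loop_desk_run(seed=1, iterations=500)


@pytest.fixture(scope="session")
def picking_benchmark(closed_loop):
    """Crowded-tomogram template-matching benchmark on the shared model."""
    from resttomo.workflows import tomogram_picking_benchmark

    return tomogram_picking_benchmark(closed_loop.restorer, seed=2)
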