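"""Shared fixtures: all inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import geneopocket as gp
from geneopocket.training import TrainingConfig, fit


def shell_training_example(seed: int, random_orientation: bool = True):
    spec = gp.ShellComplexSpec(seed=seed, random_orientation=random_orientation)
    structure = gp.read_complex(gp.make_shell_complex(spec))
    stack = gp.compute_channels(structure)
    truth = gp.ligand_truth_mask(structure.ligand_atoms, stack.grid)
    return gp.TrainingExample(stack=stack, truth=truth,
                              identifier=f"shell-{seed}"), structure


@pytest.fixture(scope="session")
def shell_structure():
    pdb = gp.make_shell_complex(gp.ShellComplexSpec(seed=1))
    return gp.read_complex(pdb)


@pytest.fixture(scope="session")
def shell_stack(shell_structure):
    return gp.compute_channels(shell_structure)


@pytest.fixture(scope="session")
def cubic_shell_stack():
    """Shell channels on a cube-symmetric grid (for grid-rotation tests)."""
    structure = gp.read_complex(gp.make_shell_complex(gp.ShellComplexSpec(seed=3)))
    half = 17.0
    grid = gp.VoxelGrid(origin=np.array([-half] * 3), spacing=1.0,
                        dims=(34, 34, 34))
    return gp.compute_channels(structure, grid=grid)


@pytest.fixture(scope="session")
def generator_params():
    """A known, deliberately non-uniform parameter vector used as the
    data-generating model in recovery tests."""
    return gp.GENEOParams(
        sigmas=np.array([1.0, 1.5, 0.8, 1.2, 2.0, 1.0, 1.5, 0.9]),
        alphas=np.array([0.4, 0.2, 0.05, 0.05, 0.1, 0.05, 0.1, 0.05]),
        theta=0.6)


@pytest.fixture(scope="session")
def trained_shell_model():
    """Detector fitted on six randomly oriented shell complexes."""
    examples = [shell_training_example(s)[0] for s in range(100, 106)]
    result = fit(examples, TrainingConfig(epochs=12, seed=0))
    return result.params


def rotations24():
    """The 24 proper rotations of the cube as (perm, flips) acting on a
    3D array via transpose + axis reversal."""
    import itertools

    mats = []
    for perm in itertools.permutations(range(3)):
        for flips in itertools.product([1, -1], repeat=3):
            mat = np.zeros((3, 3))
            for i, p in enumerate(perm):
                mat[i, p] = flips[i]
            if np.linalg.det(mat) > 0:
                mats.append((perm, flips, mat))
    assert len(mats) == 24
    return mats


def rotate_field(field: np.ndarray, perm, flips) -> np.ndarray:
    out = np.transpose(field, perm)
    sl = tuple(slice(None, None, f) for f in flips)
    return out[sl].copy()
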