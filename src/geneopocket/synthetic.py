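"""Deterministic synthetic inputs: shell "proteins" with a cavity, phantom
channel stacks with known truth, and model-generated training sets.

The shell complex is a quasi-uniform spherical cage of C/N/O atoms with an
opening cap removed and a small heavy-atom "ligand" cluster at the center —
a geometric cartoon of a binding cavity that exercises every parsing and
channel code path while keeping atom counts desk-sized.  It does not attempt
residue chemistry, secondary structure, or realistic packing.

The phantoms skip structure entirely: each channel is a scaled ball
indicator plus i.i.d. Gaussian voxel noise, which gives full control of
signal/noise for the operator-property and parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .channels import (
    ChannelStack,
    N_CHANNELS,
    TruthMask,
    normalize_channels,
)
from .errors import FixtureSpecError
from .grids import VoxelGrid
from .model import run_model
from .structure_io import RawAtom, write_pdb
from .training import TrainingExample, volumetric_loss


# ---------------------------------------------------------------------------
# Shell complexes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShellComplexSpec:
    seed: int = 0
    shell_radius: float = 10.0          # Å
    opening_half_angle: float = 30.0    # degrees, cap removed around +z
    atom_spacing: float = 1.8           # Å, target spacing on the shell
    ligand_atom_count: int = 5
    element_probs: tuple[float, float, float] = (0.70, 0.15, 0.15)  # C, N, O
    jitter: float = 0.15                # Å, radial/tangential noise
    random_orientation: bool = False
    ligand_extent: float = 1.2          # Å, cluster radius at the center


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def make_shell_complex(spec: ShellComplexSpec = ShellComplexSpec()) -> str:
    """PDB text for a cavity-enclosing atom shell plus a centered ligand.

    Deterministic per seed.  Nitrogen and oxygen shell atoms receive a
    bonded hydrogen pointing into the cavity so the donor channel is
    non-degenerate.
    """
    if spec.shell_radius <= spec.ligand_extent + 2.0:
        raise FixtureSpecError("shell radius must exceed ligand extent + 2 Å")
    n_shell = int(4.0 * np.pi * spec.shell_radius ** 2 / spec.atom_spacing ** 2)
    if n_shell < 50:
        raise FixtureSpecError("shell would have fewer than 50 atoms")
    rng = np.random.default_rng(spec.seed)

    pts = _fibonacci_sphere(n_shell)
    cap_cos = np.cos(np.deg2rad(spec.opening_half_angle))
    pts = pts[pts[:, 2] < cap_cos]                 # remove the opening cap
    pos = pts * spec.shell_radius
    pos = pos + rng.normal(scale=spec.jitter, size=pos.shape)

    elements = rng.choice(["C", "N", "O"], size=len(pos),
                          p=list(spec.element_probs))

    lig_pos = rng.normal(scale=spec.ligand_extent / 2.0,
                         size=(spec.ligand_atom_count, 3))
    lig_pos = np.clip(lig_pos, -spec.ligand_extent, spec.ligand_extent)
    lig_elements = rng.choice(["C", "N", "O"], size=spec.ligand_atom_count,
                              p=[0.6, 0.2, 0.2])

    if spec.random_orientation:
        rot = _random_rotation(rng)
        pos = pos @ rot.T
        lig_pos = lig_pos @ rot.T

    protein: list[RawAtom] = []
    serial = 0
    for i, (p, el) in enumerate(zip(pos, elements)):
        serial += 1
        protein.append(RawAtom("ATOM", serial, el, "SHL", "A", i + 1, p, el))
        if el in ("N", "O"):
            u = p / np.linalg.norm(p)
            h = p - u * 1.0                        # hydrogen aimed at cavity
            serial += 1
            protein.append(RawAtom("ATOM", serial, "H", "SHL", "A", i + 1, h, "H"))

    ligand = [RawAtom("HETATM", serial + 1 + j, f"{el}{j + 1}", "LIG", "A",
                      900, p, el)
              for j, (p, el) in enumerate(zip(lig_pos, lig_elements))]
    return write_pdb(protein, ligand)


# ---------------------------------------------------------------------------
# Phantom channel stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    seed: int = 0
    dims: tuple[int, int, int] = (16, 16, 16)
    spacing: float = 1.0
    pocket_center: tuple[float, float, float] | None = None   # voxel units
    pocket_radius: float = 3.0                                # voxel units
    signal: tuple[float, ...] | float = 1.0
    noise_sigma: float = 0.1
    truth_radius: float | None = None

    def signal_vector(self) -> np.ndarray:
        s = np.broadcast_to(np.asarray(self.signal, dtype=float),
                            (N_CHANNELS,)).copy()
        return s


def make_phantom_channels(spec: PhantomSpec = PhantomSpec()
                          ) -> tuple[ChannelStack, TruthMask]:
    """Channels = per-channel signal * ball indicator + Gaussian noise,
    then min-max normalized; truth = the (possibly smaller) ball."""
    if spec.noise_sigma < 0:
        raise FixtureSpecError("noise sigma must be non-negative")
    dims = tuple(int(d) for d in spec.dims)
    center = np.asarray(spec.pocket_center if spec.pocket_center is not None
                        else [(d - 1) / 2.0 for d in dims], dtype=float)
    if np.any(center - spec.pocket_radius < -0.5) or \
       np.any(center + spec.pocket_radius > np.array(dims) - 0.5):
        raise FixtureSpecError("pocket ball must lie strictly inside the grid")

    grid = VoxelGrid(origin=np.zeros(3), spacing=spec.spacing, dims=dims)
    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    dist = np.sqrt((ii - center[0]) ** 2 + (jj - center[1]) ** 2
                   + (kk - center[2]) ** 2)
    ball = (dist <= spec.pocket_radius).astype(float)
    truth_r = spec.truth_radius if spec.truth_radius is not None else spec.pocket_radius
    truth = dist <= truth_r

    rng = np.random.default_rng(spec.seed)
    signal = spec.signal_vector()
    fields = np.empty((N_CHANNELS,) + dims)
    for i in range(N_CHANNELS):
        fields[i] = signal[i] * ball
        if spec.noise_sigma > 0:
            fields[i] += rng.normal(scale=spec.noise_sigma, size=dims)
    stack = ChannelStack(grid=grid, fields=fields,
                         empty_space_mask=np.ones(dims, dtype=bool))
    return normalize_channels(stack), TruthMask(grid=grid, values=truth)


# ---------------------------------------------------------------------------
# Model-generated datasets (parameter-recovery oracle)
# ---------------------------------------------------------------------------

def generate_from_model(params, n_examples: int, seed: int,
                        template: PhantomSpec = PhantomSpec(),
                        loss_k: float = 0.02, **model_kwargs
                        ) -> tuple[list[TrainingExample], list[float]]:
    """Draw phantom stacks, run the model, and define the truth as the
    top-scoring pocket's voxel set.

    Returns the examples plus the generating model's own hard-threshold
    loss on each (recomputed, not assumed to be 1: lower-ranked pockets
    also enter the prediction).  Raises if more than half of the draws
    yield no pocket at all.
    """
    if n_examples < 1:
        raise FixtureSpecError("n_examples must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(s) for s in ss.generate_state(4 * n_examples)]

    dims = np.array(template.dims)
    examples: list[TrainingExample] = []
    gen_losses: list[float] = []
    failures = 0
    draws = 0
    for child in child_seeds:
        if len(examples) >= n_examples:
            break
        draws += 1
        margin = template.pocket_radius + 1.0
        center = tuple(rng.uniform(margin, d - 1 - margin) for d in dims)
        spec = replace(template, seed=child, pocket_center=center)
        stack, _ = make_phantom_channels(spec)
        out = run_model(stack, params, **model_kwargs)
        if not out.pockets:
            failures += 1
            continue
        top = out.pockets[0]
        tau = np.zeros(stack.grid.dims, dtype=bool)
        tau[tuple(top.voxel_indices.T)] = True
        truth = TruthMask(grid=stack.grid, values=tau)
        gen_losses.append(volumetric_loss(out.psi_hat, tau, k=loss_k))
        examples.append(TrainingExample(stack=stack, truth=truth,
                                        identifier=f"phantom-{len(examples)}"))
    if failures > draws / 2 or len(examples) < n_examples:
        raise FixtureSpecError(
            f"generator degenerate: {failures}/{draws} draws had no pocket")
    return examples, gen_losses
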