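"""Operator core: per-channel convolution, convex combination, thresholding,
pocket extraction, scoring and descriptor summarization.

The full model (variant ``E-NE``) is a single layer of eight convolution
operators with radially symmetric L1-normalized kernels — one per channel,
each governed by a shape parameter sigma_i — followed by a convex combination
with weights alpha_i, min-max output normalization over the empty-space
voxels, a hard threshold theta, and 3D connected-component labeling.  The
ablation variants relax the structure: ``NE-NE`` uses free kernels that are
still L1-normalized (non-expansive but not rotation-equivariant), ``NE-E``
uses fully free kernels (neither property).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree

from .channels import ChannelStack, N_CHANNELS
from .errors import (
    EmptySpaceError,
    InvalidFieldError,
    InvalidWeightsError,
    KernelTooLargeError,
)
from .grids import VoxelGrid
from .kernels import (
    DEFAULT_FAMILIES,
    SIGMA_FLOOR_FACTOR,
    KernelSpec,
    build_kernel,
    l1_normalize,
)

SIMPLEX_TOL = 1e-9
DEFAULT_CONNECTIVITY = 26
DEFAULT_VOLUME_REF = 30.0      # voxels, scale of the volume adjustment
DEFAULT_SMALL_VOLUME = 100.0   # Å^3, below which a pocket is flagged small
VARIANTS = ("E-NE", "NE-NE", "NE-E")

# direct convolution below this tap count, FFT above
_FFT_TAP_THRESHOLD = 1500


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class GENEOParams:
    """The 17 learnable parameters of the equivariant model.

    sigmas : (8,) kernel shape parameters, Å
    alphas : (8,) convex combination weights (non-negative, sum to 1)
    theta  : threshold in [0, 1]
    """

    sigmas: np.ndarray
    alphas: np.ndarray
    theta: float
    families: tuple[str, ...] = DEFAULT_FAMILIES
    spacing: float = 1.0
    truncation_factor: float = 3.0

    def __post_init__(self) -> None:
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.sigmas.shape != (N_CHANNELS,) or self.alphas.shape != (N_CHANNELS,):
            raise ValueError("sigmas and alphas must have length 8")
        validate_simplex(self.alphas)
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must lie in [0, 1]")
        floor = SIGMA_FLOOR_FACTOR * self.spacing
        if np.any(self.sigmas < floor - 1e-12):
            raise ValueError(f"every sigma must be >= {floor}")
        if len(self.families) != N_CHANNELS:
            raise ValueError("families must have length 8")

    @property
    def n_learnable(self) -> int:
        return 2 * N_CHANNELS + 1

    def named_parameters(self) -> dict[str, float]:
        out = {f"sigma_{i + 1}": float(s) for i, s in enumerate(self.sigmas)}
        out.update({f"alpha_{i + 1}": float(a) for i, a in enumerate(self.alphas)})
        out["theta"] = float(self.theta)
        return out

    def build_kernels(self) -> list[KernelSpec]:
        return [build_kernel(fam, sig, self.spacing, self.truncation_factor)
                for fam, sig in zip(self.families, self.sigmas)]

    @classmethod
    def default(cls, spacing: float = 1.0,
                families: tuple[str, ...] = DEFAULT_FAMILIES) -> "GENEOParams":
        return cls(sigmas=np.full(N_CHANNELS, 2.0),
                   alphas=np.full(N_CHANNELS, 1.0 / N_CHANNELS),
                   theta=0.5, families=families, spacing=spacing)

    def to_dict(self) -> dict:
        return {"variant": "E-NE", "sigmas": self.sigmas.tolist(),
                "alphas": self.alphas.tolist(), "theta": float(self.theta),
                "families": list(self.families), "spacing": self.spacing,
                "truncation_factor": self.truncation_factor,
                "format_version": 1}

    @classmethod
    def from_dict(cls, d: dict) -> "GENEOParams":
        return cls(sigmas=np.array(d["sigmas"]), alphas=np.array(d["alphas"]),
                   theta=d["theta"], families=tuple(d["families"]),
                   spacing=d.get("spacing", 1.0),
                   truncation_factor=d.get("truncation_factor", 3.0))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GENEOParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FreeKernelParams:
    """Ablation-variant parameters: fully learnable kernel taps.

    ``l1_normalized=True`` gives the NE-NE variant (non-expansive, not
    equivariant); ``False`` gives NE-E (neither property guaranteed).
    """

    taps: list[np.ndarray]
    alphas: np.ndarray
    theta: float
    l1_normalized: bool = True
    spacing: float = 1.0

    def __post_init__(self) -> None:
        if len(self.taps) != N_CHANNELS:
            raise ValueError("need 8 kernels")
        self.taps = [np.asarray(t, dtype=float) for t in self.taps]
        self.alphas = np.asarray(self.alphas, dtype=float)
        validate_simplex(self.alphas)
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must lie in [0, 1]")

    @property
    def variant(self) -> str:
        return "NE-NE" if self.l1_normalized else "NE-E"

    def effective_taps(self) -> list[np.ndarray]:
        if self.l1_normalized:
            return [l1_normalize(t) for t in self.taps]
        return [t.copy() for t in self.taps]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def validate_simplex(alphas: np.ndarray, tol: float = SIMPLEX_TOL) -> None:
    alphas = np.asarray(alphas, dtype=float)
    if np.any(alphas < -tol) or abs(alphas.sum() - 1.0) > tol:
        raise InvalidWeightsError(
            f"weights off the simplex: sum={alphas.sum()}, min={alphas.min()}")


def apply_geneo(field: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Same-shape zero-padded convolution of a field with kernel taps."""
    if not np.all(np.isfinite(field)):
        raise InvalidFieldError("field contains NaN or infinity")
    if any(kt > ft for kt, ft in zip(taps.shape, field.shape)):
        raise KernelTooLargeError(
            f"kernel {taps.shape} larger than grid {field.shape}")
    if taps.size <= _FFT_TAP_THRESHOLD:
        return ndimage.convolve(field, taps, mode="constant", cval=0.0)
    return fftconvolve(field, taps, mode="same")


def convex_combine(fields: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Pointwise convex combination of the eight intermediate outputs."""
    validate_simplex(alphas)
    return np.tensordot(np.asarray(alphas, dtype=float), fields, axes=(0, 0))


def normalize_output(field: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Min-max rescale over the empty-space voxels, clamped to [0, 1]
    everywhere; a constant field maps to 0.5."""
    if not np.all(np.isfinite(field)):
        raise InvalidFieldError("field contains NaN or infinity")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptySpaceError("empty-space mask has no voxels")
    vals = field[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-300:
        return np.full_like(field, 0.5)
    return np.clip((field - lo) / (hi - lo), 0.0, 1.0)


def hard_threshold(psi: np.ndarray, theta: float,
                   mask: np.ndarray) -> np.ndarray:
    """Binary pocket indicator: strictly above theta and in empty space."""
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must lie in [0, 1]")
    return (psi > theta) & np.asarray(mask, dtype=bool)


_STRUCTURES = {6: ndimage.generate_binary_structure(3, 1),
               18: ndimage.generate_binary_structure(3, 2),
               26: ndimage.generate_binary_structure(3, 3)}


def label_pockets(binary: np.ndarray,
                  connectivity: int = DEFAULT_CONNECTIVITY) -> np.ndarray:
    """Label connected components 1..P (0 = background), deterministic scan
    order; connectivity is 6, 18 or 26."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    labels, _ = ndimage.label(np.asarray(binary, dtype=bool),
                              structure=_STRUCTURES[connectivity])
    return labels


# ---------------------------------------------------------------------------
# Pockets
# ---------------------------------------------------------------------------

@dataclass
class Pocket:
    rank: int
    label: int
    score: float
    mean_psi: float
    volume_voxels: int
    volume_A3: float
    voxel_indices: np.ndarray               # (V, 3) ints
    centroid: np.ndarray | None = None      # Å
    radius: float | None = None             # Å, equivalent-sphere radius
    hba_count: int | None = None
    hbd_count: int | None = None
    lipophilicity: float | None = None
    polarity: float | None = None
    small_flag: bool | None = None


def score_and_rank(psi: np.ndarray, labels: np.ndarray, grid: VoxelGrid,
                   volume_ref: float = DEFAULT_VOLUME_REF) -> list[Pocket]:
    """Score each labeled pocket and return them ranked.

    score = mean(psi over pocket voxels) * (1 - exp(-V / volume_ref)), a
    bounded monotone volume adjustment that damps tiny high-psi specks while
    preserving mean-psi ordering at equal volume.  Ties break by larger
    volume, then lower label.
    """
    n_labels = int(labels.max())
    pockets: list[Pocket] = []
    for lab in range(1, n_labels + 1):
        sel = labels == lab
        v = int(sel.sum())
        mean_psi = float(psi[sel].mean())
        score = mean_psi * (1.0 - np.exp(-v / volume_ref))
        pockets.append(Pocket(rank=0, label=lab, score=score, mean_psi=mean_psi,
                              volume_voxels=v, volume_A3=v * grid.voxel_volume,
                              voxel_indices=np.argwhere(sel)))
    pockets.sort(key=lambda p: (-p.score, -p.volume_voxels, p.label))
    for i, p in enumerate(pockets):
        p.rank = i + 1
    return pockets


def summarize_pockets(pockets: list[Pocket], stack: ChannelStack,
                      structure=None,
                      small_volume: float = DEFAULT_SMALL_VOLUME,
                      contact_cutoff: float = 4.0) -> list[Pocket]:
    """Fill the descriptor fields of ranked pockets in place.

    centroid: unweighted mean of member voxel centers; radius: radius of the
    equal-volume sphere; HBA/HBD: acceptor/donor protein atoms within
    ``contact_cutoff`` Å of any pocket voxel center; lipophilicity/polarity:
    means of the normalized lipophilic+hydrophilic composite and of the
    polar channel over pocket voxels; small flag: volume below
    ``small_volume`` Å^3.
    """
    grid = stack.grid
    atoms = list(structure.protein_atoms) if structure is not None else []
    acceptors = np.array([a.coords for a in atoms if a.is_acceptor]).reshape(-1, 3)
    donors = np.array([a.coords for a in atoms if a.is_donor]).reshape(-1, 3)
    for p in pockets:
        centers = grid.voxel_centers_of(p.voxel_indices)
        p.centroid = centers.mean(axis=0)
        p.radius = float((3.0 * p.volume_A3 / (4.0 * np.pi)) ** (1.0 / 3.0))
        p.small_flag = bool(p.volume_A3 < small_volume)
        sel = tuple(p.voxel_indices.T)
        lipo = 0.5 * (stack.fields[3][sel] + stack.fields[4][sel])
        p.lipophilicity = float(lipo.mean())
        p.polarity = float(stack.fields[5][sel].mean())
        if atoms:
            tree = cKDTree(centers)
            p.hba_count = int(sum(
                tree.query(acceptors)[0] <= contact_cutoff)) if len(acceptors) else 0
            p.hbd_count = int(sum(
                tree.query(donors)[0] <= contact_cutoff)) if len(donors) else 0
    return pockets


def pockets_to_frame(pockets: list[Pocket]) -> pd.DataFrame:
    rows = []
    for p in pockets:
        c = p.centroid if p.centroid is not None else (np.nan,) * 3
        rows.append({"rank": p.rank, "score": p.score, "mean_psi": p.mean_psi,
                     "volume_voxels": p.volume_voxels, "volume_A3": p.volume_A3,
                     "center_x": c[0], "center_y": c[1], "center_z": c[2],
                     "radius": p.radius, "hba": p.hba_count, "hbd": p.hbd_count,
                     "lipophilicity": p.lipophilicity, "polarity": p.polarity,
                     "small": p.small_flag})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full forward pass
# ---------------------------------------------------------------------------

@dataclass
class ModelOutput:
    grid: VoxelGrid
    psis: np.ndarray              # (8, *dims) intermediate operator outputs
    combined: np.ndarray          # pre-normalization convex combination
    psi: np.ndarray               # normalized pocket-likelihood field
    psi_hat: np.ndarray           # binary field
    labels: np.ndarray            # 0 background, 1..P pockets (raw scan order)
    pockets: list[Pocket] = dc_field(default_factory=list)


def _resolve_taps(params) -> tuple[list[np.ndarray], np.ndarray, float]:
    if isinstance(params, GENEOParams):
        return [k.taps for k in params.build_kernels()], params.alphas, params.theta
    if isinstance(params, FreeKernelParams):
        return params.effective_taps(), params.alphas, params.theta
    raise TypeError(f"unsupported parameter object {type(params)!r}")


def combined_field(stack: ChannelStack, params) -> np.ndarray:
    """Convolution layer + convex combination, before output normalization.

    This is the map whose non-expansivity the E-NE and NE-NE variants
    guarantee (unit-L1 kernels and convex weights).
    """
    taps, alphas, _ = _resolve_taps(params)
    psis = np.stack([apply_geneo(stack.fields[i], taps[i])
                     for i in range(N_CHANNELS)])
    return convex_combine(psis, alphas)


def run_model(stack: ChannelStack, params,
              connectivity: int = DEFAULT_CONNECTIVITY,
              volume_ref: float = DEFAULT_VOLUME_REF,
              small_volume: float = DEFAULT_SMALL_VOLUME,
              structure=None, variant: str | None = None) -> ModelOutput:
    """Full forward pass from channels to ranked, summarized pockets.

    ``variant`` is optional validation: it must agree with the parameter
    object's own kind (GENEOParams -> E-NE, FreeKernelParams -> NE-NE/NE-E).
    """
    if variant is not None:
        actual = "E-NE" if isinstance(params, GENEOParams) else params.variant
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        if variant != actual:
            raise ValueError(f"params are {actual}, not {variant}")
    taps, alphas, theta = _resolve_taps(params)
    psis = np.stack([apply_geneo(stack.fields[i], taps[i])
                     for i in range(N_CHANNELS)])
    combined = convex_combine(psis, alphas)
    psi = normalize_output(combined, stack.empty_space_mask)
    psi_hat = hard_threshold(psi, theta, stack.empty_space_mask)
    labels = label_pockets(psi_hat, connectivity)
    pockets = score_and_rank(psi, labels, stack.grid, volume_ref)
    summarize_pockets(pockets, stack, structure, small_volume)
    return ModelOutput(grid=stack.grid, psis=psis, combined=combined, psi=psi,
                       psi_hat=psi_hat, labels=labels, pockets=pockets)


def pockets_to_pdb(pockets: list[Pocket], grid: VoxelGrid) -> str:
    """Voxel clouds as pseudo-atom PDB (one HETATM per voxel center, residue
    number = rank) for molecular viewers."""
    lines = []
    serial = 0
    for p in pockets:
        for c in grid.voxel_centers_of(p.voxel_indices):
            serial += 1
            lines.append(f"HETATM{serial:>5d}  PKT PCK P{p.rank:>4d}    "
                         f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}  1.00  0.00"
                         f"           C")
    lines.append("END")
    return "\n".join(lines) + "\n"
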