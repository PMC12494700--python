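"""Cubic voxel grids around a structure.

Conventions: cells are half-open boxes ``[origin + i*s, origin + (i+1)*s)``
with centers at ``origin + (i + 1/2)*s``; indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyStructureError, GridTooLargeError

DEFAULT_SPACING = 1.0   # Å
DEFAULT_PADDING = 5.0   # Å
MAX_VOXELS = 20_000_000


@dataclass(frozen=True)
class VoxelGrid:
    origin: np.ndarray        # (3,) minimum corner, Å
    spacing: float            # Å, cubic voxels
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must each be >= 1")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume(self) -> float:
        return float(self.spacing ** 3)

    def axis_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[k] + (np.arange(self.dims[k]) + 0.5) * self.spacing
                     for k in range(3))

    def centers(self) -> np.ndarray:
        """All voxel centers as an array of shape ``dims + (3,)``."""
        cx, cy, cz = self.axis_centers()
        out = np.empty(self.dims + (3,))
        out[..., 0] = cx[:, None, None]
        out[..., 1] = cy[None, :, None]
        out[..., 2] = cz[None, None, :]
        return out

    def index_of(self, point: np.ndarray) -> tuple[int, int, int]:
        """Half-open owning voxel of a point (may fall outside dims)."""
        idx = np.floor((np.asarray(point, dtype=float) - self.origin) / self.spacing)
        return tuple(int(v) for v in idx)

    def voxel_centers_of(self, indices: np.ndarray) -> np.ndarray:
        """Centers (N, 3) for integer index rows (N, 3)."""
        return self.origin + (np.asarray(indices, dtype=float) + 0.5) * self.spacing

    def window(self, center: np.ndarray, radius: float
               ) -> tuple[slice, slice, slice] | None:
        """Index slices covering the axis-aligned box ``center ± radius``,
        clipped to the grid; None when the box misses the grid entirely."""
        lo = np.floor((center - radius - self.origin) / self.spacing).astype(int)
        hi = np.floor((center + radius - self.origin) / self.spacing).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, self.dims)
        if np.any(lo >= hi):
            return None
        return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def build_grid(atoms, spacing: float = DEFAULT_SPACING,
               padding: float = DEFAULT_PADDING,
               max_voxels: int = MAX_VOXELS) -> VoxelGrid:
    """Grid covering the atoms' bounding box (centers ± vdW radii) expanded
    by ``padding`` on every side; ``dims = ceil(extent / spacing)``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if padding < 0:
        raise ValueError("padding must be non-negative")
    atoms = list(atoms)
    if not atoms:
        raise EmptyStructureError("cannot build a grid around zero atoms")
    xyz = np.array([a.coords for a in atoms])
    radii = np.array([getattr(a, "vdw_radius", 0.0) for a in atoms])[:, None]
    lo = (xyz - radii).min(axis=0) - padding
    hi = (xyz + radii).max(axis=0) + padding
    dims = np.maximum(np.ceil((hi - lo) / spacing - 1e-9).astype(int), 1)
    n = int(np.prod(dims))
    if n > max_voxels:
        raise GridTooLargeError(f"grid of {n} voxels exceeds cap {max_voxels}")
    return VoxelGrid(origin=lo, spacing=spacing, dims=tuple(dims))
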