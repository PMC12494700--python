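"""The eight voxelized interaction-field channels and the ligand truth mask.

Channel order (fixed everywhere in the package):

======  ===============  =====================================================
index   name             value at voxel center x
======  ===============  =====================================================
0       distance         d(x, nearest atom center) - r of that atom
1       gravitational    sum m(a) / d(x, a)
2       electrostatic    sum q(a) / d(x, a)
3       lipophilic       sum l(a) / d(x, a), l = negative part of lipo coeff
4       hydrophilic      sum h(a) / d(x, a), h = positive part of lipo coeff
5       polar            sum p(a) / d(x, a), p in {0, 1}
6       hb_acceptor      sum -eps * (R^6 - 2 R^4),  R = R_min/d + 0.96
7       hb_donor         acceptor-style term * cos^2(ang1) * cos^2(ang2),
                         maximized over the donor's bonded hydrogens
======  ===============  =====================================================

All inverse-distance sums run over atoms within a spherical neighborhood
(default 10 Å) and the distance is clamped below at ``spacing / 2`` so values
inside atoms stay bounded.  Channels are min-max normalized to [0, 1] per
protein; a constant channel maps to 0.5.  The empty-space mask is where the
raw distance channel is non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyStructureError, EmptyTruthError, InvalidFieldError
from .grids import VoxelGrid, build_grid

CHANNEL_NAMES = ("distance", "gravitational", "electrostatic", "lipophilic",
                 "hydrophilic", "polar", "hb_acceptor", "hb_donor")
N_CHANNELS = 8
DEFAULT_CUTOFF = 10.0  # Å, neighborhood radius for the sum channels
HB_OFFSET = 0.96       # additive constant in R = R_min / d + offset


@dataclass
class ChannelStack:
    """Eight scalar fields on a shared grid plus the empty-space mask."""

    grid: VoxelGrid
    fields: np.ndarray                 # (8, *dims)
    empty_space_mask: np.ndarray       # bool, dims
    normalized: bool = False
    norm_records: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = (N_CHANNELS,) + self.grid.dims
        if self.fields.shape != expected:
            raise ValueError(f"fields shape {self.fields.shape} != {expected}")

    def copy(self) -> "ChannelStack":
        return ChannelStack(self.grid, self.fields.copy(),
                            self.empty_space_mask.copy(), self.normalized,
                            [dict(r) for r in self.norm_records])


@dataclass
class TruthMask:
    grid: VoxelGrid
    values: np.ndarray                 # bool, dims

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.grid.dims:
            raise ValueError("truth mask shape does not match grid dims")

    @property
    def count(self) -> int:
        return int(self.values.sum())

    def centroid(self) -> np.ndarray:
        idx = np.argwhere(self.values)
        if idx.size == 0:
            raise EmptyTruthError("truth mask is empty")
        return self.grid.voxel_centers_of(idx).mean(axis=0)


# ---------------------------------------------------------------------------
# Individual channels
# ---------------------------------------------------------------------------

def distance_channel(atoms, grid: VoxelGrid) -> np.ndarray:
    """Signed distance to the nearest atom surface (negative inside)."""
    atoms = list(atoms)
    if not atoms:
        raise EmptyStructureError("distance channel needs at least one atom")
    xyz = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms])
    tree = cKDTree(xyz)
    centers = grid.centers().reshape(-1, 3)
    d, idx = tree.query(centers)
    return (d - radii[idx]).reshape(grid.dims)


def inverse_distance_channel(atoms, grid: VoxelGrid, coefficient: str,
                             cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Sum of coef(a) / d(x, a) over atoms within ``cutoff`` of x.

    ``coefficient`` selects the per-atom scalar: ``mass``, ``charge``,
    ``lipo_neg`` (negative part, lipophilic channel), ``lipo_pos`` (positive
    part, hydrophilic channel) or ``polar``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    def coef(a) -> float:
        if coefficient == "mass":
            return a.mass
        if coefficient == "charge":
            return a.charge
        if coefficient == "lipo_neg":
            return min(a.lipo_coeff, 0.0)
        if coefficient == "lipo_pos":
            return max(a.lipo_coeff, 0.0)
        if coefficient == "polar":
            return float(a.polar)
        raise ValueError(f"unknown coefficient selector {coefficient!r}")

    out = np.zeros(grid.dims)
    centers = grid.centers()
    d_floor = grid.spacing / 2.0
    for a in atoms:
        c = coef(a)
        if c == 0.0:
            continue
        win = grid.window(a.coords, cutoff)
        if win is None:
            continue
        d = np.linalg.norm(centers[win] - a.coords, axis=-1)
        contrib = np.where(d <= cutoff, c / np.maximum(d, d_floor), 0.0)
        out[win] += contrib
    return out


def _hb_radial_term(d: np.ndarray, eps: float, rmin: float) -> np.ndarray:
    r = rmin / d + HB_OFFSET
    return -eps * (r ** 6 - 2.0 * r ** 4)


def hb_acceptor_channel(atoms, grid: VoxelGrid,
                        cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Lennard-Jones-style acceptor potential summed over acceptor atoms."""
    out = np.zeros(grid.dims)
    centers = grid.centers()
    d_floor = grid.spacing / 2.0
    for a in atoms:
        if not a.is_acceptor:
            continue
        win = grid.window(a.coords, cutoff)
        if win is None:
            continue
        d = np.linalg.norm(centers[win] - a.coords, axis=-1)
        term = _hb_radial_term(np.maximum(d, d_floor), a.hb_eps, a.hb_rmin)
        out[win] += np.where(d <= cutoff, term, 0.0)
    return out


def _cos_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Cosine of the angle between batched vectors u and v (broadcast)."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = np.maximum(nu * nv, 1e-12)
    return np.sum(u * v, axis=-1) / denom


def hb_donor_channel(atoms, grid: VoxelGrid,
                     cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Directional donor potential.

    Per donor D with hydrogen H the radial term is modulated by
    ``cos^2(ang1) * cos^2(ang2)`` where ang1 is the angle between D->H and
    H->x (zeroed past 90 degrees) and ang2 the angle between antecedent->D
    and D->x (factor 1 when D has no antecedent).  With several hydrogens
    the most favorable (maximal) hydrogen contribution is kept.
    """
    out = np.zeros(grid.dims)
    centers = grid.centers()
    d_floor = grid.spacing / 2.0
    for a in atoms:
        if not a.is_donor or not a.donor_hydrogens:
            continue
        win = grid.window(a.coords, cutoff)
        if win is None:
            continue
        x = centers[win]
        dx = x - a.coords
        d = np.linalg.norm(dx, axis=-1)
        radial = _hb_radial_term(np.maximum(d, d_floor), a.hb_eps, a.hb_rmin)

        if a.antecedent is not None:
            cos2 = _cos_angle(np.broadcast_to(a.coords - a.antecedent, dx.shape), dx)
            ang2_factor = cos2 ** 2
        else:
            ang2_factor = np.ones_like(d)

        best = None
        for h in a.donor_hydrogens:
            cos1 = _cos_angle(np.broadcast_to(h - a.coords, dx.shape), x - h)
            factor = np.where(cos1 > 0.0, cos1 ** 2, 0.0) * ang2_factor
            val = radial * factor
            best = val if best is None else np.maximum(best, val)
        out[win] += np.where(d <= cutoff, best, 0.0)
    return out


# ---------------------------------------------------------------------------
# Stack assembly, normalization, truth mask
# ---------------------------------------------------------------------------

def compute_channels(structure, grid: VoxelGrid | None = None,
                     cutoff: float = DEFAULT_CUTOFF,
                     spacing: float | None = None,
                     padding: float | None = None,
                     normalize: bool = True,
                     flips: tuple[bool, ...] | None = None) -> ChannelStack:
    """Compute all eight channels for a structure's protein atoms.

    When ``grid`` is omitted it is built from the protein with the given
    spacing/padding (package defaults otherwise).
    """
    atoms = structure.protein_atoms if hasattr(structure, "protein_atoms") else list(structure)
    if grid is None:
        kwargs = {}
        if spacing is not None:
            kwargs["spacing"] = spacing
        if padding is not None:
            kwargs["padding"] = padding
        grid = build_grid(atoms, **kwargs)

    fields = np.empty((N_CHANNELS,) + grid.dims)
    fields[0] = distance_channel(atoms, grid)
    fields[1] = inverse_distance_channel(atoms, grid, "mass", cutoff)
    fields[2] = inverse_distance_channel(atoms, grid, "charge", cutoff)
    fields[3] = inverse_distance_channel(atoms, grid, "lipo_neg", cutoff)
    fields[4] = inverse_distance_channel(atoms, grid, "lipo_pos", cutoff)
    fields[5] = inverse_distance_channel(atoms, grid, "polar", cutoff)
    fields[6] = hb_acceptor_channel(atoms, grid, cutoff)
    fields[7] = hb_donor_channel(atoms, grid, cutoff)

    stack = ChannelStack(grid=grid, fields=fields,
                         empty_space_mask=fields[0] >= 0.0)
    return normalize_channels(stack, flips) if normalize else stack


def normalize_channels(stack: ChannelStack,
                       flips: tuple[bool, ...] | None = None) -> ChannelStack:
    """Min-max rescale every channel to [0, 1] over the whole grid.

    A constant channel maps to the constant 0.5.  ``flips[i]`` inverts
    channel i's orientation (value -> 1 - value after rescaling); default is
    no flips.
    """
    if flips is None:
        flips = (False,) * N_CHANNELS
    if not np.all(np.isfinite(stack.fields)):
        raise InvalidFieldError("channel fields contain NaN or infinity")
    out = np.empty_like(stack.fields)
    records = []
    for i in range(N_CHANNELS):
        f = stack.fields[i]
        lo, hi = float(f.min()), float(f.max())
        if hi - lo < 1e-300:
            out[i] = 0.5
        else:
            out[i] = (f - lo) / (hi - lo)
            if flips[i]:
                out[i] = 1.0 - out[i]
        records.append({"channel": CHANNEL_NAMES[i], "min": lo, "max": hi,
                        "flipped": bool(flips[i])})
    return ChannelStack(grid=stack.grid, fields=out,
                        empty_space_mask=stack.empty_space_mask.copy(),
                        normalized=True, norm_records=records)


def save_stack(path, stack: ChannelStack, truth: TruthMask | None = None,
               ligand_coords=None) -> None:
    """Persist a stack (and optional truth/ligand) as a compressed array
    container with a JSON header describing the grid and normalization."""
    import json

    header = {"origin": stack.grid.origin.tolist(),
              "spacing": stack.grid.spacing, "dims": list(stack.grid.dims),
              "channels": list(CHANNEL_NAMES), "normalized": stack.normalized,
              "norm_records": stack.norm_records}
    arrays = {"fields": stack.fields,
              "empty_space_mask": stack.empty_space_mask,
              "header": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)}
    if truth is not None:
        arrays["truth"] = truth.values
    if ligand_coords is not None:
        arrays["ligand_coords"] = np.asarray(ligand_coords, dtype=float)
    np.savez_compressed(path, **arrays)


def load_stack(path) -> tuple[ChannelStack, TruthMask | None, np.ndarray | None]:
    """Inverse of :func:`save_stack`."""
    import json

    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        grid = VoxelGrid(origin=np.array(header["origin"]),
                         spacing=header["spacing"],
                         dims=tuple(header["dims"]))
        stack = ChannelStack(grid=grid, fields=data["fields"],
                             empty_space_mask=data["empty_space_mask"].astype(bool),
                             normalized=header["normalized"],
                             norm_records=header["norm_records"])
        truth = (TruthMask(grid=grid, values=data["truth"])
                 if "truth" in data else None)
        lig = data["ligand_coords"] if "ligand_coords" in data else None
    return stack, truth, lig


def ligand_truth_mask(ligand_atoms, grid: VoxelGrid) -> TruthMask:
    """Binary mask of voxels whose cube intersects any ligand heavy-atom
    sphere (exact sphere vs axis-aligned-box test).

    Hydrogens are ignored.  A zero-radius atom marks only its half-open
    owning voxel.  Tangency (zero-volume contact) does not count as overlap.
    """
    heavy = [a for a in ligand_atoms if not getattr(a, "is_hydrogen", False)]
    if not heavy:
        raise EmptyTruthError("ligand has no heavy atoms")
    values = np.zeros(grid.dims, dtype=bool)
    s = grid.spacing
    for a in heavy:
        r = a.vdw_radius
        if r <= 0.0:
            idx = grid.index_of(a.coords)
            if all(0 <= idx[k] < grid.dims[k] for k in range(3)):
                values[idx] = True
            continue
        win = grid.window(a.coords, r)
        if win is None:
            continue
        lo_corner = np.array([grid.origin[k] + win[k].start * s for k in range(3)])
        nx, ny, nz = (win[k].stop - win[k].start for k in range(3))
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        box_lo = lo_corner + np.stack([ii, jj, kk], axis=-1) * s
        box_hi = box_lo + s
        nearest = np.clip(a.coords, box_lo, box_hi)
        dist2 = np.sum((nearest - a.coords) ** 2, axis=-1)
        values[win] |= dist2 < r * r
    if not values.any():
        raise EmptyTruthError("ligand lies entirely outside the grid")
    return TruthMask(grid=grid, values=values)
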