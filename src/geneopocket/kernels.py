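"""Radially symmetric L1-normalized convolution kernels.

Each kernel is sampled from a radial profile on the voxel lattice, truncated
at ``truncation_factor * sigma``, and normalized so the absolute tap sum is
exactly 1.  Radial construction makes central symmetry K(v) = K(-v) exact,
which together with the L1 normalization makes the induced convolution
operator equivariant under grid rotations/translations and non-expansive in
the sup norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterFloorError

SIGMA_FLOOR_FACTOR = 0.25        # sigma >= 0.25 * spacing
DEFAULT_TRUNCATION = 3.0
FAMILIES = ("gaussian", "difference_of_gaussians", "spherical_shell")

#: Kernel family per channel: a signed difference-of-Gaussians for the
#: distance channel (responds to cavity-scale contrast) and plain Gaussians
#: for the interaction-potential channels.
DEFAULT_FAMILIES = ("difference_of_gaussians",) + ("gaussian",) * 7


@dataclass(frozen=True)
class KernelSpec:
    family: str
    sigma: float
    spacing: float
    truncation_radius: float
    taps: np.ndarray              # odd-cube array, sum|taps| == 1

    @property
    def radius_voxels(self) -> int:
        return self.taps.shape[0] // 2


def _radial_profile(family: str, r: np.ndarray, sigma: float) -> np.ndarray:
    if family == "gaussian":
        return np.exp(-(r ** 2) / (2.0 * sigma ** 2))
    if family == "difference_of_gaussians":
        # center-surround: unit-mass Gaussian minus unit-mass 2*sigma Gaussian
        g1 = np.exp(-(r ** 2) / (2.0 * sigma ** 2))
        g2 = np.exp(-(r ** 2) / (2.0 * (2.0 * sigma) ** 2))
        return g1 / max(g1.sum(), 1e-300) - g2 / max(g2.sum(), 1e-300)
    if family == "spherical_shell":
        width = max(sigma / 3.0, 1e-6)
        return np.exp(-((r - sigma) ** 2) / (2.0 * width ** 2))
    raise ValueError(f"unknown kernel family {family!r}")


def build_kernel(family: str, sigma: float, spacing: float = 1.0,
                 truncation_factor: float = DEFAULT_TRUNCATION) -> KernelSpec:
    """Sample, truncate and L1-normalize a radial kernel.

    The shape parameter ``sigma`` (Å) regulates the kernel's spatial extent;
    it must stay above ``0.25 * spacing`` to remain resolvable on the
    lattice.
    """
    floor = SIGMA_FLOOR_FACTOR * spacing
    if sigma < floor - 1e-12:
        raise ParameterFloorError(f"sigma {sigma} below floor {floor}")
    if family not in FAMILIES:
        raise ValueError(f"unknown kernel family {family!r}")
    trunc = truncation_factor * sigma
    radius = max(int(np.ceil(trunc / spacing)), 1)
    ax = np.arange(-radius, radius + 1)
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    r = spacing * np.sqrt(ii ** 2 + jj ** 2 + kk ** 2)
    taps = _radial_profile(family, r, sigma)
    taps[r > trunc] = 0.0
    norm = np.abs(taps).sum()
    if norm <= 0:
        raise ParameterFloorError("kernel vanished after truncation")
    taps = taps / norm
    return KernelSpec(family=family, sigma=float(sigma), spacing=float(spacing),
                      truncation_radius=float(trunc), taps=taps)


def l1_normalize(taps: np.ndarray) -> np.ndarray:
    """Scale free taps so sum|taps| = 1 (the NE-NE ablation constraint)."""
    norm = np.abs(taps).sum()
    if norm <= 0:
        raise ValueError("cannot L1-normalize an all-zero kernel")
    return taps / norm
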