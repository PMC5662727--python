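"""Anisotropic 3D image container.

Arrays are stored in ``(z, y, x)`` order with 0-based indices; all physical
coordinates elsewhere in the package are micrometres (μm) in ``(x, y, z)``
order.  The physical position of voxel ``(i, j, k)`` (array order) is
``origin + (k*vx, j*vy, i*vz)``, i.e. voxel centres sit on integer multiples
of the voxel pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack3D:
    """A 3D grayscale volume with physical voxel sizes.

    Parameters
    ----------
    voxels
        ``(z, y, x)`` array of non-negative intensities.
    voxel_size_um
        Voxel pitch ``(vx, vy, vz)`` in μm.
    origin_um
        Physical position of voxel ``(0, 0, 0)``, in μm ``(x, y, z)``.
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        self.origin_um = tuple(float(v) for v in self.origin_um)
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_um}")
        if np.issubdtype(self.voxels.dtype, np.floating) and np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape_voxels(self) -> tuple[int, int, int]:
        """Array shape in ``(z, y, x)`` order."""
        return self.voxels.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent ``(x, y, z)`` in μm (number of voxels × pitch)."""
        nz, ny, nx = self.voxels.shape
        vx, vy, vz = self.voxel_size_um
        return (nx * vx, ny * vy, nz * vz)

    def index_to_um(self, index: tuple[int, int, int]) -> tuple[float, float, float]:
        """Physical (x, y, z) μm position of voxel ``(i, j, k)`` (array order)."""
        i, j, k = index
        vx, vy, vz = self.voxel_size_um
        ox, oy, oz = self.origin_um
        return (ox + k * vx, oy + j * vy, oz + i * vz)

    def um_to_index(self, pos_um: tuple[float, float, float]) -> tuple[int, int, int]:
        """Array index ``(i, j, k)`` of the voxel whose centre is nearest ``pos_um``.

        Ties at half-pitch are broken toward the larger index (half-open
        ownership), so boundary points have a deterministic owner.
        """
        x, y, z = pos_um
        vx, vy, vz = self.voxel_size_um
        ox, oy, oz = self.origin_um
        k = int(np.floor((x - ox) / vx + 0.5))
        j = int(np.floor((y - oy) / vy + 0.5))
        i = int(np.floor((z - oz) / vz + 0.5))
        return (i, j, k)

    def contains_um(self, pos_um: tuple[float, float, float]) -> bool:
        """Whether ``pos_um`` falls within the voxel grid (nearest-centre rule)."""
        i, j, k = self.um_to_index(pos_um)
        nz, ny, nx = self.voxels.shape
        return 0 <= i < nz and 0 <= j < ny and 0 <= k < nx


def voxel_volume_um3(voxel_size_um: tuple[float, float, float]) -> float:
    vx, vy, vz = voxel_size_um
    return float(vx) * float(vy) * float(vz)


def grid_shape_for_extent(
    shape_um: tuple[float, float, float],
    voxel_size_um: tuple[float, float, float],
) -> tuple[int, int, int]:
    """Array shape ``(z, y, x)`` covering a physical extent ``(x, y, z)`` μm."""
    ex, ey, ez = shape_um
    vx, vy, vz = voxel_size_um
    nx = max(1, int(round(ex / vx)))
    ny = max(1, int(round(ey / vy)))
    nz = max(1, int(round(ez / vz)))
    return (nz, ny, nx)


@dataclass
class BinaryMask3D:
    """Boolean foreground mask aligned with a parent :class:`ImageStack3D`."""

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        self.origin_um = tuple(float(v) for v in self.origin_um)

    @property
    def shape_voxels(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())
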