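"""Foreground extraction and block decomposition.

Foreground is obtained by global thresholding (Otsu on a 256-bin histogram,
or a fixed threshold) followed by morphological erosion and small-component
removal.  Large volumes are processed block-wise: disjoint half-open core
tiles plus a halo margin so a soma straddling a seam is fully visible to the
block that owns its centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .stack import BinaryMask3D, ImageStack3D


def binarize(
    stack: ImageStack3D,
    method: str = "otsu",
    threshold: float | None = None,
) -> BinaryMask3D:
    """Global binarization: voxel is foreground iff intensity >= threshold.

    ``method="otsu"`` computes the threshold on the full-stack 256-bin
    histogram; ``method="fixed"`` uses the given value.  A constant-intensity
    stack has no separable classes and raises under Otsu.
    """
    v = stack.voxels
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed binarization requires a threshold")
        t = float(threshold)
    elif method == "otsu":
        if v.min() == v.max():
            raise ValueError(
                "constant-intensity stack: Otsu threshold is undefined"
            )
        t = float(threshold_otsu(v, nbins=256))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return BinaryMask3D(v >= t, stack.voxel_size_um, stack.origin_um)


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # face neighbours


def erode(mask: BinaryMask3D, repetitions: int = 1) -> BinaryMask3D:
    """6-connected morphological erosion, applied ``repetitions`` times.

    Operates in voxel space (not isotropic in μm on anisotropic grids);
    ``repetitions=0`` is the identity.
    """
    if repetitions < 0:
        raise ValueError("repetitions must be >= 0")
    if repetitions == 0:
        return BinaryMask3D(mask.voxels.copy(), mask.voxel_size_um, mask.origin_um)
    out = ndimage.binary_erosion(
        mask.voxels, structure=_STRUCT6, iterations=repetitions
    )
    return BinaryMask3D(out, mask.voxel_size_um, mask.origin_um)


def remove_small_components(
    mask: BinaryMask3D, min_component_voxels: int
) -> BinaryMask3D:
    """Drop 26-connected components smaller than ``min_component_voxels``."""
    if min_component_voxels <= 1:
        return mask
    struct26 = np.ones((3, 3, 3), dtype=bool)
    lab, n = ndimage.label(mask.voxels, structure=struct26)
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_component_voxels
    keep[0] = False
    return BinaryMask3D(keep[lab], mask.voxel_size_um, mask.origin_um)


def extract_foreground(
    stack: ImageStack3D,
    method: str = "otsu",
    threshold: float | None = None,
    erosion_reps: int = 1,
    min_component_voxels: int = 20,
) -> BinaryMask3D:
    """binarize → erode → remove small 26-connected components."""
    mask = binarize(stack, method=method, threshold=threshold)
    mask = erode(mask, erosion_reps)
    return remove_small_components(mask, min_component_voxels)


@dataclass
class Block:
    """One processing block: half-open core tile plus clipped padded region.

    Regions are (x, y, z) interval pairs in μm; voxel slices are the grid
    realisation on a given stack (core half-open in voxel index space).
    """

    block_id: int
    core_lo_um: tuple[float, float, float]
    core_hi_um: tuple[float, float, float]
    padded_lo_um: tuple[float, float, float]
    padded_hi_um: tuple[float, float, float]
    core_slices: tuple[slice, slice, slice]  # (z, y, x)
    padded_slices: tuple[slice, slice, slice]

    def owns_um(self, pos: tuple[float, float, float]) -> bool:
        """Half-open ownership: lo <= pos < hi on each axis."""
        return all(
            lo <= p < hi
            for p, lo, hi in zip(pos, self.core_lo_um, self.core_hi_um)
        )


@dataclass
class BlockLayout:
    block_size_um: tuple[float, float, float]
    halo_um: float
    blocks: list[Block]


def decompose_blocks(
    stack: ImageStack3D,
    block_size_um: tuple[float, float, float] = (512.0, 512.0, 512.0),
    halo_um: float = 20.0,
) -> BlockLayout:
    """Tile a stack into half-open core blocks with a halo margin.

    Core tiles partition the voxel grid exactly once; padded regions extend
    cores by ``halo_um``, clipped at the volume bounds.
    """
    if any(b <= 0 for b in block_size_um):
        raise ValueError("block size must be positive")
    if halo_um < 0:
        raise ValueError("halo must be >= 0")
    vx, vy, vz = stack.voxel_size_um
    if block_size_um[0] < vx or block_size_um[1] < vy or block_size_um[2] < vz:
        raise ValueError("block size must be at least one voxel per axis")

    nz, ny, nx = stack.voxels.shape
    nvox = (nx, ny, nz)
    pitch = (vx, vy, vz)
    # per-axis core edges, in voxels
    bvox = [max(1, int(round(block_size_um[a] / pitch[a]))) for a in range(3)]
    hvox = [int(np.ceil(halo_um / pitch[a])) for a in range(3)]
    edges = []
    for a in range(3):
        e = list(range(0, nvox[a], bvox[a])) + [nvox[a]]
        edges.append(e)

    blocks: list[Block] = []
    bid = 0
    for iz in range(len(edges[2]) - 1):
        for iy in range(len(edges[1]) - 1):
            for ix in range(len(edges[0]) - 1):
                lo = (edges[0][ix], edges[1][iy], edges[2][iz])  # (x, y, z) voxels
                hi = (edges[0][ix + 1], edges[1][iy + 1], edges[2][iz + 1])
                plo = tuple(max(0, lo[a] - hvox[a]) for a in range(3))
                phi = tuple(min(nvox[a], hi[a] + hvox[a]) for a in range(3))
                blocks.append(
                    Block(
                        block_id=bid,
                        core_lo_um=tuple(lo[a] * pitch[a] for a in range(3)),
                        core_hi_um=tuple(hi[a] * pitch[a] for a in range(3)),
                        padded_lo_um=tuple(plo[a] * pitch[a] for a in range(3)),
                        padded_hi_um=tuple(phi[a] * pitch[a] for a in range(3)),
                        core_slices=(
                            slice(lo[2], hi[2]),
                            slice(lo[1], hi[1]),
                            slice(lo[0], hi[0]),
                        ),
                        padded_slices=(
                            slice(plo[2], phi[2]),
                            slice(plo[1], phi[1]),
                            slice(plo[0], phi[0]),
                        ),
                    )
                )
                bid += 1
    return BlockLayout(tuple(float(b) for b in block_size_um), float(halo_um), blocks)
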