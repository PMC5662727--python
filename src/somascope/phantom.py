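"""Synthetic 3D fluorescence phantoms with known soma ground truth.

Emulates sparsely labelled somas in an anisotropic image stack: intensity
ellipsoids (ovoid/spindle cell bodies), optional disjoint-but-z-aligned soma
pairs (the configuration that planar projection counting merges), dim
neurite-like tube clutter, uniform background and additive Gaussian noise.
Every run is fully determined by the spec's seed, so the ground truth can
serve as the evaluation reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .regions import UM3_PER_MM3, RegionLabelVolume
from .stack import ImageStack3D, grid_shape_for_extent, voxel_volume_um3

PLACEMENT_ATTEMPTS_PER_SOMA = 10_000


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place the requested somas."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could only place {achieved} of {requested} somas under the "
            "minimum-separation constraint"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass
class PhantomSpec:
    """Parameters of one synthetic volume.

    ``radius_dist`` is ``((a, b, c), jitter)``: mean ellipsoid semi-axes in μm
    with a ≥ b ≥ c, each multiplied per-soma by a uniform factor in
    ``[1 - jitter, 1 + jitter]``.  ``axial_pair_fraction`` is the fraction of
    somas placed as disjoint z-aligned pairs (centre gap sampled in
    ``[2c + 2, 2c + 6]`` μm so the pair is disjoint in 3D yet overlaps in a
    z-projection).  ``density`` (somas/mm³) may be given instead of
    ``n_somas``.  ``centres_um``, when provided, fixes the soma centres
    explicitly and bypasses random placement.
    """

    shape_um: tuple[float, float, float] = (100.0, 100.0, 100.0)
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 2.0)
    n_somas: int | None = 20
    density: float | None = None
    radius_dist: tuple[tuple[float, float, float], float] = ((6.0, 5.0, 4.0), 0.2)
    min_separation_um: float = 14.0
    axial_pair_fraction: float = 0.0
    neurite_density: float = 0.0
    neurite_radius_um: tuple[float, float] = (0.5, 1.0)
    neurite_length_um: float = 60.0
    soma_intensity: float = 200.0
    neurite_intensity: float | None = None
    background_intensity: float = 10.0
    noise_sigma: float = 5.0
    seed: int = 0
    centres_um: list[tuple[float, float, float]] | None = None
    random_orientation: bool = True

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.shape_um):
            raise ValueError("physical extents must be positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if not 0.0 <= self.axial_pair_fraction <= 1.0:
            raise ValueError("axial_pair_fraction must be in [0, 1]")
        if self.min_separation_um < 0:
            raise ValueError("min_separation_um must be >= 0")
        if self.soma_intensity <= self.background_intensity:
            raise ValueError("soma_intensity must exceed background_intensity")
        axes, jitter = self.radius_dist
        a, b, c = axes
        if not (a >= b >= c > 0):
            raise ValueError("mean semi-axes must satisfy a >= b >= c > 0")
        if jitter < 0 or jitter >= 1:
            raise ValueError("radius jitter must be in [0, 1)")

    @property
    def volume_mm3(self) -> float:
        ex, ey, ez = self.shape_um
        return ex * ey * ez / UM3_PER_MM3

    def resolved_n_somas(self) -> int:
        if self.centres_um is not None:
            return len(self.centres_um)
        if self.n_somas is not None:
            return int(self.n_somas)
        if self.density is not None:
            return int(round(self.density * self.volume_mm3))
        raise ValueError("either n_somas, density or centres_um must be given")


@dataclass
class TruthSoma:
    id: int
    centre_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    orientation: np.ndarray  # 3x3 rotation, columns = ellipsoid axes in (x,y,z)
    pair_partner: int | None = None


@dataclass
class GroundTruthSet:
    """True soma centres/axes emitted by the generator; evaluation reference."""

    somas: list[TruthSoma]
    spec: PhantomSpec

    def __len__(self) -> int:
        return len(self.somas)

    def centres(self) -> np.ndarray:
        if not self.somas:
            return np.zeros((0, 3))
        return np.array([s.centre_um for s in self.somas], dtype=float)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix (sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


def _jittered_axes(spec: PhantomSpec, rng: np.random.Generator) -> tuple[float, float, float]:
    (a, b, c), jitter = spec.radius_dist
    f = rng.uniform(1 - jitter, 1 + jitter, size=3) if jitter > 0 else np.ones(3)
    axes = sorted([a * f[0], b * f[1], c * f[2]], reverse=True)
    return (axes[0], axes[1], axes[2])


def _place_somas(spec: PhantomSpec, rng: np.random.Generator) -> list[TruthSoma]:
    n_total = spec.resolved_n_somas()
    (a_mean, _, c_mean), _ = spec.radius_dist

    if spec.centres_um is not None:
        somas = []
        for i, c in enumerate(spec.centres_um):
            axes = _jittered_axes(spec, rng)
            rot = _random_rotation(rng) if spec.random_orientation else np.eye(3)
            somas.append(TruthSoma(i + 1, tuple(float(v) for v in c), axes, rot))
        return somas

    ex, ey, ez = spec.shape_um
    margin = a_mean * (1 + spec.radius_dist[1])
    if 2 * margin >= min(ex, ey, ez):
        margin = min(ex, ey, ez) / 4  # tiny volumes: keep a usable interior
    lo = np.array([margin, margin, margin])
    hi = np.array([ex - margin, ey - margin, ez - margin])

    n_pairs = int(math.floor(spec.axial_pair_fraction * n_total / 2))
    placed: list[np.ndarray] = []
    pair_of: list[int | None] = []
    attempts_cap = PLACEMENT_ATTEMPTS_PER_SOMA * max(n_total, 1)
    attempts = 0

    def far_enough(p: np.ndarray, exempt: int | None = None) -> bool:
        for idx, q in enumerate(placed):
            if exempt is not None and idx == exempt:
                continue
            if np.linalg.norm(p - q) < spec.min_separation_um:
                return False
        return True

    # axial pairs first: anchor + z-offset partner, gap in [2c+2, 2c+6] μm
    for _ in range(n_pairs):
        ok = False
        while attempts < attempts_cap:
            attempts += 1
            p = rng.uniform(lo, hi)
            gap = rng.uniform(2 * c_mean + 2, 2 * c_mean + 6)
            q = p + np.array([0.0, 0.0, gap])
            if q[2] > hi[2]:
                continue
            if far_enough(p) and far_enough(q, exempt=len(placed)):
                placed.append(p)
                pair_of.append(len(placed))  # partner index (1-based id below)
                placed.append(q)
                pair_of.append(len(placed) - 2)
                ok = True
                break
        if not ok:
            raise PlacementError(n_total, len(placed))

    while len(placed) < n_total:
        if attempts >= attempts_cap:
            raise PlacementError(n_total, len(placed))
        attempts += 1
        p = rng.uniform(lo, hi)
        if far_enough(p):
            placed.append(p)
            pair_of.append(None)

    somas = []
    for i, p in enumerate(placed):
        axes = _jittered_axes(spec, rng)
        rot = _random_rotation(rng) if spec.random_orientation else np.eye(3)
        partner = pair_of[i]
        somas.append(
            TruthSoma(
                i + 1,
                (float(p[0]), float(p[1]), float(p[2])),
                axes,
                rot,
                pair_partner=(partner + 1) if partner is not None else None,
            )
        )
    return somas


def _rasterize_ellipsoid(
    frac: np.ndarray,
    soma: TruthSoma,
    voxel_size_um: tuple[float, float, float],
) -> None:
    """Accumulate (max) the partial-volume fraction of one ellipsoid.

    Fractions are estimated by 2×2×2 subvoxel sampling, which anti-aliases
    the boundary on the coarse anisotropic z-grid.
    """
    vx, vy, vz = voxel_size_um
    cx, cy, cz = soma.centre_um
    a = max(soma.semi_axes_um)
    nz, ny, nx = frac.shape

    k0 = max(0, int(math.floor((cx - a) / vx)) - 1)
    k1 = min(nx - 1, int(math.ceil((cx + a) / vx)) + 1)
    j0 = max(0, int(math.floor((cy - a) / vy)) - 1)
    j1 = min(ny - 1, int(math.ceil((cy + a) / vy)) + 1)
    i0 = max(0, int(math.floor((cz - a) / vz)) - 1)
    i1 = min(nz - 1, int(math.ceil((cz + a) / vz)) + 1)
    if k1 < k0 or j1 < j0 or i1 < i0:
        return

    # subvoxel offsets at ±1/4 pitch around each voxel centre
    off = np.array([-0.25, 0.25])
    xs = (np.arange(k0, k1 + 1)[:, None] + off[None, :]).ravel() * vx
    ys = (np.arange(j0, j1 + 1)[:, None] + off[None, :]).ravel() * vy
    zs = (np.arange(i0, i1 + 1)[:, None] + off[None, :]).ravel() * vz

    Z, Y, X = np.meshgrid(zs - cz, ys - cy, xs - cx, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)  # (..., 3) in (x, y, z)
    u = pts @ soma.orientation  # into ellipsoid frame
    ax = np.asarray(soma.semi_axes_um)
    inside = ((u / ax) ** 2).sum(axis=-1) <= 1.0

    nzz, nyy, nxx = i1 - i0 + 1, j1 - j0 + 1, k1 - k0 + 1
    inside = inside.reshape(nzz, 2, nyy, 2, nxx, 2)
    f = inside.mean(axis=(1, 3, 5))
    sub = frac[i0 : i1 + 1, j0 : j1 + 1, k0 : k1 + 1]
    np.maximum(sub, f, out=sub)


def _rasterize_neurites(
    frac: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> None:
    """Paint constant-radius random-walk tubes (binary occupancy)."""
    n_tubes = int(round(spec.neurite_density * spec.volume_mm3))
    if n_tubes == 0:
        return
    vx, vy, vz = spec.voxel_size_um
    nz, ny, nx = frac.shape
    ex, ey, ez = spec.shape_um
    step = 1.0  # μm per step
    n_steps = int(spec.neurite_length_um / step)
    for _ in range(n_tubes):
        r = rng.uniform(*spec.neurite_radius_um)
        p = rng.uniform([0, 0, 0], [ex, ey, ez])
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        for _ in range(n_steps):
            # stamp voxels with centre within r of the current point
            k0 = max(0, int(math.floor((p[0] - r) / vx)))
            k1 = min(nx - 1, int(math.ceil((p[0] + r) / vx)))
            j0 = max(0, int(math.floor((p[1] - r) / vy)))
            j1 = min(ny - 1, int(math.ceil((p[1] + r) / vy)))
            i0 = max(0, int(math.floor((p[2] - r) / vz)))
            i1 = min(nz - 1, int(math.ceil((p[2] + r) / vz)))
            if k1 >= k0 and j1 >= j0 and i1 >= i0:
                zz = np.arange(i0, i1 + 1) * vz - p[2]
                yy = np.arange(j0, j1 + 1) * vy - p[1]
                xx = np.arange(k0, k1 + 1) * vx - p[0]
                d2 = (
                    zz[:, None, None] ** 2
                    + yy[None, :, None] ** 2
                    + xx[None, None, :] ** 2
                )
                sub = frac[i0 : i1 + 1, j0 : j1 + 1, k0 : k1 + 1]
                np.maximum(sub, (d2 <= r * r).astype(np.float32), out=sub)
            p = p + step * d
            d = d + rng.normal(scale=0.25, size=3)
            d /= np.linalg.norm(d)
            p = np.clip(p, [0, 0, 0], [ex, ey, ez])


def generate_phantom(spec: PhantomSpec) -> tuple[ImageStack3D, GroundTruthSet]:
    """Render a phantom stack and its ground truth.

    Intensity model: background + per-voxel ellipsoid coverage fraction ×
    (soma − background), neurite tubes at an intermediate level, additive
    Gaussian noise, clipped to the uint16 range.  Same spec (incl. seed) ⇒
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = grid_shape_for_extent(spec.shape_um, spec.voxel_size_um)
    somas = _place_somas(spec, rng)

    frac = np.zeros(shape, dtype=np.float32)
    for s in somas:
        _rasterize_ellipsoid(frac, s, spec.voxel_size_um)

    img = spec.background_intensity + frac * (
        spec.soma_intensity - spec.background_intensity
    )

    if spec.neurite_density > 0:
        nfrac = np.zeros(shape, dtype=np.float32)
        _rasterize_neurites(nfrac, spec, rng)
        n_int = (
            spec.neurite_intensity
            if spec.neurite_intensity is not None
            else spec.background_intensity
            + 0.5 * (spec.soma_intensity - spec.background_intensity)
        )
        np.maximum(
            img,
            spec.background_intensity + nfrac * (n_int - spec.background_intensity),
            out=img,
        )

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape).astype(np.float32)

    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    stack = ImageStack3D(img, spec.voxel_size_um)
    return stack, GroundTruthSet(somas, spec)


def generate_region_atlas(
    shape_um: tuple[float, float, float],
    voxel_size_um: tuple[float, float, float],
    n_regions: int,
    seed: int = 0,
    densities_per_mm3: list[float] | None = None,
) -> tuple[RegionLabelVolume, dict[int, float]]:
    """Partition a volume into contiguous slab regions with target densities.

    The volume is split along x into ``n_regions`` contiguous slabs of
    near-equal voxel width, labelled 1..n; every voxel is covered.  Returns
    the label volume and a map label → target density (cells/mm³), drawn
    uniformly in [5,000, 50,000] when not supplied.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    shape = grid_shape_for_extent(shape_um, voxel_size_um)
    nz, ny, nx = shape
    if nx < n_regions:
        raise ValueError(
            f"voxel grid ({nx} columns) too small for {n_regions} regions"
        )
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)
    edges = np.linspace(0, nx, n_regions + 1).round().astype(int)
    for lab in range(1, n_regions + 1):
        labels[:, :, edges[lab - 1] : edges[lab]] = lab
    atlas = RegionLabelVolume(labels, voxel_size_um)
    if densities_per_mm3 is not None:
        if len(densities_per_mm3) != n_regions:
            raise ValueError("need one density per region")
        dens = {lab: float(densities_per_mm3[lab - 1]) for lab in range(1, n_regions + 1)}
    else:
        dens = {
            lab: float(rng.uniform(5_000, 50_000)) for lab in range(1, n_regions + 1)
        }
    return atlas, dens


def sample_atlas_centres(
    atlas: RegionLabelVolume,
    densities_per_mm3: dict[int, float],
    min_separation_um: float,
    seed: int,
    margin_um: float = 6.0,
) -> tuple[list[tuple[float, float, float]], dict[int, int]]:
    """Draw soma centres in each atlas region at the given densities.

    Expected counts are rounded from density × region volume; placement is
    rejection sampling with a minimum separation, keeping a margin from the
    volume faces so rendered somas stay inside.  Returns the centres and the
    per-region true counts.
    """
    rng = np.random.default_rng(seed)
    vx, vy, vz = atlas.voxel_size_um
    nz, ny, nx = atlas.labels.shape
    ext = np.array([nx * vx, ny * vy, nz * vz])
    centres: list[np.ndarray] = []
    counts: dict[int, int] = {}
    for lab in atlas.region_labels():
        n = int(round(densities_per_mm3[lab] * atlas.volumes_mm3[lab]))
        placed = 0
        attempts = 0
        cap = PLACEMENT_ATTEMPTS_PER_SOMA * max(n, 1)
        while placed < n and attempts < cap:
            attempts += 1
            p = rng.uniform([margin_um] * 3, ext - margin_um)
            if atlas.label_at_um((p[0], p[1], p[2])) != lab:
                continue
            if all(
                np.linalg.norm(p - q) >= min_separation_um for q in centres
            ):
                centres.append(p)
                placed += 1
        if placed < n:
            raise PlacementError(n, placed)
        counts[lab] = placed
    return [(float(p[0]), float(p[1]), float(p[2])) for p in centres], counts
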