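"""Region label volumes, per-region cell counts and densities.

A region label volume assigns every voxel an integer anatomical label
(0 = outside).  Per-region density is the cell count divided by the region's
physical volume in mm³, mirroring region-wise quantification of whole-brain
cell distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack import voxel_volume_um3

UM3_PER_MM3 = 1e9


@dataclass
class RegionLabelVolume:
    """Integer-labelled 3D volume on the same grid convention as ImageStack3D.

    Label 0 is reserved for "outside"; ``volumes_mm3`` maps each nonzero
    label to its physical volume (voxel count × voxel volume).
    """

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    name_table: dict[int, str] = field(default_factory=dict)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    volumes_mm3: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        self.origin_um = tuple(float(v) for v in self.origin_um)
        if not self.volumes_mm3:
            self.volumes_mm3 = self._compute_volumes()
        for lab in self.region_labels():
            self.name_table.setdefault(lab, f"region_{lab}")

    def _compute_volumes(self) -> dict[int, float]:
        vv = voxel_volume_um3(self.voxel_size_um)
        labs, counts = np.unique(self.labels, return_counts=True)
        return {
            int(l): float(c) * vv / UM3_PER_MM3
            for l, c in zip(labs, counts)
            if l != 0
        }

    def region_labels(self) -> list[int]:
        return sorted(self.volumes_mm3)

    def label_at_um(self, pos_um: tuple[float, float, float]) -> int:
        """Label of the voxel whose centre is nearest ``pos_um`` (half-open ties)."""
        x, y, z = pos_um
        vx, vy, vz = self.voxel_size_um
        ox, oy, oz = self.origin_um
        k = int(np.floor((x - ox) / vx + 0.5))
        j = int(np.floor((y - oy) / vy + 0.5))
        i = int(np.floor((z - oz) / vz + 0.5))
        nz, ny, nx = self.labels.shape
        if not (0 <= i < nz and 0 <= j < ny and 0 <= k < nx):
            raise ValueError(f"position {pos_um} μm is outside the atlas grid")
        return int(self.labels[i, j, k])


@dataclass
class RegionStats:
    """Cell count, volume and density (cells/mm³) for one region."""

    region: str
    label: int
    cell_count: int
    volume_mm3: float
    density_cells_per_mm3: float


def assign_regions(detections, atlas: RegionLabelVolume) -> dict[int, int]:
    """Map each detection id to the atlas label of the voxel holding its centre.

    Label 0 means "unassigned" (outside every named region).  A detection
    centre outside the atlas grid raises, naming the offending detection.
    """
    out: dict[int, int] = {}
    for det in detections:
        try:
            out[det.id] = atlas.label_at_um(det.centre_um)
        except ValueError as exc:
            raise ValueError(f"detection {det.id}: {exc}") from exc
    return out


def region_stats(
    assignment: dict[int, int], atlas: RegionLabelVolume
) -> list[RegionStats]:
    """Per-region counts and densities, plus unassigned and total rows.

    The "total" row sums counts over every region and the unassigned pool, so
    counts are conserved: Σ region counts + unassigned = number of detections.
    """
    counts: dict[int, int] = {lab: 0 for lab in atlas.region_labels()}
    unassigned = 0
    for lab in assignment.values():
        if lab == 0 or lab not in counts:
            unassigned += 1
        else:
            counts[lab] += 1
    rows: list[RegionStats] = []
    for lab in atlas.region_labels():
        vol = atlas.volumes_mm3[lab]
        n = counts[lab]
        if vol <= 0 and n > 0:
            raise ValueError(f"region {lab} has zero volume but {n} cells")
        rows.append(
            RegionStats(
                region=atlas.name_table.get(lab, f"region_{lab}"),
                label=lab,
                cell_count=n,
                volume_mm3=vol,
                density_cells_per_mm3=(n / vol if vol > 0 else 0.0),
            )
        )
    rows.append(RegionStats("unassigned", 0, unassigned, 0.0, 0.0))
    total_vol = sum(atlas.volumes_mm3.values())
    total_n = sum(counts.values()) + unassigned
    rows.append(
        RegionStats(
            "total", -1, total_n, total_vol, total_n / total_vol if total_vol else 0.0
        )
    )
    return rows


def region_stats_table(stats: list[RegionStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": s.region,
                "label": s.label,
                "cell_count": s.cell_count,
                "volume_mm3": s.volume_mm3,
                "density_cells_per_mm3": s.density_cells_per_mm3,
            }
            for s in stats
        ]
    )
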