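"""Standard-format I/O: multi-page TIFF stacks, soma SWC files, CSV tables.

The SWC dialect is soma-only: one parentless node per cell,
``id 1 x y z radius -1`` with coordinates in μm at three decimals.  TIFF
stacks carry no voxel-size metadata of their own here, so a JSON sidecar
(``<stack>.json``) holding ``voxel_size_um`` is required on read — the
pitch is never guessed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .localize import SomaDetection
from .phantom import GroundTruthSet
from .stack import ImageStack3D

SWC_HEADER = "# soma-only SWC: id type x_um y_um z_um radius_um parent\n"


def write_swc(detections: list[SomaDetection], path: str | Path) -> None:
    """One line per soma: ``id 1 x y z radius -1`` (type 1 = soma, no parent)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(SWC_HEADER)
        for d in detections:
            x, y, z = d.centre_um
            fh.write(f"{d.id} 1 {x:.3f} {y:.3f} {z:.3f} {d.radius_um:.3f} -1\n")


def read_swc(path: str | Path) -> list[SomaDetection]:
    """Parse a soma-only SWC file; malformed lines raise with their number."""
    out: list[SomaDetection] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 SWC fields, got {len(parts)}")
        try:
            sid = int(parts[0])
            x, y, z, r = (float(parts[i]) for i in (2, 3, 4, 5))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed SWC line") from exc
        out.append(SomaDetection(id=sid, centre_um=(x, y, z), radius_um=r, weight=0.0))
    return out


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack_tiff(stack: ImageStack3D, path: str | Path) -> None:
    """Multi-page TIFF (one page per z-plane) + JSON voxel-size sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels)
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "voxel_size_um": list(stack.voxel_size_um),
                "origin_um": list(stack.origin_um),
            }
        )
    )


def read_stack_tiff(path: str | Path, sidecar: str | Path | None = None) -> ImageStack3D:
    path = Path(path)
    sc = Path(sidecar) if sidecar else _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"voxel-size sidecar {sc} not found; the voxel pitch is never guessed"
        )
    meta = json.loads(sc.read_text())
    voxels = tifffile.imread(path)
    if voxels.ndim == 2:
        voxels = voxels[None, ...]
    return ImageStack3D(
        voxels,
        tuple(meta["voxel_size_um"]),
        tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
    )


def detections_to_frame(detections: list[SomaDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": d.id,
                "x_um": d.centre_um[0],
                "y_um": d.centre_um[1],
                "z_um": d.centre_um[2],
                "radius_um": d.radius_um,
                "weight": d.weight,
                "block": d.block_id,
            }
            for d in detections
        ],
        columns=["id", "x_um", "y_um", "z_um", "radius_um", "weight", "block"],
    )


def write_detections_csv(detections: list[SomaDetection], path: str | Path) -> None:
    detections_to_frame(detections).to_csv(path, index=False)


def read_detections_csv(path: str | Path) -> list[SomaDetection]:
    df = pd.read_csv(path)
    return [
        SomaDetection(
            id=int(r.id),
            centre_um=(float(r.x_um), float(r.y_um), float(r.z_um)),
            radius_um=float(r.radius_um),
            weight=float(r.weight),
            block_id=int(r.block),
        )
        for r in df.itertuples()
    ]


def write_truth_csv(truth: GroundTruthSet, path: str | Path) -> None:
    rows = [
        {
            "id": s.id,
            "x_um": s.centre_um[0],
            "y_um": s.centre_um[1],
            "z_um": s.centre_um[2],
            "a_um": s.semi_axes_um[0],
            "b_um": s.semi_axes_um[1],
            "c_um": s.semi_axes_um[2],
        }
        for s in truth.somas
    ]
    pd.DataFrame(
        rows, columns=["id", "x_um", "y_um", "z_um", "a_um", "b_um", "c_um"]
    ).to_csv(path, index=False)


def read_truth_centres_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
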