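"""File formats and run configuration.

Volumes and image stacks are MRC/CCP4 maps (mode 2, 32-bit float) read and
written through gemmi; orientation/center metadata travels as TSV with
angles in degrees on disk (radians in memory); run configurations are YAML.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import gemmi
import numpy as np
import pandas as pd
import yaml

from .simulate import DensityVolume, EulerTriplet, ProjectionStack, convert_euler

__all__ = [
    "RunConfig",
    "read_volume",
    "write_volume",
    "read_stack",
    "write_stack",
    "read_meta",
    "write_meta",
]

_META_COLUMNS = ["index", "phi", "theta", "psi", "dx", "dy", "snr"]


@dataclass
class RunConfig:
    """Parameters of a full simulate-and-reconstruct run."""

    grid_size: int = 64
    voxel_size: float = 2.0
    lmax: int = 25
    n_projections: int = 2000
    snr_levels: tuple = (math.inf,)
    n_blobs: int = 4
    blob_sigma: float = 3.0
    max_offset: float = 3.0
    phantom_seed: int = 0
    projection_seed: int = 42
    pad: int = 2
    output_dir: str = "."

    def __post_init__(self):
        for name in ("grid_size", "voxel_size", "lmax", "n_projections"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "snr_levels" in raw:
            raw["snr_levels"] = tuple(
                math.inf if v in ("inf", ".inf", None) else float(v)
                for v in raw["snr_levels"]
            )
        return cls(**raw)


def _read_map(path) -> tuple[np.ndarray, float]:
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as err:
        raise ValueError(f"cannot parse MRC map {path}: {err}") from err
    mode = m.header_i32(4)
    if mode != 2:
        raise ValueError(f"unsupported MRC mode {mode} (header word 4); need mode 2")
    data = np.array(m.grid, copy=True).astype(float)
    cell = m.grid.unit_cell
    voxel = cell.a / m.grid.shape[0]
    return data, voxel


def _write_map(data: np.ndarray, voxel: float, path) -> None:
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(data, dtype=np.float32))
    m.grid.unit_cell = gemmi.UnitCell(
        data.shape[0] * voxel, data.shape[1] * voxel, data.shape[2] * voxel,
        90.0, 90.0, 90.0,
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_volume(path) -> DensityVolume:
    """Read a cubic mode-2 MRC map; voxel size comes from the cell header."""
    data, voxel = _read_map(path)
    if len(set(data.shape)) != 1:
        raise ValueError(
            f"volume must be cubic; header NX/NY/NZ give shape {data.shape}"
        )
    return DensityVolume(data, voxel)


def write_volume(vol: DensityVolume, path) -> None:
    _write_map(vol.data, vol.voxel_size, path)


def read_stack(path) -> tuple[np.ndarray, float]:
    """Read an MRC image stack; returns (images (M, N, N), pixel size)."""
    data, voxel = _read_map(path)
    if data.ndim != 3 or data.shape[1] != data.shape[2]:
        raise ValueError(f"stack must be (M, N, N); got shape {data.shape}")
    return data, voxel


def write_stack(stack: ProjectionStack, path) -> None:
    _write_map(stack.images, stack.pixel_size, path)


def write_meta(stack: ProjectionStack, path) -> None:
    """Write the orientation/center table (angles in degrees, ZXZ)."""
    rows = []
    for i, (e, (dx, dy), snr) in enumerate(
        zip(stack.eulers, stack.offsets, stack.snr)
    ):
        rows.append(
            dict(
                index=i,
                phi=math.degrees(e.phi),
                theta=math.degrees(e.theta),
                psi=math.degrees(e.psi),
                dx=dx,
                dy=dy,
                snr=snr,
            )
        )
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_meta(
    path, convention: str = "zxz", degrees: bool = True
) -> tuple[list[EulerTriplet], np.ndarray, np.ndarray]:
    """Read an orientation/center table.

    Returns (eulers in ZXZ radians, offsets (M, 2), snr (M,)).  A ZYZ table
    is converted row by row.  With ``degrees=False`` the angles are taken
    as radians and theta is checked against [0, pi] to catch unit mix-ups.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table {path} lacks column(s): {missing}")
    to_rad = math.radians if degrees else float
    eulers = []
    for _, row in df.iterrows():
        th = to_rad(row["theta"])
        if not degrees and th > math.pi + 1e-9:
            raise ValueError(
                f"theta={row['theta']} exceeds pi in radians mode; "
                "angles are probably in degrees"
            )
        e = EulerTriplet(
            to_rad(row["phi"]), th, to_rad(row["psi"]), convention.lower()
        )
        if e.convention == "zyz":
            e = convert_euler(e)
        eulers.append(e)
    offsets = df[["dx", "dy"]].to_numpy(dtype=float)
    snr = df["snr"].to_numpy(dtype=float)
    return eulers, offsets, snr
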