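"""Volume I/O, field output and run-configuration handling.

Conventions used throughout the package:

* voxel indices are 0-based ``(i, j, k)``; voxel ``i`` spans
  ``[i*dx, (i+1)*dx)`` so cell centers sit at ``(i + 1/2)*dx``;
* geometry (spacing, origin, distances) is carried in **millimetres**; the
  flow solver converts to SI metres internally;
* only axis-aligned volumes are accepted — the voxel lattice *is* the
  simulation grid, so oblique orientations are rejected rather than
  resampled.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

log = logging.getLogger("hemovox")

BLOOD_DENSITY = 1060.0  # kg/m^3, Newtonian blood model
BLOOD_VISCOSITY = 0.0035  # Pa*s


# ---------------------------------------------------------------------------
# intensity volumes
# ---------------------------------------------------------------------------

@dataclass
class IntensityVolume:
    """A 3-D scalar contrast field on a regular axis-aligned voxel grid.

    ``data[i, j, k]`` is the intensity of voxel ``(i, j, k)`` in scanner
    units (arbitrary scale); ``spacing`` and ``origin`` are in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"intensity volume must be 3-D, got shape {self.data.shape}")
        if any(n < 2 for n in self.data.shape):
            raise ValueError(f"all dims must be >= 2, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if not np.all(np.isfinite(np.asarray(self.data, dtype=float))):
            raise ValueError("intensity volume contains non-finite values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def cell_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of cell centers along ``axis``."""
        n = self.data.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def center_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) cell-center coordinate arrays in mm."""
        xs = self.cell_centers(0)[:, None, None]
        ys = self.cell_centers(1)[None, :, None]
        zs = self.cell_centers(2)[None, None, :]
        return xs, ys, zs


def read_intensity_volume(path: str | Path) -> IntensityVolume:
    """Read a single-channel 3-D NIfTI-1 volume.

    The affine must be axis-aligned (rotation part diagonal up to sign);
    spacing is taken from the affine diagonal, the origin from its
    translation column. Integer intensities are preserved bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D single-channel volume, got shape {data.shape}")
    aff = np.asarray(img.affine, dtype=float)
    rot = aff[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(rot))):
        raise ValueError("unsupported orientation: affine rotation part is not diagonal up to sign")
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0):
        raise ValueError(f"non-positive voxel spacing in header: {spacing}")
    origin = aff[:3, 3]
    return IntensityVolume(data=data, spacing=tuple(spacing), origin=tuple(origin))


def write_intensity_volume(vol: IntensityVolume, path: str | Path) -> Path:
    """Write ``vol`` as NIfTI-1 with a diagonal affine built from spacing/origin."""
    path = Path(path)
    aff = np.diag(list(vol.spacing) + [1.0])
    aff[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.data), aff)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class InflowSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    U0: float = Field(gt=0, description="peak steady inflow velocity, m/s")
    f0: float = Field(default=1.0, gt=0, description="heart rate, Hz")
    harmonics: list[tuple[float, float]] = Field(
        default_factory=list,
        description="per-harmonic (centerline velocity amplitude m/s, phase deg)",
    )
    steady: bool = True

    @model_validator(mode="after")
    def _steady_consistency(self) -> "InflowSettings":
        if self.steady and self.harmonics:
            raise ValueError("a steady run cannot carry pulsatile harmonics")
        if not self.steady and not self.harmonics:
            raise ValueError("a pulsatile run needs at least one harmonic")
        return self


class PipelineConfig(BaseModel):
    """Validated run configuration (JSON document with a fixed schema).

    Unknown keys are rejected so that typos fail loudly instead of being
    silently ignored.
    """

    model_config = ConfigDict(extra="forbid")

    volume_path: Optional[str] = None
    roi: Optional[tuple[int, int, int, int, int, int]] = Field(
        default=None, description="(i_min, i_max, j_min, j_max, k_min, k_max), inclusive"
    )
    seed_voxel: tuple[int, int, int]
    threshold: float = Field(description="lumen threshold intensity I0, scanner units")
    gradient_cap: Optional[float] = Field(
        default=None, gt=0, description="optional region-growing gradient cap dI_max"
    )
    inflow_face: str = Field(description="one of x_min,x_max,y_min,y_max,z_min,z_max")
    inflow: InflowSettings
    density: float = Field(default=BLOOD_DENSITY, gt=0, description="kg/m^3")
    viscosity: float = Field(default=BLOOD_VISCOSITY, gt=0, description="Pa*s")
    dt: Optional[float] = Field(default=None, gt=0, description="fixed time step, s")
    cfl: float = Field(default=0.5, gt=0, le=1.0)
    poisson_tol: float = Field(default=1e-8, gt=0)
    steady_tol: float = Field(default=1e-3, gt=0)
    max_time: float = Field(default=1.0, gt=0, description="end of physical time, s")
    smooth_levelset: bool = True
    centerline_depth: int = Field(default=4, ge=2)
    rng_seed: int = 0
    aneurysm_box: Optional[tuple[int, int, int, int, int, int]] = Field(
        default=None,
        description="ROI-local index box labelling the aneurysm region; "
        "metrics fall back to the whole lumen when unset",
    )
    output_dir: str = "hemovox_out"

    @field_validator("inflow_face")
    @classmethod
    def _check_face(cls, v: str) -> str:
        faces = {"x_min", "x_max", "y_min", "y_max", "z_min", "z_max"}
        if v not in faces:
            raise ValueError(f"inflow_face must be one of {sorted(faces)}, got {v!r}")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a JSON run configuration, applying defaults."""
    with open(path) as fh:
        doc = json.load(fh)
    return PipelineConfig.model_validate(doc)


def validate_config_against_volume(cfg: PipelineConfig, vol: IntensityVolume) -> None:
    """Cross-checks that need both the config and an attached volume."""
    lo, hi = float(np.min(vol.data)), float(np.max(vol.data))
    if not (lo <= cfg.threshold <= hi):
        raise ValueError(
            f"threshold {cfg.threshold} outside volume intensity range [{lo}, {hi}]"
        )
    if cfg.roi is not None:
        i0, i1, j0, j1, k0, k1 = cfg.roi
        s = cfg.seed_voxel
        if not (i0 <= s[0] <= i1 and j0 <= s[1] <= j1 and k0 <= s[2] <= k1):
            raise ValueError(f"seed voxel {s} outside ROI {cfg.roi}")


# ---------------------------------------------------------------------------
# VTK ImageData output
# ---------------------------------------------------------------------------
# The field writer emits the XML VTK ImageData (.vti) format with inline
# ASCII arrays: plain text, diff-friendly and readable by any VTK-based
# viewer (contour phi=0 to display the wall). A matching minimal reader is
# provided for round-trip checks.

def _ascii_array(name: str, arr: np.ndarray, ncomp: int) -> ET.Element:
    el = ET.Element(
        "DataArray",
        attrib={
            "type": "Float64",
            "Name": name,
            "NumberOfComponents": str(ncomp),
            "format": "ascii",
        },
    )
    flat = np.asarray(arr, dtype=np.float64).reshape(-1)
    el.text = " ".join(repr(float(v)) for v in flat)
    return el


def write_field_output(
    path: str | Path,
    spacing: Sequence[float],
    origin: Sequence[float],
    cell_arrays: dict[str, np.ndarray],
) -> Path:
    """Write cell-centered fields as a VTK ImageData (.vti) file.

    ``cell_arrays`` maps names to arrays of shape (nx, ny, nz) for scalars or
    (nx, ny, nz, 3) for vectors; all must share one grid. VTK stores cell
    data with x varying fastest, so arrays are transposed accordingly.
    """
    path = Path(path)
    shapes = {a.shape[:3] for a in cell_arrays.values()}
    if len(shapes) != 1:
        raise ValueError(f"field shapes disagree: {sorted(shapes)}")
    nx, ny, nz = shapes.pop()

    root = ET.Element(
        "VTKFile", attrib={"type": "ImageData", "version": "1.0", "byte_order": "LittleEndian"}
    )
    grid = ET.SubElement(
        root,
        "ImageData",
        attrib={
            "WholeExtent": f"0 {nx} 0 {ny} 0 {nz}",
            "Origin": " ".join(repr(float(v)) for v in origin),
            "Spacing": " ".join(repr(float(v)) for v in spacing),
        },
    )
    piece = ET.SubElement(grid, "Piece", attrib={"Extent": f"0 {nx} 0 {ny} 0 {nz}"})
    cdata = ET.SubElement(piece, "CellData")
    for name, arr in cell_arrays.items():
        a = np.asarray(arr, dtype=np.float64)
        if a.ndim == 3:
            cdata.append(_ascii_array(name, a.transpose(2, 1, 0), 1))
        elif a.ndim == 4 and a.shape[3] == 3:
            cdata.append(_ascii_array(name, a.transpose(2, 1, 0, 3), 3))
        else:
            raise ValueError(f"array {name!r} must be (nx,ny,nz) or (nx,ny,nz,3), got {a.shape}")
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
    return path


def read_field_output(path: str | Path) -> dict:
    """Minimal .vti reader: returns spacing, origin and named cell arrays."""
    tree = ET.parse(str(path))
    root = tree.getroot()
    grid = root.find("ImageData")
    if grid is None:
        raise ValueError("not a VTK ImageData file")
    ext = [int(v) for v in grid.attrib["WholeExtent"].split()]
    nx, ny, nz = ext[1] - ext[0], ext[3] - ext[2], ext[5] - ext[4]
    spacing = tuple(float(v) for v in grid.attrib["Spacing"].split())
    origin = tuple(float(v) for v in grid.attrib["Origin"].split())
    arrays: dict[str, np.ndarray] = {}
    for el in grid.find("Piece").find("CellData"):
        ncomp = int(el.attrib.get("NumberOfComponents", "1"))
        vals = np.array(el.text.split(), dtype=np.float64)
        if ncomp == 1:
            arrays[el.attrib["Name"]] = vals.reshape(nz, ny, nx).transpose(2, 1, 0)
        else:
            arrays[el.attrib["Name"]] = (
                vals.reshape(nz, ny, nx, ncomp).transpose(2, 1, 0, 3)
            )
    return {"spacing": spacing, "origin": origin, "cell_arrays": arrays}
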