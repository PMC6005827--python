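"""ROI extraction, seeded 3-D region growing and opening identification.

The lumen is segmented by flood fill from a user seed over face-connected
(6-neighbor) voxels whose intensity exceeds the threshold ``I0``; an optional
gradient cap additionally requires ``|I_neighbor - I_current| < dI_max``
along the accepting edge. Bright structures not connected to the seed are
thereby cleaned up automatically. The accepted set equals graph reachability
from the seed over edges that pass both criteria, so it is independent of
visitation order.

Masked voxels on the six ROI faces form the flow-domain openings: per face,
face-connected 2-D components become boundary patches; the user names the
inflow face, every other patch is an outflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .image_io import IntensityVolume

log = logging.getLogger("hemovox")

FACES = ("x_min", "x_max", "y_min", "y_max", "z_min", "z_max")
# face label -> (axis, side): side 0 = low-index face, 1 = high-index face
FACE_AXIS_SIDE = {
    "x_min": (0, 0), "x_max": (0, 1),
    "y_min": (1, 0), "y_max": (1, 1),
    "z_min": (2, 0), "z_max": (2, 1),
}


@dataclass
class RoiBox:
    """Inclusive 0-based index ranges delimiting the region of interest."""

    i_min: int
    i_max: int
    j_min: int
    j_max: int
    k_min: int
    k_max: int

    def __post_init__(self) -> None:
        for lo, hi in self.ranges():
            if lo > hi:
                raise ValueError(f"invalid ROI range: {lo} > {hi}")
            if lo < 0:
                raise ValueError("ROI indices must be non-negative")

    @classmethod
    def full(cls, dims) -> "RoiBox":
        return cls(0, dims[0] - 1, 0, dims[1] - 1, 0, dims[2] - 1)

    def ranges(self) -> list[tuple[int, int]]:
        return [(self.i_min, self.i_max), (self.j_min, self.j_max), (self.k_min, self.k_max)]

    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo + 1 for lo, hi in self.ranges())  # type: ignore[return-value]

    def validate_within(self, dims) -> None:
        for (lo, hi), n in zip(self.ranges(), dims):
            if hi >= n:
                raise ValueError(f"ROI {self} exceeds volume dims {tuple(dims)}")


@dataclass
class LumenMask:
    """Binary masking function M on the ROI grid: 1 in the lumen, 0 elsewhere."""

    mask: np.ndarray  # bool (nx, ny, nz)
    seed: tuple[int, int, int]
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask[tuple(self.seed)]:
            raise ValueError("mask does not contain its own seed voxel")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class BoundaryPatch:
    """A face-connected opening of the flow domain on one ROI face."""

    face: str  # one of FACES
    voxels: np.ndarray  # (n, 3) ROI-local voxel indices on that face
    centroid: np.ndarray  # mm, in ROI-local physical coordinates
    role: str = "outflow"  # "inflow" | "outflow"

    @property
    def size(self) -> int:
        return len(self.voxels)


def extract_roi(volume: IntensityVolume, roi: RoiBox) -> IntensityVolume:
    """Crop ``volume`` to ``roi``; spacing preserved, origin shifted."""
    roi.validate_within(volume.dims)
    sl = tuple(slice(lo, hi + 1) for lo, hi in roi.ranges())
    origin = tuple(
        volume.origin[ax] + roi.ranges()[ax][0] * volume.spacing[ax] for ax in range(3)
    )
    return IntensityVolume(
        data=volume.data[sl].copy(), spacing=volume.spacing, origin=origin
    )


_SHIFTS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def region_grow(
    volume: IntensityVolume,
    seed: tuple[int, int, int],
    threshold: float,
    gradient_cap: Optional[float] = None,
) -> LumenMask:
    """Seeded 6-connected flood fill over the intensity criteria.

    A neighbor is accepted from an accepted voxel iff ``I_neighbor > I0``
    and, when ``gradient_cap`` is set, ``|I_neighbor - I_current| < dI_max``.
    Growth proceeds by whole frontiers (vectorized level-by-level breadth
    first search) until no further growth is possible, which computes the
    full reachable set regardless of order.
    """
    I = np.asarray(volume.data, dtype=float)
    seed = tuple(int(s) for s in seed)
    if any(s < 0 or s >= n for s, n in zip(seed, I.shape)):
        raise ValueError(f"seed {seed} outside volume dims {I.shape}")
    if not I[seed] > threshold:
        raise ValueError(
            f"seed intensity {I[seed]} fails threshold {threshold}: "
            "wrong seed or wrong I0"
        )

    bright = I > threshold
    accepted = np.zeros_like(bright)
    accepted[seed] = True
    frontier = accepted.copy()

    def shifted(arr, sh, fill=False):
        out = np.full_like(arr, fill)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for ax, d in enumerate(sh):
            if d == 1:
                src[ax], dst[ax] = slice(0, -1), slice(1, None)
            elif d == -1:
                src[ax], dst[ax] = slice(1, None), slice(0, -1)
        out[tuple(dst)] = arr[tuple(src)]
        return out

    while frontier.any():
        grown = np.zeros_like(accepted)
        for sh in _SHIFTS:
            cand = shifted(frontier, sh) & bright & ~accepted
            if gradient_cap is not None:
                # intensity of the accepting (frontier) voxel, shifted alongside
                jump = np.abs(I - shifted(I, sh, fill=0.0))
                cand &= jump < gradient_cap
            grown |= cand
        accepted |= grown
        frontier = grown

    return LumenMask(mask=accepted, seed=seed, threshold=threshold)


def identify_openings(
    lumen: LumenMask,
    spacing,
    inflow_face: str,
) -> list[BoundaryPatch]:
    """Find flow-domain openings on the six ROI faces.

    Per face, masked boundary voxels are grouped into face-connected (2-D
    4-neighbor) components; each becomes a patch with its centroid in mm.
    The largest patch on the user-named face is the inflow (a warning is
    logged if that face holds several patches); all other patches are
    outflows. A voxel on two faces (domain edge) belongs to one patch per
    face it lies on.
    """
    if inflow_face not in FACES:
        raise ValueError(f"unknown face label {inflow_face!r}")
    mask = lumen.mask
    dims = mask.shape
    patches: list[BoundaryPatch] = []
    struct2d = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])

    for face in FACES:
        axis, side = FACE_AXIS_SIDE[face]
        idx = 0 if side == 0 else dims[axis] - 1
        plane = np.take(mask, idx, axis=axis)
        if not plane.any():
            continue
        labels, nlab = ndimage.label(plane, structure=struct2d)
        for lab in range(1, nlab + 1):
            uv = np.argwhere(labels == lab)  # 2-D in-face indices
            vox = np.zeros((len(uv), 3), dtype=int)
            other = [ax for ax in range(3) if ax != axis]
            vox[:, axis] = idx
            vox[:, other[0]] = uv[:, 0]
            vox[:, other[1]] = uv[:, 1]
            centroid = (vox.mean(axis=0) + 0.5) * np.asarray(spacing, dtype=float)
            patches.append(BoundaryPatch(face=face, voxels=vox, centroid=centroid))

    on_named = [p for p in patches if p.face == inflow_face]
    if not on_named:
        raise ValueError(f"no masked voxels on the named inflow face {inflow_face!r}")
    if len(on_named) > 1:
        log.warning(
            "inflow face %s holds %d patches; choosing the largest as inflow",
            inflow_face, len(on_named),
        )
    inflow = max(on_named, key=lambda p: p.size)
    inflow.role = "inflow"
    for p in patches:
        if p is not inflow:
            p.role = "outflow"
    return patches
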