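"""Level-set wall geometry built directly from image intensity.

The raw level set is the thresholded contrast field, ``phi0 = I - I0``: it
is positive inside the lumen, negative outside, and its zero iso-surface is
the vessel wall. A separable 3x3x3 low-pass filter (per-axis weights
1/4, 1/2, 1/4) smooths noise before geometric queries. Sub-voxel wall
distances along each grid direction follow from the local linearization

    d_a = phi / (d phi / d a),

so that the wall lies at ``x_a - d_a``: ``d_a > 0`` places the wall on the
low-index side. Unit wall normals are the normalized level-set gradient and
point into the lumen (phi increasing).

The inflow frame (per-slice lumen centroids, least-squares tangent, in-plane
radius vectors by vector rejection) lives here too, since it is pure
mask/level-set geometry consumed by the inflow profile builder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .image_io import IntensityVolume
from .segmentation import FACE_AXIS_SIDE, BoundaryPatch, LumenMask

log = logging.getLogger("hemovox")

GRAD_EPS_REL = 1e-8  # relative floor on |grad phi| below which a direction is degenerate
DIST_CAP_FACTOR = 1.5  # a wall farther than 1.5 spacings in a direction is not that cell's wall


@dataclass
class LevelSetField:
    """Raw and smoothed level-set fields sharing one grid (scanner units)."""

    phi0: np.ndarray
    phi: np.ndarray
    spacing: tuple[float, float, float]  # mm
    threshold: float

    def __post_init__(self) -> None:
        if self.phi0.shape != self.phi.shape:
            raise ValueError("phi and phi0 must share the grid")


@dataclass
class WallGeometry:
    """Per wall-adjacent fluid cell: directional wall distances and normals.

    ``distances[n, a]`` is the signed distance d_a in mm (NaN where that
    direction is undefined); ``normals`` are unit vectors pointing into the
    lumen; ``wall_velocity`` is zero for the rigid, stationary walls modeled
    here.
    """

    cells: np.ndarray  # (n, 3) int indices
    distances: np.ndarray  # (n, 3) mm, NaN = absent
    normals: np.ndarray  # (n, 3) unit
    solid_neighbor: np.ndarray  # (n, 6) bool, order (+x,-x,+y,-y,+z,-z)
    wall_velocity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.wall_velocity is None:
            self.wall_velocity = np.zeros_like(self.normals)


@dataclass
class CenterlineFrame:
    """Local vessel frame at an opening: slice centers, tangent, radii."""

    face: str
    centers: np.ndarray  # (depth, 3) mm
    tangent: np.ndarray  # (3,) unit, pointing into the domain
    patch_voxels: np.ndarray  # (n, 3) int
    radial: Optional[np.ndarray] = None  # (n, 3) mm, in-plane radius vectors R'
    radial_max: Optional[float] = None  # mm


# ---------------------------------------------------------------------------
# level-set construction
# ---------------------------------------------------------------------------

def build_levelset(volume: IntensityVolume, threshold: float) -> LevelSetField:
    """phi0 = I - I0, computed voxelwise; phi starts as a copy of phi0."""
    phi0 = np.asarray(volume.data, dtype=float) - float(threshold)
    return LevelSetField(
        phi0=phi0, phi=phi0.copy(), spacing=volume.spacing, threshold=float(threshold)
    )


_KERNEL_1D = np.array([0.25, 0.5, 0.25])


def smooth_levelset(ls: LevelSetField) -> LevelSetField:
    """Apply the separable 3x3x3 low-pass filter to phi0.

    The 3-D weight of offset (p, q, r) is (1/2)^3 (1/2)^(|p|+|q|+|r|), which
    factorizes into per-axis weights (1/4, 1/2, 1/4). Out-of-range neighbors
    take the nearest edge value; the weights sum to exactly 1, so a constant
    field is a fixed point and the filter is positivity-preserving.
    """
    phi = ls.phi0
    for ax in range(3):
        phi = ndimage.correlate1d(phi, _KERNEL_1D, axis=ax, mode="nearest")
    return LevelSetField(phi0=ls.phi0, phi=phi, spacing=ls.spacing, threshold=ls.threshold)


def _gradient(phi: np.ndarray, spacing) -> list[np.ndarray]:
    # central differences inside, one-sided at the ROI boundary
    return np.gradient(phi, *spacing, edge_order=1)


# ---------------------------------------------------------------------------
# wall queries
# ---------------------------------------------------------------------------

def _solid_neighbor_table(mask: np.ndarray) -> np.ndarray:
    """(nx,ny,nz,6) bool: in-domain solid face-neighbor per direction.

    Direction order: (+x, -x, +y, -y, +z, -z). Faces on the ROI boundary are
    openings, not walls, and do not count.
    """
    solid = ~mask
    out = np.zeros(mask.shape + (6,), dtype=bool)
    out[:-1, :, :, 0] = solid[1:, :, :]
    out[1:, :, :, 1] = solid[:-1, :, :]
    out[:, :-1, :, 2] = solid[:, 1:, :]
    out[:, 1:, :, 3] = solid[:, :-1, :]
    out[:, :, :-1, 4] = solid[:, :, 1:]
    out[:, :, 1:, 5] = solid[:, :, :-1]
    out &= mask[..., None]
    return out


def wall_normals(ls: LevelSetField) -> np.ndarray:
    """Unit wall-normal field n = grad(phi)/|grad(phi)|, pointing into the lumen.

    Cells with vanishing gradient get NaN normals (flagged, not fabricated).
    """
    g = _gradient(ls.phi, ls.spacing)
    gv = np.stack(g, axis=-1)
    norm = np.linalg.norm(gv, axis=-1)
    out = np.full_like(gv, np.nan)
    ok = norm > 0
    out[ok] = gv[ok] / norm[ok][..., None]
    return out


def wall_distances(ls: LevelSetField, lumen: LumenMask) -> WallGeometry:
    """Directional sub-voxel wall distances at wall-adjacent fluid cells.

    Exact (to round-off) for affine phi. A direction is marked absent when
    the gradient component is degenerate or the implied wall is farther than
    1.5 spacings; a cell with no usable direction falls back to half a
    spacing toward each solid neighbor (logged).
    """
    mask = lumen.mask
    if mask.shape != ls.phi.shape:
        raise ValueError("mask and level set must share the grid")
    spacing = np.asarray(ls.spacing, dtype=float)
    nbr = _solid_neighbor_table(mask)
    wall_adj = nbr.any(axis=-1)
    cells = np.argwhere(wall_adj)
    if len(cells) == 0:
        raise ValueError("mask has no wall-adjacent cells")
    ci = tuple(cells.T)

    grads = _gradient(ls.phi, ls.spacing)
    phi_c = ls.phi[ci]
    scale = np.max(np.abs(ls.phi))
    dist = np.full((len(cells), 3), np.nan)
    for ax in range(3):
        g = grads[ax][ci]
        ok = np.abs(g) > GRAD_EPS_REL * scale / spacing[ax]
        d = np.where(ok, phi_c / np.where(ok, g, 1.0), np.nan)
        d[np.abs(d) > DIST_CAP_FACTOR * spacing[ax]] = np.nan
        dist[:, ax] = d

    normals_full = wall_normals(ls)
    normals = normals_full[ci]

    degenerate = np.all(np.isnan(dist), axis=1) & np.any(np.isnan(normals), axis=1)
    if degenerate.any():
        log.warning(
            "%d wall cells have no valid wall direction; using half-spacing fallback",
            int(degenerate.sum()),
        )
        for n in np.where(degenerate)[0]:
            for ax in range(3):
                # wall on the low side -> +0.5 spacing by the sign convention
                if nbr[ci[0][n], ci[1][n], ci[2][n], 2 * ax + 1]:
                    dist[n, ax] = 0.5 * spacing[ax]
                elif nbr[ci[0][n], ci[1][n], ci[2][n], 2 * ax]:
                    dist[n, ax] = -0.5 * spacing[ax]

    return WallGeometry(
        cells=cells, distances=dist, normals=normals, solid_neighbor=nbr[ci]
    )


# ---------------------------------------------------------------------------
# centerline frame
# ---------------------------------------------------------------------------

def vessel_centerline(
    lumen: LumenMask,
    patch: BoundaryPatch,
    spacing,
    depth: int = 4,
) -> CenterlineFrame:
    """Mask-weighted slice centroids near an opening and their tangent line.

    The first ``depth`` grid slices inward from the patch's face each
    contribute the centroid of their masked voxels; the tangent is the
    least-squares line direction through those centroids (for depth = 2 this
    reduces to the two-point difference), oriented to point into the domain.
    """
    if depth < 2:
        raise ValueError("centerline needs at least 2 slices")
    axis, side = FACE_AXIS_SIDE[patch.face]
    mask = lumen.mask
    n = mask.shape[axis]
    if depth > n:
        raise ValueError(f"depth {depth} exceeds grid extent {n}")
    spacing = np.asarray(spacing, dtype=float)

    centers = np.zeros((depth, 3))
    for s in range(depth):
        idx = s if side == 0 else n - 1 - s
        plane = np.take(mask, idx, axis=axis)
        if not plane.any():
            raise ValueError(
                f"slice {idx} along axis {axis} holds no lumen voxels "
                "(vessel leaves the ROI laterally)"
            )
        uv = np.argwhere(plane)
        other = [ax for ax in range(3) if ax != axis]
        vox = np.zeros((len(uv), 3))
        vox[:, axis] = idx
        vox[:, other[0]] = uv[:, 0]
        vox[:, other[1]] = uv[:, 1]
        centers[s] = (vox + 0.5).mean(axis=0) * spacing

    rel = centers - centers.mean(axis=0)
    # principal direction of the centroid cloud = least-squares line direction
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    tangent = vt[0]
    inward = np.zeros(3)
    inward[axis] = 1.0 if side == 0 else -1.0
    if np.dot(tangent, inward) < 0:
        tangent = -tangent
    tangent = tangent / np.linalg.norm(tangent)

    return CenterlineFrame(
        face=patch.face, centers=centers, tangent=tangent, patch_voxels=patch.voxels
    )


def inplane_radius(frame: CenterlineFrame, spacing) -> CenterlineFrame:
    """In-plane radius vectors R' = R - (R.s)s per patch voxel, and their max.

    R is measured from the boundary-slice center point; the rejection makes
    R' exactly perpendicular to the tangent.
    """
    spacing = np.asarray(spacing, dtype=float)
    pts = (frame.patch_voxels + 0.5) * spacing
    R = pts - frame.centers[0]
    s = frame.tangent
    Rp = R - np.outer(R @ s, s)
    frame.radial = Rp
    frame.radial_max = float(np.max(np.linalg.norm(Rp, axis=1)))
    return frame
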