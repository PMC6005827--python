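"""Synthetic angiogram phantoms with analytic ground truth.

Real 3-D rotational angiograms show a bright lumen over a dark background
with a finite-width intensity transition at the vessel wall. Every phantom
here reproduces that structure from an analytic signed-distance field
``sd(x)`` (mm, positive inside the lumen):

    I(x) = I_bg + (I_lumen - I_bg) * s(sd(x) / w),

where ``s`` is a clamped linear ramp from 0 to 1 over ``[-1, 1]`` (a step
function when the wall width ``w`` is zero), plus optional i.i.d. Gaussian
noise. By construction the half-intensity iso-level ``I0 = (I_lumen+I_bg)/2``
falls exactly on the analytic surface for noiseless phantoms, and the
sub-voxel wall position is recoverable by linear interpolation — the same
assumption the level-set wall reconstruction makes.

All phantoms are deterministic given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .image_io import IntensityVolume

DEFAULT_I_LUMEN = 1000.0
DEFAULT_I_BG = 0.0


@dataclass
class PhantomTruth:
    """Analytic ground truth attached to a generated phantom volume."""

    signed_distance: Callable[[np.ndarray], np.ndarray]  # (N,3) mm -> (N,) mm, >0 inside
    params: dict = field(default_factory=dict)
    analytic_volume: Optional[float] = None  # mm^3, where closed-form
    aneurysm_inside: Optional[Callable[[np.ndarray], np.ndarray]] = None
    component_labels: Optional[np.ndarray] = None  # per-voxel 0/1/2 labels

    def inside(self, points: np.ndarray) -> np.ndarray:
        """Lumen membership predicate: sd > 0."""
        return self.signed_distance(np.asarray(points, dtype=float)) > 0.0


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


_AXES = {
    "x": (1.0, 0.0, 0.0), "+x": (1.0, 0.0, 0.0), "-x": (-1.0, 0.0, 0.0),
    "y": (0.0, 1.0, 0.0), "+y": (0.0, 1.0, 0.0), "-y": (0.0, -1.0, 0.0),
    "z": (0.0, 0.0, 1.0), "+z": (0.0, 0.0, 1.0), "-z": (0.0, 0.0, -1.0),
}


def _resolve_axis(axis) -> np.ndarray:
    if isinstance(axis, str):
        try:
            return np.array(_AXES[axis])
        except KeyError:
            raise ValueError(f"unknown axis label {axis!r}") from None
    return _unit(axis)


def _voxel_centers(dims, spacing) -> np.ndarray:
    """(N, 3) array of cell-center coordinates in mm, C order."""
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(dims, spacing)]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")
    return np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)


def _ramp(t: np.ndarray) -> np.ndarray:
    # clamped linear ramp: 0 at t=-1, 1/2 at t=0, 1 at t=+1
    return np.clip(0.5 * (t + 1.0), 0.0, 1.0)


def _intensity_from_sd(
    sd: np.ndarray, dims, I_lumen, I_bg, wall_width, noise_sd, seed
) -> np.ndarray:
    if wall_width > 0:
        s = _ramp(sd / wall_width)
    else:
        s = (sd > 0).astype(float)
    img = I_bg + (I_lumen - I_bg) * s
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img.reshape(dims)


def _dist_to_line(points: np.ndarray, p0: np.ndarray, direction: np.ndarray) -> np.ndarray:
    rel = points - p0
    along = rel @ direction
    return np.linalg.norm(rel - along[:, None] * direction[None, :], axis=1)


def _make_volume(sd_fn, dims, spacing, I_lumen, I_bg, wall_width, noise_sd, seed):
    pts = _voxel_centers(dims, spacing)
    sd = sd_fn(pts)
    if not np.any(sd > 0):
        raise ValueError("phantom lumen does not intersect the domain")
    img = _intensity_from_sd(sd, dims, I_lumen, I_bg, wall_width, noise_sd, seed)
    return IntensityVolume(data=img, spacing=tuple(spacing))


def _check_radius(radius, spacing) -> None:
    if radius < 3.0 * max(spacing):
        raise ValueError(
            f"tube radius {radius} mm too small for voxel spacing {max(spacing)} mm "
            "(need radius >= 3 voxels)"
        )


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def straight_tube_phantom(
    dims=(32, 32, 48),
    spacing=(0.25, 0.25, 0.25),
    radius: float = 2.5,
    axis="z",
    axis_point: Optional[tuple] = None,
    I_lumen: float = DEFAULT_I_LUMEN,
    I_bg: float = DEFAULT_I_BG,
    wall_width: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[IntensityVolume, PhantomTruth]:
    """An infinite circular cylinder clipped to the domain.

    ``axis`` is a label (``+x`` .. ``-z``) or an arbitrary unit vector; the
    centerline passes through ``axis_point`` (default: the domain center,
    which for odd grid extents is a cell center).
    """
    _check_radius(radius, spacing)
    a = _resolve_axis(axis)
    extent = np.array(dims) * np.array(spacing)
    p0 = np.array(axis_point, dtype=float) if axis_point is not None else extent / 2.0

    def sd(points: np.ndarray) -> np.ndarray:
        return radius - _dist_to_line(np.atleast_2d(points), p0, a)

    # analytic volume: only closed-form for an axis-aligned tube spanning the box
    vol_analytic = None
    dominant = int(np.argmax(np.abs(a)))
    if abs(abs(a[dominant]) - 1.0) < 1e-12:
        vol_analytic = np.pi * radius**2 * extent[dominant]

    truth = PhantomTruth(
        signed_distance=sd,
        params={"kind": "straight_tube", "radius": radius, "axis": list(a),
                "axis_point": list(p0)},
        analytic_volume=vol_analytic,
    )
    return _make_volume(sd, dims, spacing, I_lumen, I_bg, wall_width, noise_sd, seed), truth


def curved_tube_phantom(
    dims=(48, 48, 48),
    spacing=(0.25, 0.25, 0.25),
    major_radius: float = 6.0,
    tube_radius: float = 2.0,
    arc_span_deg: float = 90.0,
    start_point: Optional[tuple] = None,
    I_lumen: float = DEFAULT_I_LUMEN,
    I_bg: float = DEFAULT_I_BG,
    wall_width: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[IntensityVolume, PhantomTruth]:
    """A torus-segment tube with straight tangential extensions at both ends.

    The centerline enters the domain along +z at ``start_point`` (default:
    centered on the z_min face), bends toward +y through ``arc_span_deg``
    degrees on a circle of radius ``major_radius``, and continues straight,
    so the tube meets two ROI faces. ``arc_span_deg -> 0`` degenerates to a
    straight tube along z.
    """
    if major_radius <= tube_radius:
        raise ValueError("torus major radius must exceed the tube radius")
    _check_radius(tube_radius, spacing)
    extent = np.array(dims) * np.array(spacing)
    p0 = (
        np.array(start_point, dtype=float)
        if start_point is not None
        else np.array([extent[0] / 2.0, extent[1] / 3.0, 0.0])
    )
    span = np.deg2rad(arc_span_deg)
    # arc center and in-plane frame: position(theta) = c + Rm(cos(theta) e1 + sin(theta) e2)
    e1 = np.array([0.0, -1.0, 0.0])
    e2 = np.array([0.0, 0.0, 1.0])
    e3 = np.array([1.0, 0.0, 0.0])
    c = p0 - major_radius * e1

    end1 = c + major_radius * (np.cos(span) * e1 + np.sin(span) * e2)
    tan1 = -np.sin(span) * e1 + np.cos(span) * e2

    def centerline_distance(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        q = pts - c
        a1, a2, a3 = q @ e1, q @ e2, q @ e3
        theta = np.arctan2(a2, a1)
        in_arc = (theta >= 0.0) & (theta <= span)
        d_arc = np.hypot(np.hypot(a1, a2) - major_radius, a3)
        d_arc = np.where(in_arc, d_arc, np.inf)
        # straight extension beyond the start (theta=0) end, along -e2
        rel0 = pts - p0
        s0 = np.minimum(rel0 @ e2, 0.0)
        d_ray0 = np.linalg.norm(rel0 - s0[:, None] * e2[None, :], axis=1)
        # straight extension beyond the far end, along +tan1
        rel1 = pts - end1
        s1 = np.maximum(rel1 @ tan1, 0.0)
        d_ray1 = np.linalg.norm(rel1 - s1[:, None] * tan1[None, :], axis=1)
        return np.minimum(np.minimum(d_arc, d_ray0), d_ray1)

    def sd(points: np.ndarray) -> np.ndarray:
        return tube_radius - centerline_distance(points)

    truth = PhantomTruth(
        signed_distance=sd,
        params={
            "kind": "curved_tube",
            "major_radius": major_radius,
            "tube_radius": tube_radius,
            "arc_span_deg": arc_span_deg,
            "arc_center": list(c),
            "start_point": list(p0),
            "e1": list(e1),
            "e2": list(e2),
        },
    )
    return _make_volume(sd, dims, spacing, I_lumen, I_bg, wall_width, noise_sd, seed), truth


def sidewall_aneurysm_phantom(
    dims=(40, 40, 48),
    spacing=(0.25, 0.25, 0.25),
    tube_radius: float = 2.0,
    sac_center: Optional[tuple] = None,
    sac_radius: float = 2.0,
    axis="z",
    axis_point: Optional[tuple] = None,
    I_lumen: float = DEFAULT_I_LUMEN,
    I_bg: float = DEFAULT_I_BG,
    wall_width: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[IntensityVolume, PhantomTruth]:
    """A straight parent vessel with a spherical sidewall sac.

    The lumen is the union of the tube and the sphere; the sac must
    intersect the tube wall so the lumen stays one connected component. The
    truth carries an aneurysm-region predicate (inside the sphere, outside
    the tube) for metric tests, and the union volume in the thin-wall
    (locally planar vessel wall) spherical-cap approximation.
    """
    _check_radius(tube_radius, spacing)
    a = _resolve_axis(axis)
    extent = np.array(dims) * np.array(spacing)
    p0 = np.array(axis_point, dtype=float) if axis_point is not None else np.array(
        [extent[0] / 2.0, extent[1] / 3.0, extent[2] / 2.0]
    )
    if sac_center is None:
        sac_center = p0 + np.array([0.0, tube_radius + 0.6 * sac_radius, 0.0])
    sac_center = np.asarray(sac_center, dtype=float)

    h = float(_dist_to_line(sac_center[None, :], p0, a)[0])
    if h >= tube_radius + sac_radius:
        raise ValueError("sac is disjoint from the vessel: lumen would have two components")

    def sd_tube(points: np.ndarray) -> np.ndarray:
        return tube_radius - _dist_to_line(np.atleast_2d(points), p0, a)

    def sd_sphere(points: np.ndarray) -> np.ndarray:
        return sac_radius - np.linalg.norm(np.atleast_2d(points) - sac_center, axis=1)

    def sd(points: np.ndarray) -> np.ndarray:
        return np.maximum(sd_tube(points), sd_sphere(points))

    def aneurysm_inside(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return (sd_sphere(pts) > 0) & (sd_tube(pts) <= 0)

    # union volume, treating the vessel wall as locally planar where the sac
    # overlaps it: V = V_tube + V_sphere - V_cap(inside tube)
    dominant = int(np.argmax(np.abs(a)))
    vol_analytic = None
    if abs(abs(a[dominant]) - 1.0) < 1e-12:
        v_tube = np.pi * tube_radius**2 * extent[dominant]
        v_sph = 4.0 / 3.0 * np.pi * sac_radius**3
        cut = h - tube_radius  # signed distance of sac center outside the wall
        if cut <= -sac_radius:
            overlap = v_sph
        elif cut >= sac_radius:
            overlap = 0.0
        else:
            hc = sac_radius - cut  # cap height inside the vessel
            overlap = np.pi * hc**2 * (3.0 * sac_radius - hc) / 3.0
        vol_analytic = v_tube + v_sph - overlap

    truth = PhantomTruth(
        signed_distance=sd,
        params={
            "kind": "sidewall_aneurysm",
            "tube_radius": tube_radius,
            "sac_radius": sac_radius,
            "sac_center": list(sac_center),
            "axis": list(a),
            "axis_point": list(p0),
            "wall_offset": h,
        },
        analytic_volume=vol_analytic,
        aneurysm_inside=aneurysm_inside,
    )
    return _make_volume(sd, dims, spacing, I_lumen, I_bg, wall_width, noise_sd, seed), truth


def two_vessel_phantom(
    dims=(40, 40, 40),
    spacing=(0.25, 0.25, 0.25),
    radius1: float = 1.5,
    radius2: float = 1.2,
    axis="z",
    offset1: Optional[tuple] = None,
    offset2: Optional[tuple] = None,
    I_lumen: float = DEFAULT_I_LUMEN,
    I_bg: float = DEFAULT_I_BG,
    wall_width: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[IntensityVolume, PhantomTruth]:
    """Two disconnected parallel vessels (both above threshold).

    Exercises the connectivity clean-up: a seed in one vessel must never
    leak into the other. The truth labels each voxel with a component id
    (0 background, 1 first tube, 2 second tube).
    """
    for r in (radius1, radius2):
        _check_radius(r, spacing)
    a = _resolve_axis(axis)
    extent = np.array(dims) * np.array(spacing)
    p1 = (
        np.array(offset1, dtype=float)
        if offset1 is not None
        else np.array([extent[0] * 0.3, extent[1] * 0.3, extent[2] / 2.0])
    )
    p2 = (
        np.array(offset2, dtype=float)
        if offset2 is not None
        else np.array([extent[0] * 0.72, extent[1] * 0.72, extent[2] / 2.0])
    )
    sep = float(_dist_to_line(p2[None, :], p1, a)[0])
    if sep <= radius1 + radius2:
        raise ValueError("tubes overlap: lumens would merge into one component")

    def sd1(points):
        return radius1 - _dist_to_line(np.atleast_2d(points), p1, a)

    def sd2(points):
        return radius2 - _dist_to_line(np.atleast_2d(points), p2, a)

    def sd(points):
        return np.maximum(sd1(points), sd2(points))

    pts = _voxel_centers(dims, spacing)
    labels = np.zeros(len(pts), dtype=np.uint8)
    labels[sd1(pts) > 0] = 1
    labels[sd2(pts) > 0] = 2
    labels = labels.reshape(dims)

    dominant = int(np.argmax(np.abs(a)))
    vol_analytic = None
    if abs(abs(a[dominant]) - 1.0) < 1e-12:
        vol_analytic = np.pi * (radius1**2 + radius2**2) * extent[dominant]

    truth = PhantomTruth(
        signed_distance=sd,
        params={
            "kind": "two_vessel",
            "radius1": radius1,
            "radius2": radius2,
            "axis": list(a),
            "axis_point1": list(p1),
            "axis_point2": list(p2),
        },
        analytic_volume=vol_analytic,
        component_labels=labels,
    )
    return _make_volume(sd, dims, spacing, I_lumen, I_bg, wall_width, noise_sd, seed), truth
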