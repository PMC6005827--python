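"""Inflow velocity profiles on an opening patch.

The inflow velocity is aligned with the local centerline tangent s and its
radial shape is a superposition of a steady parabola and oscillatory
rigid-tube Womersley modes:

    u(xi, t) = U0 (1 - xi^2) + sum_n Re[ A_n f_n(xi) e^{i(2 pi n f0 t + ph_n)} ],

with xi = |R'| / R'_max the normalized in-plane radius (discrete rim, so
non-circular openings are handled without assuming a circular cross
section), and per-harmonic shape

    f_n(xi) = (J0(L_n) - J0(L_n xi)) / (J0(L_n) - 1),   L_n = i^{3/2} Wo sqrt(n),

the classical oscillatory pipe-flow solution normalized so that f_n(0) = 1:
A_n is the centerline velocity amplitude of harmonic n and f_n(1) = 0
enforces no-slip at the rim for all times. Wo = R sqrt(rho 2 pi f0 / mu) is
the Womersley number of the fundamental. As Wo -> 0 each mode degenerates
to the quasi-steady parabola scaled by the instantaneous amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import jv

from .geometry import CenterlineFrame
from .segmentation import FACE_AXIS_SIDE


def womersley_number(radius_m: float, density: float, f0: float, viscosity: float) -> float:
    """Wo = R sqrt(rho 2 pi f0 / mu) (all SI)."""
    return radius_m * np.sqrt(density * 2.0 * np.pi * f0 / viscosity)


def womersley_mode_shape(xi: np.ndarray, wo: float) -> np.ndarray:
    """Complex radial shape f(xi) of one oscillatory mode, f(0)=1, f(1)=0."""
    if wo <= 0:
        raise ValueError("Womersley number must be positive")
    lam = 1j ** 1.5 * wo
    j0_wall = jv(0, lam)
    return (j0_wall - jv(0, lam * np.asarray(xi, dtype=complex))) / (j0_wall - 1.0)


@dataclass
class InflowProfile:
    """Time-dependent inflow velocity vectors on a patch.

    ``harmonics`` lists (centerline amplitude m/s, phase degrees) per
    multiple of ``f0``; an empty list is a steady parabolic inflow.
    """

    frame: CenterlineFrame
    U0: float  # peak steady velocity, m/s
    f0: float = 1.0  # Hz
    wo: Optional[float] = None  # Womersley number of the fundamental
    harmonics: Sequence[tuple[float, float]] = field(default_factory=tuple)
    xi: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.frame.radial is None or self.frame.radial_max is None:
            raise ValueError("frame needs in-plane radii (run inplane_radius first)")
        if self.frame.radial_max <= 0 or len(self.frame.patch_voxels) < 2:
            raise ValueError("degenerate inflow patch")
        if self.harmonics and (self.wo is None or self.wo <= 0):
            raise ValueError("pulsatile inflow needs a positive Womersley number")
        self.xi = np.linalg.norm(self.frame.radial, axis=1) / self.frame.radial_max

    @property
    def steady(self) -> bool:
        return len(self.harmonics) == 0

    def axial_speed(self, t: float) -> np.ndarray:
        """Signed speed along the tangent per patch voxel at time t."""
        u = self.U0 * np.clip(1.0 - self.xi**2, 0.0, None)
        for n, (amp, phase_deg) in enumerate(self.harmonics, start=1):
            shape = womersley_mode_shape(self.xi, self.wo * np.sqrt(n))
            carrier = np.exp(1j * (2.0 * np.pi * n * self.f0 * t + np.deg2rad(phase_deg)))
            u = u + amp * np.real(shape * carrier)
        return u

    def velocities(self, t: float = 0.0) -> np.ndarray:
        """(n, 3) velocity vectors, all parallel to the centerline tangent."""
        return np.outer(self.axial_speed(t), self.frame.tangent)


def parabolic_profile(frame: CenterlineFrame, U0: float) -> InflowProfile:
    """Steady fully developed profile U0 (1 - (|R'|/R'_max)^2) s."""
    if U0 <= 0:
        raise ValueError("U0 must be positive")
    return InflowProfile(frame=frame, U0=U0)


def womersley_profile(
    frame: CenterlineFrame,
    wo: float,
    f0: float,
    harmonics: Sequence[tuple[float, float]],
    t: float,
    U0: float = 0.0,
) -> np.ndarray:
    """Velocity vectors of the combined parabolic + Womersley profile at time t.

    Convenience evaluator around :class:`InflowProfile`; ``U0 = 0`` gives the
    purely oscillatory part.
    """
    if not harmonics:
        raise ValueError("a pulsatile profile needs at least one harmonic")
    prof = InflowProfile(frame=frame, U0=max(U0, 0.0), f0=f0, wo=wo, harmonics=tuple(harmonics))
    if U0 <= 0:
        # strip the steady parabola, keep only the oscillatory modes
        prof_steady = np.outer(
            max(U0, 0.0) * np.clip(1.0 - prof.xi**2, 0.0, None), frame.tangent
        )
        return prof.velocities(t) - prof_steady
    return prof.velocities(t)


@dataclass
class InflowFaceBC:
    """Inflow profile sampled onto the boundary cell faces of the ROI.

    The face-normal velocity component lives on the opening face plane; the
    two tangential components are carried per patch voxel for the mirror
    condition at the staggered near-boundary nodes. ``flux(t)`` reports the
    total imposed volumetric flux (m^3/s) as the discrete voxel sum.
    """

    profile: InflowProfile
    face: str
    axis: int
    side: int
    voxels: np.ndarray  # (n, 3) int
    face_area_m2: float
    tangential_axes: tuple[int, int]

    def normal_values(self, t: float = 0.0) -> np.ndarray:
        return self.profile.velocities(t)[:, self.axis]

    def tangential_values(self, t: float = 0.0) -> np.ndarray:
        v = self.profile.velocities(t)
        return v[:, list(self.tangential_axes)]

    def flux(self, t: float = 0.0) -> float:
        vn = self.normal_values(t)
        sign = 1.0 if self.side == 0 else -1.0  # into the domain
        return float(sign * vn.sum() * self.face_area_m2)


def map_profile_to_faces(
    profile: InflowProfile, mask: np.ndarray, spacing_mm
) -> InflowFaceBC:
    """Attach the profile to the staggered grid boundary at its patch."""
    axis, side = FACE_AXIS_SIDE[profile.frame.face]
    vox = profile.frame.patch_voxels
    if not np.all(mask[tuple(vox.T)]):
        raise ValueError("inflow patch voxels are not all inside the lumen mask")
    spacing_m = np.asarray(spacing_mm, dtype=float) * 1e-3
    other = tuple(ax for ax in range(3) if ax != axis)
    area = float(spacing_m[other[0]] * spacing_m[other[1]])
    return InflowFaceBC(
        profile=profile,
        face=profile.frame.face,
        axis=axis,
        side=side,
        voxels=vox,
        face_area_m2=area,
        tangential_axes=other,
    )
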