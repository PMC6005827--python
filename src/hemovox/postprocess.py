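"""Wall quantities and normalized hemodynamic metrics.

Wall pressure, the near-wall velocity-gradient tensor and the wall shear
stress (WSS) are evaluated on the Cartesian fluid cells adjacent to the
wall, which is where a non-body-conformal solver has its last reliable
samples; for display the values can be projected onto the wall surface
along the local normal, which does not affect any metric.

* Wall pressure: the pressure normal gradient vanishes at a rigid wall, so
  the wall value is the adjacent cell-center value (zero-normal-gradient
  extrapolation).
* Velocity gradients: one-sided differences against the boundary face
  velocity over half a spacing wherever a neighbor is solid, in the
  sign-consistent form (fluid value - wall-face value)/(spacing/2); plain
  central differences where both neighbors are fluid.
* WSS: the tangential part of the viscous traction,
  tau_w = mu { grad(u).n - ((grad(u).n).n) n }, with n the unit level-set
  normal; tangentiality to the wall holds by construction.
* Metrics: WSS magnitudes over a designated aneurysm wall region are
  normalized by the inflow dynamic pressure scale rho U0^2; reported are
  their maximum, mean and variation (population standard deviation), plus
  the aneurysm-volume average of |u|/U0 and the size ratio SR (aneurysm
  maximal length / parent vessel diameter).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import CenterlineFrame, WallGeometry
from .solver import FlowState, _bc_coeffs


@dataclass
class WallField:
    """Per wall-adjacent fluid cell: pressure, grad(u), WSS vector/magnitude."""

    cells: np.ndarray  # (n, 3)
    pressure: np.ndarray  # (n,) Pa
    grad: np.ndarray  # (n, 3, 3), grad[n, c, a] = d u_c / d x_a, 1/s
    normals: np.ndarray  # (n, 3)
    wss: np.ndarray  # (n, 3) Pa
    wss_mag: np.ndarray  # (n,) Pa


@dataclass
class AneurysmRegion:
    """Cell labels partitioning the lumen: True = aneurysm, on M = 1 cells only."""

    inside: np.ndarray  # bool (nx, ny, nz)

    @classmethod
    def from_box(cls, mask: np.ndarray, box) -> "AneurysmRegion":
        i0, i1, j0, j1, k0, k1 = box
        lab = np.zeros_like(mask, dtype=bool)
        lab[i0 : i1 + 1, j0 : j1 + 1, k0 : k1 + 1] = True
        return cls(inside=lab & mask)

    @classmethod
    def from_predicate(cls, mask: np.ndarray, spacing_mm, predicate) -> "AneurysmRegion":
        """Label lumen cells whose centers satisfy an analytic predicate."""
        sp = np.asarray(spacing_mm, dtype=float)
        idx = np.argwhere(mask)
        pts = (idx + 0.5) * sp
        lab = np.zeros_like(mask, dtype=bool)
        lab[tuple(idx[predicate(pts)].T)] = True
        return cls(inside=lab)


@dataclass
class HemodynamicMetrics:
    """Dimensionless WSS statistics and flow-strength measures."""

    tau_max: float
    tau_avg: float
    tau_var: float  # population standard deviation of tau*
    vel_avg: float  # volume-averaged |u| / U0
    sr: Optional[float] = None

    def as_row(self) -> dict:
        return {
            "tau_star_max": self.tau_max,
            "tau_star_avg": self.tau_avg,
            "tau_star_var": self.tau_var,
            "vel_norm_avg": self.vel_avg,
            "size_ratio": "" if self.sr is None else self.sr,
        }


# ---------------------------------------------------------------------------
# wall fields
# ---------------------------------------------------------------------------

def wall_pressure(state: FlowState, wallgeom: WallGeometry) -> np.ndarray:
    """Wall pressure per wall-adjacent cell (zero-normal-gradient value)."""
    return state.P[tuple(wallgeom.cells.T)]


def near_wall_gradient(
    state: FlowState, mask: np.ndarray, wallgeom: WallGeometry
) -> np.ndarray:
    """Velocity-gradient tensor at wall-adjacent cells, using boundary face
    velocities wherever a neighbor cell is solid.

    The face value of each velocity component on a wall-cut face is rebuilt
    from the cell-centered velocity and the level-set wall distance with the
    same two-branch closure the solver uses, so a linear shear profile is
    recovered exactly.
    """
    ucc = state.cell_center_velocity()  # (nx, ny, nz, 3), m/s
    h = np.asarray(state.spacing_m)
    cells = wallgeom.cells
    n = len(cells)
    grad = np.zeros((n, 3, 3))
    dims = mask.shape

    for ax in range(3):
        delta = h[ax]
        e = np.zeros(3, dtype=int)
        e[ax] = 1
        plus = cells + e
        minus = cells - e
        in_plus = plus[:, ax] <= dims[ax] - 1
        in_minus = minus[:, ax] >= 0
        plus_cl = plus.copy()
        plus_cl[:, ax] = np.clip(plus_cl[:, ax], 0, dims[ax] - 1)
        minus_cl = minus.copy()
        minus_cl[:, ax] = np.clip(minus_cl[:, ax], 0, dims[ax] - 1)

        solid_plus = wallgeom.solid_neighbor[:, 2 * ax]
        solid_minus = wallgeom.solid_neighbor[:, 2 * ax + 1]
        fluid_plus = in_plus & ~solid_plus & mask[tuple(plus_cl.T)]
        fluid_minus = in_minus & ~solid_minus & mask[tuple(minus_cl.T)]

        # signed level-set distance toward each side (meters; fallback d/2)
        d_raw = wallgeom.distances[:, ax] * 1e-3
        d_plus = np.where(
            np.isfinite(d_raw) & (d_raw < 0), -d_raw, 0.5 * delta
        )
        d_minus = np.where(
            np.isfinite(d_raw) & (d_raw > 0), d_raw, 0.5 * delta
        )

        for comp in range(3):
            u_c = ucc[tuple(cells.T) + (comp,)]
            u_p = ucc[tuple(plus_cl.T) + (comp,)]
            u_m = ucc[tuple(minus_cl.T) + (comp,)]

            an_p, ax_p = _bc_coeffs(d_plus, delta, fluid_minus)
            face_p = an_p * u_c + ax_p * u_m  # BC value on the +side face
            an_m, ax_m = _bc_coeffs(d_minus, delta, fluid_plus)
            face_m = an_m * u_c + ax_m * u_p  # BC value on the -side face

            g = np.zeros(n)
            both = fluid_plus & fluid_minus
            g[both] = (u_p[both] - u_m[both]) / (2.0 * delta)
            sp_only = solid_plus & ~solid_minus
            g[sp_only] = (face_p[sp_only] - u_c[sp_only]) / (0.5 * delta)
            sm_only = solid_minus & ~solid_plus
            g[sm_only] = (u_c[sm_only] - face_m[sm_only]) / (0.5 * delta)
            bs = solid_plus & solid_minus
            g[bs] = (face_p[bs] - face_m[bs]) / delta
            # openings on the ROI boundary: one-sided inside the domain
            edge_p = ~in_plus & ~solid_plus & fluid_minus
            g[edge_p] = (u_c[edge_p] - u_m[edge_p]) / delta
            edge_m = ~in_minus & ~solid_minus & fluid_plus
            g[edge_m] = (u_p[edge_m] - u_c[edge_m]) / delta
            grad[:, comp, ax] = g

    return grad


def wall_shear_stress(
    grad: np.ndarray, normals: np.ndarray, viscosity: float
) -> tuple[np.ndarray, np.ndarray]:
    """WSS vectors tau_w = mu {grad(u).n - ((grad(u).n).n) n} and magnitudes."""
    traction = np.einsum("nca,na->nc", grad, normals)
    normal_part = np.einsum("nc,nc->n", traction, normals)
    tau = viscosity * (traction - normal_part[:, None] * normals)
    return tau, np.linalg.norm(tau, axis=1)


def build_wall_field(
    state: FlowState,
    mask: np.ndarray,
    wallgeom: WallGeometry,
    viscosity: float,
) -> WallField:
    """Assemble pressure, gradient tensor and WSS on the wall-adjacent cells."""
    grad = near_wall_gradient(state, mask, wallgeom)
    normals = wallgeom.normals.copy()
    bad = ~np.all(np.isfinite(normals), axis=1)
    normals[bad] = 0.0  # degenerate normals contribute zero WSS, flagged upstream
    tau, mag = wall_shear_stress(grad, normals, viscosity)
    return WallField(
        cells=wallgeom.cells,
        pressure=wall_pressure(state, wallgeom),
        grad=grad,
        normals=normals,
        wss=tau,
        wss_mag=mag,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def aneurysm_metrics(
    wallfield: WallField,
    state: FlowState,
    region: AneurysmRegion,
    U0: float,
    density: float,
) -> HemodynamicMetrics:
    """Normalized WSS statistics over the aneurysm wall and the aneurysm-volume
    averaged normalized speed.

    tau* = |tau_w| / (rho U0^2); reported are its max, mean and population
    standard deviation over wall-adjacent cells labelled aneurysm, plus the
    mean of |u|/U0 over all labelled lumen cells (cells have equal volume,
    so the volume-weighted mean is the plain mean).
    """
    if U0 <= 0:
        raise ValueError("U0 must be positive")
    sel = region.inside[tuple(wallfield.cells.T)]
    if not sel.any():
        raise ValueError("aneurysm region holds no wall-adjacent cells")
    scale = density * U0**2
    tau = wallfield.wss_mag[sel] / scale
    ucc = state.cell_center_velocity()
    speed = np.linalg.norm(ucc[region.inside], axis=1)
    if speed.size == 0:
        raise ValueError("aneurysm region holds no lumen cells")
    return HemodynamicMetrics(
        tau_max=float(np.max(tau)),
        tau_avg=float(np.mean(tau)),
        tau_var=float(np.std(tau)),  # population SD
        vel_avg=float(np.mean(speed)) / U0,
    )


def size_ratio(
    region: AneurysmRegion,
    spacing_mm,
    frame: Optional[CenterlineFrame] = None,
    parent_diameter: Optional[float] = None,
) -> float:
    """SR = (maximal pairwise extent of the aneurysm region) / parent diameter.

    The parent vessel diameter defaults to twice the maximum in-plane radius
    of the inflow opening (the centerline frame's discrete rim); both
    lengths in mm.
    """
    if parent_diameter is None:
        if frame is None or frame.radial_max is None:
            raise ValueError("need either a centerline frame or an explicit diameter")
        parent_diameter = 2.0 * frame.radial_max
    if parent_diameter <= 0:
        raise ValueError("degenerate parent vessel diameter")
    pts = (np.argwhere(region.inside) + 0.5) * np.asarray(spacing_mm, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty aneurysm region")
    return _max_extent(pts) / parent_diameter


def _max_extent(pts: np.ndarray) -> float:
    """Maximum pairwise distance; hull vertices first when the set is large."""
    if len(pts) == 1:
        return 0.0
    if len(pts) > 200:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (coplanar etc.): brute force below
            pass
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))
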