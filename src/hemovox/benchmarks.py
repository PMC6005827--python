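"""Canonical verification cases with analytic references.

These drive the package's routine verification: steady Poiseuille flow in a
voxelized straight tube (velocity profile, wall shear stress and axial
pressure gradient against the closed-form solution), a two-resolution grid
refinement study of the same case, and a short end-to-end run on the
sidewall-aneurysm phantom. Problem sizes are chosen so the whole set runs
on a single core in a few minutes; the analytic references are exact, so
the reported numbers are discretization errors, not fits.
"""

from __future__ import annotations

import numpy as np

from .image_io import InflowSettings, PipelineConfig
from .phantoms import sidewall_aneurysm_phantom, straight_tube_phantom
from .pipeline import run_pipeline

DEFAULT_RHO = 1060.0  # kg/m^3
DEFAULT_MU = 0.0035  # Pa*s


def _tube_config(dims, U0, *, steady_tol=1e-3, max_time=3.0, aneurysm_box=None,
                 rho=DEFAULT_RHO, mu=DEFAULT_MU):
    center = tuple(n // 2 for n in dims[:2])
    return PipelineConfig(
        seed_voxel=(center[0], center[1], dims[2] // 2),
        threshold=500.0,
        inflow_face="z_min",
        inflow=InflowSettings(U0=U0, steady=True),
        density=rho,
        viscosity=mu,
        steady_tol=steady_tol,
        max_time=max_time,
        aneurysm_box=aneurysm_box,
    )


def poiseuille_tube_benchmark(
    radius_vox: int = 10,
    length_vox: int = 40,
    spacing_mm: float = 0.25,
    U0: float = 0.01,
    steady_tol: float = 1e-3,
    max_time: float = 3.0,
) -> dict:
    """Steady parabolic inflow through a voxelized straight tube.

    The exact solution is Poiseuille flow: axial velocity
    ``w(r) = U0 (1 - r^2/R^2)``, wall shear ``2 mu U0 / R`` and axial
    pressure gradient ``-4 mu U0 / R^2``. Returns the relative errors of the
    computed profile (L-inf and L2 on a downstream cross-section), the mean
    wall WSS, the fitted pressure slope, and the conservation diagnostics.
    """
    n_side = 2 * radius_vox + 5  # odd: the axis passes through cell centers
    dims = (n_side, n_side, length_vox)
    radius_mm = radius_vox * spacing_mm
    vol, truth = straight_tube_phantom(
        dims=dims,
        spacing=(spacing_mm,) * 3,
        radius=radius_mm,
        axis="z",
        wall_width=2.0 * spacing_mm,
    )
    cfg = _tube_config(dims, U0, steady_tol=steady_tol, max_time=max_time)
    res = run_pipeline(cfg, volume=vol, write_outputs=False)

    state = res["state"]
    mask = res["lumen"].mask
    R = radius_mm * 1e-3  # meters
    mu = cfg.viscosity

    # --- velocity profile on a downstream cross-section ---
    k_probe = int(0.7 * length_vox)
    ucc = state.cell_center_velocity()
    w = ucc[:, :, k_probe, 2]
    msk = mask[:, :, k_probe]
    xs = (np.arange(dims[0]) + 0.5) * spacing_mm * 1e-3
    ys = (np.arange(dims[1]) + 0.5) * spacing_mm * 1e-3
    cx = dims[0] * spacing_mm * 1e-3 / 2.0
    cy = dims[1] * spacing_mm * 1e-3 / 2.0
    r2 = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2
    w_exact = U0 * np.clip(1.0 - r2 / R**2, 0.0, None)
    err = (w - w_exact)[msk]
    linf = float(np.max(np.abs(err))) / U0
    l2 = float(np.sqrt(np.mean(err**2))) / U0

    # --- wall shear stress on the lateral wall, middle section ---
    wf = res["wallfield"]
    kz = wf.cells[:, 2]
    mid = (kz >= int(0.3 * length_vox)) & (kz < int(0.7 * length_vox))
    wss_mean = float(np.mean(wf.wss_mag[mid]))
    wss_exact = 2.0 * mu * U0 / R
    wss_err = abs(wss_mean - wss_exact) / wss_exact

    # --- axial pressure gradient (slice-mean lumen pressure vs z) ---
    ks = np.arange(int(0.25 * length_vox), int(0.75 * length_vox))
    p_mean = np.array([float(np.mean(state.P[:, :, k][mask[:, :, k]])) for k in ks])
    z = (ks + 0.5) * spacing_mm * 1e-3
    slope = float(np.polyfit(z, p_mean, 1)[0])
    dpdz_exact = -4.0 * mu * U0 / R**2
    dpdz_err = abs(slope - dpdz_exact) / abs(dpdz_exact)

    hist = res["solver"].history
    return dict(
        linf_profile_err=linf,
        l2_profile_err=l2,
        wss_mean=wss_mean,
        wss_exact=wss_exact,
        wss_err=wss_err,
        dpdz=slope,
        dpdz_exact=dpdz_exact,
        dpdz_err=dpdz_err,
        max_div_ratio=max(h["div_ratio"] for h in hist),
        max_flux_imbalance=max(h["flux_imbalance"] for h in hist),
        steps=len(hist),
        n_cells=int(mask.sum()),
        results=res,
    )


def grid_convergence_study(
    radius_mm: float = 2.0,
    radii_vox=(6, 12),
    U0: float = 0.01,
    steady_tol: float = 3e-4,
) -> dict:
    """Poiseuille L2 error at two resolutions of one physical tube.

    The physical radius is fixed and the voxel spacing halves between the
    runs (R = 6 and 12 voxels); the observed convergence order is
    ``log2(E_coarse / E_fine)``.
    """
    length_factor = 2.0  # tube length = 2 R
    errors = {}
    for rv in radii_vox:
        spacing = radius_mm / rv
        length_vox = int(round(length_factor * rv))
        out = poiseuille_tube_benchmark(
            radius_vox=rv,
            length_vox=length_vox,
            spacing_mm=spacing,
            U0=U0,
            steady_tol=steady_tol,
        )
        out.pop("results")
        errors[rv] = out
    rv0, rv1 = sorted(radii_vox)
    e0, e1 = errors[rv0]["l2_profile_err"], errors[rv1]["l2_profile_err"]
    order = float(np.log2(e0 / e1))
    return dict(errors=errors, order=order)


def sidewall_pipeline_run(
    output_dir,
    noise_seed: int = 0,
    noise_sd: float = 0.0,
    max_time: float = 0.05,
    U0: float = 0.01,
) -> dict:
    """Short end-to-end run on the sidewall-aneurysm phantom.

    Not run to steady state by default: this exercises the full chain
    (segmentation through metrics CSV) deterministically; pass a larger
    ``max_time`` for converged hemodynamics.
    """
    dims = (36, 40, 40)
    spacing = 0.25
    vol, truth = sidewall_aneurysm_phantom(
        dims=dims,
        spacing=(spacing,) * 3,
        tube_radius=1.5,
        sac_radius=1.5,
        wall_width=2 * spacing,
        noise_sd=noise_sd,
        seed=noise_seed,
    )
    # label the sac region by its bounding box in voxel indices
    c = np.array(truth.params["sac_center"]) / spacing
    r = truth.params["sac_radius"] / spacing
    box = (
        max(0, int(c[0] - r - 1)), min(dims[0] - 1, int(c[0] + r + 1)),
        max(0, int(np.floor(truth.params["tube_radius"] / spacing
                            + truth.params["axis_point"][1] / spacing))),
        min(dims[1] - 1, int(c[1] + r + 1)),
        max(0, int(c[2] - r - 1)), min(dims[2] - 1, int(c[2] + r + 1)),
    )
    cfg = _tube_config(dims, U0, max_time=max_time, aneurysm_box=box)
    cfg.output_dir = str(output_dir)
    res = run_pipeline(cfg, volume=vol, write_outputs=True)
    res["truth"] = truth
    return res
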