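import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemovox as hv
from hemovox.geometry import LevelSetField
from hemovox.segmentation import BoundaryPatch, LumenMask
from hemovox.solver import FLUID, ImmersedBoundarySolver, SolverConfig, ghost_face_velocity


class TestGhostFaceVelocity:
    def test_branch_agreement_at_half_spacing(self):
        assert ghost_face_velocity(1.0, 2.0, 0.5, 1.0) == pytest.approx(0.0, abs=1e-15)
        assert ghost_face_velocity(1.0, 2.0, 0.5 - 1e-12, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_interpolation_branch_algebra(self):
        # d = delta/4, u_near = 1: U_BC = 1 * (1 - 1/(2*0.25)) = -1
        assert ghost_face_velocity(1.0, 0.0, 0.25, 1.0) == pytest.approx(-1.0)

    def test_mirror_branch_algebra(self):
        # d = 3 delta/4, u_near = 1, u_next = 2: (1-2)(0.5-0.75)/1 = 0.25
        assert ghost_face_velocity(1.0, 2.0, 0.75, 1.0) == pytest.approx(0.25)

    def test_clamp_returns_wall_velocity(self):
        assert ghost_face_velocity(5.0, 1.0, 0.01, 1.0) == 0.0

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            ghost_face_velocity(1.0, 1.0, 0.0, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        a=st.floats(-5.0, 5.0), d=st.floats(0.06, 1.5), delta=st.floats(0.1, 2.0)
    )
    def test_linear_profile_exactness_property(self, a, d, delta):
        # u(x) = a (x - x_w): the face a half-spacing inside of u_near
        d = d * delta
        u_near, u_next = a * d, a * (d + delta)
        exact = a * (d - 0.5 * delta)
        got = ghost_face_velocity(u_near, u_next, d, delta)
        assert got == pytest.approx(exact, abs=1e-12 * max(1.0, abs(a) * delta))


def _slab(nx=36, ny=4, nz=4, offset=0.3, spacing_mm=0.25):
    """Solid x-walls one cell thick, wall surfaces offset sub-voxel into the
    solid cells; every other boundary face is an opening (zero-gradient)."""
    dims = (nx, ny, nz)
    mask = np.zeros(dims, dtype=bool)
    mask[1:-1, :, :] = True
    xs = (np.arange(nx) + 0.5) * spacing_mm
    xw1 = (1.0 - offset) * spacing_mm  # inside solid cell 0
    xw2 = (nx - 1.0 + offset) * spacing_mm
    phi = np.minimum(xs - xw1, xw2 - xs)[:, None, None] * np.ones((1, ny, nz))
    ls = LevelSetField(phi, phi.copy(), (spacing_mm,) * 3, 0.0)
    lumen = LumenMask(mask=mask, seed=(nx // 2, 0, 0), threshold=0.0)
    patches = []
    for face, axis, idx in (
        ("y_min", 1, 0), ("y_max", 1, ny - 1), ("z_min", 2, 0), ("z_max", 2, nz - 1),
    ):
        sel = np.argwhere(mask)
        vox = sel[sel[:, axis] == idx]
        patches.append(BoundaryPatch(face=face, voxels=vox, centroid=np.zeros(3),
                                     role="outflow"))
    H = (xw2 - xw1) * 1e-3  # true wall gap, meters
    return lumen, ls, patches, xw1 * 1e-3, H


class TestMomentumPredictor:
    def test_zero_state_stays_zero(self):
        lumen, ls, patches, _, _ = _slab()
        s = ImmersedBoundarySolver(lumen, ls, SolverConfig(), patches=patches)
        s.momentum_predictor(1e-4)
        for c in range(3):
            assert np.all(s.u[c] == 0.0)

    def test_uniform_axial_velocity_unchanged_without_walls(self):
        # all-fluid box, free boundaries: convection and diffusion both vanish
        dims = (6, 6, 8)
        mask = np.ones(dims, dtype=bool)
        phi = np.full(dims, 10.0)
        ls = LevelSetField(phi, phi.copy(), (0.25,) * 3, 0.0)
        lumen = LumenMask(mask=mask, seed=(3, 3, 4), threshold=0.0)
        patches = []
        for face, axis, idx in (
            ("x_min", 0, 0), ("x_max", 0, 5), ("y_min", 1, 0), ("y_max", 1, 5),
            ("z_min", 2, 0), ("z_max", 2, 7),
        ):
            sel = np.argwhere(mask)
            patches.append(BoundaryPatch(face=face, voxels=sel[sel[:, axis] == idx],
                                         centroid=np.zeros(3), role="outflow"))
        s = ImmersedBoundarySolver(lumen, ls, SolverConfig(), patches=patches)
        s.u[2][:] = 1.0
        for _ in range(3):
            s.momentum_predictor(5e-4)
        np.testing.assert_allclose(s.u[2], 1.0, atol=1e-13)
        assert np.max(np.abs(s.u[0])) < 1e-13
        assert np.max(np.abs(s.u[1])) < 1e-13

    def test_sine_diffusion_decay_between_offset_walls(self):
        # 1-D viscous decay of sin(pi x'/H) between walls placed 0.3 voxel
        # inside the solid cells: the decay rate must match exp(-nu k^2 t)
        # computed with the *true* wall gap H, demonstrating that the ghost
        # closure sees the sub-voxel wall position.
        lumen, ls, patches, xw1, H = _slab(nx=36, offset=0.3)
        cfg = SolverConfig(density=1060.0, viscosity=0.0035)
        s = ImmersedBoundarySolver(lumen, ls, cfg, patches=patches)
        nu = cfg.viscosity / cfg.density
        k = np.pi / H
        lam = nu * k * k
        Sw = s._shape[2]
        xs = (np.arange(Sw[0]) + 0.5) * s.h[0]
        prof = 0.01 * np.sin(np.clip(k * (xs - xw1), 0.0, np.pi))
        W = np.broadcast_to(prof[:, None, None], Sw).copy()
        keep = s.types[2] == FLUID
        s.u[2][keep.ravel()] = W[keep]
        s._apply_outflow_lag()
        s._update_cut_faces()
        a0 = float(np.max(np.abs(s.u[2])))
        dt = 0.05 / lam
        nsteps = 14
        for _ in range(nsteps):
            s.momentum_predictor(dt)
        a1 = float(np.max(np.abs(s.u[2])))
        expected = np.exp(-lam * nsteps * dt)
        assert abs(a1 / a0 - expected) / expected < 0.005


def _tube_solver(U0=0.01, dims=(17, 17, 16), radius=1.5, steady_tol=1e-3,
                 max_time=0.6):
    vol, _ = hv.straight_tube_phantom(dims=dims, radius=radius, wall_width=0.5)
    lumen = hv.region_grow(vol, (dims[0] // 2, dims[1] // 2, dims[2] // 2), 500.0)
    patches = hv.identify_openings(lumen, vol.spacing, "z_min")
    ls = hv.smooth_levelset(hv.build_levelset(vol, 500.0))
    inflow_patch = next(p for p in patches if p.role == "inflow")
    frame = hv.inplane_radius(
        hv.vessel_centerline(lumen, inflow_patch, vol.spacing), vol.spacing
    )
    prof = hv.parabolic_profile(frame, U0)
    bc = hv.map_profile_to_faces(prof, lumen.mask, vol.spacing)
    cfg = SolverConfig(steady_tol=steady_tol, max_time=max_time, init="extrude")
    return ImmersedBoundarySolver(lumen, ls, cfg, patches=patches, inflow_bc=bc)


class TestPressureProjection:
    def test_divergence_free_field_gives_zero_pressure(self):
        s = _tube_solver()
        # zero velocity everywhere (divergence-free): P must vanish
        for c in range(3):
            s.u[c][:] = 0.0
        P = s.pressure_poisson(1e-3)
        assert np.max(np.abs(P)) < 1e-12

    def test_manufactured_cosine_laplacian(self):
        # rectangular duct: solid x/y shells (Neumann), outflow at both z
        # ends; the assembled operator applied to a Neumann-compatible
        # cosine must reproduce its Laplacian to second order
        nx, ny, nz = 24, 6, 6
        sp = 0.25
        mask = np.zeros((nx, ny, nz), dtype=bool)
        mask[1:-1, 1:-1, :] = True
        phi = np.where(mask, 1.0, -1.0)
        ls = LevelSetField(phi, phi.copy(), (sp,) * 3, 0.0)
        lumen = LumenMask(mask=mask, seed=(nx // 2, ny // 2, nz // 2), threshold=0.0)
        sel = np.argwhere(mask)
        patches = [
            BoundaryPatch("z_min", sel[sel[:, 2] == 0], np.zeros(3), "outflow"),
            BoundaryPatch("z_max", sel[sel[:, 2] == nz - 1], np.zeros(3), "outflow"),
        ]
        s = ImmersedBoundarySolver(lumen, ls, SolverConfig(), patches=patches)
        h = s.h[0]
        L = (nx - 2) * h  # gap between the two staircase wall faces
        k = np.pi / L
        cells = s.fluid_cells
        x = (cells[:, 0] + 0.5) * h
        p = np.cos(k * (x - h))
        lap = s._poisson_A @ p
        interior = (cells[:, 2] > 0) & (cells[:, 2] < nz - 1)
        exact = -(k**2) * p[interior]
        assert np.max(np.abs(lap[interior] - exact)) / np.max(np.abs(exact)) < 0.01

    def test_poisson_solution_invariant_under_reordering(self):
        import scipy.sparse as sp
        from scipy.sparse.linalg import spsolve

        s = _tube_solver()
        rng = np.random.default_rng(0)
        b = rng.normal(size=s.n_cells)
        x1 = s._poisson_lu.solve(b)
        perm = rng.permutation(s.n_cells)
        Pm = sp.csr_matrix((np.ones(s.n_cells), (np.arange(s.n_cells), perm)))
        A2 = Pm @ s._poisson_A @ Pm.T
        x2 = Pm.T @ spsolve(A2.tocsc(), Pm @ b)
        assert np.max(np.abs(x1 - x2)) / np.max(np.abs(x1)) < 1e-8

    def test_all_neumann_system_reported_singular(self):
        lumen, ls, _, _, _ = _slab()
        s = ImmersedBoundarySolver(lumen, ls, SolverConfig(), patches=None)
        with pytest.raises(ValueError, match="singular|Neumann"):
            s.pressure_poisson(1e-3)

    def test_zero_pressure_corrector_is_identity_on_interior_faces(self):
        s = _tube_solver()
        s.step()
        before = [u.copy() for u in s.u]
        s.P[:] = 0.0
        s.corrector(1e-3)
        for c in range(3):
            fl = (s.types[c] == FLUID).ravel()
            np.testing.assert_array_equal(s.u[c][fl], before[c][fl])

    def test_projection_contract_and_flux_identity(self):
        s = _tube_solver()
        for _ in range(5):
            rec = s.step()
            assert rec["div_ratio"] <= 10.0 * s.cfg.poisson_tol
            assert rec["flux_imbalance"] <= 1e-10


class TestRun:
    def test_identical_runs_are_bitwise_identical(self):
        s1 = _tube_solver(max_time=0.05)
        s2 = _tube_solver(max_time=0.05)
        st1 = s1.run()
        st2 = s2.run()
        for a, b in ((st1.U, st2.U), (st1.V, st2.V), (st1.W, st2.W), (st1.P, st2.P)):
            assert np.array_equal(a, b)

    def test_steady_state_is_idempotent(self):
        s = _tube_solver(steady_tol=3e-4, max_time=3.0)
        s.run()
        rec = s.step()  # one extra step barely changes a converged state
        assert rec["rel_change"] < 1e-5

    def test_poiseuille_profile_small_tube(self):
        # R = 6 voxels: steady profile within a few percent of the parabola
        s = _tube_solver(dims=(17, 17, 20), radius=1.5, steady_tol=5e-4, max_time=3.0)
        state = s.run()
        ucc = state.cell_center_velocity()
        k = 14
        msk = s.mask[:, :, k]
        xs = (np.arange(17) + 0.5) * 0.25e-3
        c = 17 * 0.25e-3 / 2
        r2 = (xs[:, None] - c) ** 2 + (xs[None, :] - c) ** 2
        exact = 0.01 * np.clip(1 - r2 / 1.5e-3**2, 0, None)
        err = np.abs(ucc[:, :, k, 2] - exact)[msk]
        assert np.max(err) / 0.01 < 0.08
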