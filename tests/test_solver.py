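"""Equilibrium-solver verification: patch test, thick-sphere oracle,
loading monotonicity, strain extraction, energy consistency."""

import numpy as np
import pytest
from scipy import integrate, optimize

from lvmech.geometry import GeometryConfig, build_ellipsoid_mesh, build_box_mesh
from lvmech.materials import PassiveParams, passive_stress
from lvmech.active import ActiveParams, end_systolic_tension
from lvmech.solver import (SolverConfig, EquilibriumState, MMHG_TO_KPA,
                           _Assembler, _basal_constraints, BoundaryConditions,
                           solve_passive_inflation, solve_end_systole,
                           solve_dirichlet, regional_circumferential_strain,
                           global_longitudinal_strain)

COARSE = dict(n_circ=8, n_long=6, n_trans=2)


@pytest.fixture(scope="module")
def coarse_geom():
    return build_ellipsoid_mesh(GeometryConfig(**COARSE))


def make_state(geom, u, F):
    E, Q = geom.qp_wdetJ.shape
    return EquilibriumState(
        displacement=u, converged=True, residual_norm=0.0,
        cavity_volume_ml=1.0, F=np.broadcast_to(F, (E, Q, 3, 3)).copy(),
        lambda_f=np.ones((E, Q)), active_tension=np.zeros((E, Q)),
        pressure_mmhg=0.0,
    )


class TestBasicLoading:
    def test_zero_pressure_zero_displacement(self, coarse_geom):
        st = solve_passive_inflation(coarse_geom, PassiveParams(), 0.0)
        assert np.all(st.displacement == 0.0)
        assert st.residual_norm == 0.0

    def test_volume_increases_monotonically_with_pressure(self, coarse_geom):
        vols = []
        prev = None
        for p in (2.0, 4.0, 6.0, 8.0):
            prev = solve_passive_inflation(coarse_geom, PassiveParams(), p,
                                           initial_state=prev)
            vols.append(prev.cavity_volume_ml)
        assert np.all(np.diff(vols) > 0)

    def test_energy_consistency_at_equilibrium(self, coarse_geom):
        """At convergence, internal virtual work balances pressure work for
        every admissible virtual displacement (reduced residual ~ 0)."""
        st = solve_passive_inflation(coarse_geom, PassiveParams(), 8.0)
        asm = _Assembler(coarse_geom)
        C = _basal_constraints(coarse_geom, BoundaryConditions(pressure_mmhg=8.0))
        fint, _, _, _ = asm.internal_force(st.displacement, PassiveParams(), None)
        fext = asm.follower_force(st.displacement, 8.0 * MMHG_TO_KPA)
        r = C.T @ (fint - fext).ravel()
        rng = np.random.default_rng(3)
        for _ in range(5):
            dv = rng.standard_normal(r.shape)
            work_gap = abs(np.dot(r, dv))
            ref = abs(np.dot(C.T @ fext.ravel(), dv)) + 1e-12
            assert work_gap <= 1e-6 * ref

    def test_incompressibility_held_at_peak_load(self, coarse_geom):
        st = solve_passive_inflation(coarse_geom, PassiveParams(), 8.0)
        es = solve_end_systole(coarse_geom, PassiveParams(),
                               ActiveParams(T_req=144.0), 129.0, ed_state=st)
        for s in (st, es):
            J = np.linalg.det(s.F)
            Jbar = (np.sum(coarse_geom.qp_wdetJ * J, axis=1)
                    / np.sum(coarse_geom.qp_wdetJ, axis=1))
            assert np.abs(Jbar - 1.0).max() < 0.02


class TestEndSystole:
    def test_no_activation_no_extra_pressure_keeps_ed_state(self, coarse_geom):
        ed = solve_passive_inflation(coarse_geom, PassiveParams(), 8.0)
        es = solve_end_systole(coarse_geom, PassiveParams(),
                               ActiveParams(T_req=1e-9), 8.0, ed_state=ed)
        assert np.abs(es.displacement - ed.displacement).max() < 1e-6
        assert es.cavity_volume_ml == pytest.approx(ed.cavity_volume_ml, rel=1e-8)

    def test_esv_decreases_with_contractility(self, coarse_geom):
        ed = solve_passive_inflation(coarse_geom, PassiveParams(), 8.0)
        vols = []
        prev = None
        for treq in (80.0, 120.0, 160.0):
            prev = solve_end_systole(coarse_geom, PassiveParams(),
                                     ActiveParams(T_req=treq), 129.0,
                                     ed_state=ed, warm_state=prev)
            vols.append(prev.cavity_volume_ml)
        assert np.all(np.diff(vols) < 0)


class TestPatchTest:
    """Homogeneous-deformation patch test on a myocardium block: affine
    Dirichlet data must produce a uniform interior state whose stress equals
    the material-point evaluation."""

    @pytest.mark.parametrize("active", [None, ActiveParams(T_req=60.0)])
    def test_affine_boundary_gives_uniform_stress(self, active):
        geom = build_box_mesh((3, 3, 3), (1.0, 1.0, 1.0))
        A = np.array([[1.06, 0.03, 0.0],
                      [0.00, 0.97, 0.02],
                      [0.01, 0.00, 0.99]])
        X = geom.nodes
        on_bnd = np.any((X < 1e-12) | (X > 1.0 - 1e-12), axis=1)
        bnodes = np.nonzero(on_bnd)[0]
        u_b = X[bnodes] @ (A - np.eye(3)).T
        st = solve_dirichlet(geom, PassiveParams(), bnodes, u_b, active=active)
        # uniform deformation gradient equal to A everywhere
        assert np.abs(st.F - A).max() < 1e-6
        # quadrature stress equals the point-level constitutive evaluation
        asm = _Assembler(geom)
        act = None
        if active is not None:
            def act(lam):
                return end_systolic_tension(lam, active)
        sig_qp, _, _ = asm.stress(st.F.reshape(-1, 3, 3), PassiveParams(), act)
        f0 = geom.fibers.f0.reshape(-1, 3)[0]
        s0 = geom.fibers.s0.reshape(-1, 3)[0]
        sig_pt = passive_stress(A, PassiveParams(), f0, s0, include_penalty=False)
        if active is not None:
            lam = np.linalg.norm(A @ f0)
            f_cur = A @ f0 / lam
            sig_pt = sig_pt + end_systolic_tension(lam, active) * np.outer(f_cur, f_cur)
        assert np.abs(sig_qp - sig_pt).max() < 1e-6 * max(1.0, np.abs(sig_pt).max())


class TestThickSphereOracle:
    def test_isotropic_inflation_matches_1d_equilibrium(self):
        """Isotropic-limit (a_f = a_s = a_fs = 0) hemispherical shell under
        pressure: the mid-plane inner-radius expansion must match the
        incompressible 1D thick-sphere equilibrium integrated by
        quadrature, within 2%."""
        R_in, wall = 25.0, 8.0
        cfg = GeometryConfig(
            r_short_endo_mm=R_in, r_long_endo_mm=R_in, wall_thickness_mm=wall,
            apex_thickness_mm=wall, base_height_mm=1e-6, apex_opening_rad=0.12,
            n_circ=12, n_long=10, n_trans=3,
        )
        geom = build_ellipsoid_mesh(cfg)
        p = PassiveParams(a=2.0, b=3.0, a_f=0.0, b_f=1.0, a_s=0.0, b_s=1.0,
                          a_fs=0.0, b_fs=1.0, beta_s=2000.0)
        p_mmhg = 8.0
        st = solve_passive_inflation(geom, p, p_mmhg)

        # 1D incompressible oracle: r(R)^3 = R^3 - A^3 + a^3;
        # p(a) = int_a^b 2 (sigma_theta - sigma_r) / r dr,
        # sigma_theta - sigma_r = (lam / 2) dW/dlam with lam = r / R
        A, B = R_in, R_in + wall

        def dW_dlam(lam):
            I1 = 2 * lam**2 + lam**-4
            return p.a / (2 * p.b) * np.exp(p.b * (I1 - 3)) * p.b * (4 * lam - 4 * lam**-5)

        def pressure_of_inner(a_in):
            def integrand(r):
                R = (r**3 - a_in**3 + A**3) ** (1.0 / 3.0)
                lam = r / R
                return 2.0 * (lam / 2.0) * dW_dlam(lam) / r

            b_out = (B**3 - A**3 + a_in**3) ** (1.0 / 3.0)
            val, _ = integrate.quad(integrand, a_in, b_out, limit=200)
            return val

        target = p_mmhg * MMHG_TO_KPA
        a_oracle = optimize.brentq(lambda a_: pressure_of_inner(a_) - target,
                                   A + 1e-9, A * 1.5)

        # FE inner radius near the equatorial mid-plane (away from the
        # basal constraint and apical truncation)
        x = geom.nodes + st.displacement
        endo_ids = np.unique(geom.faces["endo"])
        z = geom.nodes[endo_ids, 2]
        band = endo_ids[(z < -0.3 * R_in) & (z > -0.8 * R_in)]
        r_fe = np.linalg.norm(x[band] - [0, 0, -cfg.base_height_mm], axis=1).mean()
        r_ref = np.linalg.norm(geom.nodes[band] - [0, 0, -cfg.base_height_mm],
                               axis=1).mean()
        expansion_fe = r_fe / r_ref
        expansion_oracle = a_oracle / A
        assert expansion_fe == pytest.approx(expansion_oracle, rel=0.02)


class TestStrainExtraction:
    def test_reference_state_zero_strain(self, coarse_geom):
        st = make_state(coarse_geom, np.zeros_like(coarse_geom.nodes), np.eye(3))
        eps = regional_circumferential_strain(st, coarse_geom)
        np.testing.assert_allclose(eps, 0.0, atol=1e-14)

    def test_rigid_rotation_zero_strain(self, coarse_geom, rng):
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.linalg.det(q))
        u = coarse_geom.nodes @ q.T - coarse_geom.nodes
        st = make_state(coarse_geom, u, q)
        eps = regional_circumferential_strain(st, coarse_geom)
        np.testing.assert_allclose(eps, 0.0, atol=1e-12)

    def test_prescribed_circumferential_shrink(self, coarse_geom):
        k = 0.85
        F = np.diag([k, k, 1.0])
        u = coarse_geom.nodes @ (F - np.eye(3)).T
        st = make_state(coarse_geom, u, F)
        eps = regional_circumferential_strain(st, coarse_geom)
        np.testing.assert_allclose(eps, -0.15, atol=1e-9)

    def test_strain_relative_to_reference_state(self, coarse_geom):
        Fa = np.diag([1.1, 1.1, 1.0])
        Fb = np.diag([0.99, 0.99, 1.0])
        sta = make_state(coarse_geom, coarse_geom.nodes @ (Fa - np.eye(3)).T, Fa)
        stb = make_state(coarse_geom, coarse_geom.nodes @ (Fb - np.eye(3)).T, Fb)
        eps = regional_circumferential_strain(stb, coarse_geom, reference_state=sta)
        np.testing.assert_allclose(eps, 0.99 / 1.1 - 1.0, atol=1e-9)


class TestGlobalLongitudinalStrain:
    def test_zero_without_deformation(self, coarse_geom):
        st = make_state(coarse_geom, np.zeros_like(coarse_geom.nodes), np.eye(3))
        assert global_longitudinal_strain(st, coarse_geom) == pytest.approx(0.0)

    def test_uniform_ten_percent_shortening(self, coarse_geom):
        u = -0.1 * coarse_geom.nodes
        st = make_state(coarse_geom, u, 0.9 * np.eye(3))
        gls = global_longitudinal_strain(st, coarse_geom)
        assert gls == pytest.approx(-10.0, abs=1e-9)

    def test_healthy_default_in_physiological_range(self, control_subject):
        """Forward GLS of the calibrated healthy default: negative,
        physiologically plausible in magnitude.  The basal plane is held
        longitudinally (study boundary condition), which suppresses the
        atrioventricular-plane descent that dominates clinical GLS, so the
        simulated magnitude sits below the imaging-population -20%."""
        gls = control_subject["truth"].gls_pct
        assert -20.0 < gls < -8.0


class TestMeshRefinement:
    def test_edv_stable_under_refinement(self):
        """End-diastolic volume changes by < 2% when every resolution
        direction is doubled from the default mesh (the refined solve is
        warm-started from the interpolated coarse solution)."""
        import dataclasses
        from types import SimpleNamespace
        from lvmech.geometry import interpolate_displacement

        cfg0 = GeometryConfig()
        geom0 = build_ellipsoid_mesh(cfg0)
        st0 = solve_passive_inflation(geom0, PassiveParams(), 8.0)
        cfg1 = GeometryConfig(n_circ=2 * cfg0.n_circ, n_long=2 * cfg0.n_long,
                              n_trans=2 * cfg0.n_trans)
        geom1 = build_ellipsoid_mesh(cfg1)
        u_guess = interpolate_displacement(geom0, st0.displacement, geom1)
        # warm start through a short penalty continuation: the interpolated
        # guess carries volumetric noise that the full beta_s amplifies
        prev = SimpleNamespace(displacement=u_guess)
        for beta in (30.0, 300.0, PassiveParams().beta_s):
            pp = dataclasses.replace(PassiveParams(), beta_s=beta)
            prev = solve_passive_inflation(geom1, pp, 8.0, initial_state=prev)
        rel = abs(prev.cavity_volume_ml - st0.cavity_volume_ml) / st0.cavity_volume_ml
        assert rel < 0.02
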