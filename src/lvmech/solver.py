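"""Quasi-static finite-element equilibrium of the left ventricle.

The biomarkers of interest are defined at two quasi-steady states — end-
diastole (ED) and end-systole (ES) — so the fluid-structure transient is
replaced by
quasi-static solid equilibrium: the endocardial blood pressure acts as a
follower traction and inertial/viscous blood terms are dropped.  The
reference configuration is the early-diastolic geometry, treated as
stress-free.

Discretization: total-Lagrangian trilinear hexahedra, 2x2x2 Gauss
quadrature, Newton iteration with load stepping and a backtracking line
search.  The consistent tangent is assembled from per-element (and
per-face, for the follower load) forward differences of the element force
vectors — robust for the exponential constitutive law and cheap at the
problem sizes used here.  Incompressibility is enforced through the
logarithmic penalty of the passive stress.

Boundary conditions follow the study setup: longitudinal (z) and
circumferential displacements of the basal plane are fixed, radial motion
is free.  The constraint is applied by rotating basal node dofs into a
cylindrical frame and retaining only the radial one.

Units: lengths mm, stresses kPa, pressures converted from mmHg at exactly
one point (MMHG_TO_KPA); with these choices forces are in mN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _fem
from .geometry import LVGeometry, cavity_volume
from .materials import (PassiveParams, passive_stress, infarct_scale_field,
                        penalty_pressure)
from .active import ActiveParams, end_systolic_tension

__all__ = [
    "MMHG_TO_KPA",
    "BoundaryConditions",
    "SolverConfig",
    "EquilibriumState",
    "SolverError",
    "solve_passive_inflation",
    "solve_end_systole",
    "solve_dirichlet",
    "regional_circumferential_strain",
    "global_longitudinal_strain",
]

#: The single pressure-unit conversion point of the package.
MMHG_TO_KPA = 0.133322


class SolverError(RuntimeError):
    """Raised on Newton non-convergence or element inversion; carries the
    last residual norm and load step for diagnosis."""

    def __init__(self, msg, residual=None, step=None):
        super().__init__(msg)
        self.residual = residual
        self.step = step


@dataclass(frozen=True)
class BoundaryConditions:
    """Cavity pressure (mmHg) and basal constraint flags."""

    pressure_mmhg: float = 0.0
    fix_base_longitudinal: bool = True
    fix_base_circumferential: bool = True

    def __post_init__(self):
        if self.pressure_mmhg < 0:
            raise ValueError("cavity pressure must be >= 0")


@dataclass(frozen=True)
class SolverConfig:
    """Newton/load-stepping controls."""

    n_load_steps: int = 24
    newton_tol: float = 1e-8          # relative residual
    max_newton_iter: int = 80
    fd_step: float = 1e-6             # tangent finite-difference step (mm)
    max_line_search: int = 10
    max_increment_mm: float = 3.0     # trust-region cap on one Newton update

    def __post_init__(self):
        if self.newton_tol <= 0:
            raise ValueError("tolerance must be > 0")
        if self.n_load_steps < 1:
            raise ValueError("need at least one load step")


@dataclass
class EquilibriumState:
    """Converged deformed configuration and derived fields."""

    displacement: np.ndarray          # (n, 3) mm
    converged: bool
    residual_norm: float
    cavity_volume_ml: float
    F: np.ndarray                     # (E, Q, 3, 3)
    lambda_f: np.ndarray              # (E, Q) fiber stretch
    active_tension: np.ndarray        # (E, Q) kPa (zero for passive solves)
    pressure_mmhg: float
    n_newton_total: int = 0


# ---------------------------------------------------------------------------
# assembly helpers


class _Assembler:
    """Precomputed index arrays and cached fields for one geometry."""

    def __init__(self, geom: LVGeometry):
        self.geom = geom
        E = geom.n_elems
        self.ndof = 3 * geom.n_nodes
        # element dof map (E, 24)
        self.edofs = (3 * geom.elems[:, :, None] + np.arange(3)[None, None, :]).reshape(E, 24)
        self.rows = np.repeat(self.edofs, 24, axis=1).ravel()
        self.cols = np.tile(self.edofs, (1, 24)).ravel()
        # flattened qp fields
        self.f0 = geom.fibers.f0.reshape(-1, 3)
        self.s0 = geom.fibers.s0.reshape(-1, 3)
        self.a_scale = infarct_scale_field(geom.phi).reshape(-1)
        self.phi = geom.phi.reshape(-1)
        self.wdetJ = geom.qp_wdetJ
        # endocardial faces for the follower load
        endo = geom.faces.get("endo")
        if endo is not None and len(endo):
            self.fnodes = endo                                  # (Fc, 4)
            self.fdofs = (3 * endo[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
            self.frows = np.repeat(self.fdofs, 12, axis=1).ravel()
            self.fcols = np.tile(self.fdofs, (1, 12)).ravel()
            # orientation: follower force must push the wall away from the
            # cavity; flip faces whose reference normal points toward it
            x = geom.nodes[endo]                                # (Fc, 4, 3)
            n_ref = np.cross(x[:, 1] - x[:, 0], x[:, 3] - x[:, 0])
            center = np.array([0.0, 0.0, x[..., 2].min() * 0.4])
            outward = x.mean(axis=1) - center
            self.fsign = np.where(np.einsum("fi,fi->f", n_ref, outward) > 0, 1.0, -1.0)
        else:
            self.fnodes = None

    # -- internal force ----------------------------------------------------

    def stress(self, F_flat, passive: PassiveParams, act_tension_fn):
        """Constitutive Cauchy stress at all quadrature points (no volumetric
        penalty — the assembler applies it at the element-mean dilatation).

        ``act_tension_fn(lambda_f) -> kPa`` or None; the active stress is
        scaled by (1 - phi) so the infarct core is purely passive.  Returns
        (sigma, lambda_f, T_eff)."""
        sig = passive_stress(F_flat, passive, self.f0, self.s0,
                             a_scale=self.a_scale, include_penalty=False)
        Ff = np.einsum("mij,mj->mi", F_flat, self.f0)
        lam = np.linalg.norm(Ff, axis=-1)
        if act_tension_fn is None:
            T = np.zeros_like(lam)
        else:
            T = act_tension_fn(lam) * (1.0 - self.phi)
            f_cur = Ff / lam[:, None]
            sig = sig + T[:, None, None] * np.einsum("mi,mj->mij", f_cur, f_cur)
        return sig, lam, T

    def _force_from_ue(self, ue, passive, act_tension_fn, batch: int = 1):
        """Element forces from element-local displacements.

        ``ue`` has shape (batch * E, 8, 3); a batch > 1 evaluates several
        independently perturbed copies of the mesh in one sweep (used by the
        finite-difference tangent).  The volumetric penalty is evaluated at
        the element-mean dilatation Jbar (mean-dilatation treatment) to
        avoid volumetric locking of trilinear hexahedra at large penalty
        moduli.  Returns (forces (batch*E, 24), F, lambda_f, T).
        """
        geom = self.geom
        E, Q = self.wdetJ.shape
        B = batch
        ub = ue.reshape(B, E, 8, 3)
        F = np.einsum("beai,eqaj->beqij", ub, geom.qp_G) + np.eye(3)
        if B == 1:
            f0, s0, a_sc, phi = self.f0, self.s0, self.a_scale, self.phi
        else:
            f0 = np.tile(self.f0, (B, 1))
            s0 = np.tile(self.s0, (B, 1))
            a_sc = np.tile(self.a_scale, B)
            phi = np.tile(self.phi, B)
        F_flat = F.reshape(-1, 3, 3)
        sig = passive_stress(F_flat, passive, f0, s0, a_scale=a_sc,
                             include_penalty=False)
        Ff = np.einsum("mij,mj->mi", F_flat, f0)
        lam = np.linalg.norm(Ff, axis=-1)
        if act_tension_fn is None:
            T = np.zeros_like(lam)
        else:
            T = act_tension_fn(lam) * (1.0 - phi)
            f_cur = Ff / lam[:, None]
            sig = sig + T[:, None, None] * np.einsum("mi,mj->mij", f_cur, f_cur)
        sig = sig.reshape(B, E, Q, 3, 3)
        J = np.linalg.det(F)
        Jbar = np.sum(self.wdetJ * J, axis=-1) / np.sum(self.wdetJ, axis=-1)
        pen = penalty_pressure(Jbar, passive.beta_s)
        sig = sig + pen[..., None, None, None] * np.eye(3)
        Finv = np.linalg.inv(F)
        # first Piola-Kirchhoff P = J sigma F^{-T}
        P = J[..., None, None] * np.einsum("beqik,beqjk->beqij", sig, Finv)
        f = np.einsum("eq,beqij,eqaj->beai", self.wdetJ, P, geom.qp_G)
        if B == 1:
            return (f.reshape(E, 24), F.reshape(E, Q, 3, 3),
                    lam.reshape(E, Q), T.reshape(E, Q))
        return f.reshape(B * E, 24), F, lam, T

    def internal_force_elem(self, u, passive, act_tension_fn):
        """Element internal force vectors (E, 24) at displacement u (n, 3)."""
        return self._force_from_ue(u[self.geom.elems], passive, act_tension_fn)

    def internal_force(self, u, passive, act_tension_fn):
        fe, F, lam, T = self.internal_force_elem(u, passive, act_tension_fn)
        f = np.zeros(self.ndof)
        np.add.at(f, self.edofs.ravel(), fe.ravel())
        return f, F, lam, T

    def internal_tangent(self, u, passive, act_tension_fn, h):
        """Sparse tangent of the internal force by per-element forward
        differences over the 24 local dofs, evaluated in one batched sweep
        (elements sharing a node are perturbed independently)."""
        geom = self.geom
        f0e, _, _, _ = self.internal_force_elem(u, passive, act_tension_fn)
        E = geom.n_elems
        ue = u[geom.elems]                                      # (E, 8, 3)
        # batch of 24 perturbed copies: (24, E, 8, 3)
        ub = np.broadcast_to(ue, (24, E, 8, 3)).copy()
        for d in range(24):
            ub[d, :, d // 3, d % 3] += h
        fp, _, _, _ = self._force_from_ue(
            ub.reshape(24 * E, 8, 3), passive, act_tension_fn, batch=24
        )
        K = np.moveaxis((fp.reshape(24, E, 24) - f0e[None]) / h, 0, 2)  # (E, 24, 24)
        return sp.coo_matrix((K.ravel(), (self.rows, self.cols)), shape=(self.ndof, self.ndof)).tocsr()

    # -- follower pressure -------------------------------------------------

    def follower_force_face(self, u, p_kpa):
        """Per-face nodal follower forces (Fc, 12) at pressure p (kPa)."""
        x = (self.geom.nodes + u)[self.fnodes]                  # (Fc, 4, 3)
        dN = _fem.QUAD_DN_QP                                    # (4 qp, 4, 2)
        xq1 = np.einsum("fai,qa->fqi", x, dN[..., 0])
        xq2 = np.einsum("fai,qa->fqi", x, dN[..., 1])
        n = np.cross(xq1, xq2)                                  # (Fc, 4qp, 3)
        f = p_kpa * np.einsum("f,qa,fqi->fai", self.fsign, _fem.QUAD_N_QP, n)
        return f.reshape(len(self.fnodes), 12)

    def follower_force(self, u, p_kpa):
        f = np.zeros(self.ndof)
        if self.fnodes is None or p_kpa == 0.0:
            return f
        fe = self.follower_force_face(u, p_kpa)
        np.add.at(f, self.fdofs.ravel(), fe.ravel())
        return f

    def follower_tangent(self, u, p_kpa, h):
        if self.fnodes is None or p_kpa == 0.0:
            return sp.csr_matrix((self.ndof, self.ndof))
        f0 = self.follower_force_face(u, p_kpa)
        Fc = len(self.fnodes)
        K = np.empty((Fc, 12, 12))
        for a in range(4):
            for i in range(3):
                x = (self.geom.nodes + u)[self.fnodes]
                x[:, a, i] += h
                dN = _fem.QUAD_DN_QP
                xq1 = np.einsum("fai,qa->fqi", x, dN[..., 0])
                xq2 = np.einsum("fai,qa->fqi", x, dN[..., 1])
                n = np.cross(xq1, xq2)
                fp = p_kpa * np.einsum("f,qa,fqi->fai", self.fsign, _fem.QUAD_N_QP, n)
                K[:, :, 3 * a + i] = (fp.reshape(Fc, 12) - f0) / h
        return sp.coo_matrix((K.ravel(), (self.frows, self.fcols)), shape=(self.ndof, self.ndof)).tocsr()


# ---------------------------------------------------------------------------
# constraints


def _basal_constraints(geom: LVGeometry, bc: BoundaryConditions):
    """Reduction operator C (ndof x nred) for the basal plane conditions.

    Basal nodes keep only their radial dof (longitudinal and circumferential
    fixed); all other nodes keep all three dofs.
    """
    ndof = 3 * geom.n_nodes
    zmax = geom.nodes[:, 2].max()
    basal = np.nonzero(np.abs(geom.nodes[:, 2] - zmax) < 1e-9)[0]
    basal_set = set(basal.tolist())
    rows, cols, vals = [], [], []
    col = 0
    for nd in range(geom.n_nodes):
        if nd in basal_set and (bc.fix_base_longitudinal or bc.fix_base_circumferential):
            x, y = geom.nodes[nd, 0], geom.nodes[nd, 1]
            r = np.hypot(x, y)
            e_r = np.array([x / r, y / r, 0.0])
            e_c = np.array([-y / r, x / r, 0.0])
            dirs = [e_r]
            if not bc.fix_base_circumferential:
                dirs.append(e_c)
            if not bc.fix_base_longitudinal:
                dirs.append(np.array([0.0, 0.0, 1.0]))
            for d in dirs:
                for i in range(3):
                    if d[i] != 0.0:
                        rows.append(3 * nd + i)
                        cols.append(col)
                        vals.append(d[i])
                col += 1
        else:
            for i in range(3):
                rows.append(3 * nd + i)
                cols.append(col)
                vals.append(1.0)
                col += 1
    C = sp.coo_matrix((vals, (rows, cols)), shape=(ndof, col)).tocsr()
    return C


# ---------------------------------------------------------------------------
# Newton driver


def _newton(asm, C, passive, pressure_of_k, act_of_k, solver, u_start=None,
            u_anchor=None):
    """Adaptive incremental-load Newton solve over a continuation parameter
    k in (0, 1].

    ``pressure_of_k(k)`` gives the cavity pressure (kPa) and ``act_of_k(k)``
    the tension law (or None) at load level k.  A warm start ``u_start`` is
    tried directly at full load; on failure the solver falls back to load
    continuation from ``u_anchor`` (the displacement consistent with k = 0;
    zero by default).  The load increment is halved on Newton failure and
    re-grown on success; within each Newton iteration the update is capped
    in the max-norm (trust region) and backtracked on the residual norm.
    Returns the state at k = 1.
    """
    zeros = np.zeros((asm.ndof // 3, 3))
    u = zeros if u_start is None else u_start.copy()
    n_newton = 0

    def residual(u_val, k):
        fint, F, lam, T = asm.internal_force(u_val, passive, act_of_k(k))
        fext = asm.follower_force(u_val, pressure_of_k(k))
        r = C.T @ (fint - fext).ravel()
        ref = max(float(np.linalg.norm(C.T @ fext.ravel())), 1e-8)
        return r, ref, F, lam, T

    def try_solve_at(k, u_in, n_newton, max_iter=None):
        """Newton at fixed load level; returns (u, rnorm, ref, F, lam, T) or
        raises SolverError/ValueError."""
        u_loc = u_in.copy()
        r, ref, F, lam, T = residual(u_loc, k)
        rnorm = float(np.linalg.norm(r))
        rnorm0 = rnorm
        n_tiny_alpha = 0
        it = 0
        for it in range(max_iter or solver.max_newton_iter):
            if rnorm > 20.0 * rnorm0 + 1e3 * ref:
                raise SolverError("Newton divergence", residual=rnorm)
            if rnorm <= solver.newton_tol * ref:
                return u_loc, rnorm, ref, F, lam, T, n_newton
            K = asm.internal_tangent(u_loc, passive, act_of_k(k), solver.fd_step)
            K = K - asm.follower_tangent(u_loc, pressure_of_k(k), solver.fd_step)
            Kr = (C.T @ K @ C).tocsc()
            dq = spla.spsolve(Kr, r)
            if not np.all(np.isfinite(dq)):
                raise SolverError("singular tangent", residual=rnorm)
            # trust region: cap the nodal update
            du = (C @ dq).reshape(-1, 3)
            dmax = float(np.abs(du).max())
            alpha0 = min(1.0, solver.max_increment_mm / max(dmax, 1e-30))
            alpha = alpha0
            accepted = False
            for _ in range(solver.max_line_search):
                try:
                    u_try = u_loc - alpha * du
                    r_try, ref, F, lam, T = residual(u_try, k)
                except (ValueError, FloatingPointError):
                    alpha *= 0.5
                    continue
                if np.linalg.norm(r_try) < rnorm * (1.0 - 1e-4 * alpha) or alpha < 1e-3:
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                raise SolverError("line search failed", residual=rnorm)
            # stagnation guard: repeated deep backtracking (beyond the trust
            # region cap) means the load increment is too ambitious — fail
            # fast so it gets halved
            n_tiny_alpha = n_tiny_alpha + 1 if alpha < 0.05 * alpha0 else 0
            if n_tiny_alpha >= 3:
                raise SolverError("line search stagnation", residual=rnorm)
            u_loc, r = u_try, r_try
            rnorm = float(np.linalg.norm(r))
            n_newton += 1
        if rnorm <= solver.newton_tol * ref:
            return u_loc, rnorm, ref, F, lam, T, n_newton
        raise SolverError("Newton iteration limit", residual=rnorm)

    if u_start is not None:
        # warm start: try the full load directly (fast path for repeated
        # solves at nearby parameters inside the inverse loops)
        try:
            u_new, rnorm, ref, F, lam, T, n_newton = try_solve_at(
                1.0, u, n_newton, max_iter=min(25, solver.max_newton_iter)
            )
            return u_new, rnorm, ref, F, lam, T, n_newton
        except (SolverError, ValueError, FloatingPointError):
            # fall back to continuation from the k = 0 consistent state
            u = zeros if u_anchor is None else u_anchor.copy()

    k_done = 0.0
    dk = 1.0 / solver.n_load_steps
    dk_min = dk / 64.0
    state = None
    while k_done < 1.0 - 1e-12:
        k_try = min(1.0, k_done + dk)
        n_before = n_newton
        try:
            u_new, rnorm, ref, F, lam, T, n_newton = try_solve_at(k_try, u, n_newton)
        except (SolverError, ValueError, FloatingPointError) as exc:
            dk *= 0.5
            if dk < dk_min:
                raise SolverError(
                    f"load continuation failed near k = {k_try:.4f}: {exc}",
                    residual=getattr(exc, "residual", None), step=k_try,
                ) from None
            continue
        u = u_new
        k_done = k_try
        state = (rnorm, ref, F, lam, T)
        # grow the increment according to how hard this level was
        its = n_newton - n_before
        if its <= 6:
            dk = min(dk * 2.0, 0.4)
        elif its <= 12:
            dk = min(dk * 1.5, 0.4)
        elif its <= 20:
            dk = min(dk * 1.1, 0.4)
    rnorm, ref, F, lam, T = state
    return u, rnorm, ref, F, lam, T, n_newton


def solve_passive_inflation(
    geom: LVGeometry,
    passive: PassiveParams,
    edp_mmhg: float,
    solver: SolverConfig | None = None,
    initial_state: EquilibriumState | None = None,
) -> EquilibriumState:
    """Inflate the passive ventricle to the end-diastolic pressure.

    Pressure is a follower traction on the endocardium; basal boundary
    conditions fix longitudinal and circumferential motion of the base.
    ``initial_state`` warm-starts the Newton solve (nearby parameters in an
    inverse loop).  Returns the converged ED equilibrium with its cavity
    volume.
    """
    solver = solver or SolverConfig()
    bc = BoundaryConditions(pressure_mmhg=edp_mmhg)
    asm = _Assembler(geom)
    C = _basal_constraints(geom, bc)
    if edp_mmhg == 0.0:
        E, Q = geom.qp_wdetJ.shape
        return EquilibriumState(
            displacement=np.zeros_like(geom.nodes), converged=True, residual_norm=0.0,
            cavity_volume_ml=cavity_volume(geom),
            F=np.broadcast_to(np.eye(3), (E, Q, 3, 3)).copy(),
            lambda_f=np.ones((E, Q)), active_tension=np.zeros((E, Q)),
            pressure_mmhg=0.0,
        )
    p_kpa = edp_mmhg * MMHG_TO_KPA
    u, rnorm, ref, F, lam, T, n_newton = _newton(
        asm, C, passive, lambda k: k * p_kpa, lambda k: None, solver,
        u_start=None if initial_state is None else initial_state.displacement,
    )
    return EquilibriumState(
        displacement=u, converged=True, residual_norm=rnorm / ref,
        cavity_volume_ml=cavity_volume(geom, u), F=F, lambda_f=lam,
        active_tension=T, pressure_mmhg=edp_mmhg, n_newton_total=n_newton,
    )


def solve_end_systole(
    geom: LVGeometry,
    passive: PassiveParams,
    active: ActiveParams,
    sbp_mmhg: float,
    solver: SolverConfig | None = None,
    ed_state: EquilibriumState | None = None,
    warm_state: EquilibriumState | None = None,
) -> EquilibriumState:
    """End-systolic equilibrium under systolic pressure and full activation.

    The quasi-static end-systolic tension law T = T_req (1 + beta_0
    (lambda_f - 1)) acts along the current fiber direction, scaled by
    (1 - phi) so the infarct core stays purely passive.  Activation and the
    ED -> SBP pressure ramp are applied together over the load steps; the
    ED state (if given) anchors the ramp and provides the initial guess.
    ``warm_state`` (e.g. the previous end-systolic solution in an inverse
    loop) overrides the initial guess only.
    """
    solver = solver or SolverConfig()
    asm = _Assembler(geom)
    C = _basal_constraints(geom, BoundaryConditions(pressure_mmhg=sbp_mmhg))
    p_kpa = sbp_mmhg * MMHG_TO_KPA
    u_anchor = None if ed_state is None else ed_state.displacement
    u_start = u_anchor if warm_state is None else warm_state.displacement

    def act_of(k):
        if k == 0.0:
            return None

        def law(lam, _k=k):
            return _k * end_systolic_tension(lam, active)

        return law

    # ramp pressure from the ED value (the initial-guess equilibrium) to the
    # systolic pressure while activation rises 0 -> 1 along the same path
    p0 = ed_state.pressure_mmhg * MMHG_TO_KPA if ed_state is not None else 0.0

    def pressure_of(k):
        return p0 + k * (p_kpa - p0)

    u, rnorm, ref, F, lam, T, n_newton = _newton(
        asm, C, passive, pressure_of, act_of, solver, u_start=u_start,
        u_anchor=u_anchor,
    )
    return EquilibriumState(
        displacement=u, converged=True, residual_norm=rnorm / ref,
        cavity_volume_ml=cavity_volume(geom, u), F=F, lambda_f=lam,
        active_tension=T, pressure_mmhg=sbp_mmhg, n_newton_total=n_newton,
    )


def solve_dirichlet(
    geom: LVGeometry,
    passive: PassiveParams,
    boundary_nodes: np.ndarray,
    boundary_disp: np.ndarray,
    solver: SolverConfig | None = None,
    active: ActiveParams | None = None,
) -> EquilibriumState:
    """Equilibrium under prescribed displacements on ``boundary_nodes``.

    Verification entry point (homogeneous-deformation patch tests): interior
    nodes are solved for, boundary displacements are ramped over the load
    steps.  No pressure load.
    """
    solver = solver or SolverConfig()
    asm = _Assembler(geom)
    ndof = asm.ndof
    fixed = np.zeros(ndof, dtype=bool)
    for i in range(3):
        fixed[3 * boundary_nodes + i] = True
    free = np.nonzero(~fixed)[0]
    C = sp.coo_matrix(
        (np.ones(len(free)), (free, np.arange(len(free)))), shape=(ndof, len(free))
    ).tocsr()

    act = None
    if active is not None:
        def act(lam):
            return end_systolic_tension(lam, active)

    u = np.zeros_like(geom.nodes)
    n_newton = 0
    rnorm, ref = 0.0, 1.0
    F = lam = T = None
    for k in np.linspace(1.0 / solver.n_load_steps, 1.0, solver.n_load_steps):
        u[boundary_nodes] = k * boundary_disp
        for it in range(solver.max_newton_iter + 1):
            fint, F, lam, T = asm.internal_force(u, passive, act)
            r = C.T @ fint.ravel()
            rnorm = float(np.linalg.norm(r))
            ref = max(float(np.linalg.norm(fint.ravel())), 1e-8)
            if rnorm <= solver.newton_tol * ref:
                break
            if it == solver.max_newton_iter:
                raise SolverError("Dirichlet Newton did not converge", residual=rnorm)
            K = asm.internal_tangent(u, passive, act, solver.fd_step)
            Kr = (C.T @ K @ C).tocsc()
            dq = spla.spsolve(Kr, r)
            u = u - (C @ dq).reshape(-1, 3)
            n_newton += 1
    vol = cavity_volume(geom, u) if "endo" in geom.faces else 0.0
    return EquilibriumState(
        displacement=u, converged=True, residual_norm=rnorm / ref,
        cavity_volume_ml=vol, F=F, lambda_f=lam,
        active_tension=T if T is not None else np.zeros_like(lam),
        pressure_mmhg=0.0, n_newton_total=n_newton,
    )


# ---------------------------------------------------------------------------
# strain extraction


def regional_circumferential_strain(
    state: EquilibriumState,
    geom: LVGeometry,
    reference_state: EquilibriumState | None = None,
) -> np.ndarray:
    """Per-segment mean engineering circumferential strain.

    Fractional length change of circumferential material line elements
    relative to the reference state (identity if None); negative values
    mean shortening.  Mass-weighted mean over each segment's quadrature
    points.
    """
    c0 = geom.local_basis[..., 0, :]
    lam_cur = np.linalg.norm(np.einsum("eqij,eqj->eqi", state.F, c0), axis=-1)
    if reference_state is not None:
        lam_ref = np.linalg.norm(
            np.einsum("eqij,eqj->eqi", reference_state.F, c0), axis=-1
        )
    else:
        lam_ref = 1.0
    eps = lam_cur / lam_ref - 1.0
    w = geom.qp_wdetJ
    num = np.zeros(geom.n_segments)
    den = np.zeros(geom.n_segments)
    np.add.at(num, geom.segment_id, np.sum(w * eps, axis=1))
    np.add.at(den, geom.segment_id, np.sum(w, axis=1))
    return num / den


def global_longitudinal_strain(
    state: EquilibriumState,
    geom: LVGeometry,
    reference_state: EquilibriumState | None = None,
    n_lines: int = 6,
) -> float:
    """Global longitudinal strain (%, negative = shortening).

    Mean fractional length change of mid-wall base-to-apex polylines at
    ``n_lines`` evenly spaced circumferential positions (three long-axis
    planes, two wall lines each), relative to the reference state.
    """
    c = geom.config
    nc, nl, nt = c.n_circ, c.n_long, c.n_trans

    def nid(it_, il_, ic_):
        return (it_ * (nl + 1) + il_) * nc + (ic_ % nc)

    it_mid = nt // 2
    x_ref = geom.nodes + (reference_state.displacement if reference_state is not None else 0.0)
    x_cur = geom.nodes + state.displacement
    ratios = []
    for ic in np.linspace(0, nc, n_lines, endpoint=False).astype(int):
        ids = nid(it_mid, np.arange(nl + 1), ic)
        L_ref = np.linalg.norm(np.diff(x_ref[ids], axis=0), axis=1).sum()
        L_cur = np.linalg.norm(np.diff(x_cur[ids], axis=0), axis=1).sum()
        ratios.append(L_cur / L_ref - 1.0)
    return float(np.mean(ratios) * 100.0)
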