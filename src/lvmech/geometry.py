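"""Idealized left-ventricular geometry, fibers, segments and infarct fields.

The ventricle is a truncated prolate ellipsoid: endocardial and epicardial
ellipsoidal surfaces sharing a center on the long axis, cut by a flat basal
plane and opened by a small apical truncation that keeps all hexahedra
well-shaped.  Coordinates are millimetres; the long axis is z, the base sits
at z = 0 and the apex points toward negative z; the circumferential
direction is right-handed about +z.

The mesh is a structured hexahedral shell (circumferential x longitudinal x
transmural).  Circumferential node radii carry an equal-area correction so
that the polygonal cross-section preserves the elliptical cross-sectional
area, which keeps discrete cavity volumes close to the smooth geometry even
on coarse meshes.

Myofiber architecture follows the standard rule-based description: the
helix angle varies linearly across the wall between prescribed endocardial
and epicardial angles; the sheet axis is transmural.  Infarcts are defined
by an angular core region with full transition to viable tissue over a
finite width (default 10 mm), encoded as a pointwise infarct fraction
phi in [0, 1] (1 = scar core, 0 = viable myocardium).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import _fem

__all__ = [
    "GeometryConfig",
    "InfarctSpec",
    "FiberField",
    "LVGeometry",
    "build_ellipsoid_mesh",
    "assign_fibers",
    "define_infarct",
    "calibrate_infarct_extent",
    "segment_regions",
    "remote_segments",
    "infarct_mass_fraction",
    "cavity_volume",
    "build_box_mesh",
    "analytic_cavity_volume",
]

#: Segments whose mass-weighted mean infarct fraction is below this value
#: count as remote (viable) myocardium for the inverse problem.
REMOTE_PHI_THRESHOLD = 0.05


@dataclass(frozen=True)
class GeometryConfig:
    """Dimensions and discretization of the idealized ventricle.

    Lengths in mm.  The defaults are calibrated so that a healthy-control
    forward model (default passive parameters, 8 mmHg end-diastolic
    pressure) lands near the population end-diastolic volume of ~121 mL.
    """

    r_short_endo_mm: float = 23.7
    r_long_endo_mm: float = 60.0
    wall_thickness_mm: float = 8.7
    apex_thickness_mm: float = 4.8
    base_height_mm: float = 5.8
    apex_opening_rad: float = 0.25
    n_circ: int = 12
    n_long: int = 8
    n_trans: int = 2
    fiber_angle_endo_deg: float = 60.0
    fiber_angle_epi_deg: float = -60.0
    n_sectors: int = 6
    n_slices: int = 3

    def __post_init__(self) -> None:
        for name in ("r_short_endo_mm", "r_long_endo_mm", "wall_thickness_mm",
                     "apex_thickness_mm", "base_height_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.wall_thickness_mm >= self.r_short_endo_mm:
            raise ValueError(
                f"degenerate geometry: wall thickness {self.wall_thickness_mm} mm "
                f">= endocardial short semi-axis {self.r_short_endo_mm} mm"
            )
        if self.base_height_mm >= self.r_long_endo_mm:
            raise ValueError("basal truncation height must be below the long semi-axis")
        if self.n_circ < 4 or self.n_long < 4 or self.n_trans < 2:
            raise ValueError("mesh resolution must be at least 4 x 4 x 2")
        if self.n_sectors < 4:
            raise ValueError("need at least 4 circumferential sectors")
        if self.n_slices < 2:
            raise ValueError("need at least 2 longitudinal slices")
        if not 0 < self.apex_opening_rad < 1.0:
            raise ValueError("apex opening must lie in (0, 1) rad")

    def scaled(self, s: float) -> "GeometryConfig":
        """Uniformly scale all linear dimensions by ``s`` (subject size)."""
        return replace(
            self,
            r_short_endo_mm=self.r_short_endo_mm * s,
            r_long_endo_mm=self.r_long_endo_mm * s,
            wall_thickness_mm=self.wall_thickness_mm * s,
            apex_thickness_mm=self.apex_thickness_mm * s,
            base_height_mm=self.base_height_mm * s,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class InfarctSpec:
    """Infarct core region in prolate angular coordinates.

    theta/phi are the polar angle from the basal (+z) direction of the
    ellipsoid and the circumferential angle; extents are full angular widths
    of the core.  ``transmurality`` is the endocardium-to-epicardium depth
    fraction of the core; ``transition_mm`` the width of the linear ramp
    from scar (phi = 1) to viable tissue (phi = 0), default 10 mm.
    """

    center_theta_rad: float = 1.85
    center_phi_rad: float = np.pi
    extent_theta_rad: float = 0.8
    extent_phi_rad: float = 4.19
    transmurality: float = 1.0
    transition_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.extent_theta_rad < 0 or self.extent_phi_rad < 0:
            raise ValueError("angular extents must be >= 0")
        if not 0.0 < self.transmurality <= 1.0:
            raise ValueError("transmurality must lie in (0, 1]")
        if self.transition_mm < 0:
            raise ValueError("transition width must be >= 0")

    def scaled_extents(self, s: float) -> "InfarctSpec":
        return replace(
            self,
            extent_theta_rad=self.extent_theta_rad * s,
            extent_phi_rad=self.extent_phi_rad * s,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FiberField:
    """Unit fiber (f0) and sheet (s0) directions per quadrature point."""

    f0: np.ndarray  # (E, Q, 3)
    s0: np.ndarray  # (E, Q, 3)


@dataclass
class LVGeometry:
    """Hexahedral ventricle mesh with per-quadrature-point fields.

    ``faces`` maps surface tags ('endo', 'epi', 'base', 'apex') to arrays of
    quad connectivity; every boundary facet carries exactly one tag.
    ``phi`` is the infarct fraction field (E, Q), zero for healthy tissue.
    """

    config: GeometryConfig | None
    nodes: np.ndarray            # (n, 3) mm
    elems: np.ndarray            # (E, 8)
    faces: dict
    qp_G: np.ndarray             # (E, Q, 8, 3) shape gradients wrt X
    qp_wdetJ: np.ndarray         # (E, Q)
    qp_X: np.ndarray             # (E, Q, 3)
    local_basis: np.ndarray      # (E, Q, 3, 3) rows: circumferential, longitudinal, transmural
    qp_mu: np.ndarray            # (E, Q) transmural coordinate, 0 = endo
    qp_theta: np.ndarray         # (E, Q) polar angle of the parameterization
    qp_phi_ang: np.ndarray       # (E, Q) circumferential angle
    fibers: FiberField | None = None
    phi: np.ndarray = None       # (E, Q) infarct fraction
    infarct: InfarctSpec | None = None
    segment_id: np.ndarray = None  # (E,)
    n_segments: int = 0
    elem_grid: np.ndarray = None   # (E, 3) (ic, il, it) structured indices

    def __post_init__(self) -> None:
        if self.phi is None:
            self.phi = np.zeros(self.qp_wdetJ.shape)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def wall_volume_ml(self) -> float:
        return float(self.qp_wdetJ.sum()) / 1000.0


# ---------------------------------------------------------------------------
# mesh construction


def _area_correction(n_circ: int) -> float:
    # radius factor making the inscribed n-gon preserve the circle's area
    return float(np.sqrt(2.0 * np.pi / (n_circ * np.sin(2.0 * np.pi / n_circ))))


def _surface_point(rs, rl, hb, theta, ph):
    """Point on an ellipsoidal surface, center (0,0,-hb)."""
    st, ct = np.sin(theta), np.cos(theta)
    x = rs * st * np.cos(ph)
    y = rs * st * np.sin(ph)
    z = np.broadcast_to(-hb + rl * ct, x.shape)
    return np.stack([x, y, z], axis=-1)


def build_ellipsoid_mesh(config: GeometryConfig) -> LVGeometry:
    """Structured hexahedral mesh of the truncated-ellipsoid ventricle.

    Element count equals n_circ * n_long * n_trans; surface facets are
    tagged endo / epi / base / apex; all element Jacobians are checked
    positive.  Fibers are assigned with the configured helix angles and the
    default segmentation is applied.
    """
    c = config
    corr = _area_correction(c.n_circ)
    rs_en = c.r_short_endo_mm * corr
    rl_en = c.r_long_endo_mm
    rs_ep = (c.r_short_endo_mm + c.wall_thickness_mm) * corr
    rl_ep = c.r_long_endo_mm + c.apex_thickness_mm
    hb = c.base_height_mm

    th_base_en = np.arccos(np.clip(hb / rl_en, -1, 1))
    th_base_ep = np.arccos(np.clip(hb / rl_ep, -1, 1))
    th_apex = np.pi - c.apex_opening_rad

    nc, nl, nt = c.n_circ, c.n_long, c.n_trans
    ic = np.arange(nc)
    il = np.arange(nl + 1)
    it = np.arange(nt + 1)
    ph = 2.0 * np.pi * ic / nc
    v = il / nl
    mu = it / nt

    # node grid indexed [it, il, ic]
    PH = ph[None, None, :]
    V = v[None, :, None]
    MU = mu[:, None, None]
    th_en = th_base_en + V * (th_apex - th_base_en)
    th_ep = th_base_ep + V * (th_apex - th_base_ep)
    p_en = _surface_point(rs_en, rl_en, hb, th_en, PH)
    p_ep = _surface_point(rs_ep, rl_ep, hb, th_ep, PH)
    pts = (1.0 - MU[..., None]) * p_en + MU[..., None] * p_ep   # (nt+1, nl+1, nc, 3)
    nodes = pts.reshape(-1, 3)

    def nid(it_, il_, ic_):
        return (it_ * (nl + 1) + il_) * nc + (ic_ % nc)

    IC, IL, IT = np.meshgrid(np.arange(nc), np.arange(nl), np.arange(nt), indexing="ij")
    ic_f, il_f, it_f = IC.ravel(), IL.ravel(), IT.ravel()
    elems = np.stack(
        [
            nid(it_f, il_f, ic_f),
            nid(it_f, il_f + 1, ic_f),
            nid(it_f, il_f + 1, ic_f + 1),
            nid(it_f, il_f, ic_f + 1),
            nid(it_f + 1, il_f, ic_f),
            nid(it_f + 1, il_f + 1, ic_f),
            nid(it_f + 1, il_f + 1, ic_f + 1),
            nid(it_f + 1, il_f, ic_f + 1),
        ],
        axis=1,
    )
    elem_grid = np.stack([ic_f, il_f, it_f], axis=1)

    # surface quads (ordered counterclockwise seen from outside the solid)
    ICq, ILq = np.meshgrid(np.arange(nc), np.arange(nl), indexing="ij")
    icq, ilq = ICq.ravel(), ILq.ravel()
    endo = np.stack(
        [nid(0, ilq, icq), nid(0, ilq + 1, icq), nid(0, ilq + 1, icq + 1), nid(0, ilq, icq + 1)],
        axis=1,
    )
    epi = np.stack(
        [nid(nt, ilq, icq), nid(nt, ilq, icq + 1), nid(nt, ilq + 1, icq + 1), nid(nt, ilq + 1, icq)],
        axis=1,
    )
    ICb, ITb = np.meshgrid(np.arange(nc), np.arange(nt), indexing="ij")
    icb, itb = ICb.ravel(), ITb.ravel()
    base = np.stack(
        [nid(itb, 0, icb), nid(itb, 0, icb + 1), nid(itb + 1, 0, icb + 1), nid(itb + 1, 0, icb)],
        axis=1,
    )
    apex = np.stack(
        [nid(itb, nl, icb), nid(itb + 1, nl, icb), nid(itb + 1, nl, icb + 1), nid(itb, nl, icb + 1)],
        axis=1,
    )
    faces = {"endo": endo, "epi": epi, "base": base, "apex": apex}

    G, wdetJ, Xqp, J = _fem.element_qp_geometry(nodes, elems)

    # local orthonormal basis at quadrature points from the isoparametric map:
    # column 0 of J ~ longitudinal (toward apex), column 1 ~ circumferential,
    # column 2 ~ transmural (endo -> epi)
    e_c = J[..., :, 1]
    e_l = -J[..., :, 0]   # point from apex toward base
    c_hat = e_c / np.linalg.norm(e_c, axis=-1, keepdims=True)
    e_l = e_l - np.einsum("eqi,eqi->eq", e_l, c_hat)[..., None] * c_hat
    l_hat = e_l / np.linalg.norm(e_l, axis=-1, keepdims=True)
    t_hat = np.cross(c_hat, l_hat)
    local_basis = np.stack([c_hat, l_hat, t_hat], axis=-2)

    # parametric coordinates of the quadrature points
    xi = _fem.HEX_QP  # (Q, 3): (long, circ, trans)
    mu_qp = (it_f[:, None] + (xi[None, :, 2] + 1.0) / 2.0) / nt
    v_qp = (il_f[:, None] + (xi[None, :, 0] + 1.0) / 2.0) / nl
    theta_qp = th_base_en + v_qp * (th_apex - th_base_en)
    phi_qp = np.arctan2(Xqp[..., 1], Xqp[..., 0])

    geom = LVGeometry(
        config=c,
        nodes=nodes,
        elems=elems,
        faces=faces,
        qp_G=G,
        qp_wdetJ=wdetJ,
        qp_X=Xqp,
        local_basis=local_basis,
        qp_mu=mu_qp,
        qp_theta=theta_qp,
        qp_phi_ang=phi_qp,
        elem_grid=elem_grid,
    )
    geom.fibers = assign_fibers(geom, c.fiber_angle_endo_deg, c.fiber_angle_epi_deg)
    segment_regions(geom, c.n_sectors, c.n_slices)
    return geom


def assign_fibers(geom: LVGeometry, angle_endo: float, angle_epi: float) -> FiberField:
    """Rule-based myofiber architecture.

    The helix angle varies linearly with the transmural coordinate from
    ``angle_endo`` (degrees, at the endocardium) to ``angle_epi`` (at the
    epicardium); f0 lies in the wall-tangent plane, s0 is the transmural
    sheet axis, orthonormal to f0 by construction.
    """
    a_en = np.deg2rad(angle_endo)
    a_ep = np.deg2rad(angle_epi)
    alpha = a_en + (a_ep - a_en) * geom.qp_mu
    c_hat = geom.local_basis[..., 0, :]
    l_hat = geom.local_basis[..., 1, :]
    t_hat = geom.local_basis[..., 2, :]
    f0 = np.cos(alpha)[..., None] * c_hat + np.sin(alpha)[..., None] * l_hat
    s0 = t_hat
    geom.fibers = FiberField(f0=f0, s0=s0)
    return geom.fibers


# ---------------------------------------------------------------------------
# infarct field


def _wrap_angle(d):
    return np.abs((np.asarray(d) + np.pi) % (2.0 * np.pi) - np.pi)


def _infarct_distance(geom: LVGeometry, spec: InfarctSpec) -> np.ndarray:
    """Arc-length distance (mm) from each quadrature point to the infarct
    core, measured in the reference configuration.

    Angular offsets beyond the core extents are converted to arc lengths
    with the local mid-wall radii; transmural excess depth is scaled by the
    wall thickness.  This is the Euclidean distance up to the metric of the
    curved mid-wall surface.
    """
    c = geom.config
    rs_m = c.r_short_endo_mm + 0.5 * c.wall_thickness_mm
    rl_m = c.r_long_endo_mm + 0.5 * c.apex_thickness_mm
    th = geom.qp_theta
    dth = np.maximum(np.abs(th - spec.center_theta_rad) - 0.5 * spec.extent_theta_rad, 0.0)
    # meridional arc length per radian at the local polar angle
    r_mer = np.sqrt((rs_m * np.cos(th)) ** 2 + (rl_m * np.sin(th)) ** 2)
    d_long = dth * r_mer
    dph = np.maximum(
        _wrap_angle(geom.qp_phi_ang - spec.center_phi_rad) - 0.5 * spec.extent_phi_rad, 0.0
    )
    d_circ = dph * rs_m * np.sin(th)
    d_trans = np.maximum(geom.qp_mu - spec.transmurality, 0.0) * c.wall_thickness_mm
    return np.sqrt(d_long**2 + d_circ**2 + d_trans**2)


def define_infarct(geom: LVGeometry, spec: InfarctSpec) -> LVGeometry:
    """Set the infarct fraction field phi on the geometry.

    phi = 1 inside the angular core, falls linearly to 0 over the
    transition width, and is 0 at and beyond that distance from the core.
    A zero-extent spec yields phi = 0 everywhere with a warning.
    """
    if spec.extent_theta_rad == 0.0 or spec.extent_phi_rad == 0.0:
        warnings.warn("empty infarct spec: phi set to zero everywhere", stacklevel=2)
        geom.phi = np.zeros_like(geom.qp_wdetJ)
        geom.infarct = spec
        return geom
    d = _infarct_distance(geom, spec)
    if spec.transition_mm == 0.0:
        phi = (d == 0.0).astype(float)
    else:
        phi = np.clip(1.0 - d / spec.transition_mm, 0.0, 1.0)
    geom.phi = phi
    geom.infarct = spec
    return geom


def infarct_mass_fraction(geom: LVGeometry) -> float:
    """Infarcted fraction of LV mass: mass-weighted mean of phi."""
    w = geom.qp_wdetJ
    return float(np.sum(w * geom.phi) / np.sum(w))


def calibrate_infarct_extent(
    geom: LVGeometry,
    spec: InfarctSpec,
    target_mass_fraction: float,
    tol: float = 0.002,
    max_iter: int = 60,
) -> InfarctSpec:
    """Bisection on a common angular-extent scale so that the infarct mass
    fraction matches ``target_mass_fraction`` within ``tol``.

    Returns the calibrated spec (the geometry is left with the calibrated
    field applied).
    """

    def mass(s):
        define_infarct(geom, spec.scaled_extents(s))
        return infarct_mass_fraction(geom)

    lo, hi = 1e-3, 1.0
    # grow hi until the target is bracketed (extents are capped by geometry)
    while mass(hi) < target_mass_fraction and hi < 8.0:
        hi *= 1.4
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m = mass(mid)
        if abs(m - target_mass_fraction) < tol:
            break
        if m < target_mass_fraction:
            lo = mid
        else:
            hi = mid
    else:
        mid = 0.5 * (lo + hi)
    out = spec.scaled_extents(mid)
    define_infarct(geom, out)
    return out


# ---------------------------------------------------------------------------
# segmentation


def segment_regions(geom: LVGeometry, sectors: int, slices: int) -> LVGeometry:
    """Label every element by an (slice, sector) segment.

    Slices partition the longitudinal element index from base to apex,
    sectors partition the circumferential angle; total segment count
    N = sectors * slices.  Segment id = slice * sectors + sector.
    """
    if sectors < 4:
        raise ValueError("need at least 4 sectors")
    if slices < 2:
        raise ValueError("need at least 2 slices")
    c = geom.config
    il = geom.elem_grid[:, 1]
    slice_id = np.minimum(il * slices // c.n_long, slices - 1)
    # sector from the element-centroid circumferential angle
    cent = geom.qp_X.mean(axis=1)
    ang = np.mod(np.arctan2(cent[:, 1], cent[:, 0]), 2.0 * np.pi)
    sector_id = np.minimum((ang / (2.0 * np.pi / sectors)).astype(int), sectors - 1)
    geom.segment_id = slice_id * sectors + sector_id
    geom.n_segments = sectors * slices
    return geom


def remote_segments(geom: LVGeometry, threshold: float = REMOTE_PHI_THRESHOLD) -> np.ndarray:
    """Ids of segments whose mass-weighted mean infarct fraction is below
    ``threshold`` — the viable segments entering the inverse objective."""
    w = geom.qp_wdetJ
    num = np.zeros(geom.n_segments)
    den = np.zeros(geom.n_segments)
    np.add.at(num, geom.segment_id, np.sum(w * geom.phi, axis=1))
    np.add.at(den, geom.segment_id, np.sum(w, axis=1))
    mean_phi = num / np.maximum(den, 1e-30)
    return np.nonzero(mean_phi < threshold)[0]


# ---------------------------------------------------------------------------
# cavity volume


def _cavity_triangles(geom: LVGeometry) -> np.ndarray:
    """Triangulation (T, 3 node-or-virtual ids) of the closed cavity surface:
    endocardium plus basal and apical cap fans.  Virtual ids >= n_nodes refer
    to the two cap centroids (computed from current positions)."""
    endo = geom.faces["endo"]
    tris = np.concatenate([endo[:, [0, 1, 2]], endo[:, [0, 2, 3]]], axis=0)
    c = geom.config
    nc, nl = c.n_circ, c.n_long

    def nid(it_, il_, ic_):
        return (it_ * (nl + 1) + il_) * nc + (ic_ % nc)

    icr = np.arange(nc)
    base_ring = nid(0, 0, icr)
    apex_ring = nid(0, nl, icr)
    n = geom.n_nodes
    base_c, apex_c = n, n + 1
    base_fan = np.stack([np.full(nc, base_c), base_ring, nid(0, 0, icr + 1)], axis=1)
    apex_fan = np.stack([np.full(nc, apex_c), nid(0, nl, icr + 1), apex_ring], axis=1)
    return np.concatenate([tris, base_fan, apex_fan], axis=0), base_ring, apex_ring


def cavity_volume(geom: LVGeometry, displacement: np.ndarray | None = None) -> float:
    """Cavity volume (mL) enclosed by the (displaced) endocardial surface
    and the basal/apical cap planes, by the divergence theorem.

    The closed surface is triangulated and the signed tetrahedron volumes
    summed; the result is invariant under rigid-body motion of the mesh.
    Raises if the surface is inverted (non-positive volume or flipped
    normals relative to the reference configuration).
    """
    if "endo" not in geom.faces:
        raise ValueError("geometry has no endocardial surface")
    x = geom.nodes if displacement is None else geom.nodes + displacement
    tris, base_ring, apex_ring = _cavity_triangles(geom)
    verts = np.concatenate(
        [x, x[base_ring].mean(axis=0)[None], x[apex_ring].mean(axis=0)[None]], axis=0
    )
    p = verts[tris]  # (T, 3, 3)
    signed = np.einsum("ti,ti->t", p[:, 0], np.cross(p[:, 1], p[:, 2])) / 6.0
    vol = float(signed.sum())
    sign = -1.0 if vol < 0 else 1.0
    vol *= sign
    if vol <= 0:
        raise ValueError("inverted endocardial surface: non-positive cavity volume")
    if displacement is not None:
        ref = _reference_signed_orientation(geom)
        if sign != ref:
            raise ValueError("endocardial surface orientation flipped relative to reference")
    return vol / 1000.0  # mm^3 -> mL


def _reference_signed_orientation(geom: LVGeometry) -> float:
    tris, base_ring, apex_ring = _cavity_triangles(geom)
    x = geom.nodes
    verts = np.concatenate(
        [x, x[base_ring].mean(axis=0)[None], x[apex_ring].mean(axis=0)[None]], axis=0
    )
    p = verts[tris]
    s = float(np.einsum("ti,ti->t", p[:, 0], np.cross(p[:, 1], p[:, 2])).sum())
    return -1.0 if s < 0 else 1.0


def analytic_cavity_volume(config: GeometryConfig) -> float:
    """Closed-form cavity volume (mL) of the smooth truncated ellipsoid with
    a flat apical cap at the mesh's apical ring plane — the solid of
    revolution the discrete cavity converges to.

    Evaluated as the exact antiderivative of pi * r(z)^2 between the apical
    ring plane and the base; used as the oracle for the discrete volume.
    """
    rs, rl, hb = config.r_short_endo_mm, config.r_long_endo_mm, config.base_height_mm
    z_apex = -hb + rl * np.cos(np.pi - config.apex_opening_rad)

    def antider(z):
        # integral of pi rs^2 (1 - (z + hb)^2 / rl^2) dz
        return np.pi * rs**2 * (z - (z + hb) ** 3 / (3.0 * rl**2))

    return float(antider(0.0) - antider(z_apex)) / 1000.0


def interpolate_displacement(coarse: LVGeometry, u: np.ndarray,
                             fine: LVGeometry) -> np.ndarray:
    """Transfer a nodal displacement field between two structured meshes of
    the same ventricle (trilinear interpolation on the parametric grid;
    periodic circumferentially).  Used to warm-start refined solves."""
    from scipy.ndimage import map_coordinates

    cc, cf = coarse.config, fine.config
    grid = u.reshape(cc.n_trans + 1, cc.n_long + 1, cc.n_circ, 3)
    it, il, ic = np.meshgrid(
        np.arange(cf.n_trans + 1) / cf.n_trans * cc.n_trans,
        np.arange(cf.n_long + 1) / cf.n_long * cc.n_long,
        np.arange(cf.n_circ) / cf.n_circ * cc.n_circ,
        indexing="ij",
    )
    coords = np.stack([it.ravel(), il.ravel(), ic.ravel()])
    out = np.empty((coords.shape[1], 3))
    for d in range(3):
        out[:, d] = map_coordinates(grid[..., d], coords, order=1,
                                    mode="grid-wrap")
    return out


# ---------------------------------------------------------------------------
# auxiliary meshes (verification problems)


def build_box_mesh(n: tuple = (3, 3, 3), lengths: tuple = (1.0, 1.0, 1.0),
                   f0=(1.0, 0.0, 0.0), s0=(0.0, 1.0, 0.0)) -> LVGeometry:
    """Rectangular block of myocardium with uniform fiber field.

    Used for homogeneous-deformation (patch) verification of the
    equilibrium solver; all boundary facets carry the single tag
    'boundary'.  Lengths in mm.
    """
    nx, ny, nz = n
    lx, ly, lz = lengths
    X, Y, Z = np.meshgrid(
        np.linspace(0, lx, nx + 1), np.linspace(0, ly, ny + 1), np.linspace(0, lz, nz + 1),
        indexing="ij",
    )
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    i, j, k = I.ravel(), J.ravel(), K.ravel()
    elems = np.stack(
        [
            nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
            nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
        ],
        axis=1,
    )
    G, wdetJ, Xqp, _ = _fem.element_qp_geometry(nodes, elems)
    E, Q = wdetJ.shape
    f0v = np.broadcast_to(np.asarray(f0, float), (E, Q, 3)).copy()
    s0v = np.broadcast_to(np.asarray(s0, float), (E, Q, 3)).copy()
    basis = np.broadcast_to(np.eye(3), (E, Q, 3, 3)).copy()
    geom = LVGeometry(
        config=None,
        nodes=nodes,
        elems=elems,
        faces={"boundary": np.zeros((0, 4), dtype=int)},
        qp_G=G,
        qp_wdetJ=wdetJ,
        qp_X=Xqp,
        local_basis=basis,
        qp_mu=np.zeros((E, Q)),
        qp_theta=np.zeros((E, Q)),
        qp_phi_ang=np.zeros((E, Q)),
        fibers=FiberField(f0=f0v, s0=s0v),
        segment_id=np.zeros(E, dtype=int),
        n_segments=1,
        elem_grid=np.stack([i, j, k], axis=1),
    )
    return geom
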