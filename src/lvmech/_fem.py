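"""Shared trilinear-hexahedron finite-element tables.

Reference element [-1, 1]^3 with the standard 8-node ordering; 2x2x2 Gauss
quadrature for cells and 2x2 for bilinear quad faces.  Geometry construction
and the equilibrium solver both consume these tables.
"""

from __future__ import annotations

import numpy as np

# node sign pattern (xi, eta, zeta) of the 8 corners, VTK hexahedron order
HEX_SIGNS = np.array(
    [
        [-1, -1, -1],
        [+1, -1, -1],
        [+1, +1, -1],
        [-1, +1, -1],
        [-1, -1, +1],
        [+1, -1, +1],
        [+1, +1, +1],
        [-1, +1, +1],
    ],
    dtype=float,
)

_G = 1.0 / np.sqrt(3.0)
# 8 Gauss points of the 2x2x2 rule (weight 1 each)
HEX_QP = HEX_SIGNS * _G
HEX_QW = np.ones(8)

QUAD_SIGNS = np.array([[-1, -1], [+1, -1], [+1, +1], [-1, +1]], dtype=float)
QUAD_QP = QUAD_SIGNS * _G
QUAD_QW = np.ones(4)


def hex_shape(xi: np.ndarray) -> np.ndarray:
    """Shape function values N_a at points xi (..., 3) -> (..., 8)."""
    xi = np.asarray(xi, dtype=float)
    return 0.125 * np.prod(1.0 + xi[..., None, :] * HEX_SIGNS, axis=-1)


def hex_dshape(xi: np.ndarray) -> np.ndarray:
    """Shape gradients dN_a/dxi at points xi (..., 3) -> (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    t = 1.0 + xi[..., None, :] * HEX_SIGNS  # (..., 8, 3)
    out = np.empty(t.shape)
    for k in range(3):
        others = [j for j in range(3) if j != k]
        out[..., k] = 0.125 * HEX_SIGNS[:, k] * t[..., others[0]] * t[..., others[1]]
    return out


def quad_shape(xi: np.ndarray) -> np.ndarray:
    xi = np.asarray(xi, dtype=float)
    return 0.25 * np.prod(1.0 + xi[..., None, :] * QUAD_SIGNS, axis=-1)


def quad_dshape(xi: np.ndarray) -> np.ndarray:
    xi = np.asarray(xi, dtype=float)
    t = 1.0 + xi[..., None, :] * QUAD_SIGNS
    out = np.empty(t.shape)
    out[..., 0] = 0.25 * QUAD_SIGNS[:, 0] * t[..., 1]
    out[..., 1] = 0.25 * QUAD_SIGNS[:, 1] * t[..., 0]
    return out


# precomputed tables at the cell / face quadrature points
HEX_DN_QP = hex_dshape(HEX_QP)        # (8 qp, 8 nodes, 3)
HEX_N_QP = hex_shape(HEX_QP)          # (8 qp, 8 nodes)
QUAD_DN_QP = quad_dshape(QUAD_QP)     # (4 qp, 4 nodes, 2)
QUAD_N_QP = quad_shape(QUAD_QP)       # (4 qp, 4 nodes)


def element_qp_geometry(nodes: np.ndarray, elems: np.ndarray):
    """Quadrature-point geometry of a hex mesh.

    Returns (G, wdetJ, Xqp, Jcols) where G (E, Q, 8, 3) are shape-function
    gradients with respect to reference coordinates X, wdetJ (E, Q) the
    quadrature weights times Jacobian determinants, Xqp (E, Q, 3) the
    quadrature-point positions and Jcols (E, Q, 3, 3) the isoparametric
    Jacobian (columns = covariant basis vectors).
    """
    Xe = nodes[elems]                                   # (E, 8, 3)
    # J[e,q,i,k] = sum_a Xe[e,a,i] dN[q,a,k]
    J = np.einsum("eai,qak->eqik", Xe, HEX_DN_QP)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        bad = int(np.sum(np.any(detJ <= 0, axis=1)))
        raise ValueError(f"non-positive Jacobian in {bad} element(s)")
    invJ = np.linalg.inv(J)
    # G[e,q,a,i] = dN[q,a,k] invJ[e,q,k,i]
    G = np.einsum("qak,eqki->eqai", HEX_DN_QP, invJ)
    wdetJ = HEX_QW[None, :] * detJ
    Xqp = np.einsum("qa,eai->eqi", HEX_N_QP, Xe)
    return G, wdetJ, Xqp, J
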