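"""Passive myocardium constitutive model.

Implements the anisotropic exponential (Holzapfel-Ogden type) strain-energy
function for passive myocardium with fiber/sheet invariants,

    W = a/(2b) exp[b(I1-3)]
      + sum_{i=f,s} a_i/(2b_i) (exp[b_i (I4i-1)^2] - 1)
      + a_fs/(2b_fs) (exp[b_fs I8fs^2] - 1),

where the I4 terms contribute only in tension (I4i > 1, fibers cannot bear
compressive load), together with the Cauchy stress

    sigma_p = J^-1 (dW/dF) F^T + (beta_s / J) log(J^2) I,

whose last term is a logarithmic volumetric penalty (the Cauchy stress of
the penalty energy beta_s (ln J)^2) enforcing near-incompressibility.
All stress-like quantities are in kPa; the deformation gradient is
dimensionless.

The derivative dW/dF is written out analytically (chain rule through the
invariants); an independent finite-difference oracle guards it in the test
suite.  Infarcted tissue is stiffened by scaling the four stress-like
parameters, leaving the dimensionless exponents untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np

__all__ = [
    "PassiveParams",
    "invariants",
    "strain_energy",
    "passive_stress",
    "infarct_blend",
    "penalty_pressure",
    "INFARCT_STIFFENING",
]

#: Stiffening factor of fully infarcted (scar) tissue relative to viable
#: myocardium, applied to the stress-like parameters.
INFARCT_STIFFENING = 50.0

# Below this value an exponent b is replaced by its quadratic Taylor limit
# to avoid 0/0 in a/(2b)(exp[b x]-1) -> a x / 2.
_B_EPS = 1e-8


@dataclass(frozen=True)
class PassiveParams:
    """Constitutive parameters of the passive law.

    ``a``-type parameters are stress-like (kPa, >= 0), ``b``-type are
    dimensionless exponents (>= 0).  ``beta_s`` (kPa, > 0) is the
    incompressibility penalty modulus.

    The defaults are the package's healthy baseline: the shear-data
    reference set of the constitutive family with all four stress-like
    parameters scaled by a single population factor calibrated so that the
    default ventricle inflated to 8 mmHg lands near the healthy-population
    end-diastolic volume.  They are configuration (the starting point the
    per-subject fits scale), not results.  beta_s is set so that the
    element-mean dilatation stays within ~1.5% of unity under peak loads.
    """

    a: float = 0.0590
    b: float = 10.810
    a_f: float = 5.0093
    b_f: float = 14.154
    a_s: float = 0.9311
    b_s: float = 5.1645
    a_fs: float = 0.1027
    b_fs: float = 11.300
    beta_s: float = 1500.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "a_f", "b_f", "a_s", "b_s", "a_fs", "b_fs"):
            if getattr(self, name) < 0:
                raise ValueError(f"passive parameter {name!r} must be >= 0")
        if self.beta_s <= 0:
            raise ValueError("beta_s must be > 0")

    def scaled(self, iso_scale: float = 1.0, aniso_scale: float = 1.0) -> "PassiveParams":
        """Return a copy with ``a`` scaled by ``iso_scale`` and the three
        anisotropic stress-like parameters scaled jointly by ``aniso_scale``."""
        return replace(
            self,
            a=self.a * iso_scale,
            a_f=self.a_f * aniso_scale,
            a_s=self.a_s * aniso_scale,
            a_fs=self.a_fs * aniso_scale,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _as_batch(F: np.ndarray) -> tuple[np.ndarray, bool]:
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] != (3, 3):
        raise ValueError("deformation gradient must have shape (..., 3, 3)")
    single = F.ndim == 2
    return (F[None] if single else F), single


def invariants(F: np.ndarray, f0: np.ndarray, s0: np.ndarray) -> tuple:
    """Strain invariants (I1, I4f, I4s, I8fs) of C = F^T F.

    ``f0``/``s0`` are unit fiber and sheet directions in the reference
    configuration.  Accepts a single 3x3 tensor or a batch (..., 3, 3) with
    matching (..., 3) direction arrays; returns scalars or arrays.
    """
    Fb, single = _as_batch(F)
    f0 = np.asarray(f0, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    if single:
        f0, s0 = f0[None], s0[None]
    C = np.einsum("...ki,...kj->...ij", Fb, Fb)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    Cf = np.einsum("...ij,...j->...i", C, f0)
    Cs = np.einsum("...ij,...j->...i", C, s0)
    I4f = np.einsum("...i,...i->...", f0, Cf)
    I4s = np.einsum("...i,...i->...", s0, Cs)
    I8fs = np.einsum("...i,...i->...", f0, Cs)
    if single:
        return I1[0], I4f[0], I4s[0], I8fs[0]
    return I1, I4f, I4s, I8fs


def _exp_term(a: float, b: float, x: np.ndarray) -> np.ndarray:
    """a/(2b) (exp[b x] - 1), with the analytic b -> 0 limit a x / 2."""
    if b < _B_EPS:
        return 0.5 * a * x
    return a / (2.0 * b) * np.expm1(b * x)


def strain_energy(F, params: PassiveParams, f0, s0):
    """Strain-energy density W (kPa) of the passive law.

    The I4 terms switch on only in tension (I4i > 1); at F = I the energy
    reduces to the constant a/(2b) carried by the isotropic term.
    """
    I1, I4f, I4s, I8fs = invariants(F, f0, s0)
    p = params
    if p.b < _B_EPS:
        w = 0.5 * p.a * (I1 - 3.0) + p.a / 2.0 * np.ones_like(np.asarray(I1))
    else:
        w = p.a / (2.0 * p.b) * np.exp(p.b * (I1 - 3.0))
    e4f = np.maximum(np.asarray(I4f) - 1.0, 0.0)
    e4s = np.maximum(np.asarray(I4s) - 1.0, 0.0)
    w = w + _exp_term(p.a_f, p.b_f, e4f**2)
    w = w + _exp_term(p.a_s, p.b_s, e4s**2)
    w = w + _exp_term(p.a_fs, p.b_fs, np.asarray(I8fs) ** 2)
    return w


def _dW_dF(Fb: np.ndarray, params: PassiveParams, f0: np.ndarray, s0: np.ndarray,
           a_scale: np.ndarray | None = None) -> np.ndarray:
    """Analytic dW/dF for a batch (n, 3, 3); optional per-point scaling of the
    stress-like parameters (infarct stiffening field)."""
    p = params
    I1, I4f, I4s, I8fs = invariants(Fb, f0, s0)

    def psi(a, b, x):
        # d/dx of the exponential term: (a/2) exp(b x) -> at b=0, a/2
        if b < _B_EPS:
            return 0.5 * a * np.ones_like(x)
        return 0.5 * a * np.exp(b * x)

    c1 = 2.0 * psi(p.a, p.b, I1 - 3.0)                      # dW/dI1 * 2
    e4f = np.maximum(I4f - 1.0, 0.0)
    e4s = np.maximum(I4s - 1.0, 0.0)
    c4f = 2.0 * 2.0 * e4f * psi(p.a_f, p.b_f, e4f**2)       # dW/dI4f * 2
    c4s = 2.0 * 2.0 * e4s * psi(p.a_s, p.b_s, e4s**2)
    c8 = 2.0 * I8fs * psi(p.a_fs, p.b_fs, I8fs**2)          # dW/dI8fs (used once)
    if a_scale is not None:
        c1 = c1 * a_scale
        c4f = c4f * a_scale
        c4s = c4s * a_scale
        c8 = c8 * a_scale

    Ff = np.einsum("...ij,...j->...i", Fb, f0)
    Fs = np.einsum("...ij,...j->...i", Fb, s0)
    # dI1/dF = 2F ; dI4f/dF = 2 (F f0) x f0 ; dI8fs/dF = (F s0) x f0 + (F f0) x s0
    dW = c1[..., None, None] * Fb
    dW = dW + c4f[..., None, None] * np.einsum("...i,...j->...ij", Ff, f0)
    dW = dW + c4s[..., None, None] * np.einsum("...i,...j->...ij", Fs, s0)
    dW = dW + c8[..., None, None] * (
        np.einsum("...i,...j->...ij", Fs, f0) + np.einsum("...i,...j->...ij", Ff, s0)
    )
    return dW


def penalty_pressure(J, beta_s: float):
    """Volumetric penalty mean stress U'(J) = (beta_s/J) log(J^2) (kPa).

    Cauchy stress contribution U'(J) I of the penalty energy
    U = beta_s (ln J)^2; its negative is a pressure that is positive under
    compression (J < 1), opposing it.
    """
    J = np.asarray(J, dtype=float)
    return (beta_s / J) * np.log(J**2)


def passive_stress(F, params: PassiveParams, f0, s0, a_scale=None, include_penalty=True):
    """Passive Cauchy stress sigma_p (kPa), symmetric.

    sigma_p = J^-1 (dW/dF) F^T + (beta_s/J) log(J^2) I (volumetric penalty,
    see :func:`penalty_pressure`).  Raises on J <= 0 (element inversion).
    ``a_scale`` optionally scales the stress-like parameters pointwise
    (infarct stiffening inside the solver); ``include_penalty=False`` returns
    the constitutive part only (the solver applies the penalty through a
    mean-dilatation treatment to avoid volumetric locking).
    """
    Fb, single = _as_batch(F)
    f0 = np.asarray(f0, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    if single:
        f0, s0 = f0[None], s0[None]
        if a_scale is not None:
            a_scale = np.asarray([a_scale], dtype=float)
    J = np.linalg.det(Fb)
    if np.any(J <= 0):
        raise ValueError("element inversion: det(F) <= 0")
    dW = _dW_dF(Fb, params, f0, s0, a_scale=a_scale)
    sig = np.einsum("...ij,...kj->...ik", dW, Fb) / J[..., None, None]
    if include_penalty:
        pen = penalty_pressure(J, params.beta_s)
        sig = sig + pen[..., None, None] * np.eye(3)
    # enforce exact symmetry against floating-point drift
    sig = 0.5 * (sig + np.swapaxes(sig, -1, -2))
    return sig[0] if single else sig


def infarct_blend(params: PassiveParams, phi: float) -> PassiveParams:
    """Passive parameters of tissue with infarct fraction ``phi`` in [0, 1].

    Stress-like parameters are scaled by (1 + (k-1) phi) with k = 50: fully
    infarcted tissue is 50x stiffer, the linear transition zone interpolates.
    Exponents are unchanged.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("infarct fraction must lie in [0, 1]")
    scale = 1.0 + (INFARCT_STIFFENING - 1.0) * phi
    return params.scaled(iso_scale=scale, aniso_scale=scale)


def uniaxial_fiber_stress(params: PassiveParams, stretch):
    """Uniaxial passive Cauchy stress along the fiber direction (kPa).

    Incompressible uniaxial kinematics F = diag(lam, 1/sqrt(lam),
    1/sqrt(lam)) in the fiber frame; the reported stress is the difference
    sigma_ff - sigma_nn, which removes the undetermined hydrostatic part
    (J = 1, so the penalty drops out).  Vectorized over stretch; used for
    myofiber stiffness comparisons between fitted parameter sets.
    """
    lam = np.atleast_1d(np.asarray(stretch, dtype=float))
    F = np.zeros((len(lam), 3, 3))
    F[:, 0, 0] = lam
    F[:, 1, 1] = F[:, 2, 2] = 1.0 / np.sqrt(lam)
    f0 = np.tile([1.0, 0.0, 0.0], (len(lam), 1))
    s0 = np.tile([0.0, 1.0, 0.0], (len(lam), 1))
    sig = passive_stress(F, params, f0, s0, include_penalty=False)
    out = sig[:, 0, 0] - sig[:, 2, 2]
    return out if out.size > 1 else float(out[0])


def infarct_scale_field(phi: np.ndarray) -> np.ndarray:
    """Pointwise stress-parameter scaling (1 + 49 phi) for an infarct field."""
    phi = np.asarray(phi, dtype=float)
    return 1.0 + (INFARCT_STIFFENING - 1.0) * phi
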