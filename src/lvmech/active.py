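"""Active tension generation by cross-bridge cycling (fading-memory model).

The active Cauchy stress is rank-one along the current fiber direction,
sigma_a = T f (x) f.  The tension follows a fading-memory law

    T = T_req (1 + beta_0 (lambda_f - 1)) (z / z_max) Phi(sum Q_i),

    Phi(Q) = (1 + alpha Q) / (1 - Q)        if Q < 0   (shortening)
           = (1 + (2 + alpha) Q) / (1 + Q)  otherwise,

    dQ_i/dt = A_i dlambda_f/dt - alpha_i Q_i,  i = 1..3,

where T_req is the tension at unit fiber stretch under full activation (the
"required contractility" estimated by the inverse pipeline), beta_0 the
length-dependence slope, alpha the force-velocity curvature, and the Q_i
exponentially fading memories of the stretch-rate history.  z/z_max is the
calcium-driven activation level, saturating at 1 once the prescribed calcium
transient reaches its plateau.

At end-systole the pipeline uses the quasi-static reduction of this model:
with stretch rate zero the Q_i have decayed, the calcium transient is at
plateau, and the tension reduces to T = T_req (1 + beta_0 (lambda_f - 1)),
clamped at zero.  The dynamic model is retained for point-level studies and
as the oracle that the reduction equals its steady state.

Default rate parameters are taken from the cited fading-memory model family
(force-velocity weights A_i, rates alpha_i, curvature alpha) and the steep
length dependence beta_0 = 4.9 of the skeletal/cardiac overlap function;
they are configuration, not fitted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "CalciumTransient",
    "ActiveParams",
    "ActiveState",
    "tension",
    "step_Q",
    "activation_level",
    "end_systolic_tension",
    "active_stress",
]


@dataclass(frozen=True)
class CalciumTransient:
    """Prescribed intracellular calcium waveform (uM vs time).

    Linear rise to the plateau over ``rise_time`` then constant — the
    transient is held at its maximum once attained.
    """

    plateau: float = 1.0      # uM
    rise_time: float = 0.1    # s

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        frac = np.clip(t / self.rise_time, 0.0, 1.0) if self.rise_time > 0 else np.ones_like(t)
        out = self.plateau * frac
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ActiveParams:
    """Parameters of the active tension model.

    T_req : kPa, tension at lambda_f = 1 under full activation (> 0).
    beta_0 : length-dependence slope of the overlap function.
    alpha : force-velocity curvature.
    A, alpha_rate : fading-memory weights (dimensionless) and rates (1/s).
    hill_n, ca50 : Hill exponent and half-activation calcium (uM) of the
        activation level; the level is normalized to equal 1 exactly at the
        plateau of the transient.
    sl_ref : resting sarcomere length (um), metadata only — the model is
        formulated in the stretch lambda_f = SL / SL_ref.
    """

    T_req: float = 150.0
    beta_0: float = 4.9
    alpha: float = 0.5
    A: tuple = (-29.0, 138.0, 129.0)
    alpha_rate: tuple = (30.0, 130.0, 625.0)
    calcium: CalciumTransient = field(default_factory=CalciumTransient)
    hill_n: float = 3.0
    ca50: float = 0.5
    z_max: float = 1.0
    sl_ref: float = 1.9

    def __post_init__(self) -> None:
        if self.T_req <= 0:
            raise ValueError("T_req must be > 0")
        if any(a <= 0 for a in self.alpha_rate):
            raise ValueError("fading-memory rates alpha_i must be > 0")
        if not 0.0 < self.z_max <= 1.0:
            raise ValueError("z_max must lie in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["calcium"] = asdict(self.calcium)
        return d


@dataclass
class ActiveState:
    """Point state of the active model at one instant."""

    time: float = 0.0
    stretch: float = 1.0          # fiber stretch lambda_f
    stretch_rate: float = 0.0     # 1/s
    Q: np.ndarray = field(default_factory=lambda: np.zeros(3))
    calcium: float = 0.0          # uM

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.stretch <= 0:
            raise ValueError("fiber stretch must be > 0")
        if not np.all(np.isfinite(self.Q)):
            raise ValueError("Q_i must be finite")


def activation_level(calcium: float, stretch: float, params: ActiveParams) -> float:
    """Activation level z/z_max in [0, 1].

    Normalized Hill saturation of calcium: the raw Hill curve
    Ca^n / (Ca^n + Ca50^n) is rescaled so that the level equals exactly 1 at
    the plateau calcium of the prescribed transient (full activation), then
    clipped to [0, 1].  Monotone non-decreasing in calcium; 0 at zero calcium.
    The ``stretch`` argument is accepted for a length-dependent half
    activation hook; the default keeps ca50 stretch-independent since the
    end-systolic analysis only uses the saturated limit.
    """
    if calcium < 0:
        raise ValueError("calcium must be >= 0")
    n, c50 = params.hill_n, params.ca50
    ca_pl = params.calcium.plateau

    def hill(c):
        cn = c**n
        return cn / (cn + c50**n)

    ref = hill(ca_pl)
    if ref <= 0:
        return 0.0
    return float(np.clip(hill(calcium) / ref, 0.0, 1.0))


def _phi_fv(Qsum: float, alpha: float) -> float:
    """Force-velocity factor Phi of the fading-memory model."""
    if Qsum >= 1.0:
        raise FloatingPointError(
            f"force-velocity denominator blow-up: sum(Q_i) = {Qsum!r} >= 1"
        )
    if Qsum < 0.0:
        return (1.0 + alpha * Qsum) / (1.0 - Qsum)
    return (1.0 + (2.0 + alpha) * Qsum) / (1.0 + Qsum)


def tension(state: ActiveState, params: ActiveParams) -> float:
    """Active tension T (kPa) at the given state, clamped at zero.

    T = T_req (1 + beta_0 (lambda_f - 1)) (z/z_max) Phi(sum Q_i).
    Raises if sum Q_i approaches the shortening-velocity singularity; the
    raised error carries the state for diagnosis.
    """
    Qsum = float(np.sum(state.Q))
    try:
        phi = _phi_fv(Qsum, params.alpha)
    except FloatingPointError as exc:
        raise FloatingPointError(f"{exc}; state = {state!r}") from None
    z = activation_level(state.calcium, state.stretch, params)
    T = params.T_req * (1.0 + params.beta_0 * (state.stretch - 1.0)) * z * phi
    return max(T, 0.0)


def step_Q(Q: np.ndarray, stretch_rate: float, dt: float, params: ActiveParams) -> np.ndarray:
    """Advance the fading-memory states over one step of length ``dt``.

    Exact exponential integrator of dQ_i/dt = A_i r - alpha_i Q_i for a
    stretch rate r held constant over the step:

        Q_i(t+dt) = Q_i(t) e^{-alpha_i dt} + (A_i r / alpha_i)(1 - e^{-alpha_i dt}).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    A = np.asarray(params.A, dtype=float)
    al = np.asarray(params.alpha_rate, dtype=float)
    decay = np.exp(-al * dt)
    return np.asarray(Q, dtype=float) * decay + (A * stretch_rate / al) * (1.0 - decay)


def end_systolic_tension(stretch, params: ActiveParams):
    """Quasi-static end-systolic tension (kPa), vectorized over stretch.

    Steady state of the dynamic model at plateau calcium and zero stretch
    rate (Q_i decayed to zero): T = T_req (1 + beta_0 (lambda_f - 1)),
    clamped at zero from below.
    """
    lam = np.asarray(stretch, dtype=float)
    T = params.T_req * (1.0 + params.beta_0 * (lam - 1.0))
    T = np.maximum(T, 0.0)
    return float(T) if T.ndim == 0 else T


def active_stress(T, f):
    """Active Cauchy stress sigma_a = T f (x) f (kPa).

    ``f`` is the unit fiber direction in the current configuration; accepts
    batches (..., 3) with matching tension array.
    """
    f = np.asarray(f, dtype=float)
    T = np.asarray(T, dtype=float)
    return T[..., None, None] * np.einsum("...i,...j->...ij", f, f)
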