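"""Inverse estimation of passive stiffness and required contractility.

The personalization mirrors the study's two-stage procedure.

Diastolic stage: the eight-parameter passive law is not identifiable from
cavity volume plus segmental strains, so the search space is reduced to two
multiplicative scales — one on the isotropic stress-like parameter ``a``,
one jointly on the anisotropic stress-like parameters (a_f, a_s, a_fs) —
with the exponents held at their reference values.  The objective has the
same form as the systolic one, applied at end-diastole:

    Obj_ED = sum_i (eps_i - eps'_i)^2 / N + ((V - V') / V')^2,

with V the simulated end-diastolic volume and eps_i the simulated
diastolic segmental circumferential strains (relative to the
early-diastolic reference).  For infarcted subjects the remote-zone scales
are fitted while the infarct stays 50x stiffer through the blended
stiffening field.

Systolic stage: scalar bounded search for T_req.

    Healthy:  Obj_HV = sum_{i=1..N} (eps_i - eps'_i)^2 / N + ((V - V')/V')^2
              (V' = measured end-systolic volume);
    Infarct:  Obj_MI = sum over the N_un remote segments only, no volume
              term (the scar is purely passive; its strain and the
              end-systolic volume are not used).

Both stages are deterministic given a measurement set; all randomness
lives in the synthetic cohort.  Repeated forward solves are warm-started
from the previous equilibrium, which makes the inner loops cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .geometry import LVGeometry
from .materials import PassiveParams
from .active import ActiveParams
from .solver import (SolverConfig, SolverError, solve_passive_inflation,
                     solve_end_systole, regional_circumferential_strain)
from .cohort import MeasurementSet
from .stats import mean_active_tension, at_nor

__all__ = [
    "OptimizerConfig",
    "DiastolicFit",
    "SystolicFit",
    "FitMetrics",
    "fit_passive",
    "fit_treq_healthy",
    "fit_treq_mi",
    "fit_treq",
    "fit_metrics",
    "sensitivity_edp",
    "sensitivity_strain",
    "perturb_systolic_strain",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OptimizerConfig:
    """Search controls of the inverse problems."""

    treq_bounds_kpa: tuple = (20.0, 500.0)
    treq_tol_kpa: float = 0.5
    treq_start_kpa: float = 150.0
    passive_scale_bounds: tuple = (0.2, 5.0)
    passive_max_evals: int = 60
    passive_tol: float = 1e-10

    def __post_init__(self):
        lo, hi = self.treq_bounds_kpa
        if not (0 < lo < hi):
            raise ValueError("T_req bounds must be positive and ordered")
        lo, hi = self.passive_scale_bounds
        if not (0 < lo < hi):
            raise ValueError("passive-scale bounds must be positive and ordered")


@dataclass
class DiastolicFit:
    """Result of the diastolic passive-parameter fit."""

    iso_scale: float
    aniso_scale: float
    params: PassiveParams
    objective: float
    edv_rel_err_pct: float
    n_solves: int
    converged: bool
    ed_state: object = None
    log: list = field(default_factory=list)


@dataclass
class SystolicFit:
    """Result of the systolic required-contractility fit."""

    treq_kpa: float
    objective: float
    segment_residuals: np.ndarray
    esv_rel_err_pct: float | None
    converged: bool
    n_solves: int
    es_state: object = None
    sigma_a_kpa: float = float("nan")
    at_nor_kpa_per_mmhg: float = float("nan")


@dataclass(frozen=True)
class FitMetrics:
    """Cohort-level agreement metrics between fitted models and data.

    volume_difference_pct: mean over subjects of |V - V'| / V' x 100.
    strain_difference_pct: mean over subjects of the absolute relative
    difference of the subject-average systolic strain x 100.
    """

    volume_difference_pct: float
    strain_difference_pct: float


# ---------------------------------------------------------------------------
# diastolic stage


def fit_passive(
    meas: MeasurementSet,
    geom: LVGeometry,
    edp_mmhg: float | None = None,
    opt: OptimizerConfig | None = None,
    solver: SolverConfig | None = None,
    base: PassiveParams | None = None,
) -> DiastolicFit:
    """Fit the two passive scales to end-diastolic volume and diastolic
    segmental strains.

    Nelder-Mead in log-scale space within the configured bounds; warm
    restarts reuse the previous end-diastolic equilibrium.  If the
    evaluation budget is exhausted the best point so far is returned with
    ``converged=False``.
    """
    opt = opt or OptimizerConfig()
    edp = meas.edp_mmhg if edp_mmhg is None else edp_mmhg
    base = base or PassiveParams()
    N = meas.n_segments
    state = {"ed": None, "n": 0, "best": None}
    lo, hi = np.log(opt.passive_scale_bounds)

    def objective(x):
        xi, xa = np.clip(x, lo, hi)
        params = base.scaled(float(np.exp(xi)), float(np.exp(xa)))
        try:
            ed = solve_passive_inflation(geom, params, edp, solver,
                                         initial_state=state["ed"])
        except SolverError as exc:
            log.warning("diastolic solve failed at scales (%.3g, %.3g): %s",
                        np.exp(xi), np.exp(xa), exc)
            return 1e6
        state["ed"] = ed
        state["n"] += 1
        eps = regional_circumferential_strain(ed, geom)
        obj = float(np.sum((eps - meas.diastolic_strain) ** 2) / N
                    + ((ed.cavity_volume_ml - meas.edv_ml) / meas.edv_ml) ** 2)
        if state["best"] is None or obj < state["best"][0]:
            state["best"] = (obj, float(np.exp(xi)), float(np.exp(xa)), ed)
        return obj

    res = optimize.minimize(
        objective, x0=np.zeros(2), method="Nelder-Mead",
        options=dict(maxfev=opt.passive_max_evals, fatol=opt.passive_tol,
                     xatol=1e-3, initial_simplex=[[0, 0], [0.35, 0], [0, 0.35]]),
    )
    obj_best, s_iso, s_aniso, ed = state["best"]
    params = base.scaled(s_iso, s_aniso)
    edv_err = abs(ed.cavity_volume_ml - meas.edv_ml) / meas.edv_ml * 100.0
    return DiastolicFit(
        iso_scale=s_iso, aniso_scale=s_aniso, params=params,
        objective=obj_best, edv_rel_err_pct=float(edv_err),
        n_solves=state["n"], converged=bool(res.success), ed_state=ed,
        log=[{"nfev": int(res.nfev), "message": str(res.message)}],
    )


# ---------------------------------------------------------------------------
# systolic stage


def _fit_treq_core(meas, geom, passive, sbp, opt, solver, segments, use_volume,
                   ed_state=None):
    if segments is not None and len(segments) == 0:
        raise ValueError("no remote segments: Obj_MI undefined (N_un = 0)")
    if np.allclose(meas.systolic_strain, 0.0) and not use_volume:
        raise ValueError("all measured strains zero: objective is flat in T_req")
    opt = opt or OptimizerConfig()
    ed = ed_state or solve_passive_inflation(geom, passive, meas.edp_mmhg, solver)
    state = {"es": ed, "n": 0}
    sel = slice(None) if segments is None else np.asarray(segments)

    def simulate(treq):
        es = solve_end_systole(geom, passive, ActiveParams(T_req=float(treq)),
                               sbp, solver, ed_state=ed, warm_state=state["es"])
        state["es"] = es
        state["n"] += 1
        return es

    def objective(treq):
        try:
            es = simulate(treq)
        except SolverError as exc:
            log.warning("systolic solve failed at T_req = %.1f: %s", treq, exc)
            return 1e6
        eps = regional_circumferential_strain(es, geom, reference_state=ed)
        resid = eps[sel] - meas.systolic_strain[sel]
        obj = float(np.mean(resid**2))
        if use_volume:
            obj += float(((es.cavity_volume_ml - meas.esv_ml) / meas.esv_ml) ** 2)
        return obj

    res = optimize.minimize_scalar(
        objective, bounds=opt.treq_bounds_kpa, method="bounded",
        options=dict(xatol=opt.treq_tol_kpa),
    )
    treq = float(res.x)
    es = simulate(treq)
    eps = regional_circumferential_strain(es, geom, reference_state=ed)
    resid = eps - meas.systolic_strain
    esv_err = (abs(es.cavity_volume_ml - meas.esv_ml) / meas.esv_ml * 100.0
               if use_volume else None)
    sig_a = mean_active_tension(es, geom)
    return SystolicFit(
        treq_kpa=treq, objective=float(res.fun), segment_residuals=resid,
        esv_rel_err_pct=esv_err, converged=bool(res.success),
        n_solves=state["n"], es_state=es, sigma_a_kpa=sig_a,
        at_nor_kpa_per_mmhg=at_nor(sig_a, sbp),
    ), ed


def fit_treq_healthy(meas, geom, passive, sbp_mmhg=None, opt=None, solver=None,
                     ed_state=None) -> SystolicFit:
    """Estimate T_req of a healthy subject (Obj_HV: all segments' systolic
    strains plus the end-systolic volume term)."""
    sbp = meas.sbp_mmhg if sbp_mmhg is None else sbp_mmhg
    fit, _ = _fit_treq_core(meas, geom, passive, sbp, opt, solver,
                            segments=None, use_volume=True, ed_state=ed_state)
    return fit


def fit_treq_mi(meas, geom, passive, sbp_mmhg=None, opt=None, solver=None,
                ed_state=None) -> SystolicFit:
    """Estimate T_req of an infarcted subject (Obj_MI: remote segments
    only, no volume term; the purely passive scar is excluded)."""
    sbp = meas.sbp_mmhg if sbp_mmhg is None else sbp_mmhg
    fit, _ = _fit_treq_core(meas, geom, passive, sbp, opt, solver,
                            segments=meas.remote_segments, use_volume=False,
                            ed_state=ed_state)
    return fit


def fit_treq(meas, geom, passive, **kw) -> SystolicFit:
    """Dispatch to the healthy or infarcted objective by subject group."""
    if meas.group == "control":
        return fit_treq_healthy(meas, geom, passive, **kw)
    return fit_treq_mi(meas, geom, passive, **kw)


# ---------------------------------------------------------------------------
# cohort metrics


def fit_metrics(sim_volumes, meas_volumes, sim_strains, meas_strains) -> FitMetrics:
    """Cohort agreement metrics.

    ``sim_volumes``/``meas_volumes``: per-subject simulated and measured
    volumes (mL).  ``sim_strains``/``meas_strains``: per-subject arrays of
    segmental systolic strains; each subject contributes its segment-average
    strain.
    """
    sv = np.asarray(sim_volumes, dtype=float)
    mv = np.asarray(meas_volumes, dtype=float)
    if sv.size == 0 or sv.shape != mv.shape:
        raise ValueError("need matching, non-empty volume arrays")
    vol_diff = float(np.mean(np.abs(sv - mv) / mv) * 100.0)
    sbar = np.array([np.mean(s) for s in sim_strains], dtype=float)
    mbar = np.array([np.mean(m) for m in meas_strains], dtype=float)
    strain_diff = float(np.mean(np.abs((sbar - mbar) / mbar)) * 100.0)
    return FitMetrics(volume_difference_pct=vol_diff,
                      strain_difference_pct=strain_diff)


# ---------------------------------------------------------------------------
# sensitivity re-analyses


def run_subject_fit(meas, geom, edp_mmhg=None, opt=None, solver=None):
    """Full two-stage personalization of one subject at the given EDP.

    Returns (DiastolicFit, SystolicFit)."""
    dia = fit_passive(meas, geom, edp_mmhg=edp_mmhg, opt=opt, solver=solver)
    use_mi = meas.group != "control"
    fitter = fit_treq_mi if use_mi else fit_treq_healthy
    sysf = fitter(meas, geom, dia.params, opt=opt, solver=solver,
                  ed_state=dia.ed_state)
    return dia, sysf


def sensitivity_edp(meas, geom, edp_alt_mmhg, baseline=None, opt=None, solver=None):
    """Re-run both stages at an alternative end-diastolic pressure against
    the same measurements; report relative changes of the fitted passive
    scales, T_req, sigma_a and AT_nor.

    ``baseline`` may carry a precomputed (DiastolicFit, SystolicFit) pair at
    the subject's nominal EDP.
    """
    if baseline is None:
        baseline = run_subject_fit(meas, geom, opt=opt, solver=solver)
    dia0, sys0 = baseline
    dia1, sys1 = run_subject_fit(meas, geom, edp_mmhg=edp_alt_mmhg, opt=opt,
                                 solver=solver)

    def rel(new, old):
        return (new - old) / old * 100.0

    return {
        "baseline": {"dia": dia0, "sys": sys0},
        "alternative": {"dia": dia1, "sys": sys1},
        "edp_alt_mmhg": edp_alt_mmhg,
        "delta_iso_scale_pct": rel(dia1.iso_scale, dia0.iso_scale),
        "delta_aniso_scale_pct": rel(dia1.aniso_scale, dia0.aniso_scale),
        "delta_treq_pct": rel(sys1.treq_kpa, sys0.treq_kpa),
        "delta_sigma_a_pct": rel(sys1.sigma_a_kpa, sys0.sigma_a_kpa),
        "delta_at_nor_pct": rel(sys1.at_nor_kpa_per_mmhg, sys0.at_nor_kpa_per_mmhg),
    }


def perturb_systolic_strain(meas: MeasurementSet, delta: float) -> MeasurementSet:
    """Reduce the magnitude of every measured systolic strain by ``delta``
    (clamped at zero), leaving signs intact."""
    from dataclasses import replace

    eps = np.asarray(meas.systolic_strain, dtype=float)
    reduced = np.sign(eps) * np.maximum(np.abs(eps) - delta, 0.0)
    return replace(meas, systolic_strain=reduced)


def sensitivity_strain(meas, geom, passive_fit: DiastolicFit, delta=0.015,
                       baseline_fit: SystolicFit | None = None, opt=None,
                       solver=None):
    """Re-fit T_req after reducing every measured systolic strain magnitude
    by ``delta`` (default 0.015, about 10% of a typical -0.15 strain);
    report the changes in T_req and AT_nor."""
    use_mi = meas.group != "control"
    fitter = fit_treq_mi if use_mi else fit_treq_healthy
    if baseline_fit is None:
        baseline_fit = fitter(meas, geom, passive_fit.params, opt=opt,
                              solver=solver, ed_state=passive_fit.ed_state)
    pert = perturb_systolic_strain(meas, delta)
    fit1 = fitter(pert, geom, passive_fit.params, opt=opt, solver=solver,
                  ed_state=passive_fit.ed_state)
    return {
        "baseline": baseline_fit,
        "perturbed": fit1,
        "delta": delta,
        "delta_treq_pct": (fit1.treq_kpa - baseline_fit.treq_kpa)
        / baseline_fit.treq_kpa * 100.0,
        "delta_at_nor_pct": (fit1.at_nor_kpa_per_mmhg - baseline_fit.at_nor_kpa_per_mmhg)
        / baseline_fit.at_nor_kpa_per_mmhg * 100.0,
    }
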