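"""Shared fixtures.

The expensive session fixtures forward-simulate one control and one
infarcted subject on the coarse mesh (noise-free) and personalize them;
several test modules and the acceptance checks share these results.
"""

from __future__ import annotations

import numpy as np
import pytest

from lvmech.cohort import sample_cohort, forward_solve
from lvmech.personalize import fit_passive, fit_treq_healthy, fit_treq_mi

COHORT_SEED = 7


@pytest.fixture(scope="session")
def control_subject():
    """Noise-free forward-simulated control subject (coarse mesh)."""
    specs = sample_cohort(2, seed=COHORT_SEED)
    spec = next(s for s in specs if s.group == "control")
    geom, ed, es, truth = forward_solve(spec)
    return {"spec": spec, "geom": geom, "ed": ed, "es": es, "truth": truth}


@pytest.fixture(scope="session")
def control_fit(control_subject):
    """Two-stage personalization of the control subject."""
    cs = control_subject
    dia = fit_passive(cs["truth"], cs["geom"])
    sysf = fit_treq_healthy(cs["truth"], cs["geom"], dia.params,
                            ed_state=dia.ed_state)
    return {"dia": dia, "sys": sysf, **cs}


@pytest.fixture(scope="session")
def mi_subject():
    """Noise-free forward-simulated STEMI subject (coarse mesh)."""
    specs = sample_cohort(2, seed=COHORT_SEED)
    spec = next(s for s in specs if s.group == "stemi")
    geom, ed, es, truth = forward_solve(spec)
    return {"spec": spec, "geom": geom, "ed": ed, "es": es, "truth": truth}


@pytest.fixture(scope="session")
def mi_fit(mi_subject):
    """Two-stage personalization of the STEMI subject."""
    ms = mi_subject
    dia = fit_passive(ms["truth"], ms["geom"])
    sysf = fit_treq_mi(ms["truth"], ms["geom"], dia.params, ed_state=dia.ed_state)
    return {"dia": dia, "sys": sysf, **ms}


@pytest.fixture(scope="session")
def noisy_recovery_errors(control_subject):
    """Relative T_req recovery errors of three noisy replicates of the
    control subject under 6.5% strain observation noise (the condition the
    recovery property is stated for; volumes are left noise-free)."""
    import dataclasses

    from lvmech.cohort import NoiseConfig, forward_observe

    spec = control_subject["spec"]
    geom = control_subject["geom"]
    truth = control_subject["truth"]
    noise = NoiseConfig(strain_rel_sd=0.065, strain_bias=0.0, volume_rel_sd=0.0)
    errs = []
    for k in range(3):
        s = dataclasses.replace(spec, seed=spec.seed + 300 + k)
        obs = forward_observe(s, noise, precomputed_truth=truth)
        dia = fit_passive(obs, geom)
        fit = fit_treq_healthy(obs, geom, dia.params, ed_state=dia.ed_state)
        errs.append(abs(fit.treq_kpa - spec.treq_kpa) / spec.treq_kpa)
    return errs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)
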