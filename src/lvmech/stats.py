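"""Biomarkers and cohort statistics.

Biomarkers: the required contractility T_req (kPa) from the inverse fit;
the mean systolic active tension sigma_a (kPa), a volume-weighted average
of the active tension over functional myocardium (infarct fraction < 0.5)
at end-systole; the normalized active tension AT_nor = sigma_a / SBP
(kPa/mmHg), the active tension generated per mmHg of systolic blood
pressure; plus the standard LVEF and GLS.

Statistics mirror the study's analysis plan: Kolmogorov-Smirnov normality
checks, pooled two-sample t-tests for group differences, Pearson
correlation with Fisher-z confidence intervals for 6-month outcomes, and
an exact noncentral-t power calculation for the two-group design (the
paired variant is exposed as an option).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import LVGeometry
from .solver import EquilibriumState

__all__ = [
    "BiomarkerRecord",
    "GroupComparison",
    "CorrelationResult",
    "PowerSpec",
    "mean_active_tension",
    "at_nor",
    "lvef",
    "ttest_from_summary",
    "ttest_samples",
    "ks_normality",
    "pearson_with_ci",
    "correlation_inference",
    "power_two_sample_t",
    "run_cohort_analysis",
]

log = logging.getLogger(__name__)

#: Tissue with infarct fraction at or above this value is excluded from the
#: functional-myocardium average behind sigma_a.
FUNCTIONAL_PHI_MAX = 0.5


@dataclass(frozen=True)
class BiomarkerRecord:
    """Per-subject biomarker row."""

    subject_id: str
    group: str
    treq_kpa: float
    sigma_a_kpa: float
    at_nor_kpa_per_mmhg: float
    sbp_mmhg: float
    edv_ml: float
    esv_ml: float
    lvef_pct: float
    gls_pct: float

    def __post_init__(self):
        if not np.isclose(self.at_nor_kpa_per_mmhg, self.sigma_a_kpa / self.sbp_mmhg,
                          rtol=0, atol=1e-12):
            raise ValueError("AT_nor must equal sigma_a / SBP")
        if not np.isclose(self.lvef_pct,
                          100.0 * (self.edv_ml - self.esv_ml) / self.edv_ml,
                          rtol=0, atol=1e-9):
            raise ValueError("LVEF must equal 100 (EDV - ESV) / EDV")

    @classmethod
    def build(cls, subject_id, group, treq_kpa, sigma_a_kpa, sbp_mmhg,
              edv_ml, esv_ml, gls_pct):
        return cls(
            subject_id=subject_id, group=group, treq_kpa=treq_kpa,
            sigma_a_kpa=sigma_a_kpa,
            at_nor_kpa_per_mmhg=at_nor(sigma_a_kpa, sbp_mmhg),
            sbp_mmhg=sbp_mmhg, edv_ml=edv_ml, esv_ml=esv_ml,
            lvef_pct=lvef(edv_ml, esv_ml), gls_pct=gls_pct,
        )

    def to_dict(self):
        return asdict(self)


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison summary (pooled-variance t-test)."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t_statistic: float
    p_value: float
    test: str = "two-sample pooled t"

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least 2 observations per group")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with Fisher-z CI and t-based p-value."""

    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r out of range")
        if not self.ci_low - 1e-12 <= self.r <= self.ci_high + 1e-12:
            raise ValueError("CI must contain r")


@dataclass(frozen=True)
class PowerSpec:
    """Inputs and result of a t-test power calculation."""

    n_per_group: int
    mean_difference: float
    sd: float
    alpha: float
    power: float
    design: str = "two-sample"


# ---------------------------------------------------------------------------
# biomarkers


def mean_active_tension(es_state: EquilibriumState, geom: LVGeometry,
                        phi_max: float = FUNCTIONAL_PHI_MAX) -> float:
    """Volume-weighted mean active tension sigma_a (kPa) over functional
    myocardium (infarct fraction < phi_max) at end-systole."""
    mask = geom.phi < phi_max
    if not np.any(mask):
        raise ValueError("no functional myocardium (phi < %.2f nowhere)" % phi_max)
    w = geom.qp_wdetJ[mask]
    return float(np.sum(w * es_state.active_tension[mask]) / np.sum(w))


def at_nor(sigma_a_kpa: float, sbp_mmhg: float) -> float:
    """Normalized active tension AT_nor = sigma_a / SBP (kPa/mmHg)."""
    if sbp_mmhg <= 0:
        raise ValueError("systolic blood pressure must be > 0")
    return sigma_a_kpa / sbp_mmhg


def lvef(edv_ml: float, esv_ml: float) -> float:
    """Ejection fraction 100 (EDV - ESV) / EDV (%)."""
    return 100.0 * (edv_ml - esv_ml) / edv_ml


# ---------------------------------------------------------------------------
# statistics


def ttest_from_summary(m1, s1, n1, m2, s2, n2) -> GroupComparison:
    """Pooled-variance two-sample t-test from group summaries
    (n1 + n2 - 2 degrees of freedom, two-sided p)."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("group SDs must be > 0")
    t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return GroupComparison(mean1=m1, sd1=s1, n1=n1, mean2=m2, sd2=s2, n2=n2,
                           t_statistic=float(t), p_value=float(p))


def ttest_samples(x, y) -> GroupComparison:
    """Pooled two-sample t-test on raw samples (matches the summary form
    applied to the samples' own statistics)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return ttest_from_summary(x.mean(), x.std(ddof=1), len(x),
                              y.mean(), y.std(ddof=1), len(y))


def ks_normality(sample, lilliefors: bool = False, mean=None, sd=None):
    """One-sample Kolmogorov-Smirnov normality test.

    By default the normal parameters are estimated from the sample (the
    plain KS p-value is then conservative; a Lilliefors-corrected variant
    is available via ``lilliefors=True``).  Passing ``mean``/``sd`` tests
    against that fixed normal law instead.  Returns (statistic, p).
    Degenerate (constant) samples are rejected with an error.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if x.std(ddof=1) == 0:
        raise ValueError("degenerate sample: zero variance")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
        return float(stat), float(p)
    loc = x.mean() if mean is None else mean
    scale = x.std(ddof=1) if sd is None else sd
    stat, p = sps.kstest(x, "norm", args=(loc, scale))
    return float(stat), float(p)


def correlation_inference(r: float, n: int, alpha: float = 0.05) -> CorrelationResult:
    """Fisher-z CI (SE = 1/sqrt(n-3)) and two-sided p-value
    (t = r sqrt((n-2)/(1-r^2)), n-2 df) for a given Pearson r and n."""
    if n < 3:
        raise ValueError("need n >= 3")
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zc = sps.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - zc / np.sqrt(n - 3)), np.tanh(z + zc / np.sqrt(n - 3))
    t = r * np.sqrt((n - 2) / max(1 - r**2, 1e-300))
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=float(r), ci_low=float(lo), ci_high=float(hi),
                             p_value=p, n=n)


def pearson_with_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation of two samples with the Fisher-z confidence
    interval and t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need matching samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return correlation_inference(r, n, alpha)


def power_two_sample_t(n_per_group: int, delta: float, sd: float,
                       alpha: float = 0.05, paired: bool = False) -> PowerSpec:
    """Exact power of the two-sided t-test via the noncentral t
    distribution.

    Two-sample (default): df = 2n - 2, noncentrality delta/(sd sqrt(2/n)).
    Paired: df = n - 1, noncentrality delta/(sd/sqrt(n)) with ``sd`` the SD
    of the within-pair differences.
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if paired:
        df = n_per_group - 1
        ncp = delta / (sd / np.sqrt(n_per_group))
    else:
        df = 2 * n_per_group - 2
        ncp = delta / (sd * np.sqrt(2.0 / n_per_group))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    power = float(1 - sps.nct.cdf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
    return PowerSpec(n_per_group=n_per_group, mean_difference=delta, sd=sd,
                     alpha=alpha, power=power,
                     design="paired" if paired else "two-sample")


# ---------------------------------------------------------------------------
# cohort report


_COMPARISON_VARS = ["treq_kpa", "sigma_a_kpa", "sbp_mmhg", "at_nor_kpa_per_mmhg",
                    "edv_ml", "esv_ml", "lvef_pct", "gls_pct"]
_CORRELATION_VARS = ["lvef_pct", "gls_pct", "treq_kpa", "sigma_a_kpa",
                     "at_nor_kpa_per_mmhg"]


def run_cohort_analysis(records, followups=None, p_decimals: int = 2) -> dict:
    """Cohort report: group summary with comparisons, and (if follow-ups
    are given) the correlation table of baseline biomarkers against
    6-month outcomes in the patient group.

    ``records``: iterable of BiomarkerRecord or a DataFrame with the same
    columns.  ``followups``: iterable of FollowUp or DataFrame with
    subject_id, gls_6m_pct, delta_lvef_pct.  Subjects with missing
    follow-up are dropped from the correlation table with a log entry.
    Returns dict of DataFrames: 'group_summary', 'correlations' plus
    'records' (the assembled table).  p-values are reported both at full
    precision and rounded to ``p_decimals``.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.to_dict() for r in records])
    groups = sorted(df["group"].unique())
    rows = []
    for var in _COMPARISON_VARS:
        row = {"variable": var}
        for gname in groups:
            gv = df.loc[df.group == gname, var]
            row[f"{gname}_mean"] = gv.mean()
            row[f"{gname}_sd"] = gv.std(ddof=1)
            row[f"{gname}_n"] = len(gv)
        if len(groups) == 2:
            a = df.loc[df.group == groups[0], var]
            b = df.loc[df.group == groups[1], var]
            cmp_ = ttest_samples(a, b)
            row["t"] = cmp_.t_statistic
            row["p"] = cmp_.p_value
            row["p_rounded"] = round(cmp_.p_value, p_decimals)
        rows.append(row)
    summary = pd.DataFrame(rows)

    out = {"records": df, "group_summary": summary}
    if followups is not None:
        if isinstance(followups, pd.DataFrame):
            fu = followups.copy()
        else:
            fu = pd.DataFrame([{"subject_id": f.subject_id,
                                "gls_6m_pct": f.gls_6m_pct,
                                "delta_lvef_pct": f.delta_lvef_pct}
                               for f in followups])
        merged = df.merge(fu, on="subject_id", how="left")
        dropped = merged[merged.gls_6m_pct.isna()]
        if len(dropped):
            log.info("dropping %d subjects without follow-up from the "
                     "correlation table", len(dropped))
        merged = merged.dropna(subset=["gls_6m_pct", "delta_lvef_pct"])
        rows = []
        for var in _CORRELATION_VARS:
            for outcome in ("delta_lvef_pct", "gls_6m_pct"):
                cr = pearson_with_ci(merged[var], merged[outcome])
                rows.append({
                    "baseline": var, "outcome": outcome, "r": cr.r,
                    "ci_low": cr.ci_low, "ci_high": cr.ci_high,
                    "p": cr.p_value, "p_rounded": round(cr.p_value, p_decimals),
                    "n": cr.n,
                })
        out["correlations"] = pd.DataFrame(rows)
    return out
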