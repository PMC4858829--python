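"""Clinical-decision layer for promoter-methylation biomarkers.

Operates on a cohort table (pandas DataFrame, one row per patient) with the
columns of :class:`PatientRecord`: demographics, WHO grade, IDH1 status,
three methylation readouts (continuous HRM %, continuous PSQ %, binary MSP
status), and progression-free / overall survival in months with event flags.

The layer covers: exclusion of IDH1-mutant cases (a favorable prognostic
subgroup that would confound the predictive analysis), dichotomization of
continuous scores at a cut-off, ROC evaluation of a binary predictor
against survival landmarks, a scan over candidate cut-offs, Kaplan–Meier /
log-rank group comparison, multivariable Cox regression, method-comparison
correlations, and table-style cohort summaries.

Survival machinery (product-limit estimate, log-rank, Cox with Efron tie
handling) is delegated to lifelines behind this module's interface.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times
from scipy import stats

from .errors import CohortFormatError, UndefinedStatisticError
from .util import round_half_away

__all__ = [
    "PatientRecord",
    "SurvivalCurve",
    "CoxResult",
    "CutoffScanResult",
    "COHORT_COLUMNS",
    "filter_idh1_wildtype",
    "dichotomize",
    "binary_roc_auc",
    "scan_cutoffs",
    "km_estimate",
    "logrank_test",
    "cox_model",
    "correlate",
    "summarize_cohort",
    "survival_summary",
]

COHORT_COLUMNS = [
    "patient_id", "age", "sex", "who_grade", "idh1_status", "karnofsky",
    "hrm_percent", "psq_percent", "msp_status",
    "pfs_months", "pfs_event", "os_months", "os_event",
]


@dataclass(frozen=True)
class PatientRecord:
    """One patient's demographics, assay results, and follow-up."""

    patient_id: str
    age: float
    sex: str  # woman | man
    who_grade: str  # III | IV
    idh1_status: str  # wildtype | mutant
    karnofsky: float | None
    hrm_percent: float
    psq_percent: float
    msp_status: str  # methylated | unmethylated
    pfs_months: float
    pfs_event: int
    os_months: float
    os_event: int


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=COHORT_COLUMNS)


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan–Meier step function with risk-set bookkeeping."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    median: float  # nan when the curve never reaches 0.5

    def rate_at(self, t: float) -> float:
        """S(t): survival probability at time t (step function, right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CoxResult:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class CutoffScanResult:
    cutoffs: tuple[float, ...]
    auc_pfs: tuple[float, ...]
    auc_os: tuple[float, ...]
    best_cutoff: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cutoff": self.cutoffs, "auc_pfs": self.auc_pfs, "auc_os": self.auc_os}
        )


# ---------------------------------------------------------------------------
# filtering and dichotomization
# ---------------------------------------------------------------------------

def filter_idh1_wildtype(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop IDH1-mutant patients, preserving row order.

    IDH1-mutant gliomas have distinctly better prognosis and are strongly
    co-methylated, so they are excluded before any survival modelling.
    """
    status = cohort["idh1_status"]
    missing = cohort.loc[status.isna() | ~status.isin(["wildtype", "mutant"]), "patient_id"]
    if len(missing):
        raise CohortFormatError(
            f"missing/invalid idh1_status for patients: {list(missing)}"
        )
    return cohort.loc[status == "wildtype"].copy()


def dichotomize(percent: float, cutoff: float) -> str:
    """'methylated' iff the continuous score is >= the cut-off."""
    if not 0.0 < cutoff < 100.0:
        raise ValueError("cutoff must lie in (0, 100)")
    return "methylated" if percent >= cutoff else "unmethylated"


def _meth_indicator(cohort: pd.DataFrame, assay: str, cutoff: float) -> pd.Series:
    assay = assay.upper()
    if assay == "HRM":
        return (cohort["hrm_percent"] >= cutoff).astype(int)
    if assay == "PSQ":
        return (cohort["psq_percent"] >= cutoff).astype(int)
    if assay == "MSP":
        return (cohort["msp_status"] == "methylated").astype(int)
    raise ValueError(f"unknown assay {assay!r}")


# ---------------------------------------------------------------------------
# ROC over a binary predictor
# ---------------------------------------------------------------------------

def binary_roc_auc(predictor: Sequence[bool], outcome: Sequence[bool]) -> float:
    """ROC AUC of a single-threshold (binary) predictor.

    For an already-dichotomized predictor the ROC has a single interior
    point, so the trapezoidal AUC reduces to (sensitivity + specificity)/2.
    A positive outcome is survival meeting the landmark; a positive
    prediction is a methylated call.
    """
    pred = np.asarray(predictor, bool)
    out = np.asarray(outcome, bool)
    if pred.size != out.size:
        raise ValueError("predictor and outcome must be the same length")
    n_pos, n_neg = int(out.sum()), int((~out).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("both outcome classes must be present for ROC")
    sens = float((pred & out).sum()) / n_pos
    spec = float((~pred & ~out).sum()) / n_neg
    return (sens + spec) / 2.0


def _landmark_outcome(months: pd.Series, event: pd.Series, threshold: float) -> pd.Series:
    """Survival >= threshold, NaN where unknowable (censored before it)."""
    reached = months >= threshold
    failed_before = (months < threshold) & (event == 1)
    out = pd.Series(np.nan, index=months.index, dtype=float)
    out[reached] = 1.0
    out[failed_before] = 0.0
    return out


def scan_cutoffs(
    cohort: pd.DataFrame,
    cutoffs: Sequence[float] = tuple(range(1, 16)),
    pfs_threshold: float = 12.0,
    os_threshold: float = 18.0,
    objective: str = "pfs",
) -> CutoffScanResult:
    """ROC AUC of the HRM call at each candidate cut-off, for both landmarks.

    Patients censored before a landmark without an event are excluded from
    that landmark's ROC (their outcome is unknowable).  The best cut-off
    maximizes the PFS AUC with the OS AUC as tie-break (``objective='sum'``
    maximizes the sum instead); remaining ties go to the smallest cut-off.
    """
    if len(cutoffs) == 0:
        raise ValueError("cutoff list must be non-empty")
    out_pfs = _landmark_outcome(cohort["pfs_months"], cohort["pfs_event"], pfs_threshold)
    out_os = _landmark_outcome(cohort["os_months"], cohort["os_event"], os_threshold)
    auc_pfs, auc_os = [], []
    for c in cutoffs:
        pred = cohort["hrm_percent"] >= c
        m_p = out_pfs.notna()
        m_o = out_os.notna()
        auc_pfs.append(binary_roc_auc(pred[m_p], out_pfs[m_p].astype(bool)))
        auc_os.append(binary_roc_auc(pred[m_o], out_os[m_o].astype(bool)))
    if objective == "pfs":
        keys = [(auc_pfs[i], auc_os[i], -c) for i, c in enumerate(cutoffs)]
    elif objective == "sum":
        keys = [(auc_pfs[i] + auc_os[i], -c) for i, c in enumerate(cutoffs)]
    else:
        raise ValueError("objective must be 'pfs' or 'sum'")
    best = max(range(len(cutoffs)), key=lambda i: keys[i])
    return CutoffScanResult(
        cutoffs=tuple(float(c) for c in cutoffs),
        auc_pfs=tuple(auc_pfs),
        auc_os=tuple(auc_os),
        best_cutoff=float(cutoffs[best]),
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate of the survival function."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if t.size == 0:
        raise ValueError("need at least one observation")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    timeline = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(float)
    below = timeline[surv <= 0.5]
    median = float(below[0]) if below.size else float("nan")
    return SurvivalCurve(
        times=timeline,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(t[e == 0]),
        median=median,
    )


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[int]],
    group_b: tuple[Sequence[float], Sequence[int]],
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and two-sided p-value."""
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], int)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise UndefinedStatisticError("log-rank undefined with no events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


_DEFAULT_COVARIATES = ("methylated", "woman", "age_lt_70", "grade_iii")


def cox_model(
    cohort: pd.DataFrame,
    outcome: str = "OS",
    assay: str = "HRM",
    cutoff: float = 5.0,
    covariates: Sequence[str] = _DEFAULT_COVARIATES,
) -> list[CoxResult]:
    """Multivariable Cox proportional-hazards fit (Efron tie handling).

    Covariates are 0/1 indicators: ``methylated`` (assay call at the
    cut-off), ``woman``, ``age_lt_70``, ``grade_iii``.  Effects are reported
    as hazard ratios with Wald 95 % CIs and p-values, so HR < 1 for the
    methylated indicator means methylated patients progress/die more slowly.
    """
    outcome = outcome.upper()
    if outcome not in ("OS", "PFS"):
        raise ValueError("outcome must be 'OS' or 'PFS'")
    dur_col, evt_col = (("os_months", "os_event") if outcome == "OS"
                        else ("pfs_months", "pfs_event"))
    if int(cohort[evt_col].sum()) < 2:
        raise UndefinedStatisticError("need at least 2 events for Cox regression")

    design = pd.DataFrame(index=cohort.index)
    builders = {
        "methylated": lambda: _meth_indicator(cohort, assay, cutoff),
        "woman": lambda: (cohort["sex"] == "woman").astype(int),
        "age_lt_70": lambda: (cohort["age"] < 70).astype(int),
        "grade_iii": lambda: (cohort["who_grade"] == "III").astype(int),
    }
    for cov in covariates:
        if cov in builders:
            design[cov] = builders[cov]()
        elif cov in cohort.columns:
            design[cov] = cohort[cov]
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    # drop constant columns (separation-by-degeneracy) with a clear message
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        raise UndefinedStatisticError(f"covariates with no variation: {constant}")

    df = design.copy()
    df["duration"] = cohort[dur_col].to_numpy(float)
    df["event"] = cohort[evt_col].to_numpy(int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="duration", event_col="event")
    except Exception as exc:  # convergence failure / separation
        raise UndefinedStatisticError(f"Cox fit failed: {exc}") from exc
    summ = cph.summary
    return [
        CoxResult(
            covariate=str(name),
            hazard_ratio=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p_value=float(row["p"]),
        )
        for name, row in summ.iterrows()
    ]


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> tuple[float, float]:
    """Two-sided Spearman or Pearson correlation between two score vectors."""
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("values must be finite")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    if method == "spearman":
        r, p = stats.spearmanr(xa, ya)
    elif method == "pearson":
        r, p = stats.pearsonr(xa, ya)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(r), float(p)


# ---------------------------------------------------------------------------
# table-style summaries
# ---------------------------------------------------------------------------

def summarize_cohort(
    cohort: pd.DataFrame, cutoff: float = 5.0, psq_cutoff: float = 8.0
) -> pd.DataFrame:
    """Per-stratum methylation percentages by assay, plus percent IDH1-mutant.

    Strata: all patients, sex, age >= 70 / < 70, WHO grade.  Continuous
    assays are dichotomized at their cut-offs (HRM at ``cutoff``, PSQ at
    ``psq_cutoff``); percentages are reported to one decimal.
    """
    if cohort.empty:
        raise ValueError("cohort must be non-empty")
    strata = {
        "all": pd.Series(True, index=cohort.index),
        "woman": cohort["sex"] == "woman",
        "man": cohort["sex"] == "man",
        "age_ge_70": cohort["age"] >= 70,
        "age_lt_70": cohort["age"] < 70,
        "grade_iii": cohort["who_grade"] == "III",
        "grade_iv": cohort["who_grade"] == "IV",
    }
    hrm = _meth_indicator(cohort, "HRM", cutoff)
    psq = _meth_indicator(cohort, "PSQ", psq_cutoff)
    msp = _meth_indicator(cohort, "MSP", cutoff)
    idh = (cohort["idh1_status"] == "mutant").astype(int)
    rows = []
    for name, mask in strata.items():
        n = int(mask.sum())
        pct = lambda ind: round_half_away(100.0 * ind[mask].mean(), 1) if n else float("nan")
        rows.append(
            {
                "stratum": name,
                "n": n,
                "hrm_me_pct": pct(hrm),
                "msp_me_pct": pct(msp),
                "psq_me_pct": pct(psq),
                "idh1_mut_pct": pct(idh),
            }
        )
    return pd.DataFrame(rows)


def _median_with_ci(times: np.ndarray, events: np.ndarray) -> tuple[float, float, float]:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    med = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo = float(ci.iloc[0, 0])
    hi = float(ci.iloc[0, 1])
    return med, lo, hi


def survival_summary(
    cohort: pd.DataFrame, cutoff: float = 5.0, assay: str = "HRM"
) -> pd.DataFrame:
    """Median PFS/OS (with 95 % CI) and landmark rates per methylation status.

    Reports, for the methylated and unmethylated groups under the given
    assay call: median PFS and OS in months with Brookmeyer–Crowley-style
    95 % confidence intervals (inversion of the pointwise survival CI), the
    PFS rate at 6 months, and the OS rate at 18 months.
    """
    meth = _meth_indicator(cohort, assay, cutoff).astype(bool)
    rows = []
    for status, mask in (("methylated", meth), ("unmethylated", ~meth)):
        n = int(mask.sum())
        row: dict[str, object] = {"status": status, "n": n, "empty": n == 0}
        if n == 0:
            rows.append(row)
            continue
        sub = cohort[mask]
        for label, (dc, ec, landmark) in {
            "pfs": (("pfs_months", "pfs_event", 6.0)),
            "os": (("os_months", "os_event", 18.0)),
        }.items():
            t = sub[dc].to_numpy(float)
            e = sub[ec].to_numpy(int)
            med, lo, hi = _median_with_ci(t, e)
            curve = km_estimate(t, e)
            row[f"{label}_median"] = med
            row[f"{label}_ci_low"] = lo
            row[f"{label}_ci_high"] = hi
            row[f"{label}_rate_pct"] = round_half_away(100.0 * curve.rate_at(landmark), 1)
        rows.append(row)
    return pd.DataFrame(rows)
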