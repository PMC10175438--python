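"""Prognostic stratification and survival statistics for the 3D gap area.

Implements the clinical decision layer: prognostic group classification
(excellent / good / moderate / poor by gap-area boundaries 150 / 550 /
1000 mm²), ROC analysis with Youden's J cut-off selection (critical
cut-off 550 mm²), Kaplan–Meier native-knee survivorship, log-rank group
comparison, and Cox proportional-hazards adjustment for age, sex,
smoking, BMI and inadequate articular reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn import metrics as _skmetrics
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "GROUP_BOUNDARIES",
    "CRITICAL_CUTOFF_MM2",
    "PROGNOSTIC_GROUPS",
    "REFERENCE_CUTOFF_TABLE",
    "classify_prognosis",
    "high_risk_flag",
    "youden_j",
    "roc_curve",
    "build_cutoff_table",
    "select_cutoff",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "reduction_adequacy",
    "KMCurve",
    "CoxFit",
    "ROCResult",
    "LogrankResult",
]

#: Gap-area boundaries (mm²) between excellent/good, good/moderate,
#: moderate/poor prognostic groups.
GROUP_BOUNDARIES: tuple[float, float, float] = (150.0, 550.0, 1000.0)

#: Critical cut-off (mm²) flagging high risk of conversion to TKA.
CRITICAL_CUTOFF_MM2: float = 550.0

PROGNOSTIC_GROUPS: tuple[str, ...] = ("excellent", "good", "moderate", "poor")

#: Operating points (cut-off mm², sensitivity %, specificity %, Youden's J)
#: reported for the 3D gap area in the clinical cohort that introduced the
#: measure; used as a worked reference for cut-off selection.
REFERENCE_CUTOFF_TABLE = pd.DataFrame(
    {
        "cutoff_mm2": [150.0, 350.0, 550.0, 750.0, 950.0],
        "sensitivity_pct": [91.5, 81.4, 76.3, 59.3, 49.2],
        "specificity_pct": [41.4, 61.7, 73.9, 81.2, 86.3],
        "youden_j": [0.33, 0.43, 0.50, 0.41, 0.36],
    }
)


def classify_prognosis(
    gap_area: float, boundaries: tuple[float, float, float] = GROUP_BOUNDARIES
) -> str:
    """Prognostic group of a gap area (half-open intervals).

    <= b0 → excellent; (b0, b1] → good; (b1, b2] → moderate; > b2 → poor.
    The published ranges are printed as integers (0–150, 151–550, …);
    measured areas are continuous, hence the half-open convention.
    """
    if gap_area < 0:
        raise ValueError("gap area must be non-negative")
    b0, b1, b2 = boundaries
    if not b0 < b1 < b2:
        raise ValueError("boundaries must be strictly increasing")
    if gap_area <= b0:
        return "excellent"
    if gap_area <= b1:
        return "good"
    if gap_area <= b2:
        return "moderate"
    return "poor"


def high_risk_flag(gap_area: float, cutoff: float = CRITICAL_CUTOFF_MM2) -> bool:
    """True when the gap area is at or above the critical cut-off (>= 550 mm²).

    Note the published convention places 550 mm² itself both in the "good"
    range (151–550) and at the high-risk flag (>= 550); both behaviours are
    kept verbatim, so exactly at the cut-off the flag is high-risk while
    the group is "good".
    """
    if gap_area < 0:
        raise ValueError("gap area must be non-negative")
    return gap_area >= cutoff


def youden_j(sensitivity: float, specificity: float) -> float:
    """Youden's J statistic: sensitivity + specificity − 1 (proportions)."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    return sensitivity + specificity - 1.0


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_curve(scores, labels) -> ROCResult:
    """Empirical ROC of gap area vs event, higher score = more positive.

    Thresholds are the observed score values (plus a sentinel above the
    maximum); a case is called positive when score >= threshold.  AUC by
    the trapezoidal rule.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = _skmetrics.roc_curve(
        labels, scores, drop_intermediate=False
    )
    auc = float(_skmetrics.auc(fpr, tpr))
    return ROCResult(
        thresholds=thresholds, sensitivity=tpr, specificity=1.0 - fpr, auc=auc
    )


def build_cutoff_table(scores, labels, candidates=None) -> pd.DataFrame:
    """Sensitivity/specificity/Youden table over candidate cut-offs.

    Positive call: score >= cut-off (larger gap area → higher risk).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if candidates is None:
        candidates = np.unique(scores)
    rows = []
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    for c in np.asarray(candidates, dtype=float):
        called = scores >= c
        sens = float(np.sum(called & labels)) / n_pos
        spec = float(np.sum(~called & ~labels)) / n_neg
        rows.append(
            {
                "cutoff_mm2": float(c),
                "sensitivity_pct": 100.0 * sens,
                "specificity_pct": 100.0 * spec,
                "youden_j": youden_j(sens, spec),
            }
        )
    return pd.DataFrame(rows)


def select_cutoff(table_or_scores, labels=None) -> float:
    """Critical cut-off: the candidate maximizing Youden's J (ties → smallest).

    Accepts either a cut-off table (as from :func:`build_cutoff_table`,
    needing ``cutoff_mm2`` plus either ``youden_j`` or the sensitivity/
    specificity percentage columns) or raw scores + labels.
    """
    if labels is not None:
        table = build_cutoff_table(table_or_scores, labels)
    else:
        table = pd.DataFrame(table_or_scores)
    if len(table) == 0:
        raise ValueError("no candidate cut-offs")
    if "youden_j" in table.columns:
        j = table["youden_j"].to_numpy(dtype=float)
    else:
        j = (
            table["sensitivity_pct"].to_numpy(dtype=float)
            + table["specificity_pct"].to_numpy(dtype=float)
        ) / 100.0 - 1.0
    cutoffs = table["cutoff_mm2"].to_numpy(dtype=float)
    best = j.max()
    return float(cutoffs[np.isclose(j, best)].min())


@dataclass
class KMCurve:
    """Product-limit (Kaplan–Meier) survival curve."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _km_single(times, events) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    grid = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    at_risk = tbl["at_risk"].to_numpy(dtype=int)
    censor_times = np.asarray(times, dtype=float)[~np.asarray(events, dtype=bool)]
    return KMCurve(times=grid, survival=surv, at_risk=at_risk, censor_times=censor_times)


def km_estimate(times, events, groups=None):
    """Kaplan–Meier estimate, overall or per group.

    ``events`` is 1 for TKA conversion, 0 for censoring at end of
    follow-up.  With ``groups`` returns a dict group -> KMCurve.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if len(times) == 0:
        raise ValueError("empty group")
    if np.any(times <= 0):
        raise ValueError("follow-up times must be positive")
    if groups is None:
        return _km_single(times, events)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            raise ValueError("empty group")
        out[g] = _km_single(times[sel], events[sel])
    return out


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(groups) -> LogrankResult:
    """Log-rank test across two or more groups of (times, events)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for k, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e).astype(int)
        if len(t) == 0:
            raise ValueError("empty group")
        times.append(t)
        events.append(e)
        labels.append(np.full(len(t), k))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
    )


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary."""

    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    converged: bool
    separation_suspected: bool
    n: int
    n_events: int
    ties: str

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hazard_ratios,
                "HR 95% CI lower": self.ci_lower,
                "HR 95% CI upper": self.ci_upper,
                "p": self.p_values,
            },
            index=self.covariates,
        )


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "followup_years",
    event_col: str = "tka",
    ties: str = "breslow",
) -> CoxFit:
    """Cox proportional-hazards regression (partial likelihood).

    ``records`` must contain the duration, event indicator and covariate
    columns; categorical covariates must already be coded numerically.
    Breslow tie handling by default ("efron" available).  Raises on
    constant covariates and flags suspected complete separation (runaway
    coefficients) rather than reporting it silently.
    """
    df = pd.DataFrame(records)
    for col in (duration_col, event_col, *covariates):
        if col not in df.columns:
            raise KeyError(f"missing column {col!r}")
    if int(df[event_col].sum()) < 1:
        raise ValueError("need at least one event")
    exog = df[covariates].to_numpy(dtype=float)
    for j, name in enumerate(covariates):
        if np.ptp(exog[:, j]) == 0:
            raise ValueError(f"no variation in covariate {name!r}")
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")

    model = PHReg(
        df[duration_col].to_numpy(dtype=float),
        exog,
        status=df[event_col].to_numpy(dtype=int),
        ties=ties,
    )
    res = model.fit(maxiter=100)
    coef = np.asarray(res.params)
    se = np.asarray(res.bse)
    if not np.all(np.isfinite(coef)) or not np.all(np.isfinite(se)):
        raise RuntimeError("Cox fit did not converge: non-finite estimates")
    z = 1.959963984540054
    hr = np.exp(coef)
    ci_lo = np.exp(coef - z * se)
    ci_hi = np.exp(coef + z * se)
    separation = bool(np.any(np.abs(coef) > 20) or np.any(se > 100))
    return CoxFit(
        covariates=list(covariates),
        coef=coef,
        se=se,
        hazard_ratios=hr,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        p_values=np.asarray(res.pvalues),
        log_likelihood=float(model.loglike(coef)),
        converged=bool(np.all(np.isfinite(coef))),
        separation_suspected=separation,
        n=len(df),
        n_events=int(df[event_col].sum()),
        ties=ties,
    )


def reduction_adequacy(max_gap: float, max_stepoff: float) -> bool:
    """Articular reduction adequacy: both residual gap and step-off <= 2 mm."""
    if max_gap < 0 or max_stepoff < 0:
        raise ValueError("gap and step-off must be non-negative")
    return max_gap <= 2.0 and max_stepoff <= 2.0
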