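"""Endpoint construction and cohort-level survival statistics.

Implements the composite cardiac endpoint with its severity hierarchy
(HF hospitalization < sustained ventricular tachyarrhythmia < cardiac death),
the Kaplan-Meier estimator and log-rank test, Cox proportional-hazards fits
(Efron ties, Wald confidence intervals, Harrell's C), nested-model likelihood
ratio tests for incremental prognostic value, number-needed-to-treat effect
sizes, dichotomization with a deterministic tie rule, and the 18-segment
3D-echo image quality score.

Model fitting is delegated to lifelines; this module defines the result
containers and endpoint/effect-size logic around it.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import chi2 as chi2_dist

from .errors import SchemaError, StatsError

__all__ = [
    "EVENT_SEVERITY",
    "EndpointRecord",
    "composite_endpoint",
    "endpoint_table",
    "KMEstimate",
    "km_estimate",
    "logrank_test",
    "SurvivalFit",
    "cox_fit",
    "nested_lrt",
    "nnt_binary",
    "nnt_continuous",
    "auc",
    "dichotomize",
    "QualityScore",
    "image_quality_score",
    "ADJUSTMENT_SETS",
]

#: severity order of composite-endpoint components (higher = harder event)
EVENT_SEVERITY: dict[str, int] = {
    "hf_hospitalization": 1,
    "ventricular_tachyarrhythmia": 2,
    "cardiac_death": 3,
}

#: named multivariate adjustment sets (age, CKD, LV systolic + one diastolic index)
ADJUSTMENT_SETS: dict[str, list[str]] = {
    "e_over_e_prime": ["age", "ckd", "lvef_3d", "e_over_e_prime"],
    "lavi": ["age", "ckd", "lvef_3d", "lavi_max"],
    "tapse": ["age", "ckd", "lvef_3d", "tapse"],
}


@dataclass(frozen=True)
class EndpointRecord:
    """One subject's time-to-event record after hierarchy selection."""

    subject_id: str
    time_months: float
    status: int  # 1 = event, 0 = censored
    label: str  # hierarchy-selected event type, or "none"

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise StatsError(f"time_months must be > 0, got {self.time_months}")
        if self.status == 1 and self.label == "none":
            raise StatsError("status=1 requires an event label")


def composite_endpoint(
    events: Iterable[tuple[str, float]],
    followup_months: float,
    subject_id: str = "",
) -> EndpointRecord:
    """Collapse a subject's event list to one composite-endpoint record.

    The record label is the severity-maximal event; the time is the first
    qualifying event (standard time-to-first-event convention). With no
    qualifying event the subject is censored at the end of follow-up.
    """
    events = list(events)
    for label, t in events:
        if label not in EVENT_SEVERITY:
            raise StatsError(f"unknown event type {label!r}")
        if t < 0:
            raise StatsError(f"negative event time {t} for {label!r}")
        if t > followup_months:
            raise StatsError(f"event at {t} after end of follow-up {followup_months}")
    if not events:
        return EndpointRecord(subject_id, followup_months, 0, "none")
    label = max(events, key=lambda e: EVENT_SEVERITY[e[0]])[0]
    time = min(t for _, t in events)
    return EndpointRecord(subject_id, time, 1, label)


def endpoint_table(cohort: pd.DataFrame, endpoint: str = "composite") -> pd.DataFrame:
    """Build a (time_months, status) table from a cohort with event labels.

    ``endpoint='composite'`` counts any component event; ``endpoint='hf'``
    counts only HF hospitalization (the secondary endpoint), with all other
    trajectories censored at their follow-up end.
    """
    for col in ("followup_months", "event"):
        if col not in cohort.columns:
            raise SchemaError(f"cohort table missing required column {col!r}")
    if endpoint == "composite":
        status = (cohort["event"] != "none").astype(int)
    elif endpoint == "hf":
        status = (cohort["event"] == "hf_hospitalization").astype(int)
    else:
        raise StatsError(f"unknown endpoint {endpoint!r}")
    out = pd.DataFrame(
        {
            "subject_id": cohort["id"] if "id" in cohort else np.arange(len(cohort)),
            "time_months": cohort["followup_months"].astype(float),
            "status": status,
            "label": cohort["event"],
        }
    )
    if (out["time_months"] <= 0).any():
        raise StatsError("all follow-up times must be > 0")
    return out


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve plus median follow-up (reverse KM)."""

    times: np.ndarray
    survival: np.ndarray
    median_followup: float

    def at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMEstimate:
    """Kaplan-Meier product-limit estimate with right censoring.

    Median follow-up is computed by the reverse Kaplan-Meier method
    (censoring treated as the event of interest).
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if len(t) == 0:
        raise StatsError("no records")
    if (t <= 0).all():
        raise StatsError("all subjects censored at t = 0")
    kmf = KaplanMeierFitter().fit(t, e)
    sf = kmf.survival_function_
    rev = KaplanMeierFitter().fit(t, 1 - e)
    return KMEstimate(
        times=sf.index.to_numpy(float),
        survival=sf.iloc[:, 0].to_numpy(float),
        median_followup=float(rev.median_survival_time_),
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns (chi2, p)."""
    if len(times_a) == 0 or len(times_b) == 0:
        raise StatsError("both groups must be non-empty")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class SurvivalFit:
    """Cox PH fit summary: per-covariate log-HRs with Wald CIs, and model stats."""

    covariates: tuple[str, ...]
    coefficients: dict[str, float]
    hr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    p: dict[str, float]
    loglik: float
    n: int
    n_events: int
    c_statistic: float

    def covers(self, name: str, hazard_ratio: float) -> bool:
        """Whether the 95% CI for ``name`` covers a given hazard ratio."""
        lo, hi = self.ci95[name]
        return lo <= hazard_ratio <= hi

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "coefficients": self.coefficients,
            "hr": self.hr,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "p": self.p,
            "loglik": self.loglik,
            "n": self.n,
            "n_events": self.n_events,
            "c_statistic": self.c_statistic,
        }


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time_months",
    event_col: str = "status",
) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron tie handling, Wald CIs, Harrell's C)."""
    covariates = list(covariates)
    if not covariates:
        raise StatsError("at least one covariate required")
    for c in covariates:
        if c not in records.columns:
            raise SchemaError(f"records missing covariate column {c!r}")
        if np.ptp(records[c].to_numpy(float)) == 0:
            raise StatsError(f"covariate {c!r} is constant")
    n_events = int(records[event_col].sum())
    if n_events < len(covariates) + 1:
        raise StatsError(
            f"{n_events} events insufficient for {len(covariates)} covariates"
        )
    df = records[[duration_col, event_col] + covariates].astype(float)
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise StatsError(f"Cox fit failed to converge: {exc}") from exc
    summ = fitter.summary
    return SurvivalFit(
        covariates=tuple(covariates),
        coefficients={c: float(summ.loc[c, "coef"]) for c in covariates},
        hr={c: float(summ.loc[c, "exp(coef)"]) for c in covariates},
        ci95={
            c: (
                float(summ.loc[c, "exp(coef) lower 95%"]),
                float(summ.loc[c, "exp(coef) upper 95%"]),
            )
            for c in covariates
        },
        p={c: float(summ.loc[c, "p"]) for c in covariates},
        loglik=float(fitter.log_likelihood_),
        n=len(df),
        n_events=n_events,
        c_statistic=float(fitter.concordance_index_),
    )


def nested_lrt(fit_small: SurvivalFit, fit_large: SurvivalFit) -> tuple[float, int, float]:
    """Likelihood-ratio test between nested Cox models on the same records.

    Returns (delta chi2, df, p) with delta = 2 (loglik_large - loglik_small).
    """
    if not set(fit_small.covariates) <= set(fit_large.covariates):
        raise StatsError("models are not nested (small covariates not a subset)")
    if (fit_small.n, fit_small.n_events) != (fit_large.n, fit_large.n_events):
        raise StatsError("nested models must be fitted on the same records")
    df = len(fit_large.covariates) - len(fit_small.covariates)
    delta = 2.0 * (fit_large.loglik - fit_small.loglik)
    p = 1.0 if df == 0 else float(chi2_dist.sf(max(delta, 0.0), df))
    return float(delta), df, p


def nnt_binary(risk_a: float, risk_b: float) -> float:
    """Number needed to treat from two absolute event risks: 1 / |r_a - r_b|."""
    diff = abs(risk_a - risk_b)
    return float("inf") if diff == 0 else 1.0 / diff


def nnt_continuous(auc_value: float) -> float:
    """NNT for a continuous marker from its AUC: 1 / (2 AUC - 1)."""
    denom = 2.0 * auc_value - 1.0
    return float("inf") if denom == 0 else 1.0 / denom


def auc(values: Sequence[float], outcome: Sequence[int]) -> float:
    """Area under the ROC curve of a marker against a binary outcome.

    Oriented so that AUC >= 0.5 (the marker's direction is not assumed).
    """
    from sklearn.metrics import roc_auc_score

    a = float(roc_auc_score(np.asarray(outcome, int), np.asarray(values, float)))
    return max(a, 1.0 - a)


def dichotomize(values: Sequence[float], cutoff: float, direction: str = "<") -> np.ndarray:
    """Boolean mask of the at-risk group; values equal to the cutoff go to '>='.

    ``direction='<'`` flags subjects strictly below the cutoff (e.g. RVEF < 45);
    ``direction='>'`` flags subjects strictly above it (e.g. LAVI > 34).
    """
    v = np.asarray(values, float)
    if not np.isfinite(cutoff):
        raise StatsError("cutoff must be finite")
    if direction == "<":
        mask = v < cutoff
    elif direction == ">":
        mask = v > cutoff
    else:
        raise StatsError(f"direction must be '<' or '>', got {direction!r}")
    if mask.all() or not mask.any():
        warnings.warn(f"dichotomize at {cutoff} produced an empty group")
    return mask


@dataclass(frozen=True)
class QualityScore:
    """18-segment endocardial visualization score (0 / 0.5 / 1 per segment)."""

    segments: tuple[float, ...]
    total: float
    category: str

    @property
    def excluded(self) -> bool:
        """Extremely poor image quality mandates exclusion from analysis."""
        return self.category == "extremely_poor"


def image_quality_score(segment_scores: Sequence[float]) -> QualityScore:
    """Total image quality score and category.

    Each of 18 segments scores 0 (no endocardial visualization), 0.5 (partial
    visualization during one cycle) or 1 (complete visualization); the total
    (0-18) is categorized as good (>= 16), fair (13 <= s < 16),
    poor (10 <= s < 13) or extremely poor (< 10).
    """
    scores = tuple(float(s) for s in segment_scores)
    if len(scores) != 18:
        raise SchemaError(f"expected 18 segment scores, got {len(scores)}")
    if any(s not in (0.0, 0.5, 1.0) for s in scores):
        raise SchemaError("segment scores must be 0, 0.5 or 1")
    total = sum(scores)
    if total >= 16:
        category = "good"
    elif total >= 13:
        category = "fair"
    elif total >= 10:
        category = "poor"
    else:
        category = "extremely_poor"
    return QualityScore(scores, total, category)
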