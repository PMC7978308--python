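"""Therapy-outcome evaluation for biomarker-guided treatment.

Best response follows RECIST v1.1 categories (CR, PR, SD, PD); a responder
is CR or PR, and the objective response rate (ORR) is the responder fraction
among all treated patients, reported as a half-up one-decimal percent.

Progression-free survival on the matched therapy (PFS2) is compared with
PFS on the immediately prior unmatched line (PFS1): a ratio
PFS2/PFS1 >= 1.3 defines therapeutic benefit (Von Hoff criterion).  Patients
with unmeasurable PFS1 have an undefined ratio and are excluded from the
benefit denominator.

Survival curves use the Kaplan-Meier product-limit estimator (events before
censorings at tied times); group comparisons use the one-degree-of-freedom
log-rank test.  Both are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from lifelines.utils import median_survival_times

logger = logging.getLogger(__name__)

RESPONDER_CLASSES = frozenset({"CR", "PR"})
BENEFIT_RATIO_THRESHOLD = 1.3


def classify_response_and_orr(best_responses: list[str] | pd.Series) -> dict:
    """Responder coding and ORR over all treated patients.

    Returns ``{"n_treated", "n_responders", "orr_percent"}``; the percent is
    rounded half-up to one decimal (12 of 46 -> 26.1).
    """
    from .pipeline import percent

    responses = list(best_responses)
    if not responses:
        raise ValueError("no treated patients")
    bad = sorted(set(responses) - {"CR", "PR", "SD", "PD"})
    if bad:
        raise ValueError(f"unknown best_response value(s): {bad}")
    n_resp = sum(1 for r in responses if r in RESPONDER_CLASSES)
    return {
        "n_treated": len(responses),
        "n_responders": n_resp,
        "orr_percent": percent(n_resp, len(responses)),
    }


def pfs_ratio_benefit(
    pfs2_months: float, pfs1_months: float | None
) -> tuple[float | None, bool | None]:
    """PFS2/PFS1 ratio and benefit flag (ratio >= 1.3, boundary inclusive).

    With PFS1 missing both are ``None`` and the patient drops out of the
    benefit denominator.
    """
    if pfs2_months is None or not pfs2_months > 0:
        raise ValueError(f"pfs2_months must be positive, got {pfs2_months}")
    if pfs1_months is None or (isinstance(pfs1_months, float) and np.isnan(pfs1_months)):
        return None, None
    if not pfs1_months > 0:
        raise ValueError(f"pfs1_months must be positive, got {pfs1_months}")
    ratio = pfs2_months / pfs1_months
    return ratio, ratio >= BENEFIT_RATIO_THRESHOLD


def evaluate_benefit(outcomes: pd.DataFrame, count_censored: bool = True) -> dict:
    """Cohort benefit summary over ratio-defined patients.

    ``outcomes`` needs columns pfs2_months, pfs1_months and (optionally)
    pfs2_event; censored PFS2 rows are excluded from the ratio when
    ``count_censored`` is false, with the exclusion count logged.
    """
    from .pipeline import percent

    df = outcomes.copy()
    if not count_censored and "pfs2_event" in df.columns:
        censored = df["pfs2_event"] == False  # noqa: E712 (may hold None)
        n_censored = int(censored.sum())
        if n_censored:
            logger.info("evaluate_benefit: excluding %d censored PFS2 value(s)", n_censored)
        df = df[~censored]
    ratios = []
    n_benefit = 0
    n_missing_pfs1 = 0
    for _, row in df.iterrows():
        ratio, benefit = pfs_ratio_benefit(row["pfs2_months"], row["pfs1_months"])
        if ratio is None:
            n_missing_pfs1 += 1
            continue
        ratios.append(ratio)
        n_benefit += bool(benefit)
    n_defined = len(ratios)
    return {
        "n_ratio_eligible": len(df),
        "n_missing_pfs1": n_missing_pfs1,
        "n_ratio_defined": n_defined,
        "n_benefit": n_benefit,
        "benefit_percent": percent(n_benefit, n_defined) if n_defined else None,
    }


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit curve with median and at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    median: float | None
    median_ci: tuple[float | None, float | None]

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, event_flags) -> SurvivalCurve:
    """Kaplan-Meier estimate; median is the first time with S(t) <= 0.5.

    The median confidence interval is the Brookmeyer-Crowley style interval
    derived from the log-log (Greenwood) survival band.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    median = kmf.median_survival_time_
    median = None if np.isinf(median) else float(median)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return SurvivalCurve(
        times=grid,
        survival=surv,
        n_at_risk=at_risk,
        median=median,
        median_ci=(None if np.isinf(lo) else lo, None if np.isinf(hi) else hi),
    )


def logrank(times, event_flags, group_labels) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test between two groups.

    Returns ``(chi_square, p_value)``.  With no events at all the statistic
    is 0 and p is 1 by convention.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    g = np.asarray(group_labels)
    groups = pd.unique(g)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    m0, m1 = g == groups[0], g == groups[1]
    if not m0.any() or not m1.any():
        raise ValueError("both groups must be non-empty")
    if not e.any():
        return 0.0, 1.0
    res = _lifelines_logrank(t[m0], t[m1], event_observed_A=e[m0], event_observed_B=e[m1])
    stat = float(res.test_statistic)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return stat, float(res.p_value)
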