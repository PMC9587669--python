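"""Kaplan-Meier estimation, log-rank testing and median-split stratification.

Estimation and testing are delegated to lifelines (product-limit estimator,
Mantel-Cox log-rank with hypergeometric variance); this module fixes the
stratification conventions: patients are split at the median of the score,
with scores exactly equal to the median assigned to the low group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .core import SurvivalTable


@dataclass
class KMEstimate:
    """Product-limit survival curve over the distinct event times."""

    event_times: np.ndarray   # ascending distinct event times
    at_risk: np.ndarray       # subjects at risk just before each event time
    survival: np.ndarray      # S(t) just after each event time
    n: int

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function lookup; S(0) = 1."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


@dataclass(frozen=True)
class LogRankResult:
    statistic: float  # chi-square, 1 df for two groups
    p: float


def km_estimate(table: SurvivalTable) -> KMEstimate:
    """Kaplan-Meier estimate; censored-at-event-time subjects stay at risk."""
    if len(table.table) == 0:
        raise ValueError("survival table is empty")
    kmf = KaplanMeierFitter()
    kmf.fit(table.time, event_observed=table.event)
    ev = kmf.event_table
    ev = ev[ev["observed"] > 0]
    times = ev.index.to_numpy(float)
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy(float)
    return KMEstimate(
        event_times=times,
        at_risk=ev["at_risk"].to_numpy(int),
        survival=surv,
        n=len(table.table),
    )


def logrank_test(group_a: SurvivalTable, group_b: SurvivalTable) -> LogRankResult:
    """Two-group Mantel-Cox log-rank test (chi-square, 1 df, two-sided)."""
    if len(group_a.table) == 0 or len(group_b.table) == 0:
        raise ValueError("both groups must be non-empty")
    if group_a.event.sum() + group_b.event.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = _lifelines_logrank(
        group_a.time, group_b.time,
        event_observed_A=group_a.event, event_observed_B=group_b.event,
    )
    return LogRankResult(statistic=float(res.test_statistic), p=float(res.p_value))


def stratify_by_median(scores: pd.Series) -> pd.Series:
    """Label patients 'high' (score > median) or 'low' (score <= median)."""
    s = scores.astype(float)
    if len(s) < 2:
        raise ValueError("need >= 2 patients to stratify")
    if s.nunique() == 1:
        raise ValueError("all scores identical; median split impossible")
    med = s.median()
    return pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")


def median_split_logrank(table: SurvivalTable, score_column: str = "score") -> tuple[LogRankResult, pd.Series]:
    """Median-split the score column and log-rank test high versus low."""
    labels = stratify_by_median(table.table[score_column])
    high = SurvivalTable(table.table[labels == "high"])
    low = SurvivalTable(table.table[labels == "low"])
    return logrank_test(high, low), labels
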