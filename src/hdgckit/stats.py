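"""Cohort statistics: Fisher exact, chi-square, BH-FDR, Kaplan-Meier, log-rank.

Thin, explicitly-conventioned wrappers over scipy, statsmodels, and
lifelines. Conventions that matter downstream:

* Fisher's exact test is two-sided by the small-p-values method (sum of
  probabilities of all same-margin tables at most as likely as the
  observed one).
* The chi-square test applies no continuity correction unless asked.
* BH q-values follow the step-up rule q_(i) = min_{j>=i} p_(j)*m/j, capped
  at 1, reported in the input order.
* Kaplan-Meier is the product-limit estimator; at tied times events
  precede censorings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "percent",
    "fisher_exact",
    "chi2_test",
    "choose_association_test",
    "bh_fdr",
    "km_estimate",
    "KaplanMeierResult",
    "logrank_test",
]


def percent(count: float, total: float, decimals: int = 1) -> float:
    """100*count/total rounded half away from zero to ``decimals`` places.

    Matches how clinical tables print percentages (e.g. 8/284 -> 2.8).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    x = 100.0 * count / total
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (small-p-values method)."""
    return float(sps.fisher_exact(table.as_array(), alternative="two-sided")[1])


def chi2_test(table: ContingencyTable2x2, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and p, without Yates correction by default."""
    stat, p, _, _ = sps.chi2_contingency(table.as_array(), correction=correction)
    return float(stat), float(p)


def choose_association_test(table: ContingencyTable2x2) -> tuple[str, float]:
    """Fisher when any expected cell is below 5, chi-square otherwise."""
    arr = table.as_array()
    expected = sps.contingency.expected_freq(arr)
    if (expected < 5).any():
        return "fisher", fisher_exact(table)
    return "chi2", chi2_test(table)[1]


def bh_fdr(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class KaplanMeierResult:
    """Survival curve with an at-risk table and a horizon estimate."""

    times: np.ndarray            # distinct event times, ascending
    survival: np.ndarray         # S(t) immediately after each event time
    at_risk: np.ndarray          # subjects at risk just before each time
    events: np.ndarray           # events at each time
    _kmf: KaplanMeierFitter

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step-function value at time t."""
        return float(self._kmf.predict(t))

    def survival_at_with_ci(self, t: float, alpha: float = 0.05) -> tuple[float, float, float]:
        """Survival at a horizon with its Greenwood-based confidence band.

        Uses the exponential-Greenwood (log(-log)) transform, which keeps
        the band inside [0, 1].
        """
        s = self.survival_at(t)
        ci = self._kmf.confidence_interval_survival_function_
        idx = ci.index.searchsorted(t, side="right") - 1
        if idx < 0:
            return s, 1.0, 1.0
        lo, hi = ci.iloc[idx, 0], ci.iloc[idx, 1]
        return s, float(min(lo, hi)), float(max(lo, hi))


def km_estimate(times, events) -> KaplanMeierResult:
    """Kaplan-Meier product-limit estimate of the survival function."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("at least one subject required")
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValueError("survival times must be finite and non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e, alpha=0.05)
    tbl = kmf.event_table
    event_rows = tbl[tbl["observed"] > 0]
    out_times = event_rows.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.predict(ti)) for ti in out_times])
    return KaplanMeierResult(
        times=out_times,
        survival=surv,
        at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        events=event_rows["observed"].to_numpy(dtype=int),
        _kmf=kmf,
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic on 1 df, p-value)."""
    ta, tb = np.asarray(times_a, dtype=float), np.asarray(times_b, dtype=float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(ta, tb, event_observed_A=np.asarray(events_a, dtype=bool),
                      event_observed_B=np.asarray(events_b, dtype=bool))
    return float(res.test_statistic), float(res.p_value)
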