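"""From-scratch survival machinery.

Kaplan-Meier product-limit estimation with Greenwood variance and
complementary-log-log confidence bands, the unstratified two-group log-rank
test, fixed-point 5-year survival status, follow-up summaries and
first-recurrence tabulations. Ties at a time point follow the standard
convention: events are processed before censorings, so a subject censored at
time t is still at risk for an event at t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord
from .utils import round_half_up

SURVIVOR = "survivor"
EVENT_BEFORE_5Y = "event_before_5y"
LOST_BEFORE_5Y = "lost_before_5y"


@dataclass
class KMCurve:
    """Kaplan-Meier estimate over the distinct event times.

    ``survival[i]`` is S(t) just after ``event_times[i]``; the curve is 1
    before the first event time. Confidence bands are pointwise 95% intervals
    on the complementary log-log scale (degenerate where S is 0 or 1).
    """

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median(self) -> float | None:
        """Smallest event time with S(t) <= 0.5, or None if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return None if below.size == 0 else float(self.event_times[below[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float


def km_estimate(times, events, level: float = 0.95) -> KMCurve:
    """Product-limit estimate of the survivor function.

    Parameters
    ----------
    times, events
        Equal-length sequences of non-negative follow-up times and event
        indicators (True = event, False = censored).
    level
        Confidence level of the pointwise bands.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("negative follow-up time")

    event_times = np.unique(t[e])
    n = t.size
    n_at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    for i, ti in enumerate(event_times):
        n_at_risk[i] = int(np.sum(t >= ti))  # censored at ti still at risk
        n_events[i] = int(np.sum(e & (t == ti)))

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - n_events / n_at_risk
    survival = np.cumprod(frac)

    # Greenwood: Var[S] = S^2 * sum d / (n (n - d)); the cumulative sum term
    # also drives the cloglog band.
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(
            n_at_risk > n_events,
            n_events / (n_at_risk * (n_at_risk - n_events).astype(float)),
            np.inf,
        )
    gw_cum = np.cumsum(gw_terms)

    z = stats.norm.ppf(0.5 + level / 2.0)
    ci_low = np.empty_like(survival)
    ci_high = np.empty_like(survival)
    for i, s in enumerate(survival):
        if s <= 0.0 or s >= 1.0 or not math.isfinite(gw_cum[i]):
            ci_low[i] = ci_high[i] = min(max(s, 0.0), 1.0)
            continue
        se_theta = math.sqrt(gw_cum[i]) / abs(math.log(s))
        ci_low[i] = s ** math.exp(z * se_theta)
        ci_high[i] = s ** math.exp(-z * se_theta)
    survival = np.clip(survival, 0.0, 1.0)
    ci_low = np.clip(ci_low, 0.0, 1.0)
    ci_high = np.clip(ci_high, 0.0, 1.0)
    return KMCurve(event_times, n_at_risk, n_events, survival, ci_low, ci_high)


def logrank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Unstratified two-group log-rank test (1 df chi-square, no continuity
    correction).

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation given the pooled risk set; the
    statistic is (O_A - E_A)^2 / V with V the summed hypergeometric variance.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")

    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    event_times = np.unique(t_all[e_all])

    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        na = int(np.sum(ta >= ti))
        nb = int(np.sum(tb >= ti))
        n = na + nb
        d = int(np.sum(e_all & (t_all == ti)))
        da = int(np.sum(ea & (ta == ti)))
        if n == 0 or d == 0:
            continue
        o_minus_e += da - d * na / n
        if n > 1:
            var += na * nb * d * (n - d) / (n * n * (n - 1.0))
    if var <= 0.0:
        return LogRankResult(0.0, 1.0)
    chi = o_minus_e * o_minus_e / var
    return LogRankResult(float(chi), float(stats.chi2.sf(chi, df=1)))


def five_year_status(record: PatientRecord, endpoint: str = "os") -> str:
    """Classify a record at the fixed 5-year landmark for OS or RFS.

    ``survivor``: no event by year 5 and follow-up reaching at least 5 years.
    ``event_before_5y``: the endpoint event occurred at t <= 5 (an event at
    exactly 5.0 counts). ``lost_before_5y``: censored with follow-up short of
    5 years (censoring at exactly 5.0 counts as adequate follow-up). An event
    after year 5 does not negate 5-year survival.
    """
    ep = endpoint.lower()
    if ep == "os":
        time, event = record.os_time_years, record.os_event
    elif ep == "rfs":
        time, event = record.rfs_time_years, record.rfs_event
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if event and time <= 5.0:
        return EVENT_BEFORE_5Y
    if time >= 5.0:
        return SURVIVOR
    return LOST_BEFORE_5Y


def median_follow_up_censored(cohort: list[PatientRecord]) -> dict[str, float]:
    """Median and IQR of follow-up among OS-censored patients.

    Follow-up duration is conventionally summarised over patients still alive
    (deaths truncate follow-up by the event, not by the observation process).
    Note a reverse-KM estimate is a common alternative; this is the plain
    censored-subset median.
    """
    t = np.array([r.os_time_years for r in cohort if not r.os_event], dtype=float)
    if t.size == 0:
        raise ValueError("no OS-censored patients in cohort")
    q25, q50, q75 = np.percentile(t, [25, 50, 75])
    return {"median": float(q50), "iqr_low": float(q25), "iqr_high": float(q75)}


def recurrence_table(cohort: list[PatientRecord]) -> dict:
    """First-recurrence site tabulation among patients recurring after R0/R1.

    Sites are counted with multiplicity per patient (a patient recurring in
    liver and lung contributes to both rows), so percentages can exceed 100 in
    total. Also reports the fraction of recurrences observed within 2 years.
    """
    recurrent = [
        r
        for r in cohort
        if r.residual in ("R0", "R1") and r.recurrence_time_years is not None
    ]
    n = len(recurrent)
    sites: dict[str, dict[str, float]] = {}
    if n:
        counts: dict[str, int] = {}
        for r in recurrent:
            for s in r.recurrence_sites:
                counts[s] = counts.get(s, 0) + 1
        for site, k in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            sites[site] = {"count": k, "percent": round_half_up(100.0 * k / n, 1)}
    within_2y = sum(1 for r in recurrent if r.recurrence_time_years <= 2.0)
    return {
        "n_recurrent": n,
        "sites": sites,
        "fraction_within_2y": (
            round_half_up(100.0 * within_2y / n, 1) if n else None
        ),
    }


def survival_after_recurrence(cohort: list[PatientRecord]) -> tuple[KMCurve, float | None]:
    """KM of time from first recurrence to death among recurrent patients.

    Returns the curve and its median (None when survival never drops to 0.5,
    i.e. the median is not reached).
    """
    recurrent = [r for r in cohort if r.recurrence_time_years is not None]
    if not recurrent:
        raise ValueError("no recurrent patients in cohort")
    bad = [r for r in recurrent if r.recurrence_time_years > r.os_time_years + 1e-12]
    if bad:
        raise ValueError(
            f"recurrence_time > os_time for patient {bad[0].patient_id}"
        )
    times = [r.os_time_years - r.recurrence_time_years for r in recurrent]
    events = [r.os_event for r in recurrent]
    curve = km_estimate(times, events)
    return curve, curve.median()
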