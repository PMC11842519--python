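"""Kaplan-Meier estimation, log-rank testing and score dichotomisation.

The product-limit estimator and the one-degree-of-freedom log-rank test are
implemented directly (they also back the power/size simulations, which need
a fast statistic).  Ties follow the simultaneous-event convention: all
deaths at a time are counted before censorings at the same time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SurvivalCurve:
    """Step-function survival estimate with at-risk bookkeeping."""

    table: pd.DataFrame  # columns: time, at_risk, events, censored, survival

    def __post_init__(self) -> None:
        s = self.table["survival"].to_numpy()
        if (np.diff(s) > 1e-12).any():
            raise ValueError("survival estimates must be non-increasing")
        if ((s < 0) | (s > 1)).any():
            raise ValueError("survival estimates must lie in [0, 1]")

    def survival_at(self, t: float) -> float:
        """S(t): survival just after time t (S(0) = 1 before any event)."""
        tab = self.table[self.table["time"] <= t]
        return float(tab["survival"].iloc[-1]) if len(tab) else 1.0


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times and events must be matching 1-D arrays")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    uniq = np.unique(times)
    n = len(times)
    rows = []
    at_risk = n
    surv = 1.0
    for t in uniq:
        mask = times == t
        d = int(events[mask].sum())
        c = int((~events[mask].astype(bool)).sum())
        if d > 0:
            surv *= 1.0 - d / at_risk
        rows.append({"time": float(t), "at_risk": at_risk, "events": d,
                     "censored": c, "survival": surv})
        at_risk -= d + c
    return SurvivalCurve(table=pd.DataFrame(rows))


def logrank_test(times_a, events_a, times_b, events_b) -> dict:
    """Two-group log-rank test: chi-square(1) on (sum(O-E))^2 / sum(V).

    O-E and the hypergeometric variance are accumulated over the pooled
    event times.  Invariant to swapping the group labels.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a).astype(int)
    eb = np.asarray(events_b).astype(int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = int((ta >= t).sum())
        n_b = int((tb >= t).sum())
        d_a = int(((ta == t) & (ea == 1)).sum())
        d_b = int(((tb == t) & (eb == 1)).sum())
        n = n_a + n_b
        d = d_a + d_b
        if n <= 1:
            continue
        e_a = d * n_a / n
        v = d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
        o_minus_e += d_a - e_a
        var += v
    if var == 0:
        return {"statistic": 0.0, "p": 1.0}
    chi2 = o_minus_e ** 2 / var
    return {"statistic": float(chi2), "p": float(stats.chi2.sf(chi2, df=1))}


def median_split(scores: pd.Series) -> pd.Series:
    """Dichotomise at the median; ties at the median go to the low group."""
    scores = pd.Series(scores)
    if scores.nunique() < 2:
        raise ValueError("all scores equal; cannot split")
    med = float(scores.median())
    labels = pd.Series(np.where(scores > med, "high", "low"),
                       index=scores.index, name="group")
    if labels.nunique() < 2:
        raise ValueError("median split produced an empty group")
    return labels


def survival_report(clinical_df: pd.DataFrame, groups: pd.Series,
                    time_col: str = "os_time", event_col: str = "os_event") -> dict:
    """KM curves per group plus the log-rank comparison of the two groups."""
    aligned = clinical_df.loc[groups.index]
    names = sorted(groups.dropna().unique())
    if len(names) != 2:
        raise ValueError(f"expected 2 groups, got {names}")
    curves = {}
    arms = []
    for g in names:
        mask = (groups == g).to_numpy()
        t = aligned.loc[mask, time_col].to_numpy(dtype=float)
        e = aligned.loc[mask, event_col].to_numpy()
        curves[g] = km_estimate(t, e)
        arms.append((t, e))
    lr = logrank_test(arms[0][0], arms[0][1], arms[1][0], arms[1][1])
    return {"curves": curves, "logrank": lr, "groups": names}
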