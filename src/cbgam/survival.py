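"""Kaplan-Meier OS/PFS estimation by molecular subtype and pairwise
cross-subtype comparison.

OS events are deaths; PFS events are progression or death.  Subtypes are
compared pairwise with the log-rank test (whose statistic is chi-squared
distributed with 1 dof) and Bonferroni correction over all pairs.  OS and
PFS are deliberately *not* endpoints of the prediction model; the survival
analysis only probes for differences across subtypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = ["KMCurve", "km_estimate", "compare_subtypes", "km_by_subtype"]


@dataclass
class KMCurve:
    """Product-limit survival estimate with at-risk and censoring bookkeeping."""

    time: np.ndarray        # event-time grid (months), starts at 0
    survival: np.ndarray    # S(t), starts at 1, non-increasing
    at_risk: np.ndarray     # number at risk entering each time
    censored: np.ndarray    # censored count at each time
    events: np.ndarray      # observed events at each time
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.time, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "survival": self.survival,
             "at_risk": self.at_risk, "events": self.events,
             "censored": self.censored}
        )


def km_estimate(times, events, label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i/n_i).

    ``events``: 1 = event (death/progression), 0 = right-censored.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    if not np.isin(np.unique(events), [0, 1]).all():
        raise ValueError("events must be binary 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or None)
    tab = kmf.event_table
    t = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(t).to_numpy(dtype=float)
    return KMCurve(
        time=t,
        survival=surv,
        at_risk=tab["at_risk"].to_numpy(dtype=int),
        censored=tab["censored"].to_numpy(dtype=int),
        events=tab["observed"].to_numpy(dtype=int),
        label=label,
    )


def _endpoint_columns(df: pd.DataFrame, endpoint: str):
    endpoint = endpoint.lower()
    if endpoint == "os":
        return df["os"].to_numpy(dtype=float), df["death"].to_numpy(dtype=int)
    if endpoint == "pfs":
        ev = ((df["progression"] == 1) | (df["death"] == 1)).astype(int)
        return df["pfs"].to_numpy(dtype=float), ev.to_numpy()
    raise ValueError("endpoint must be 'OS' or 'PFS'")


def km_by_subtype(df: pd.DataFrame, endpoint: str = "OS") -> dict:
    """One KM curve per molecular subtype for the chosen endpoint."""
    times, events = _endpoint_columns(df, endpoint)
    out = {}
    for subtype in sorted(df["subtype"].unique()):
        mask = (df["subtype"] == subtype).to_numpy()
        out[subtype] = km_estimate(times[mask], events[mask], label=str(subtype))
    return out


def compare_subtypes(df: pd.DataFrame, endpoint: str = "OS") -> pd.DataFrame:
    """Pairwise log-rank comparisons across subtypes, Bonferroni-adjusted.

    Returns one row per subtype pair with the chi-squared-distributed
    log-rank statistic, the raw p-value, and p multiplied by the number of
    pairs (capped at 1).
    """
    times, events = _endpoint_columns(df, endpoint)
    subtypes = []
    for s in sorted(df["subtype"].unique()):
        mask = (df["subtype"] == s).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"subtype {s!r} has < 2 patients; excluded", stacklevel=2)
            continue
        if times[mask].sum() == 0:
            warnings.warn(f"subtype {s!r} has zero total risk time; excluded",
                          stacklevel=2)
            continue
        subtypes.append(s)
    if len(subtypes) < 2:
        raise ValueError("need >= 2 comparable subtypes")
    pairs = [(a, b) for i, a in enumerate(subtypes) for b in subtypes[i + 1:]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        ma = (df["subtype"] == a).to_numpy()
        mb = (df["subtype"] == b).to_numpy()
        res = logrank_test(times[ma], times[mb], events[ma], events[mb])
        p = float(res.p_value)
        rows.append({
            "subtype_a": a,
            "subtype_b": b,
            "statistic": float(res.test_statistic),
            "p_value": p,
            "p_adjusted": min(1.0, m * p),
            "n_comparisons": m,
        })
    return pd.DataFrame(rows)
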