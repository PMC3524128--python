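"""Survival stratified by micro-aberration burden.

Samples are rank-ordered by micro-aberration count and split into the bottom
33% ("low" burden) vs. the top 67% ("high"); the groups' Kaplan-Meier curves
are compared with a log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io_formats import ClinicalRecord


@dataclass(frozen=True)
class SurvivalSplit:
    upper_fraction: float = 0.67
    lower_fraction: float = 0.33

    def __post_init__(self):
        if abs(self.upper_fraction + self.lower_fraction - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class KMCurve:
    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # survival just after each event time

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def rank_split(counts: pd.Series, split: SurvivalSplit = SurvivalSplit()) -> pd.Series:
    """Label samples low/high burden by ascending rank with a floor rule.

    The lowest ``floor(n * lower_fraction)`` samples are "low", the rest
    "high". Samples tied at the boundary value stay together in the group
    where that value first occurs in the ascending order (the low group), so
    the realised group sizes can deviate from the target fractions by ties.
    All-equal counts collapse to a single group with a warning.
    """
    counts = pd.Series(counts)
    if len(counts) < 2:
        raise ValueError("rank_split needs at least two samples")
    if counts.nunique() == 1:
        warnings.warn("all burden counts equal; single survival group", stacklevel=2)
        return pd.Series("low", index=counts.index, name="group")
    n_low = max(1, int(np.floor(len(counts) * split.lower_fraction)))
    order = counts.sort_values(kind="stable")
    labels = pd.Series("high", index=counts.index, name="group")
    if n_low > 0:
        boundary = order.iloc[n_low - 1]
        low_idx = order.index[: n_low]
        labels.loc[low_idx] = "low"
        # ties straddling the boundary stay with the low group
        tied = order.index[(order == boundary).to_numpy()]
        labels.loc[tied] = "low"
    return labels


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Product-limit survival estimate (censored observations shrink the risk set only)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one observation")
    if np.any(times < 0) or not set(np.unique(events)) <= {0, 1}:
        raise ValueError("times must be >= 0 and events binary")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    tab = tab[tab["observed"] > 0]
    event_times = tab.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times])
    return KMCurve(
        event_times=event_times,
        n_at_risk=tab["at_risk"].to_numpy(dtype=int),
        n_events=tab["observed"].to_numpy(dtype=int),
        survival=surv,
    )


def logrank_test(
    times_a, events_a, times_b, events_b
) -> tuple[float, float]:
    """Two-group log-rank: returns (chi-square statistic, p). Zero events -> NaN."""
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if events_a.sum() + events_b.sum() == 0:
        warnings.warn("no events in either group; log-rank undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def survival_by_burden(
    clinical: Sequence[ClinicalRecord],
    micro_counts: pd.Series,
    split: SurvivalSplit = SurvivalSplit(),
    endpoint: str = "os",
) -> dict:
    """KM curves and log-rank comparison for low vs. high micro burden.

    ``endpoint`` selects overall ("os") or relapse-free ("rfs") survival.
    Returns a dict with group labels, per-group curves, and the test result.
    """
    if endpoint not in ("os", "rfs"):
        raise ValueError("endpoint must be 'os' or 'rfs'")
    ids = [c.sample_id for c in clinical]
    counts = micro_counts.reindex(ids).fillna(0)
    groups = rank_split(counts, split)
    time_attr, event_attr = f"{endpoint}_time", f"{endpoint}_event"
    times = pd.Series({c.sample_id: getattr(c, time_attr) for c in clinical})
    events = pd.Series({c.sample_id: getattr(c, event_attr) for c in clinical})
    out = {"groups": groups, "curves": {}, "n": {}}
    for g in ("low", "high"):
        members = groups.index[groups == g]
        out["n"][g] = len(members)
        if len(members):
            out["curves"][g] = km_estimate(times[members].to_numpy(), events[members].to_numpy())
    if set(out["curves"]) == {"low", "high"}:
        lo = groups.index[groups == "low"]
        hi = groups.index[groups == "high"]
        stat, p = logrank_test(
            times[lo].to_numpy(), events[lo].to_numpy(), times[hi].to_numpy(), events[hi].to_numpy()
        )
    else:
        stat, p = float("nan"), float("nan")
    out["logrank_stat"], out["logrank_p"] = stat, p
    return out


def km_table(curve: KMCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": curve.event_times,
            "n_at_risk": curve.n_at_risk,
            "n_events": curve.n_events,
            "survival": curve.survival,
        }
    )
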