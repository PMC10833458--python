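"""Kaplan-Meier estimation and log-rank comparison of score-defined strata.

Cohorts are stratified into high/low groups by fitting a StepMiner step to
the sorted composite scores and splitting at the resulting threshold —
score > SThr is "high", anything at or below is "low" (the same tie rule as
expression binarization). Estimation and testing are standard product-limit
and two-group log-rank (1 df), with events processed before censored
subjects at tied times.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .stepminer import fit_step

REQUIRED_COLS = ("time", "event")


def _check(data: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLS:
        if col not in data.columns:
            raise KeyError(f"survival data needs a {col!r} column")
    if (data["time"] < 0).any():
        bad = data.index[data["time"] < 0].tolist()
        raise ValueError(f"negative survival time for subject(s) {bad}")
    if not data["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (event)")
    return data


def km_estimate(data: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Product-limit survival curve, optionally restricted to one group.

    Returns a step-function table (time, survival) with S(0) = 1; survival
    drops at event times only, censoring just shrinks the risk set.
    """
    data = _check(data)
    if group is not None:
        data = data[data["group"] == group]
        if data.empty:
            raise ValueError(f"no subjects in group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(data["time"], event_observed=data["event"])
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    return curve


def logrank(data: pd.DataFrame, group_a: str, group_b: str) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns (chi2, two-sided p)."""
    data = _check(data)
    a = data[data["group"] == group_a]
    b = data[data["group"] == group_b]
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    if a["event"].sum() + b["event"].sum() == 0:
        raise ValueError("no events in either group")
    res = logrank_test(a["time"], b["time"],
                       event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def stratify_by_score(scores: pd.Series, survival: pd.DataFrame,
                      high_label: str = "high", low_label: str = "low") -> pd.DataFrame:
    """Split a cohort into high/low strata at the StepMiner threshold of the scores.

    ``scores`` and ``survival`` must share subject ids. Scores strictly
    above the threshold go to the high group; ties go low.
    """
    survival = _check(survival)
    missing = [s for s in survival.index if s not in scores.index]
    if missing:
        raise ValueError(f"subjects without scores: {missing}")
    aligned = scores.loc[survival.index]
    if aligned.nunique() == 1:
        raise ValueError("no threshold: all scores identical")
    fit = fit_step(np.sort(aligned.to_numpy(dtype=float)))
    out = survival.copy()
    out["score"] = aligned
    out["group"] = np.where(aligned > fit.sthr, high_label, low_label)
    return out


def plot_km(data: pd.DataFrame, path, groups: list[str] | None = None) -> None:
    """KM curves per group in one figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = _check(data)
    if groups is None:
        groups = sorted(data["group"].unique())
    fig, ax = plt.subplots(figsize=(5, 4))
    for g in groups:
        sub = data[data["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(g))
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
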