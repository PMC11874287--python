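"""Outcome association: Kaplan-Meier, log-rank (plain and trend), marker
dichotomisation and fixed-horizon ROC analysis.

Survival input is one record per patient: time in months, an event flag
(progression or death observed; censored records have ``event=False``) and a
group label. Kaplan-Meier estimation and the plain log-rank test are
delegated to lifelines; the log-rank test for trend — the 1-degree-of-
freedom test against ordered groups used when comparing the three
immunotypes — is computed from the pooled risk table with score weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .params import ParameterError

__all__ = [
    "SurvivalRecord",
    "km_curve",
    "logrank_test",
    "logrank_trend",
    "dichotomise_marker",
    "roc_auc_pfs",
    "bonferroni",
    "plot_km",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time (months), event flag, group label."""

    patient_id: str
    time: float
    event: bool
    group: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and self.time > 0):
            raise ParameterError(
                f"survival time must be finite and positive, got {self.time!r}"
            )


def _to_frame(records: Sequence[SurvivalRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {"patient_id": r.patient_id, "time": r.time,
                 "event": r.event, "group": r.group}
                for r in records
            ]
        )
    if (df["time"] <= 0).any() or not np.isfinite(df["time"]).all():
        raise ParameterError("survival times must be finite and positive")
    return df


@dataclass
class KMCurve:
    """Product-limit estimate: right-continuous step function + median."""

    times: np.ndarray
    survival: np.ndarray
    median: float  # NaN when S never reaches 0.5
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """S(t); 1 before the first event time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(records) -> KMCurve:
    """Kaplan-Meier estimate with the median survival time.

    The median is the earliest time at which S(t) drops to 0.5 or below;
    NaN if the curve never does (e.g. no events).
    """
    df = _to_frame(records)
    if df.empty:
        raise ParameterError("need at least one survival record")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"].astype(bool))
    sf = kmf.survival_function_
    times = sf.index.to_numpy(float)
    surv = sf.iloc[:, 0].to_numpy(float)
    median = float(kmf.median_survival_time_)
    if math.isinf(median):
        median = math.nan
    return KMCurve(
        times=times,
        survival=surv,
        median=median,
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def _risk_table(df: pd.DataFrame):
    """Per-event-time risk/death counts by group (pooled distinct event times)."""
    groups = list(pd.unique(df["group"]))
    event_times = np.sort(df.loc[df["event"].astype(bool), "time"].unique())
    n_at_risk = np.zeros((len(event_times), len(groups)))
    deaths = np.zeros((len(event_times), len(groups)))
    for g_idx, g in enumerate(groups):
        sub = df[df["group"] == g]
        t = sub["time"].to_numpy(float)
        e = sub["event"].to_numpy(bool)
        for t_idx, et in enumerate(event_times):
            n_at_risk[t_idx, g_idx] = np.sum(t >= et)
            deaths[t_idx, g_idx] = np.sum((t == et) & e)
    return groups, event_times, n_at_risk, deaths


def _observed_expected(df: pd.DataFrame):
    """O, E and the covariance matrix of O - E over groups."""
    groups, _, n_at_risk, deaths = _risk_table(df)
    g = len(groups)
    O = deaths.sum(axis=0)
    E = np.zeros(g)
    V = np.zeros((g, g))
    for n_j, d_j in zip(n_at_risk, deaths):
        N = n_j.sum()
        D = d_j.sum()
        if N == 0 or D == 0:
            continue
        p = n_j / N
        E += D * p
        factor = D * (N - D) / (N - 1) if N > 1 else 0.0
        V += factor * (np.diag(p) - np.outer(p, p))
    return groups, O, E, V


def logrank_test(records) -> tuple[float, float]:
    """Plain log-rank chi-square over >= 2 groups, with g-1 df.

    Returns ``(statistic, p_value)``; with no events anywhere the statistic
    is 0 and p is 1.
    """
    df = _to_frame(records)
    groups = pd.unique(df["group"])
    if len(groups) < 2:
        raise ParameterError("log-rank test needs >= 2 groups")
    if int(df["event"].sum()) == 0:
        return 0.0, 1.0
    result = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return float(result.test_statistic), float(result.p_value)


def logrank_trend(
    records,
    group_order: Sequence[str],
    scores: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Log-rank test for trend across >= 3 ordered groups (1 df).

    The statistic is ``(sum_g s_g (O_g - E_g))^2 / (s' V s)`` with scores
    ``s`` (default 1, 2, 3, ...), O/E the observed/expected event counts and
    V the hypergeometric covariance of O - E. Zero variance (e.g. identical
    groups with no between-group information, or no events) gives statistic
    0 and p = 1. Reversing the group order flips the signed trend but not
    the chi-square.
    """
    if len(group_order) < 3:
        raise ParameterError(
            "trend test needs >= 3 ordered groups; use logrank_test for 2"
        )
    df = _to_frame(records)
    missing = set(group_order) - set(df["group"])
    if missing:
        raise ParameterError(f"groups absent from records: {sorted(missing)}")
    df = df[df["group"].isin(group_order)]
    s = np.asarray(scores if scores is not None else range(1, len(group_order) + 1),
                   dtype=float)
    if len(s) != len(group_order) or np.any(np.diff(s) <= 0):
        raise ParameterError("scores must be strictly increasing, one per group")
    groups, O, E, V = _observed_expected(df)
    order_index = [groups.index(g) for g in group_order]
    z = float(s @ (O - E)[order_index])
    var = float(s @ V[np.ix_(order_index, order_index)] @ s)
    if var <= 0:
        return 0.0, 1.0
    chi2 = z * z / var
    return chi2, float(stats.chi2.sf(chi2, df=1))


def dichotomise_marker(
    values: pd.Series, rule: str = "median", threshold: float | None = None
) -> pd.DataFrame:
    """Split patients into high/low marker groups.

    ``median`` rule: high iff value > median. ``fixed`` rule: high iff value
    > threshold, low otherwise; values exactly at the threshold are assigned
    low and flagged (the published groupings are strict > / < and leave the
    boundary case to convention).
    """
    values = pd.Series(values)
    if len(values) < 2:
        raise ParameterError("need >= 2 patients to dichotomise")
    flagged = pd.Series(False, index=values.index)
    if rule == "median":
        cut = float(values.median())
        if values.nunique() == 1:
            raise ParameterError("all marker values identical; median split degenerate")
        high = values > cut
    elif rule == "fixed":
        if threshold is None:
            raise ParameterError("fixed rule needs a threshold")
        cut = float(threshold)
        high = values > cut
        flagged = values == cut
    else:
        raise ParameterError(f"unknown dichotomisation rule {rule!r}")
    return pd.DataFrame(
        {
            "value": values,
            "group": np.where(high, "high", "low"),
            "cutpoint": cut,
            "at_threshold": flagged,
        }
    )


def roc_auc_pfs(
    marker: pd.Series, records, horizon: float = 8.0
) -> dict:
    """ROC curve and AUC of a marker for surviving past a fixed horizon.

    The binary outcome is progression-free survival >= ``horizon`` months.
    Patients censored before the horizon carry no outcome information and
    are excluded (their number is reported). AUC is the trapezoid area,
    equivalently the tie-corrected rank-sum probability that a random
    long-PFS patient has the higher marker.
    """
    if not horizon > 0:
        raise ParameterError("horizon must be positive")
    df = _to_frame(records).set_index("patient_id")
    marker = pd.Series(marker)
    df = df.loc[marker.index]
    censored_before = (~df["event"].astype(bool)) & (df["time"] < horizon)
    keep = ~censored_before
    outcome = (df.loc[keep, "time"] >= horizon).astype(int)
    values = marker[keep]
    n_pos, n_neg = int(outcome.sum()), int((1 - outcome).sum())
    if n_pos < 1 or n_neg < 1:
        raise ParameterError(
            "need patients in both outcome classes after censoring exclusion"
        )
    from sklearn.metrics import roc_auc_score, roc_curve

    auc = float(roc_auc_score(outcome, values))
    fpr, tpr, thresholds = roc_curve(outcome, values)
    return {
        "auc": auc,
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thresholds,
        "n_excluded_censored": int(censored_before.sum()),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "horizon": horizon,
    }


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni family-wise correction; never auto-applied by the tests."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * len(p), 1.0)


def plot_km(records, ax=None, by_group: bool = True):
    """Diagnostic Kaplan-Meier plot (one curve per group)."""
    import matplotlib.pyplot as plt

    df = _to_frame(records)
    if ax is None:
        _, ax = plt.subplots()
    groups = pd.unique(df["group"]) if by_group else ["all"]
    for g in groups:
        sub = df if g == "all" else df[df["group"] == g]
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(sub["time"], event_observed=sub["event"].astype(bool))
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    return ax
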