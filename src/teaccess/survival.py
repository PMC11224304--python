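"""Kaplan-Meier estimation, log-rank testing and maximally selected
rank-statistic cutpoints for continuous prognostic markers.

The cutpoint search evaluates every distinct marker value inside a quantile
band as a high/low split and maximizes the absolute standardized two-group
log-rank statistic. The naive log-rank p of the selected split is reported
with an explicit selection-bias annotation; an optional seeded permutation
p-value corrects for the selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps


def _validate(df: pd.DataFrame) -> None:
    if (df["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")


def km_estimate(
    records: pd.DataFrame, group_labels: Optional[pd.Series] = None
) -> Dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    ``records`` has columns (sample, time, event); ``group_labels`` maps
    sample -> label (a single group when omitted). Returns per group a
    frame (time, survival) — the right-continuous step function, starting
    at S(0) = 1.
    """
    _validate(records)
    if group_labels is None:
        group_labels = pd.Series("all", index=records["sample"].values)
    out: Dict[str, pd.DataFrame] = {}
    for label in pd.unique(group_labels.loc[records["sample"]].values):
        mask = group_labels.loc[records["sample"]].values == label
        sub = records[mask]
        if len(sub) == 0:
            raise ValueError(f"group {label!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        out[label] = pd.DataFrame(
            {"time": sf.index.values, "survival": sf.iloc[:, 0].values}
        )
    return out


def logrank_test(
    records: pd.DataFrame, group_labels: pd.Series
) -> Tuple[float, int, float]:
    """k-group log-rank test; returns (chi-square, df, two-sided p)."""
    _validate(records)
    labels = group_labels.loc[records["sample"]].values
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if records["event"].sum() == 0:
        return 0.0, len(uniq) - 1, 1.0
    res = multivariate_logrank_test(records["time"], labels, records["event"])
    return float(res.test_statistic), len(uniq) - 1, float(res.p_value)


def two_group_logrank_z(
    time: np.ndarray, event: np.ndarray, in_high: np.ndarray
) -> float:
    """Standardized log-rank statistic (O - E) / sqrt(V) for the high group.

    Uses the simultaneous-risk-set convention at tied event times with the
    hypergeometric variance. Positive values mean excess events (worse
    survival) in the high group.
    """
    order = np.argsort(time, kind="stable")
    time, event, in_high = time[order], event[order], in_high[order]
    o_minus_e = 0.0
    var = 0.0
    n = len(time)
    i = 0
    n_at_risk = n
    n1_at_risk = int(in_high.sum())
    while i < n:
        t = time[i]
        j = i
        d = d1 = removed = removed1 = 0
        while j < n and time[j] == t:
            d += int(event[j])
            d1 += int(event[j] & in_high[j])
            removed += 1
            removed1 += int(in_high[j])
            j += 1
        if d > 0 and n_at_risk > 1:
            frac = n1_at_risk / n_at_risk
            o_minus_e += d1 - d * frac
            var += d * frac * (1 - frac) * (n_at_risk - d) / (n_at_risk - 1)
        n_at_risk -= removed
        n1_at_risk -= removed1
        i = j
    if var <= 0:
        return 0.0
    return o_minus_e / math.sqrt(var)


@dataclass(frozen=True)
class CutpointResult:
    """A maximally selected rank-statistic split.

    ``logrank_p`` is the NAIVE p-value of the selected split and is
    selection-biased (anti-conservative); ``permutation_p``, when computed,
    accounts for the maximization.
    """

    cutpoint: float
    statistic: float
    n_high: int
    n_low: int
    logrank_p: float
    permutation_p: Optional[float] = None
    selection_biased: bool = True


def _max_abs_z(
    time: np.ndarray, event: np.ndarray, score: np.ndarray, candidates: np.ndarray
) -> Tuple[float, float, int, int]:
    best = (-1.0, math.nan, 0, 0)
    for cut in candidates:
        in_high = score > cut
        z = two_group_logrank_z(time, event, in_high)
        n_high = int(in_high.sum())
        n_low = len(score) - n_high
        key = abs(z)
        if key > best[0] + 1e-12 or (
            abs(key - best[0]) <= 1e-12 and min(n_high, n_low) > min(best[2], best[3])
        ):
            best = (key, cut, n_high, n_low)
    return best


def maxstat_cutpoint(
    records: pd.DataFrame,
    q_low: float = 0.1,
    q_high: float = 0.9,
    n_permutations: int = 0,
    seed: int = 0,
) -> CutpointResult:
    """Best high/low split of a continuous score by the log-rank statistic.

    Candidates are the distinct score values whose split keeps both groups
    inside the ``[q_low, q_high]`` quantile band; ties in |z| break toward
    the more balanced split. Set ``n_permutations > 0`` for a seeded
    permutation p-value of the maximal statistic.
    """
    _validate(records)
    if "score" not in records.columns:
        raise ValueError("records must carry a 'score' column")
    score = records["score"].values.astype(float)
    time = records["time"].values.astype(float)
    event = records["event"].values.astype(int)
    lo, hi = np.quantile(score, [q_low, q_high])
    candidates = np.unique(score[(score >= lo) & (score < hi)])
    candidates = candidates[candidates < score.max()]  # both groups non-empty
    if len(candidates) < 1 or len(np.unique(score)) < 2:
        raise ValueError("need >= 2 distinct score values within the quantile band")

    absz, cut, n_high, n_low = _max_abs_z(time, event, score, candidates)
    naive_p = float(sps.chi2.sf(absz**2, df=1))

    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(score)
            z_perm, _, _, _ = _max_abs_z(time, event, perm, candidates)
            exceed += z_perm >= absz - 1e-12
        perm_p = (exceed + 1) / (n_permutations + 1)

    return CutpointResult(
        cutpoint=float(cut),
        statistic=float(absz),
        n_high=n_high,
        n_low=n_low,
        logrank_p=naive_p,
        permutation_p=perm_p,
    )


def km_plot(curves: Dict[str, pd.DataFrame], path=None, title: str = ""):
    """Step-function plot of the per-group survival curves (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=str(label))
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
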