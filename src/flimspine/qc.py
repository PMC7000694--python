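"""Exclusion rules and group-level statistics.

Three exclusion mechanisms are supported: baseline-stability filtering of
the ROI mean lifetime (records whose baseline fluctuation exceeds 0.15 ns
are excluded before analysis), ROUT outlier removal on spine-volume data
(robust location fit followed by an FDR-controlled sweep of residual
t-ratios, Q = 1% by default), and a manual exclusion list for subjective
health criteria (dendritic blebbing, spine collapse) that cannot be
automated.  Group summaries are mean +/- SEM; two-group comparisons use the
unpaired two-tailed Student's t test (pooled variance, Welch by flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ExclusionReport",
    "GroupSummary",
    "TTestResult",
    "baseline_stability_filter",
    "rout_outliers",
    "apply_manual_exclusions",
    "summarize_group",
    "two_sample_test",
]


@dataclass(frozen=True)
class ExclusionReport:
    record_id: str
    rule: str  # baseline_fluctuation | rout_outlier | health_flag
    metric_value: float
    threshold: float
    excluded: bool


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    n: int
    mean: float
    sem: float  # sd / sqrt(n); NaN (undefined) for a single value
    n_neurons: int | None = None


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def baseline_stability_filter(
    baseline_tau,
    threshold: float = 0.15,
    record_id: str = "",
    metric: str = "ptp",
) -> ExclusionReport:
    """Flag a recording whose baseline mean lifetime fluctuates too much.

    The fluctuation metric is the peak-to-peak range (max - min) of the
    per-frame baseline ROI mean lifetime, in ns; ``metric="sd"`` uses the
    standard deviation instead.  The record is excluded iff the metric
    exceeds ``threshold`` (default 0.15 ns).
    """
    tau = np.asarray(baseline_tau, dtype=float)
    tau = tau[np.isfinite(tau)]
    if tau.size < 2:
        raise ValueError("need at least two baseline frames to assess stability")
    if metric == "ptp":
        value = float(tau.max() - tau.min())
    elif metric == "sd":
        value = float(tau.std(ddof=1))
    else:
        raise ValueError(f"unknown fluctuation metric '{metric}'")
    return ExclusionReport(
        record_id=record_id,
        rule="baseline_fluctuation",
        metric_value=value,
        threshold=threshold,
        excluded=value > threshold,
    )


def _rsdr(residuals: np.ndarray, n_params: int) -> float:
    """Robust standard deviation of residuals: the 68.27th percentile of
    |residuals| with the n/(n - K) small-sample correction."""
    n = residuals.size
    p68 = float(np.percentile(np.abs(residuals), 68.27))
    return p68 * n / max(n - n_params, 1)


def rout_outliers(
    values, q_percent: float = 1.0, *, max_iter: int = 60, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """ROUT outlier detection for a single column of measurements.

    The location model (K = 1 parameter) is fitted robustly: starting from
    the median, iteratively reweighted least squares with Lorentzian
    weights w = 1/(1 + (r/RSDR)^2), the robust scale RSDR re-estimated each
    pass from the 68.27th percentile of absolute residuals.  Each value
    then gets a t-ratio |r|/RSDR with two-tailed p from t(n - 1), and
    values are tested from the largest residual inward against the FDR
    thresholds alpha_i = Q i / n (i = 1 for the largest residual); the
    sweep stops at the first value that is not significant, so the
    most extreme point faces the most stringent threshold and clean
    Gaussian data are flagged only rarely.

    Returns (flags, cleaned): a boolean outlier mask and the retained
    values.  The decision is invariant under affine maps a x + b (a > 0)
    since t-ratios are location- and scale-free.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need at least 3 values for outlier analysis")
    if not 0 < q_percent < 100:
        raise ValueError("Q must be a percentage in (0, 100)")
    n = x.size

    mu = float(np.median(x))
    for _ in range(max_iter):
        r = x - mu
        s = _rsdr(r, 1)
        if s <= tol * max(1.0, float(np.abs(x).max())):
            break  # (near-)constant data: no outliers
        w = 1.0 / (1.0 + (r / s) ** 2)
        mu_new = float(np.sum(w * x) / np.sum(w))
        if abs(mu_new - mu) < tol * max(1.0, abs(mu)):
            mu = mu_new
            break
        mu = mu_new

    r = x - mu
    s = _rsdr(r, 1)
    flags = np.zeros(n, dtype=bool)
    if s <= tol * max(1.0, float(np.abs(x).max())):
        return flags, x.copy()

    t_ratio = np.abs(r) / s
    pvals = 2.0 * stats.t.sf(t_ratio, df=n - 1)
    order = np.argsort(pvals)  # largest residuals first
    q = q_percent / 100.0
    for i, idx in enumerate(order):
        alpha_i = q * (i + 1) / n
        if pvals[idx] < alpha_i:
            flags[idx] = True
        else:
            break
    return flags, x[~flags]


def apply_manual_exclusions(record_ids: Sequence[str], excluded_ids: Iterable[str]) -> list[ExclusionReport]:
    """Represent subjective health-based exclusions as an explicit list."""
    excluded = set(excluded_ids)
    return [
        ExclusionReport(record_id=rid, rule="health_flag", metric_value=float(rid in excluded), threshold=0.5, excluded=rid in excluded)
        for rid in record_ids
    ]


def summarize_group(values, labels=None, n_neurons=None) -> list[GroupSummary]:
    """Per-group mean +/- SEM.

    With ``labels`` omitted, all values form one group "all".  SEM is
    sd/sqrt(n) with ddof = 1; for a single value it is undefined (NaN).
    ``n_neurons`` may map group label -> number of neurons for n reporting
    in the neurons/spines convention.
    """
    x = np.asarray(values, dtype=float)
    if labels is None:
        labels = np.array(["all"] * x.size)
    labels = np.asarray(labels)
    if labels.shape != x.shape:
        raise ValueError("labels must align with values")
    out = []
    for g in dict.fromkeys(labels.tolist()):  # preserve first-seen order
        vals = x[labels == g]
        if vals.size == 0:
            raise ValueError(f"group '{g}' is empty")
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
        out.append(
            GroupSummary(
                group_label=str(g),
                n=int(vals.size),
                mean=float(vals.mean()),
                sem=sem,
                n_neurons=None if n_neurons is None else n_neurons.get(g),
            )
        )
    return out


def two_sample_test(a, b, *, welch: bool = False) -> TTestResult:
    """Unpaired two-tailed Student's t test.

    Pooled-variance by default (df = n1 + n2 - 2); ``welch=True`` uses the
    Welch-Satterthwaite correction instead.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))
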