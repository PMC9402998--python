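"""Discrimination statistics: AUC, DeLong comparison, rank correlation.

The AUC is the Mann-Whitney estimator (ties between an event and a
non-event score receive half credit).  Variances and the paired comparison
of two correlated AUCs use DeLong's structural components, computed with
the midrank formulation so the cost is O(n log n).  Confidence intervals
are Wald on the AUC scale, clipped to [0, 1]; a logit-scale interval is
available via ``ci_scale="logit"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .synthetic_cohort import ORGAN_DYSFUNCTIONS

__all__ = [
    "AucResult",
    "AucComparison",
    "CorrelationResult",
    "auc",
    "delong_test",
    "spearman",
    "organ_dysfunction_aucs",
]


@dataclass(frozen=True)
class AucResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_events: int
    n_nonevents: int


@dataclass(frozen=True)
class AucComparison:
    auc_a: AucResult
    auc_b: AucResult
    difference: float
    z_statistic: float
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    rho_squared: float
    p_value: float


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be binary 0/1")
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("need both classes present")
    return labels.astype(bool)


def _structural_components(scores: np.ndarray, events: np.ndarray):
    """(auc, V10 per event, V01 per non-event) via midranks."""
    x = scores[events]
    y = scores[~events]
    m, n = x.size, y.size
    tz = stats.rankdata(np.concatenate([x, y]))
    tx = stats.rankdata(x)
    ty = stats.rankdata(y)
    a = float((tz[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return a, v10, v01


def auc(scores, labels, ci_scale: str = "auc") -> AucResult:
    """Mann-Whitney AUC with DeLong variance and a 95% CI."""
    scores = np.asarray(scores, dtype=float)
    events = _check_labels(labels)
    if scores.shape != events.shape:
        raise ValueError("scores and labels must have equal length")
    a, v10, v01 = _structural_components(scores, events)
    m, n = v10.size, v01.size
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.975)
    if ci_scale == "logit" and 0 < a < 1 and se > 0:
        # delta method on the log-odds of the AUC
        se_l = se / (a * (1 - a))
        lo, hi = expit(logit(a) - z * se_l), expit(logit(a) + z * se_l)
    else:
        lo, hi = max(a - z * se, 0.0), min(a + z * se, 1.0)
    return AucResult(
        auc=a, variance=var, ci_low=float(lo), ci_high=float(hi),
        n_events=m, n_nonevents=n,
    )


def delong_test(scores_a, scores_b, labels) -> AucComparison:
    """Paired DeLong test for the difference of two correlated AUCs.

    Both score vectors must be measured on the same patients; the shared
    structural components supply the covariance term.  When the scores are
    identical the difference is 0 and p = 1 by convention.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    events = _check_labels(labels)
    if scores_a.shape != events.shape:
        raise ValueError("scores and labels must have equal length")

    a1, v10_1, v01_1 = _structural_components(scores_a, events)
    a2, v10_2, v01_2 = _structural_components(scores_b, events)
    m, n = v10_1.size, v01_1.size
    d10 = v10_1 - v10_2
    d01 = v01_1 - v01_2
    var_diff = 0.0
    if m > 1:
        var_diff += float(np.var(d10, ddof=1)) / m
    if n > 1:
        var_diff += float(np.var(d01, ddof=1)) / n
    diff = a1 - a2
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return AucComparison(
        auc_a=auc(scores_a, labels),
        auc_b=auc(scores_b, labels),
        difference=float(diff),
        z_statistic=float(z),
        p_value=p,
    )


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (Pearson on midranks, t-approximation p).

    ``rho_squared`` is reported alongside rho so a squared-correlation
    annotation on a marker-vs-score figure is directly reproducible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input vector")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    return CorrelationResult(rho=rho, rho_squared=rho**2, p_value=float(res.pvalue))


def organ_dysfunction_aucs(
    frame: pd.DataFrame, markers=("hbp", "crp", "nlr"), dysfunctions=ORGAN_DYSFUNCTIONS
) -> pd.DataFrame:
    """Per-(marker, organ-dysfunction) discrimination table.

    For each marker and each of the six acute organ dysfunction flags, the
    AUC of the raw marker value for the flag, with 95% CI.  ``frame`` must
    carry an ``organ_dysfunction`` column (semicolon-joined set encoding,
    as written by the cohort CSV).
    """
    if "organ_dysfunction" not in frame.columns:
        raise ValueError("cohort frame missing column 'organ_dysfunction'")
    dys_sets = frame["organ_dysfunction"].fillna("").astype(str).str.split(";")
    rows = []
    for dys in dysfunctions:
        flag = np.array([dys in s for s in dys_sets], dtype=int)
        for marker in markers:
            if marker not in frame.columns:
                raise ValueError(f"cohort frame missing marker column {marker!r}")
            res = auc(frame[marker].to_numpy(dtype=float), flag)
            rows.append(
                {
                    "dysfunction": dys,
                    "marker": marker,
                    "auc": res.auc,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n_with": res.n_events,
                    "n_without": res.n_nonevents,
                }
            )
    return pd.DataFrame(rows)
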