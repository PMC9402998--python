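"""Calibration of fitted risk models: Brier score, Hosmer-Lemeshow, bins.

The Hosmer-Lemeshow statistic groups patients by quantiles of predicted
risk.  Score-based models produce at most six distinct predicted risks, so
groups with identical predictions are merged; the statistic is

    chi2 = sum_g (O_g - E_g)^2 / (E_g * (1 - e_g))

with O_g the observed events, E_g the expected events (sum of predictions)
and e_g the mean prediction in group g, referred to a chi-square with
g - 2 degrees of freedom (a validation-style g df variant is available via
``df_style="validation"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationReport",
    "brier",
    "hosmer_lemeshow",
    "calibration_bins",
    "calibration_report",
]


@dataclass(frozen=True)
class CalibrationReport:
    brier: float
    hl_chi2: float
    hl_df: int
    hl_p: float
    bins: pd.DataFrame


def _check_probs(p, y):
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("p and y must be 1-d and of equal length")
    if p.size == 0:
        raise ValueError("empty input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary 0/1")
    return p, y


def brier(p, y) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p, y = _check_probs(p, y)
    return float(np.mean((p - y) ** 2))


def _risk_groups(p: np.ndarray, n_groups: int) -> np.ndarray:
    """Group index per patient: quantile bins of p with tied p merged."""
    uniq = np.unique(p)
    if uniq.size <= n_groups:
        # discrete predictions: one group per distinct risk
        return np.searchsorted(uniq, p)
    binned = pd.qcut(p, q=n_groups, labels=False, duplicates="drop")
    return np.asarray(binned, dtype=int)


def hosmer_lemeshow(
    p, y, n_groups: int = 10, df_style: str = "development"
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit test; returns (chi2, df, p_value)."""
    p, y = _check_probs(p, y)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need both classes present")
    groups = _risk_groups(p, n_groups)
    ids = np.unique(groups)
    if ids.size < 3:
        raise ValueError(
            f"only {ids.size} effective risk groups after merging ties; "
            "need at least 3"
        )
    chi2 = 0.0
    for g in ids:
        sel = groups == g
        n_g = int(sel.sum())
        obs = float(y[sel].sum())
        exp = float(p[sel].sum())
        ebar = exp / n_g
        denom = exp * (1.0 - ebar)
        if denom <= 0:
            # a group with all-zero (or all-one) predictions contributes
            # nothing unless observed disagrees, which is impossible for
            # p identically 0/1 within the group
            if obs != exp:
                chi2 = np.inf
            continue
        chi2 += (obs - exp) ** 2 / denom
    df = ids.size - (2 if df_style == "development" else 0)
    if df <= 0:
        raise ValueError(f"degenerate degrees of freedom ({df}) after merging")
    p_value = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p_value


def calibration_bins(p, y, n_groups: int = 10) -> pd.DataFrame:
    """Per-bin calibration points for plotting.

    Returns one row per risk group: patient count, mean predicted risk,
    observed event rate and a 95% Wilson interval for the observed rate.
    """
    p, y = _check_probs(p, y)
    groups = _risk_groups(p, n_groups)
    rows = []
    for g in np.unique(groups):
        sel = groups == g
        n_g = int(sel.sum())
        k = int(y[sel].sum())
        lo, hi = _wilson_interval(k, n_g)
        rows.append(
            {
                "n": n_g,
                "mean_predicted": float(p[sel].mean()),
                "observed_rate": k / n_g,
                "obs_ci_low": lo,
                "obs_ci_high": hi,
            }
        )
    return pd.DataFrame(rows).sort_values("mean_predicted", ignore_index=True)


def _wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    phat = k / n
    denom = 1.0 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return float(max(center - half, 0.0)), float(min(center + half, 1.0))


def calibration_report(p, y, n_groups: int = 10) -> CalibrationReport:
    """Brier score, Hosmer-Lemeshow test and calibration bins in one pass."""
    chi2, df, p_value = hosmer_lemeshow(p, y, n_groups)
    return CalibrationReport(
        brier=brier(p, y),
        hl_chi2=chi2,
        hl_df=df,
        hl_p=p_value,
        bins=calibration_bins(p, y, n_groups),
    )
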