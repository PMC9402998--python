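"""Net reclassification improvement and integrated discrimination improvement.

Added value of a new risk model over an old one on the same patients:

* categorical NRI — patients are placed in low / moderate / high predicted
  risk categories (default cuts 0.15 and 0.35, half-open on the left:
  p < 0.15 low, 0.15 <= p < 0.35 moderate, p >= 0.35 high); the event
  component is P(up) - P(down) among events, the non-event component is
  P(down) - P(up) among non-events, and the NRI is their sum;
* continuous NRI — the same up-minus-down construction with "up" meaning
  any increase of predicted risk; with no ties it equals twice the
  difference in upward-movement probability between events and non-events;
* IDI — the change in discrimination slope (mean predicted risk in events
  minus non-events) between the two models.

Standard errors are the asymptotic ones built from independent
within-stratum multinomial variances; a seeded stratified bootstrap
(percentile CI) is available as a cross-check via ``bootstrap_reps``.
Ties (identical old and new prediction) count as no movement throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RiskCategories",
    "ReclassificationTable",
    "NriResult",
    "IdiResult",
    "categorize",
    "categorical_nri",
    "continuous_nri",
    "idi",
]


@dataclass(frozen=True)
class RiskCategories:
    """Predicted-mortality risk strata (probability cut points)."""

    cuts: tuple[float, float] = (0.15, 0.35)
    labels: tuple[str, str, str] = ("low", "moderate", "high")

    def __post_init__(self) -> None:
        lo, hi = self.cuts
        if not (0 < lo < hi < 1):
            raise ValueError(f"cuts must be strictly increasing inside (0, 1), got {self.cuts}")

    def index(self, p) -> np.ndarray:
        """0/1/2 category index; intervals are half-open on the left."""
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        return np.searchsorted(np.asarray(self.cuts), p, side="right")


#: Sensitivity-analysis categories (20% / 40% cuts).
SENSITIVITY_CATEGORIES = RiskCategories(cuts=(0.20, 0.40))


def categorize(p, cats: RiskCategories = RiskCategories()):
    """Risk category label(s) for predicted probabilities."""
    idx = cats.index(p)
    labels = np.asarray(cats.labels, dtype=object)[idx]
    if np.ndim(p) == 0:
        return str(labels)
    return labels


@dataclass(frozen=True)
class ReclassificationTable:
    """Old-category x new-category counts, stratified by event status."""

    events: np.ndarray  # 3x3, rows = old category, cols = new category
    nonevents: np.ndarray
    labels: tuple[str, str, str]

    def movements(self, stratum: str) -> tuple[int, int, int]:
        """(up, down, total) counts for 'events' or 'nonevents'."""
        m = self.events if stratum == "events" else self.nonevents
        up = int(np.triu(m, k=1).sum())
        down = int(np.tril(m, k=-1).sum())
        return up, down, int(m.sum())


@dataclass(frozen=True)
class NriResult:
    nri: float
    event_component: float
    nonevent_component: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    variant: str
    bootstrap_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class IdiResult:
    idi: float
    discrimination_slope_old: float
    discrimination_slope_new: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    bootstrap_ci: tuple[float, float] | None = None


def _check_paired(p_old, p_new, y):
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (p_old.shape == p_new.shape == y.shape) or p_old.ndim != 1:
        raise ValueError("p_old, p_new and y must be 1-d and of equal length")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need both events and non-events")
    return p_old, p_new, y.astype(bool)


def _component_stats(up: np.ndarray, down: np.ndarray):
    """Mean difference and its variance for one stratum's up/down indicators."""
    n = up.size
    pu = up.mean()
    pd_ = down.mean()
    comp = pu - pd_
    var = (pu + pd_ - comp**2) / n
    return float(comp), float(var)


def _assemble_nri(comp_e, var_e, comp_ne_signed, var_ne, variant) -> dict:
    nri = comp_e + comp_ne_signed
    se = float(np.sqrt(var_e + var_ne))
    z = stats.norm.ppf(0.975)
    if se > 0:
        p_value = float(2.0 * stats.norm.sf(abs(nri) / se))
    else:
        p_value = 1.0 if nri == 0 else 0.0
    return dict(
        nri=float(nri),
        event_component=float(comp_e),
        nonevent_component=float(comp_ne_signed),
        se=se,
        ci_low=float(nri - z * se),
        ci_high=float(nri + z * se),
        p_value=p_value,
        variant=variant,
    )


def _movement_indicators(p_old, p_new, events, cats: RiskCategories | None):
    """Up/down indicator arrays for the event and non-event strata."""
    if cats is None:
        old_v, new_v = p_old, p_new
    else:
        old_v, new_v = cats.index(p_old), cats.index(p_new)
    up = new_v > old_v
    down = new_v < old_v
    return (up[events], down[events]), (up[~events], down[~events])


def _bootstrap_ci(statistic, p_old, p_new, events, reps: int, seed, level=0.95):
    rng = np.random.default_rng(seed)
    idx_e = np.flatnonzero(events)
    idx_ne = np.flatnonzero(~events)
    vals = np.empty(reps)
    for r in range(reps):
        take = np.concatenate(
            [rng.choice(idx_e, idx_e.size), rng.choice(idx_ne, idx_ne.size)]
        )
        vals[r] = statistic(p_old[take], p_new[take], events[take])
    alpha = 1.0 - level
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def categorical_nri(
    p_old,
    p_new,
    y,
    cats: RiskCategories = RiskCategories(),
    bootstrap_reps: int = 0,
    seed: int = 0,
) -> tuple[NriResult, ReclassificationTable]:
    """Categorical NRI with its old-vs-new reclassification tables."""
    p_old, p_new, events = _check_paired(p_old, p_new, y)
    old_idx = cats.index(p_old)
    new_idx = cats.index(p_new)

    def crosstab(sel):
        t = np.zeros((3, 3), dtype=int)
        np.add.at(t, (old_idx[sel], new_idx[sel]), 1)
        return t

    table = ReclassificationTable(
        events=crosstab(events), nonevents=crosstab(~events), labels=cats.labels
    )
    (up_e, down_e), (up_ne, down_ne) = _movement_indicators(p_old, p_new, events, cats)
    comp_e, var_e = _component_stats(up_e, down_e)
    comp_ne, var_ne = _component_stats(down_ne, up_ne)  # sign: down is correct
    fields = _assemble_nri(comp_e, var_e, comp_ne, var_ne, "categorical")
    boot = None
    if bootstrap_reps > 0:
        def stat(po, pn, ev):
            (ue, de), (une, dne) = _movement_indicators(po, pn, ev, cats)
            return (ue.mean() - de.mean()) + (dne.mean() - une.mean())

        boot = _bootstrap_ci(stat, p_old, p_new, events, bootstrap_reps, seed)
    return NriResult(**fields, bootstrap_ci=boot), table


def continuous_nri(
    p_old, p_new, y, bootstrap_reps: int = 0, seed: int = 0
) -> NriResult:
    """Category-free NRI: any change of predicted risk counts as movement.

    Computed from the up-minus-down components in each stratum; in the
    absence of ties this equals 2 * (P(up | event) - P(up | non-event)).
    """
    p_old, p_new, events = _check_paired(p_old, p_new, y)
    (up_e, down_e), (up_ne, down_ne) = _movement_indicators(p_old, p_new, events, None)
    comp_e, var_e = _component_stats(up_e, down_e)
    comp_ne, var_ne = _component_stats(down_ne, up_ne)
    fields = _assemble_nri(comp_e, var_e, comp_ne, var_ne, "continuous")
    boot = None
    if bootstrap_reps > 0:
        def stat(po, pn, ev):
            (ue, de), (une, dne) = _movement_indicators(po, pn, ev, None)
            return (ue.mean() - de.mean()) + (dne.mean() - une.mean())

        boot = _bootstrap_ci(stat, p_old, p_new, events, bootstrap_reps, seed)
    return NriResult(**fields, bootstrap_ci=boot)


def idi(p_old, p_new, y, bootstrap_reps: int = 0, seed: int = 0) -> IdiResult:
    """Integrated discrimination improvement.

    Difference of discrimination slopes (mean predicted risk in events
    minus non-events) between the new and the old model; the SE treats the
    event and non-event strata as independent and uses the empirical
    variance of the per-patient prediction change within each.
    """
    p_old, p_new, events = _check_paired(p_old, p_new, y)
    slope_old = float(p_old[events].mean() - p_old[~events].mean())
    slope_new = float(p_new[events].mean() - p_new[~events].mean())
    d = p_new - p_old
    d_e, d_ne = d[events], d[~events]
    var = 0.0
    if d_e.size > 1:
        var += float(np.var(d_e, ddof=1)) / d_e.size
    if d_ne.size > 1:
        var += float(np.var(d_ne, ddof=1)) / d_ne.size
    value = slope_new - slope_old
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    if se > 0:
        p_value = float(2.0 * stats.norm.sf(abs(value) / se))
    else:
        p_value = 1.0 if value == 0 else 0.0
    boot = None
    if bootstrap_reps > 0:
        def stat(po, pn, ev):
            dd = pn - po
            return (pn[ev].mean() - pn[~ev].mean()) - (po[ev].mean() - po[~ev].mean())

        boot = _bootstrap_ci(stat, p_old, p_new, events, bootstrap_reps, seed)
    return IdiResult(
        idi=float(value),
        discrimination_slope_old=slope_old,
        discrimination_slope_new=slope_new,
        se=se,
        ci_low=float(value - z * se),
        ci_high=float(value + z * se),
        p_value=p_value,
        bootstrap_ci=boot,
    )
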