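"""qSOFA and biomarker-modified qSOFA scores.

qSOFA awards one point each for altered mentation (GCS <= 14), hypotension
(SBP <= 100 mmHg) and tachypnea (RR > 22/min); a score >= 2 is the
conventional positivity threshold.  A serum biomarker is added as an
ordinal 0/1/2 class (for HBP: < 41, 41-151, > 151 ng/mL), extending the
score to the 0-5 range.  Adding marker points never changes the positivity
flag, which remains a function of the qSOFA points alone.

Both cut values of a marker classifier map to the middle class: "under" the
lower cut and "above" the upper cut are read strictly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerClassifier",
    "ScorePanel",
    "HBP_CLASSIFIER",
    "qsofa_score",
    "classify_marker",
    "combined_score",
    "score_panel",
    "empirical_tertile_classifier",
    "score_cohort",
]


@dataclass(frozen=True)
class BiomarkerClassifier:
    """Ordinal 0/1/2 coding of a serum marker by two cut points."""

    marker_name: str
    lower_cut: float
    upper_cut: float

    def __post_init__(self) -> None:
        if not 0 < self.lower_cut < self.upper_cut:
            raise ValueError(
                f"cuts must be positive and ordered, got "
                f"({self.lower_cut}, {self.upper_cut})"
            )


#: Literature-backed HBP cuts (ng/mL) used by the primary modified score.
HBP_CLASSIFIER = BiomarkerClassifier("hbp", 41.0, 151.0)


@dataclass(frozen=True)
class ScorePanel:
    """Full score breakdown for one patient."""

    qsofa: int
    marker_class: int
    combined: int
    positive_flag: bool


def qsofa_score(gcs, sbp, rr):
    """qSOFA points: GCS <= 14, SBP <= 100 mmHg, RR > 22/min (one each)."""
    gcs = np.asarray(gcs)
    sbp = np.asarray(sbp)
    rr = np.asarray(rr)
    if np.any((gcs < 3) | (gcs > 15)):
        raise ValueError("gcs out of range [3, 15]")
    if np.any(sbp <= 0) or np.any(rr <= 0):
        raise ValueError("sbp and rr must be positive")
    score = (gcs <= 14).astype(int) + (sbp <= 100).astype(int) + (rr > 22).astype(int)
    if score.ndim == 0:
        return int(score)
    return score


def classify_marker(value, classifier: BiomarkerClassifier):
    """Ordinal class: 0 below lower cut, 2 above upper cut, else 1.

    Values equal to either cut fall in class 1 (the worded ranges are
    strict: "under" the lower cut, "above" the upper).
    """
    value = np.asarray(value, dtype=float)
    if np.any(value <= 0):
        raise ValueError(f"{classifier.marker_name} values must be positive")
    cls = np.where(
        value < classifier.lower_cut, 0, np.where(value > classifier.upper_cut, 2, 1)
    )
    if cls.ndim == 0:
        return int(cls)
    return cls


def combined_score(qsofa, marker_class):
    """Additive biomarker-modified score on the 0-5 scale."""
    qsofa = np.asarray(qsofa)
    marker_class = np.asarray(marker_class)
    if np.any((qsofa < 0) | (qsofa > 3)):
        raise ValueError("qsofa points out of range [0, 3]")
    if np.any((marker_class < 0) | (marker_class > 2)):
        raise ValueError("marker class out of range [0, 2]")
    total = qsofa + marker_class
    if total.ndim == 0:
        return int(total)
    return total


def score_panel(gcs, sbp, rr, marker_value, classifier: BiomarkerClassifier = HBP_CLASSIFIER) -> ScorePanel:
    q = qsofa_score(gcs, sbp, rr)
    m = classify_marker(marker_value, classifier)
    return ScorePanel(
        qsofa=q, marker_class=m, combined=combined_score(q, m), positive_flag=q >= 2
    )


def empirical_tertile_classifier(values, marker_name: str) -> BiomarkerClassifier:
    """Cuts at the empirical 1/3 and 2/3 quantiles of a derivation sample.

    Used for markers whose literature cuts are not established (CRP, NLR);
    quantiles use linear interpolation of order statistics (type 7), so the
    cuts are reproducible from the sorted sample alone.
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 3:
        raise ValueError("need at least 3 distinct marker values for tertiles")
    lower, upper = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0])
    return BiomarkerClassifier(marker_name, float(lower), float(upper))


def score_cohort(
    frame: pd.DataFrame,
    hbp_classifier: BiomarkerClassifier = HBP_CLASSIFIER,
    crp_classifier: BiomarkerClassifier | None = None,
    nlr_classifier: BiomarkerClassifier | None = None,
) -> pd.DataFrame:
    """Append score columns to a cohort frame.

    Adds ``qsofa``, ``hbp_class`` and ``qsofa_hbp`` always, plus
    ``qsofa_crp`` / ``qsofa_nlr`` when the corresponding tertile
    classifiers (typically derived on the derivation split) are given.
    """
    out = frame.copy()
    out["qsofa"] = qsofa_score(
        out["gcs"].to_numpy(), out["sbp"].to_numpy(), out["rr"].to_numpy()
    )
    out["hbp_class"] = classify_marker(out["hbp"].to_numpy(), hbp_classifier)
    out["qsofa_hbp"] = combined_score(out["qsofa"].to_numpy(), out["hbp_class"].to_numpy())
    for name, clf in (("crp", crp_classifier), ("nlr", nlr_classifier)):
        if clf is not None:
            cls = classify_marker(out[name].to_numpy(), clf)
            out[f"{name}_class"] = cls
            out[f"qsofa_{name}"] = combined_score(out["qsofa"].to_numpy(), cls)
    return out
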