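"""End-to-end study pipeline and the bedside mortality calculator.

Reproduces the full prediction-model workflow on a cohort table:
simulate (or load) -> score -> 70/30 split -> fit logistic models on the
derivation set -> discrimination and calibration on the validation set ->
reclassification (NRI/IDI) on all patients -> written report.

The AUC comparison is validated on the held-out 30%, while
reclassification defaults to the full cohort; both choices are
configurable (``reclassify_on``).  Everything is deterministic under the
configured seed: the cohort comes from the generator seed, and split and
bootstrap seeds are spawned from the pipeline seed.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import calibration_report
from .discrimination import auc, delong_test, organ_dysfunction_aucs, spearman
from .reclassification import (
    RiskCategories,
    SENSITIVITY_CATEGORIES,
    categorical_nri,
    continuous_nri,
    idi,
)
from .risk_model import RiskModel, fit_logistic, predict_prob
from .scoring import (
    HBP_CLASSIFIER,
    BiomarkerClassifier,
    ScorePanel,
    empirical_tertile_classifier,
    score_cohort,
    score_panel,
)
from .synthetic_cohort import (
    Cohort,
    CohortSpec,
    default_cohort_spec,
    generate_cohort,
    split_cohort,
)

__all__ = [
    "PipelineConfig",
    "StudyReport",
    "PipelineError",
    "run_pipeline",
    "predict_mortality",
    "default_risk_model",
    "read_cohort",
    "write_report",
]

log = logging.getLogger("qsofa_hbp")

MODEL_NAMES = ("qsofa", "qsofa_hbp", "qsofa_crp", "qsofa_nlr")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    cohort_source: CohortSpec | str | Path | None = None  # None -> packaged default
    derivation_fraction: float = 0.7
    seed: int = 0
    models: tuple[str, ...] = MODEL_NAMES
    primary_categories: RiskCategories = field(default_factory=RiskCategories)
    sensitivity_categories: RiskCategories = field(
        default_factory=lambda: SENSITIVITY_CATEGORIES
    )
    bootstrap_reps: int = 2000
    reclassify_on: str = "all"  # or "validation"
    hl_groups: int = 10
    categorical_fit: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.derivation_fraction < 1:
            raise ValueError("derivation_fraction must lie in (0, 1)")
        if len(self.models) < 2 or self.models[0] != "qsofa":
            raise ValueError("models must start with 'qsofa' plus >= 1 comparator")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown model names: {sorted(unknown)}")
        if self.reclassify_on not in ("all", "validation"):
            raise ValueError("reclassify_on must be 'all' or 'validation'")


@dataclass
class StudyReport:
    """All tabular outputs of one pipeline run."""

    auc_table: pd.DataFrame
    delong_table: pd.DataFrame
    calibration_table: pd.DataFrame
    calibration_bins: dict[str, pd.DataFrame]
    reclassification_table: pd.DataFrame
    correlation_table: pd.DataFrame
    organ_dysfunction_table: pd.DataFrame
    models: dict[str, RiskModel]
    classifiers: dict[str, BiomarkerClassifier]
    cohort: Cohort
    metadata: dict
    created_at: str = ""


def read_cohort(path) -> Cohort:
    """Load a cohort CSV (lossless round-trip with :meth:`Cohort.to_csv`)."""
    return Cohort.from_csv(path)


def _obtain_cohort(config: PipelineConfig) -> Cohort:
    src = config.cohort_source
    if src is None:
        src = default_cohort_spec()
    if isinstance(src, CohortSpec):
        return generate_cohort(src)
    return read_cohort(src)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute the full study workflow; deterministic under the seed."""
    ss = np.random.SeedSequence(config.seed)
    split_seed, boot_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))

    cohort = _stage("cohort")(_obtain_cohort)(config)
    cohort = _stage("split")(split_cohort)(cohort, config.derivation_fraction, split_seed)
    deriv_mask = (cohort.frame["split"] == "derivation").to_numpy()

    # CRP/NLR cuts are derivation-set tertiles; HBP uses literature cuts.
    classifiers: dict[str, BiomarkerClassifier] = {"hbp": HBP_CLASSIFIER}
    needed = {m.split("_", 1)[1] for m in config.models if m != "qsofa"}
    for marker in ("crp", "nlr"):
        if marker in needed:
            classifiers[marker] = _stage(f"tertiles_{marker}")(
                empirical_tertile_classifier
            )(cohort.frame.loc[deriv_mask, marker].to_numpy(), marker)

    frame = _stage("score")(score_cohort)(
        cohort.frame,
        hbp_classifier=classifiers["hbp"],
        crp_classifier=classifiers.get("crp"),
        nlr_classifier=classifiers.get("nlr"),
    )
    cohort = Cohort(frame, provenance=cohort.provenance)
    y_all = frame["died_30d"].to_numpy(dtype=int)
    y_deriv = y_all[deriv_mask]
    y_valid = y_all[~deriv_mask]

    models: dict[str, RiskModel] = {}
    auc_rows, delong_rows, calib_rows = [], [], []
    calib_bins: dict[str, pd.DataFrame] = {}
    for name in config.models:
        x_all = frame[name].to_numpy(dtype=float)
        model = _stage(f"fit_{name}")(fit_logistic)(
            x_all[deriv_mask], y_deriv, predictor_name=name,
            categorical=config.categorical_fit,
        )
        models[name] = model
        for label, sel, y_sel in (
            ("derivation", deriv_mask, y_deriv),
            ("validation", ~deriv_mask, y_valid),
        ):
            res = auc(x_all[sel], y_sel)
            auc_rows.append(
                {
                    "model": name,
                    "dataset": label,
                    "auc": res.auc,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n": int(sel.sum()),
                    "n_events": res.n_events,
                }
            )
        p_valid = predict_prob(model, x_all[~deriv_mask])
        rep = _stage(f"calibration_{name}")(calibration_report)(
            p_valid, y_valid, config.hl_groups
        )
        calib_rows.append(
            {
                "model": name,
                "dataset": "validation",
                "brier": rep.brier,
                "hl_chi2": rep.hl_chi2,
                "hl_df": rep.hl_df,
                "hl_p": rep.hl_p,
            }
        )
        calib_bins[name] = rep.bins

    x_ref_valid = frame.loc[~deriv_mask, "qsofa"].to_numpy(dtype=float)
    for name in config.models[1:]:
        comp = _stage(f"delong_{name}")(delong_test)(
            frame.loc[~deriv_mask, name].to_numpy(dtype=float), x_ref_valid, y_valid
        )
        delong_rows.append(
            {
                "model": name,
                "reference": "qsofa",
                "dataset": "validation",
                "auc_model": comp.auc_a.auc,
                "auc_reference": comp.auc_b.auc,
                "difference": comp.difference,
                "z": comp.z_statistic,
                "p_value": comp.p_value,
            }
        )

    reclass_mask = (
        np.ones(len(frame), dtype=bool) if config.reclassify_on == "all" else ~deriv_mask
    )
    y_rec = y_all[reclass_mask]
    p_old = predict_prob(models["qsofa"], frame.loc[reclass_mask, "qsofa"].to_numpy(dtype=float))
    reclass_rows = []
    for name in config.models[1:]:
        p_new = predict_prob(
            models[name], frame.loc[reclass_mask, name].to_numpy(dtype=float)
        )
        for cats, tag in (
            (config.primary_categories, "categorical_15_35"),
            (config.sensitivity_categories, "categorical_20_40"),
        ):
            res, _table = categorical_nri(
                p_old, p_new, y_rec, cats,
                bootstrap_reps=config.bootstrap_reps, seed=boot_seed,
            )
            reclass_rows.append(_nri_row(name, tag, res))
        res = continuous_nri(
            p_old, p_new, y_rec, bootstrap_reps=config.bootstrap_reps, seed=boot_seed
        )
        reclass_rows.append(_nri_row(name, "continuous", res))
        idi_res = idi(
            p_old, p_new, y_rec, bootstrap_reps=config.bootstrap_reps, seed=boot_seed
        )
        reclass_rows.append(
            {
                "model": name,
                "statistic": "idi",
                "estimate": idi_res.idi,
                "component_events": idi_res.discrimination_slope_new,
                "component_nonevents": idi_res.discrimination_slope_old,
                "se": idi_res.se,
                "ci_low": idi_res.ci_low,
                "ci_high": idi_res.ci_high,
                "p_value": idi_res.p_value,
                "bootstrap_ci_low": None if idi_res.bootstrap_ci is None else idi_res.bootstrap_ci[0],
                "bootstrap_ci_high": None if idi_res.bootstrap_ci is None else idi_res.bootstrap_ci[1],
            }
        )

    qsofa_class = np.minimum(frame["qsofa"].to_numpy(dtype=int), 2)
    corr_rows = []
    for marker in ("hbp", "crp", "nlr"):
        c = spearman(frame[marker].to_numpy(dtype=float), qsofa_class)
        corr_rows.append(
            {"marker": marker, "rho": c.rho, "rho_squared": c.rho_squared, "p_value": c.p_value}
        )

    organ_table = _stage("organ_dysfunction_aucs")(organ_dysfunction_aucs)(frame)

    metadata = {
        "seed": config.seed,
        "split_seed": split_seed,
        "bootstrap_seed": boot_seed,
        "derivation_fraction": config.derivation_fraction,
        "n_total": int(len(frame)),
        "n_derivation": int(deriv_mask.sum()),
        "n_validation": int((~deriv_mask).sum()),
        "models": list(config.models),
        "reclassify_on": config.reclassify_on,
        "bootstrap_reps": config.bootstrap_reps,
        "package_version": __version__,
        "cohort_provenance": (
            "synthetic" if isinstance(cohort.provenance, CohortSpec) else str(cohort.provenance)
        ),
    }
    return StudyReport(
        auc_table=pd.DataFrame(auc_rows),
        delong_table=pd.DataFrame(delong_rows),
        calibration_table=pd.DataFrame(calib_rows),
        calibration_bins=calib_bins,
        reclassification_table=pd.DataFrame(reclass_rows),
        correlation_table=pd.DataFrame(corr_rows),
        organ_dysfunction_table=organ_table,
        models=models,
        classifiers=classifiers,
        cohort=cohort,
        metadata=metadata,
        created_at=datetime.now(timezone.utc).isoformat(),
    )


def _nri_row(model: str, tag: str, res) -> dict:
    return {
        "model": model,
        "statistic": f"nri_{tag}",
        "estimate": res.nri,
        "component_events": res.event_component,
        "component_nonevents": res.nonevent_component,
        "se": res.se,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "p_value": res.p_value,
        "bootstrap_ci_low": None if res.bootstrap_ci is None else res.bootstrap_ci[0],
        "bootstrap_ci_high": None if res.bootstrap_ci is None else res.bootstrap_ci[1],
    }


def write_report(report: StudyReport, outdir) -> None:
    """Write all report tables, fitted models and metadata to a directory.

    Output is byte-identical across runs with the same configuration and
    seed (no timestamps are written).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.auc_table.to_csv(outdir / "auc.csv", index=False)
    report.delong_table.to_csv(outdir / "delong.csv", index=False)
    report.calibration_table.to_csv(outdir / "calibration.csv", index=False)
    for name, bins in report.calibration_bins.items():
        bins.to_csv(outdir / f"calibration_bins_{name}.csv", index=False)
    report.reclassification_table.to_csv(outdir / "reclassification.csv", index=False)
    report.correlation_table.to_csv(outdir / "correlations.csv", index=False)
    report.organ_dysfunction_table.to_csv(outdir / "organ_dysfunction_auc.csv", index=False)
    report.cohort.to_csv(outdir / "cohort.csv")
    models_dir = outdir / "models"
    models_dir.mkdir(exist_ok=True)
    for name, model in report.models.items():
        model.to_json(models_dir / f"{name}.json")
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(report.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(render_summary(report))


def render_summary(report: StudyReport) -> str:
    """Human-readable run summary (deterministic text)."""
    lines = []
    md = report.metadata
    lines.append("qsofa-hbp study report")
    lines.append(
        f"cohort: n={md['n_total']} ({md['cohort_provenance']}), "
        f"derivation {md['n_derivation']} / validation {md['n_validation']}, "
        f"seed {md['seed']}"
    )
    lines.append("")
    lines.append("Discrimination (AUC, 95% CI):")
    for row in report.auc_table.itertuples(index=False):
        lines.append(
            f"  {row.model:<10} {row.dataset:<11} "
            f"{row.auc:.3f} ({row.ci_low:.3f}-{row.ci_high:.3f})"
        )
    lines.append("")
    lines.append("DeLong vs qSOFA (validation):")
    for row in report.delong_table.itertuples(index=False):
        lines.append(
            f"  {row.model:<10} dAUC {row.difference:+.3f}  z {row.z:+.2f}  p {row.p_value:.4g}"
        )
    lines.append("")
    lines.append("Calibration (validation):")
    for row in report.calibration_table.itertuples(index=False):
        lines.append(
            f"  {row.model:<10} Brier {row.brier:.3f}  "
            f"HL chi2 {row.hl_chi2:.2f} (df {row.hl_df}, p {row.hl_p:.3f})"
        )
    lines.append("")
    lines.append(f"Reclassification vs qSOFA (on {md['reclassify_on']} patients):")
    for row in report.reclassification_table.itertuples(index=False):
        lines.append(
            f"  {row.model:<10} {row.statistic:<18} {row.estimate:+.3f} "
            f"({row.ci_low:+.3f} to {row.ci_high:+.3f})  p {row.p_value:.4g}"
        )
    lines.append("")
    lines.append("Marker vs qSOFA class (Spearman):")
    for row in report.correlation_table.itertuples(index=False):
        lines.append(
            f"  {row.marker:<5} rho {row.rho:+.3f}  rho^2 {row.rho_squared:.3f}  "
            f"p {row.p_value:.4g}"
        )
    lines.append("")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Bedside calculator


_DEFAULT_MODEL: RiskModel | None = None

#: Provenance warning for the packaged calculator model.
SYNTHETIC_MODEL_WARNING = (
    "The packaged default model was trained on a SYNTHETIC cohort produced "
    "by this package's simulator; it is a demonstration artifact, not a "
    "clinically validated model."
)


def default_risk_model() -> RiskModel:
    """The packaged qSOFA+HBP model, trained on the default synthetic cohort."""
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        ref = importlib.resources.files("qsofa_hbp.data") / "synthetic_default_model.json"
        try:
            _DEFAULT_MODEL = RiskModel.from_json(ref.read_text())
        except FileNotFoundError:  # pragma: no cover - packaging fallback
            _DEFAULT_MODEL = train_default_model()
    return _DEFAULT_MODEL


def train_default_model() -> RiskModel:
    """Retrain the packaged calculator model from the default generator."""
    spec = default_cohort_spec()
    cohort = generate_cohort(spec)
    frame = score_cohort(cohort.frame)
    return fit_logistic(
        frame["qsofa_hbp"].to_numpy(dtype=float),
        frame["died_30d"].to_numpy(dtype=int),
        predictor_name="qsofa_hbp",
    )


def predict_mortality(
    gcs: int,
    sbp: float,
    rr: float,
    hbp: float,
    model: RiskModel | None = None,
    cats: RiskCategories = RiskCategories(),
) -> tuple[float, str, ScorePanel]:
    """Predicted 30-day mortality from the four bedside inputs.

    Returns (probability, risk label, score breakdown).  Physiologic inputs
    are range-checked: GCS 3-15, SBP 30-300 mmHg, RR 4-80 /min, HBP > 0.
    """
    if not 3 <= gcs <= 15:
        raise ValueError("gcs must lie in [3, 15]")
    if not 30 <= sbp <= 300:
        raise ValueError("sbp outside plausible range [30, 300] mmHg")
    if not 4 <= rr <= 80:
        raise ValueError("rr outside plausible range [4, 80] /min")
    if hbp <= 0:
        raise ValueError("hbp must be positive")
    if model is None:
        model = default_risk_model()
    panel = score_panel(gcs, sbp, rr, hbp)
    prob = predict_prob(model, float(panel.combined))
    from .reclassification import categorize

    return prob, str(categorize(prob, cats)), panel
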