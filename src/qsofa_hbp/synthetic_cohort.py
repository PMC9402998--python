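"""Seeded synthetic ED sepsis cohorts.

The generator emulates a three-group severity mixture (survivors,
critically-ill, non-survivors) with right-skewed biomarker distributions.
Targets are given as printed-style summary statistics — a median with an
interquartile range per group — so any published cohort table can be turned
into a simulator configuration:

* biomarkers (HBP, CRP, NLR, WBC, platelets, lymphocytes) are lognormal,
  with the location solved from the target median and the scale from the
  IQR ratio via the normal 0.75 quantile;
* qSOFA components (GCS, SBP, RR) and age use a two-piece linear quantile
  function through (q25, median, q75), discretized and truncated to their
  physiologic support — this reproduces the printed median and IQR exactly
  even at a ceiling such as GCS 15;
* the HBP measurement passes through an assay-noise model: multiplicative
  lognormal error whose CV interpolates log-linearly between two reference
  concentrations, and left-censoring at the limit of detection;
* 30-day death is deterministic given severity group (non-survivors are by
  definition the patients who die within 30 days).

Within a severity group all variables are drawn independently; the group
mixture alone induces the marginal biomarker-score correlation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "SEVERITY_GROUPS",
    "ORGAN_DYSFUNCTIONS",
    "INFECTION_SOURCES",
    "QuantileTriple",
    "AssaySpec",
    "GroupTargets",
    "CohortSpec",
    "PatientRecord",
    "Cohort",
    "default_cohort_spec",
    "load_cohort_spec",
    "generate_cohort",
    "apply_assay_noise",
    "split_cohort",
]

SEVERITY_GROUPS = ("survivor", "critically_ill", "non_survivor")
ORGAN_DYSFUNCTIONS = (
    "respiratory",
    "cardiovascular",
    "renal",
    "hepatic",
    "hematologic",
    "mental",
)
INFECTION_SOURCES = (
    "pneumonia",
    "urinary_tract",
    "biliary_tract",
    "intra_abdominal",
    "skin_soft_tissue",
    "bloodstream",
    "miscellaneous",
)
BIOMARKERS = ("hbp", "crp", "nlr", "wbc", "platelets", "lymphocytes")
VITALS = ("gcs", "sbp", "rr", "age")

#: z_{0.75}, the standard-normal upper quartile used to map an IQR ratio to
#: a lognormal scale parameter.
_Z75 = float(stats.norm.ppf(0.75))

#: Cohort CSV column order (the canonical on-disk schema).
COHORT_COLUMNS = (
    "id",
    "age",
    "male",
    "gcs",
    "sbp",
    "rr",
    "hbp",
    "crp",
    "neutrophils",
    "lymphocytes",
    "nlr",
    "wbc",
    "platelets",
    "severity_group",
    "died_30d",
    "organ_dysfunction",
    "infection_source",
    "split",
)


@dataclass(frozen=True)
class QuantileTriple:
    """A (q25, median, q75) summary used as a distribution target."""

    q25: float
    median: float
    q75: float

    def __post_init__(self) -> None:
        if not (self.q25 <= self.median <= self.q75):
            raise ValueError(
                f"quantiles must be ordered, got ({self.q25}, {self.median}, {self.q75})"
            )

    @property
    def degenerate(self) -> bool:
        return self.q75 <= self.q25

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the lognormal with this median and IQR ratio."""
        if self.median <= 0 or self.q25 <= 0:
            raise ValueError("lognormal targets must be strictly positive")
        if self.degenerate:
            raise ValueError(f"degenerate IQR (q75 {self.q75} <= q25 {self.q25})")
        mu = np.log(self.median)
        sigma = np.log(self.q75 / self.q25) / (2.0 * _Z75)
        return mu, sigma

    def piecewise_quantile(self, u: np.ndarray) -> np.ndarray:
        """Two-piece linear quantile function through the three targets.

        Linear from (0.25, q25) through (0.5, median) below the median and
        from (0.5, median) through (0.75, q75) above, extended with the same
        slopes into the tails; support is [2*q25 - median, 2*q75 - median].
        """
        u = np.asarray(u, dtype=float)
        lo = self.median + 4.0 * (self.median - self.q25) * (u - 0.5)
        hi = self.median + 4.0 * (self.q75 - self.median) * (u - 0.5)
        return np.where(u <= 0.5, lo, hi)


@dataclass(frozen=True)
class AssaySpec:
    """HBP immunoassay error model: detection limit and inter-assay CV.

    The CV is interpolated log-linearly in concentration between
    ``cv_low`` at ``cv_low_at`` and ``cv_high`` at ``cv_high_at`` and
    clamped outside that range.  Measurements below ``lod`` are reported
    at the detection limit (left-censoring).
    """

    lod: float = 5.9
    cv_low: float = 0.11
    cv_low_at: float = 21.0
    cv_high: float = 0.07
    cv_high_at: float = 81.0

    def __post_init__(self) -> None:
        if self.lod < 0:
            raise ValueError("lod must be >= 0")
        for cv in (self.cv_low, self.cv_high):
            if not 0 <= cv < 1:
                raise ValueError("cv values must lie in [0, 1)")
        if not 0 < self.cv_low_at < self.cv_high_at:
            raise ValueError("cv reference concentrations must be ordered and positive")

    def cv_at(self, value: np.ndarray) -> np.ndarray:
        value = np.asarray(value, dtype=float)
        t = (np.log(value) - np.log(self.cv_low_at)) / (
            np.log(self.cv_high_at) - np.log(self.cv_low_at)
        )
        t = np.clip(t, 0.0, 1.0)
        return self.cv_low + t * (self.cv_high - self.cv_low)


@dataclass(frozen=True)
class GroupTargets:
    """Per-severity-group distribution targets."""

    biomarkers: Mapping[str, QuantileTriple]
    vitals: Mapping[str, QuantileTriple]
    organ_dysfunction: Mapping[str, float]
    infection_source: Mapping[str, float]
    male_fraction: float = 0.5

    def __post_init__(self) -> None:
        missing = set(BIOMARKERS) - set(self.biomarkers)
        if missing:
            raise ValueError(f"missing biomarker targets: {sorted(missing)}")
        missing = set(VITALS) - set(self.vitals)
        if missing:
            raise ValueError(f"missing vital targets: {sorted(missing)}")
        for name, prev in self.organ_dysfunction.items():
            if name not in ORGAN_DYSFUNCTIONS:
                raise ValueError(f"unknown organ dysfunction {name!r}")
            if not 0 <= prev <= 1:
                raise ValueError(f"prevalence for {name!r} outside [0, 1]")
        for name in self.infection_source:
            if name not in INFECTION_SOURCES:
                raise ValueError(f"unknown infection source {name!r}")

    def source_probabilities(self) -> np.ndarray:
        """Infection-source probabilities, renormalized to sum to one."""
        w = np.array([self.infection_source.get(s, 0.0) for s in INFECTION_SOURCES])
        if w.sum() <= 0:
            raise ValueError("infection-source weights sum to zero")
        return w / w.sum()


@dataclass(frozen=True)
class CohortSpec:
    """Full generator configuration: mixture, targets, assay model, seed."""

    n: int
    group_proportions: Mapping[str, float]
    groups: Mapping[str, GroupTargets]
    assay: AssaySpec = field(default_factory=AssaySpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if set(self.group_proportions) != set(SEVERITY_GROUPS):
            raise ValueError(f"group_proportions must have keys {SEVERITY_GROUPS}")
        if set(self.groups) != set(SEVERITY_GROUPS):
            raise ValueError(f"groups must have keys {SEVERITY_GROUPS}")
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group proportions sum to {total}, not 1")
        if any(p < 0 for p in self.group_proportions.values()):
            raise ValueError("group proportions must be non-negative")

    def group_sizes(self) -> dict[str, int]:
        """Deterministic largest-remainder rounding of n * proportions."""
        props = np.array([self.group_proportions[g] for g in SEVERITY_GROUPS])
        raw = self.n * props
        base = np.floor(raw).astype(int)
        short = self.n - int(base.sum())
        # ties broken by group order, stable
        order = np.argsort(-(raw - base), kind="stable")
        for i in order[:short]:
            base[i] += 1
        return dict(zip(SEVERITY_GROUPS, (int(b) for b in base)))

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PatientRecord:
    """One ED patient: demographics, qSOFA components, biomarkers, outcome."""

    id: str
    age: int
    male: bool
    gcs: int
    sbp: float
    rr: float
    hbp: float
    crp: float
    neutrophils: float
    lymphocytes: float
    nlr: float
    wbc: float
    platelets: float
    severity_group: str
    died_30d: bool
    organ_dysfunction: frozenset[str]
    infection_source: str
    split: str = "unassigned"


class Cohort:
    """An ordered patient collection backed by a pandas DataFrame.

    The DataFrame (``frame``) is the canonical representation used by the
    scoring and evaluation stages; ``records`` materializes typed
    :class:`PatientRecord` objects on demand.
    """

    def __init__(self, frame: pd.DataFrame, provenance: CohortSpec | str = "file"):
        frame = frame.reset_index(drop=True)
        missing = [c for c in COHORT_COLUMNS if c not in frame.columns and c != "split"]
        if missing:
            raise ValueError(f"cohort frame missing required columns: {missing}")
        if "split" not in frame.columns:
            frame = frame.assign(split="unassigned")
        if frame["id"].duplicated().any():
            raise ValueError("patient ids must be unique")
        self.frame = frame
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @property
    def records(self) -> list[PatientRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            dys = row.organ_dysfunction
            if isinstance(dys, str):
                dys = frozenset(d for d in dys.split(";") if d)
            elif not isinstance(dys, frozenset):
                dys = frozenset(dys)
            out.append(
                PatientRecord(
                    id=str(row.id),
                    age=int(row.age),
                    male=bool(row.male),
                    gcs=int(row.gcs),
                    sbp=float(row.sbp),
                    rr=float(row.rr),
                    hbp=float(row.hbp),
                    crp=float(row.crp),
                    neutrophils=float(row.neutrophils),
                    lymphocytes=float(row.lymphocytes),
                    nlr=float(row.nlr),
                    wbc=float(row.wbc),
                    platelets=float(row.platelets),
                    severity_group=str(row.severity_group),
                    died_30d=bool(row.died_30d),
                    organ_dysfunction=dys,
                    infection_source=str(row.infection_source),
                    split=str(row.split),
                )
            )
        return out

    def subset(self, split: str) -> "Cohort":
        sub = self.frame[self.frame["split"] == split]
        return Cohort(sub.copy(), provenance=self.provenance)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        cols = list(COHORT_COLUMNS) + [
            c for c in out.columns if c not in COHORT_COLUMNS
        ]
        out[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        try:
            frame = pd.read_csv(path, dtype={"id": str, "organ_dysfunction": str})
        except pd.errors.EmptyDataError:
            raise ValueError(f"empty cohort file: {path}") from None
        if len(frame) == 0:
            raise ValueError(f"cohort file has no patient rows: {path}")
        missing = [c for c in COHORT_COLUMNS if c not in frame.columns and c != "split"]
        if missing:
            raise ValueError(f"cohort CSV missing required columns: {missing}")
        frame["organ_dysfunction"] = frame["organ_dysfunction"].fillna("")
        for col in ("male", "died_30d"):
            if frame[col].dtype == object:
                frame[col] = frame[col].map({"True": True, "False": False})
            frame[col] = frame[col].astype(bool)
        return cls(frame, provenance="file")


def _spec_from_mapping(cfg: Mapping, n: int | None = None, seed: int | None = None) -> CohortSpec:
    weights = cfg["group_weights"]
    total = float(sum(weights.values()))
    proportions = {g: weights[g] / total for g in SEVERITY_GROUPS}
    groups = {}
    for g in SEVERITY_GROUPS:
        gc = cfg["groups"][g]
        groups[g] = GroupTargets(
            biomarkers={k: QuantileTriple(*v) for k, v in gc["biomarkers"].items()},
            vitals={k: QuantileTriple(*v) for k, v in gc["vitals"].items()},
            organ_dysfunction=dict(gc["organ_dysfunction"]),
            infection_source=dict(gc["infection_source"]),
            male_fraction=float(gc["male_fraction"]),
        )
    assay = AssaySpec(**cfg.get("assay", {}))
    return CohortSpec(
        n=int(cfg["n"] if n is None else n),
        group_proportions=proportions,
        groups=groups,
        assay=assay,
        seed=int(cfg["seed"] if seed is None else seed),
    )


def load_cohort_spec(path, n: int | None = None, seed: int | None = None) -> CohortSpec:
    """Read a generator configuration from a YAML (or JSON) file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _spec_from_mapping(cfg, n=n, seed=seed)


def default_cohort_spec(n: int | None = None, seed: int | None = None) -> CohortSpec:
    """The packaged configuration: 794 patients, 350/265/179 severity mix."""
    ref = importlib.resources.files("qsofa_hbp.data") / "table1_cohort.yaml"
    cfg = yaml.safe_load(ref.read_text())
    return _spec_from_mapping(cfg, n=n, seed=seed)


def apply_assay_noise(
    true_value, assay: AssaySpec, rng: np.random.Generator
) -> np.ndarray | float:
    """Measured concentration: multiplicative lognormal error + LOD censoring.

    The noise factor is mean-one lognormal with sigma chosen so that the
    coefficient of variation matches :meth:`AssaySpec.cv_at` at the true
    concentration.  Results below the detection limit are reported at the
    limit.
    """
    arr = np.asarray(true_value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("assay input concentrations must be positive")
    cv = assay.cv_at(arr)
    sigma = np.sqrt(np.log1p(cv**2))
    factor = np.exp(rng.normal(size=arr.shape) * sigma - sigma**2 / 2.0)
    measured = np.maximum(arr * factor, assay.lod)
    if np.isscalar(true_value) or np.ndim(true_value) == 0:
        return float(measured)
    return measured


def _draw_group(
    targets: GroupTargets, size: int, assay: AssaySpec, rng: np.random.Generator
) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}

    cols["age"] = np.round(
        np.clip(targets.vitals["age"].piecewise_quantile(rng.random(size)), 20, None)
    ).astype(int)
    cols["male"] = rng.random(size) < targets.male_fraction
    cols["gcs"] = np.round(
        np.clip(targets.vitals["gcs"].piecewise_quantile(rng.random(size)), 3, 15)
    ).astype(int)
    cols["sbp"] = np.round(
        np.clip(targets.vitals["sbp"].piecewise_quantile(rng.random(size)), 40, None)
    ).astype(int)
    cols["rr"] = np.round(
        np.clip(targets.vitals["rr"].piecewise_quantile(rng.random(size)), 5, None)
    ).astype(int)

    draws: dict[str, np.ndarray] = {}
    for marker in BIOMARKERS:
        mu, sigma = targets.biomarkers[marker].lognormal_params()
        draws[marker] = np.exp(rng.normal(loc=mu, scale=sigma, size=size))

    cols["hbp"] = apply_assay_noise(draws["hbp"], assay, rng)
    cols["crp"] = np.round(draws["crp"], 2)
    cols["wbc"] = np.round(draws["wbc"], 2)
    cols["platelets"] = np.round(draws["platelets"]).astype(int)
    # NLR is simulated directly (it is the published quantity); the absolute
    # counts are backed out so that nlr == neutrophils / lymphocytes holds
    # exactly on the stored, rounded values.
    lymph = np.round(np.clip(draws["lymphocytes"], 0.05, None), 2)
    neut = np.round(np.clip(draws["nlr"] * lymph, 0.01, None), 2)
    cols["lymphocytes"] = lymph
    cols["neutrophils"] = neut
    cols["nlr"] = neut / lymph

    for dys in ORGAN_DYSFUNCTIONS:
        prev = targets.organ_dysfunction.get(dys, 0.0)
        cols[f"_dys_{dys}"] = rng.random(size) < prev
    src_p = targets.source_probabilities()
    cols["infection_source"] = np.array(INFECTION_SOURCES)[
        rng.choice(len(INFECTION_SOURCES), size=size, p=src_p)
    ]
    return pd.DataFrame(cols)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full synthetic cohort; identical spec+seed gives identical output."""
    rng = np.random.default_rng(spec.seed)
    sizes = spec.group_sizes()
    parts = []
    for group in SEVERITY_GROUPS:
        size = sizes[group]
        part = _draw_group(spec.groups[group], size, spec.assay, rng)
        part["severity_group"] = group
        parts.append(part)
    if spec.n == 0:
        frame = pd.DataFrame(columns=list(COHORT_COLUMNS))
        return Cohort(frame, provenance=spec)
    frame = pd.concat(parts, ignore_index=True)
    frame["died_30d"] = frame["severity_group"] == "non_survivor"
    dys_cols = [f"_dys_{d}" for d in ORGAN_DYSFUNCTIONS]
    frame["organ_dysfunction"] = [
        ";".join(d for d, on in zip(ORGAN_DYSFUNCTIONS, flags) if on)
        for flags in frame[dys_cols].to_numpy()
    ]
    frame = frame.drop(columns=dys_cols)
    width = max(4, len(str(spec.n)))
    frame.insert(0, "id", [f"P{i + 1:0{width}d}" for i in range(len(frame))])
    frame["split"] = "unassigned"
    frame = frame[list(COHORT_COLUMNS)]
    return Cohort(frame, provenance=spec)


def split_cohort(cohort: Cohort, derivation_fraction: float, seed: int) -> Cohort:
    """Random derivation/validation partition (round-half-up derivation size)."""
    if not 0 < derivation_fraction < 1:
        raise ValueError("derivation_fraction must lie in (0, 1)")
    n = len(cohort)
    if n == 0:
        raise ValueError("cannot split an empty cohort")
    n_deriv = int(np.floor(n * derivation_fraction + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.full(n, "validation", dtype=object)
    labels[perm[:n_deriv]] = "derivation"
    frame = cohort.frame.copy()
    frame["split"] = labels
    return Cohort(frame, provenance=cohort.provenance)
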