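# Methods

## Scores

qSOFA awards one point per criterion: GCS ≤ 14, SBP ≤ 100 mmHg,
RR > 22/min. Boundary handling follows the worded definitions exactly:
SBP of exactly 100 scores, RR of exactly 22 does not. A positivity flag
(qSOFA ≥ 2) is carried alongside and is a function of the qSOFA points
only — adding marker points never flips it.

A serum marker enters as an ordinal 0/1/2 class. For HBP the cuts are the
literature values 41 and 151 ng/mL; "under" and "above" are read strictly,
so a value equal to either cut falls in the middle class. The modified
score is the plain sum, range 0–5 with six attainable levels; we do not
cap it at 5 — the additive reading is the only one consistent with a
0–3 score plus a 0–2 class, and the "five-point" shorthand is taken to
mean a maximum of five points. CRP and NLR have no established prognostic
cuts at ED presentation, so their classifiers are derivation-set tertiles
(type-7 linear-interpolation quantiles, stated so cuts are reproducible
from a sorted sample). Notably, under the packaged severity mixture the
pooled lower tertile of HBP sits near 58 ng/mL — well above the 41 ng/mL
literature cut — so the HBP coding is not a literal tertile of the
marginal distribution; the class-0 group is smaller than a third.

## Risk models

Each score maps to 30-day mortality through a univariable logistic model
fitted by iteratively reweighted least squares with step-halving
(log-likelihood provably non-decreasing per iteration; convergence when
the relative log-likelihood change falls below 1e-10, cap 100
iterations; covariance = inverse observed information). The integer
score enters linearly by default: parsimonious, monotone, and it gives
the bedside calculator a smooth risk curve. A saturated
one-coefficient-per-level option (`categorical=True`) exists for
checking the linearity assumption. A constant predictor degenerates to
the closed-form intercept-only fit. Separated data are reported as an
error (`SeparationError`) rather than silently clipped — detected either
by coefficient divergence during iteration or by a perfectly separating
non-converged fit; penalized alternatives are deliberately out of scope.

Restricted cubic splines (truncated-power natural-spline basis with
Harrell's (t_k − t_1)² scaling; default 4 knots at the
0.05/0.35/0.65/0.95 quantiles, a standard default) support exploration
of the marker–log-odds shape when choosing cuts. The basis guarantees
linearity beyond the boundary knots; `explore_cutoffs` only tabulates
the curve — cut selection is left to the analyst.

## Evaluation statistics

**AUC** is the Mann–Whitney estimator with half-credit ties, computed by
midranks in O(n log n); its variance and the paired comparison of two
correlated AUCs use DeLong structural components. Confidence intervals
are Wald on the AUC scale clipped to [0, 1] (a logit-scale interval is
available), matching the symmetric intervals conventional in this
literature. Two identical score vectors compare with difference 0 and
p = 1 by convention.

**Calibration.** Brier score is mean(p − y)². The Hosmer–Lemeshow
statistic groups patients by quantiles of predicted risk; because a
score model yields at most six distinct risks, groups with identical
predictions are merged (grouping degenerates to one group per distinct
risk). Cell contributions are (O − E)²/(E(1 − ē)) with ē the group mean
prediction; df = g − 2 by default (a g-df variant for external
validation is available). Fewer than three effective groups after
merging is an error — with two groups the default df would be zero, so a
statistic is not computable in the development parametrization.

**Reclassification.** Risk categories are half-open on the left:
p < 0.15 low, 0.15 ≤ p < 0.35 moderate, p ≥ 0.35 high (sensitivity cuts
0.20/0.40). Categorical and continuous NRI are both computed as
(P(up) − P(down) | events) + (P(down) − P(up) | non-events); ties count
as no movement, and tie-free the continuous form reduces to
2(P(up|event) − P(up|non-event)). IDI is the difference in
discrimination slopes. Standard errors are the canonical asymptotic
forms — within-stratum multinomial variance (p_up + p_down −
(p_up − p_down)²)/n per stratum for NRI, and the empirical variance of
per-patient prediction changes for IDI, with events and non-events
independent. A seeded stratified bootstrap (default 2,000 replicates,
percentile CI, resampling within events and within non-events so both
strata persist) is reported alongside as a cross-check; disagreement
between the two is surfaced in the output rather than resolved.

## Study pipeline

The default workflow mirrors a derivation/validation prediction study:
simple random 70/30 patient-level split (derivation size rounded half
up, so 794 → 556/238), CRP/NLR tertiles and all model coefficients
estimated on the derivation rows only, AUC/DeLong/calibration assessed
on the held-out 30%, and reclassification computed on all patients by
default (`reclassify_on="validation"` restricts it). Split and
bootstrap seeds are spawned from the single pipeline seed; written
reports are byte-identical across reruns (timestamps exist only on the
in-memory report object, never in files).

The packaged calculator model is a qSOFA+HBP logistic fit to the default
synthetic cohort and is labelled as such everywhere it surfaces; no
claim of clinical validity attaches to its coefficients.

## Synthetic cohort generator

The generator emulates a three-group severity mixture — survivors,
critically-ill, non-survivors, weights 350/265/179 — with each group's
variables drawn independently given the group:

- **Biomarkers** (HBP, CRP, NLR, WBC, platelets) are lognormal, location
  from the target median (exactly preserved) and scale from the IQR
  ratio via σ = ln(q75/q25)/(2·z₀.₇₅). A two-parameter lognormal cannot
  also match asymmetric quantile bounds: for targets whose median sits
  far off-center in the IQR (non-survivor CRP: 11.3/22.0/101.2 mg/L) the
  individual quartiles shift by ~15% and the IQR width by up to ~35%,
  while the median and IQR ratio are preserved. Tests therefore check
  medians against targets and quartiles against the implied lognormal.
- **Vitals and age** (GCS, SBP, RR) use a two-piece linear quantile
  function through (q25, median, q75) with same-slope tails, rounded to
  integers and truncated to physiologic support (GCS to [3, 15]); this
  reproduces printed medians and quartiles exactly, including a ceiling
  such as a survivor GCS of 15 (15, 15) — which then degenerates to a
  point mass at 15.
- **HBP assay noise**: mean-one multiplicative lognormal error with CV
  interpolated log-linearly between 0.11 at 21 ng/mL and 0.07 at
  81 ng/mL (clamped outside), then left-censored at the 5.9 ng/mL
  detection limit.
- **Outcome** is deterministic given group (non-survivors die within 30
  days, by definition of the stratum); organ-dysfunction flags and
  infection source are drawn from the printed per-group prevalences
  (source weights renormalized, as printed percentages do not sum to
  100). NLR is simulated directly as the published quantity; lymphocyte
  counts (not published per group; defaults encode typical sepsis
  lymphopenia, medians 1.2/0.9/0.8 ×10³/mm³) back out a neutrophil count
  so that NLR equals the stored count ratio exactly.

Group sizes are the largest-remainder rounding of n × proportions; all
draws come from one `numpy` Generator seeded by the spec, so identical
spec + seed is bit-identical.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: within-group correlations between
markers, vitals and dysfunction flags (only the severity mixture induces
marginal associations, so e.g. per-organ-dysfunction marker AUCs are
compressed toward 0.5 relative to a real cohort and only the marker
ordering is meaningful); any marker–GCS dependence among survivors (their
GCS is constant 15); longitudinal dynamics, treatment effects,
time-to-event structure; and consistency between WBC and the
neutrophil + lymphocyte sum. Directional conclusions (HBP improves
discrimination and reclassification, CRP/NLR do not) are robust to these
simplifications because they are driven by the between-group separation
the generator does reproduce; absolute AUC/NRI magnitudes on synthetic
cohorts should not be read as estimates for any real population.

## Numerical conventions

- Quantiles everywhere are numpy's default type-7 linear interpolation.
- Tie handling: midranks (AUC, Spearman); prediction ties are "no
  movement" (NRI); event/non-event score ties get half credit (AUC).
- Derivation-size rounding is half-up; group-size rounding is largest
  remainder with ties broken in group order.
- IRLS floors working weights at 1e-12; coefficient magnitudes above 1e3
  are treated as divergence.
- Bootstrap and split seeds are spawned from the master seed via
  `SeedSequence` and kept below 2³¹.

## Problem sizes used in tests

Distribution-recovery checks run at n = 10,000; frequentist-calibration
checks (DeLong type-I error, Hosmer–Lemeshow rejection rate) use 2,000
null replicates at n = 300–400; DeLong-vs-bootstrap agreement uses 20
datasets of n = 500 with 10,000 bootstrap replicates; the directional
study reproduction runs 50 replicate synthetic studies at the design
size n = 794. These sizes give Monte-Carlo error comfortably inside the
asserted tolerances.
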