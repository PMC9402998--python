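# qsofa-hbp

Biomarker-augmented qSOFA risk modelling for 30-day sepsis mortality.

The quick Sequential Organ Failure Assessment (qSOFA) score — one point
each for altered mentation (GCS ≤ 14), hypotension (SBP ≤ 100 mmHg) and
tachypnea (RR > 22/min) — is the standard bedside screen for
emergency-department sepsis, but its prognostic accuracy is modest.
Heparin-binding protein (HBP, azurocidin/CAP37) is a neutrophil-released
mediator of vascular leakage whose serum level rises before septic organ
dysfunction becomes clinically apparent. This package implements, end to
end, the evaluation of an HBP-augmented qSOFA: the serum marker is coded
as an ordinal class (0: < 41 ng/mL, 1: 41–151 ng/mL, 2: > 151 ng/mL) and
added to qSOFA, extending the score to a 0–5 scale while leaving the
qSOFA ≥ 2 positivity rule untouched. C-reactive protein (CRP) and the
neutrophil-to-lymphocyte ratio (NLR), coded by derivation-set tertiles,
serve as comparator modifications.

The statistical core, for two nested risk models fitted by logistic
regression of 30-day death on a score *S* (p = expit(β₀ + β₁S)):

- **Discrimination** — Mann–Whitney AUC with DeLong structural-component
  variances; correlated AUCs compared with the paired DeLong test.
- **Calibration** — Brier score mean(p − y)², Hosmer–Lemeshow
  χ² = Σ(O₉ − E₉)²/(E₉(1 − ē₉)) over predicted-risk groups, and
  calibration-plot bins.
- **Reclassification** — categorical NRI over low/moderate/high risk
  strata (< 15%, 15–35%, ≥ 35%; sensitivity cuts 20%/40%), category-free
  continuous NRI = 2(P(up|event) − P(up|non-event)) in the tie-free case,
  and IDI = Δ discrimination slope, all with asymptotic and bootstrap
  confidence intervals.
- **Cutoff exploration** — restricted cubic spline logistic fits of the
  marker–log-odds relation, linear beyond the boundary knots.

Because no patient-level cohort is distributed, the package ships a
seeded synthetic-cohort generator calibrated to published group-level
summary statistics of a 794-patient multicenter ED sepsis cohort (a
350/265/179 mixture of survivors, critically-ill patients and
non-survivors; lognormal biomarkers matched to printed medians and IQRs;
immunoassay noise with CV 11% @ 21 ng/mL → 7% @ 81 ng/mL and left
censoring at the 5.9 ng/mL detection limit). Every analysis stage is
therefore runnable and testable out of the box.

## Worked example

Full synthetic study — simulate, score, split 70/30, fit, evaluate:

```bash
qsofa-hbp report --seed 1 --bootstrap 0 --outdir report/
```

`report/summary.txt` begins:

```
qsofa-hbp study report
cohort: n=794 (synthetic), derivation 556 / validation 238, seed 1

Discrimination (AUC, 95% CI):
  qsofa      derivation  0.761 (0.715-0.806)
  qsofa      validation  0.741 (0.679-0.803)
  qsofa_hbp  derivation  0.831 (0.794-0.868)
  qsofa_hbp  validation  0.835 (0.786-0.885)
  qsofa_crp  derivation  0.697 (0.648-0.746)
  qsofa_crp  validation  0.695 (0.624-0.765)
  qsofa_nlr  derivation  0.665 (0.613-0.718)
  qsofa_nlr  validation  0.634 (0.559-0.708)

DeLong vs qSOFA (validation):
  qsofa_hbp  dAUC +0.094  z +4.73  p 2.25e-06
  qsofa_crp  dAUC -0.046  z -2.07  p 0.03813
  qsofa_nlr  dAUC -0.107  z -3.82  p 0.0001322
```

Adding HBP lifts the validation AUC of qSOFA from 0.74 to 0.84 on this
simulated cohort (DeLong p ≈ 2×10⁻⁶), while the CRP and NLR
modifications do not improve discrimination — the qualitative pattern
the score construction is designed to expose. The directory also
contains the reclassification table (NRI/IDI with CIs), calibration
statistics and bins, rank correlations, per-organ-dysfunction marker
AUCs, the fitted models as JSON, and the cohort itself.

Bedside calculator (the packaged default model is trained on the
synthetic cohort and says so on stderr):

```bash
$ qsofa-hbp predict --gcs 10 --sbp 95 --rr 24 --hbp 200
{
  "probability_30d_mortality": 0.8825,
  "risk_category": "high",
  "qsofa": 3,
  "qsofa_positive": true,
  "hbp_class": 2,
  "combined_score": 5
}
```

The same operations are available as library functions:

```python
import qsofa_hbp as q

cohort = q.generate_cohort(q.default_cohort_spec(seed=1))
frame = q.score_cohort(cohort.frame)
model = q.fit_logistic(frame["qsofa_hbp"], frame["died_30d"].astype(int))
res = q.auc(frame["qsofa_hbp"], frame["died_30d"].astype(int))
```

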