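# Default synthetic-cohort configuration.
#
# Targets are literature-derived summary statistics (medians with
# interquartile ranges, prevalences) of a multicenter emergency-department
# sepsis cohort of 794 adults, stratified into three severity groups:
# survivors (hospitalized without events), critically-ill (ICU admission,
# alive at 30 days) and non-survivors (died within 30 days).
#
# Biomarker units: hbp ng/mL, crp mg/L, wbc/platelets/lymphocytes 10^3/mm^3,
# nlr dimensionless.  Vitals: gcs (3-15), sbp mmHg, rr breaths/min, age years.
# Quantile triples are [q25, median, q75].
#
# lymphocytes has no published group summary; the defaults encode the
# lymphopenia typical of ED sepsis and exist only to back out an absolute
# neutrophil count consistent with the simulated NLR.

n: 794
seed: 20180601

group_weights:
  survivor: 350
  critically_ill: 265
  non_survivor: 179

assay:
  lod: 5.9
  cv_low: 0.11
  cv_low_at: 21.0
  cv_high: 0.07
  cv_high_at: 81.0

groups:
  survivor:
    male_fraction: 0.611
    vitals:
      gcs: [15, 15, 15]
      sbp: [110, 130, 148]
      rr: [18, 20, 20]
      age: [52, 62, 77]
    biomarkers:
      hbp: [28.7, 71.5, 156.6]
      crp: [6.6, 10.3, 16.4]
      nlr: [4.5, 8.0, 13.6]
      wbc: [6.90, 10.20, 14.06]
      platelets: [147, 217, 282]
      lymphocytes: [0.8, 1.2, 1.8]
    organ_dysfunction:
      respiratory: 0.271
      cardiovascular: 0.234
      renal: 0.174
      hepatic: 0.149
      hematologic: 0.106
      mental: 0.177
    infection_source:
      pneumonia: 0.326
      urinary_tract: 0.183
      biliary_tract: 0.146
      intra_abdominal: 0.254
      skin_soft_tissue: 0.097
      bloodstream: 0.020
      miscellaneous: 0.034
  critically_ill:
    male_fraction: 0.645
    vitals:
      gcs: [11, 15, 15]
      sbp: [105, 123, 145]
      rr: [20, 22, 27]
      age: [52, 67, 77]
    biomarkers:
      hbp: [36.2, 73.8, 139.5]
      crp: [17.8, 48.4, 108.4]
      nlr: [5.8, 11.2, 21.2]
      wbc: [7.11, 10.95, 14.73]
      platelets: [114, 174, 261]
      lymphocytes: [0.6, 0.9, 1.4]
    organ_dysfunction:
      respiratory: 0.740
      cardiovascular: 0.464
      renal: 0.419
      hepatic: 0.294
      hematologic: 0.234
      mental: 0.453
    infection_source:
      pneumonia: 0.664
      urinary_tract: 0.106
      biliary_tract: 0.034
      intra_abdominal: 0.151
      skin_soft_tissue: 0.019
      bloodstream: 0.098
      miscellaneous: 0.125
  non_survivor:
    male_fraction: 0.715
    vitals:
      gcs: [5, 11, 15]
      sbp: [94, 114, 135]
      rr: [20, 22, 26]
      age: [53, 67, 80]
    biomarkers:
      hbp: [116.0, 209.5, 286.2]
      crp: [11.3, 22.0, 101.2]
      nlr: [4.5, 7.8, 15.2]
      wbc: [8.75, 12.36, 17.31]
      platelets: [110, 194, 267]
      lymphocytes: [0.5, 0.8, 1.3]
    organ_dysfunction:
      respiratory: 0.726
      cardiovascular: 0.665
      renal: 0.508
      hepatic: 0.296
      hematologic: 0.263
      mental: 0.710
    infection_source:
      pneumonia: 0.598
      urinary_tract: 0.073
      biliary_tract: 0.062
      intra_abdominal: 0.159
      skin_soft_tissue: 0.045
      bloodstream: 0.123
      miscellaneous: 0.117
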