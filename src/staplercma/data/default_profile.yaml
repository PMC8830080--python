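# Default synthetic-cohort profile: covariate marginals, device utilization and
# cost-noise dispersion emulating the published ECHELON powered (n=296) vs.
# ECHELON manual (n=92) VATS-lobectomy cohort from a Chinese tertiary hospital.
#
# Binary covariates are per-group prevalences (complete-case proportions);
# categorical blocks are per-group probability vectors (renormalized on load);
# continuous fields are mean/sd pairs. Comorbidities that appear in the
# reference cost equations but were not reported in the published baseline
# table (cardiovascular, immune_system, breast, vascular, lung_infection,
# tuberculosis) carry package-chosen realistic prevalences (see docs/methods.md).
dispersion: 4.94   # gamma shape of the cost noise; SD/mean = 1/sqrt(shape) ~ 0.45
groups:
  powered:
    n: 296
    age_mean_sd: [57.9, 8.9]
    bmi_mean_sd: [23.8, 3.1]
    male: 0.530
    married: 0.993
    residence:
      provincial_capital: 0.254
      prefecture: 0.593
      county: 0.075
      other: 0.078
    insurance:
      urban_employee: 0.271
      urban_resident: 0.220
      new_rural: 0.271
      other: 0.237
    histology:
      squamous: 0.146
      adenocarcinoma: 0.782
      other: 0.071
    stage:
      in_situ: 0.010
      I: 0.565
      II: 0.118
      III: 0.297
      IV: 0.010
    site:
      upper_right: 0.381
      right_middle: 0.075
      lower_right: 0.143
      upper_middle_right: 0.008
      lower_middle_right: 0.016
      left_lung: 0.004
      upper_left: 0.258
      bottom_left: 0.115
    comorbidity:
      digestive: 0.439
      urological: 0.230
      hypertension: 0.203
      reproductive: 0.172
      cerebrovascular: 0.159
      bronchial: 0.135
      endocrine: 0.111
      sport_system: 0.098
      diabetes: 0.091
      heart_disease: 0.088
      emphysema: 0.074
      bullae: 0.051
      coronary: 0.027
      lung_infection: 0.10
      tuberculosis: 0.05
      cardiovascular: 0.10
      immune_system: 0.02
      breast: 0.02
      vascular: 0.02
    marrow:
      inr: 0.039
      hemoglobin: 0.159
      erythrocyte: 0.244
      leukocyte: 0.085
      platelet: 0.075
    staplers_mean_sd: [1.2, 0.6]
    cartridges_mean_sd: [7.0, 3.9]
  manual:
    n: 92
    age_mean_sd: [58.5, 9.0]
    bmi_mean_sd: [23.5, 2.8]
    male: 0.630
    married: 1.0
    residence:
      provincial_capital: 0.143
      prefecture: 0.604
      county: 0.198
      other: 0.055
    insurance:
      urban_employee: 0.192
      urban_resident: 0.077
      new_rural: 0.365
      other: 0.365
    histology:
      squamous: 0.148
      adenocarcinoma: 0.815
      other: 0.037
    stage:
      in_situ: 0.0
      I: 0.478
      II: 0.174
      III: 0.337
      IV: 0.011
    site:
      upper_right: 0.258
      right_middle: 0.030
      lower_right: 0.242
      upper_middle_right: 0.0
      lower_middle_right: 0.015
      left_lung: 0.0
      upper_left: 0.212
      bottom_left: 0.242
    comorbidity:
      digestive: 0.380
      urological: 0.163
      hypertension: 0.174
      reproductive: 0.130
      cerebrovascular: 0.174
      bronchial: 0.033
      endocrine: 0.076
      sport_system: 0.033
      diabetes: 0.087
      heart_disease: 0.120
      emphysema: 0.076
      bullae: 0.054
      coronary: 0.098
      lung_infection: 0.10
      tuberculosis: 0.05
      cardiovascular: 0.10
      immune_system: 0.02
      breast: 0.02
      vascular: 0.02
    marrow:
      inr: 0.035
      hemoglobin: 0.242
      erythrocyte: 0.143
      leukocyte: 0.099
      platelet: 0.121
    staplers_mean_sd: [1.2, 0.5]
    cartridges_mean_sd: [7.5, 4.0]
# Operational fields are drawn inside the eligibility envelope (clipped normal):
operational:
  operation_minutes: [180.0, 50.0, 30.0, 480.0]   # mean, sd, lo, hi
  length_of_stay: [10.0, 4.0, 2.0, 21.0]
  bleeding_ml: [100.0, 80.0, 10.0, 600.0]
  drainage_ml: [800.0, 400.0, 50.0, 2400.0]
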