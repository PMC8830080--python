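{
  "family": "gamma",
  "link": "log",
  "n": 388,
  "source": "published multivariable generalized linear regression estimates for classified hospital costs of VATS lobectomy in a Chinese tertiary hospital (ECHELON powered vs. manual stapler cohort, n=296/92)",
  "categories": {
    "disposables": {
      "intercept": 9.279,
      "intercept_ci": [9.203, 9.357],
      "terms": [
        {"name": "powered", "coef": -0.007, "ci": [-0.084, 0.069], "p": 0.854},
        {"name": "male", "coef": 0.041, "ci": [-0.048, 0.129], "p": 0.361},
        {"name": "bmi_18_5_24", "coef": -0.099, "ci": [-0.171, -0.028], "p": 0.007},
        {"name": "bmi_24_28", "coef": -0.133, "ci": [-0.214, -0.052], "p": 0.001},
        {"name": "bmi_30_40", "coef": -0.388, "ci": [-0.624, -0.134], "p": 0.002},
        {"name": "adenocarcinoma", "coef": -0.041, "ci": [-0.108, 0.025], "p": 0.225},
        {"name": "stage_i", "coef": 0.058, "ci": [-0.005, 0.120], "p": 0.072},
        {"name": "abnormal_inr", "coef": 0.141, "ci": [-0.022, 0.311], "p": 0.099},
        {"name": "abnormal_hemoglobin", "coef": 0.076, "ci": [-0.004, 0.157], "p": 0.066},
        {"name": "site_upper_left", "coef": -0.026, "ci": [-0.100, 0.050], "p": 0.500},
        {"name": "hypertension", "coef": -0.051, "ci": [-0.128, 0.026], "p": 0.193},
        {"name": "immune_system", "coef": 0.177, "ci": [-0.193, 0.583], "p": 0.355},
        {"name": "breast", "coef": -0.524, "ci": [-0.917, -0.075], "p": 0.015}
      ]
    },
    "drugs": {
      "intercept": 9.492,
      "intercept_ci": [9.337, 9.649],
      "terms": [
        {"name": "powered", "coef": -0.256, "ci": [-0.375, -0.139], "p": 0.001},
        {"name": "male", "coef": 0.041, "ci": [-0.048, 0.129], "p": 0.361},
        {"name": "bmi_24_28", "coef": -0.148, "ci": [-0.250, -0.044], "p": 0.005},
        {"name": "bmi_28_30", "coef": -0.330, "ci": [-0.535, -0.112], "p": 0.002},
        {"name": "county", "coef": 0.134, "ci": [-0.002, 0.273], "p": 0.058},
        {"name": "married", "coef": -0.010, "ci": [-0.129, 0.106], "p": 0.864},
        {"name": "urban_employee_insurance", "coef": -0.049, "ci": [-0.155, 0.058], "p": 0.367},
        {"name": "adenocarcinoma", "coef": 0.018, "ci": [-0.074, 0.109], "p": 0.702},
        {"name": "stage_i", "coef": -0.153, "ci": [-0.240, -0.067], "p": 0.001},
        {"name": "abnormal_platelet", "coef": 0.233, "ci": [0.085, 0.386], "p": 0.002},
        {"name": "site_upper_left", "coef": 0.029, "ci": [-0.071, 0.131], "p": 0.576},
        {"name": "diabetes", "coef": 0.124, "ci": [-0.017, 0.270], "p": 0.091},
        {"name": "cerebrovascular", "coef": 0.095, "ci": [-0.018, 0.210], "p": 0.103},
        {"name": "urological", "coef": 0.144, "ci": [0.045, 0.246], "p": 0.005},
        {"name": "cardiovascular", "coef": 0.073, "ci": [-0.066, 0.217], "p": 0.310},
        {"name": "endocrine", "coef": -0.164, "ci": [-0.297, -0.026], "p": 0.019}
      ]
    },
    "operation": {
      "intercept": 8.925,
      "intercept_ci": [8.856, 8.994],
      "terms": [
        {"name": "powered", "coef": 0.004, "ci": [-0.065, 0.072], "p": 0.909},
        {"name": "stage_i", "coef": -0.052, "ci": [-0.110, 0.006], "p": 0.079},
        {"name": "site_upper_left", "coef": 0.002, "ci": [-0.070, 0.075], "p": 0.954},
        {"name": "bronchial", "coef": 0.108, "ci": [0.015, 0.203], "p": 0.025},
        {"name": "immune_system", "coef": -0.393, "ci": [-0.707, -0.047], "p": 0.019},
        {"name": "cerebrovascular", "coef": 0.040, "ci": [-0.038, 0.120], "p": 0.316},
        {"name": "urological", "coef": 0.074, "ci": [0.002, 0.146], "p": 0.045},
        {"name": "cardiovascular", "coef": 0.066, "ci": [-0.032, 0.167], "p": 0.196},
        {"name": "sport_system", "coef": 0.071, "ci": [-0.033, 0.178], "p": 0.186},
        {"name": "vascular", "coef": 0.088, "ci": [-0.142, 0.334], "p": 0.472}
      ]
    },
    "laboratory": {
      "intercept": 9.133,
      "intercept_ci": [8.851, 9.417],
      "terms": [
        {"name": "powered", "coef": -0.094, "ci": [-0.203, 0.014], "p": 0.082},
        {"name": "age", "coef": 0.002, "ci": [-0.003, 0.007], "p": 0.367},
        {"name": "bmi_18_5_24", "coef": 0.100, "ci": [0.013, 0.188], "p": 0.024},
        {"name": "new_rural_insurance", "coef": -0.029, "ci": [-0.128, 0.071], "p": 0.562},
        {"name": "adenocarcinoma", "coef": -0.031, "ci": [-0.117, 0.055], "p": 0.480},
        {"name": "stage_i", "coef": -0.033, "ci": [-0.113, 0.048], "p": 0.427},
        {"name": "abnormal_leukocyte", "coef": -0.117, "ci": [-0.256, 0.026], "p": 0.101},
        {"name": "site_upper_left", "coef": 0.014, "ci": [-0.082, 0.111], "p": 0.781},
        {"name": "immune_system", "coef": -0.521, "ci": [-0.944, -0.039], "p": 0.023},
        {"name": "diabetes", "coef": 0.165, "ci": [0.030, 0.305], "p": 0.019},
        {"name": "cerebrovascular", "coef": 0.046, "ci": [-0.063, 0.157], "p": 0.415},
        {"name": "urological", "coef": 0.133, "ci": [0.038, 0.230], "p": 0.007},
        {"name": "cardiovascular", "coef": 0.088, "ci": [-0.046, 0.225], "p": 0.206}
      ]
    },
    "other": {
      "intercept": 7.707,
      "intercept_ci": [7.618, 7.798],
      "terms": [
        {"name": "powered", "coef": -0.008, "ci": [-0.099, 0.080], "p": 0.854},
        {"name": "stage_i", "coef": -0.083, "ci": [-0.159, -0.007], "p": 0.033},
        {"name": "site_upper_left", "coef": -0.019, "ci": [-0.111, 0.075], "p": 0.684},
        {"name": "immune_system", "coef": -0.410, "ci": [-0.817, 0.054], "p": 0.064},
        {"name": "diabetes", "coef": 0.158, "ci": [0.028, 0.292], "p": 0.020},
        {"name": "cerebrovascular", "coef": 0.068, "ci": [-0.033, 0.172], "p": 0.195},
        {"name": "urological", "coef": 0.176, "ci": [0.084, 0.269], "p": 0.001}
      ]
    }
  }
}
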