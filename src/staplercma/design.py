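"""Covariate coding shared by the synthetic generator, the cost regressions
and the decision model.

Every cost equation is written against a small vocabulary of named terms
(e.g. ``powered``, ``bmi_24_28``, ``urological``). This module maps term
names to 0/1 indicator (or continuous) columns derived from a patient-level
cohort table, so the same coding is used when simulating costs from a
coefficient table and when fitting equations back from data.

BMI bands are one-vs-rest indicators against "all other bands", matching how
the reference coefficient table phrases them, rather than levels of a single
factor with one reference band.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

#: BMI band labels and their half-open [lo, hi) boundaries in kg/m^2.
#: The top band is unbounded above so every BMI maps to exactly one band.
BMI_BANDS: tuple[tuple[str, float, float], ...] = (
    ("<18.5", -np.inf, 18.5),
    ("18.5-24", 18.5, 24.0),
    ("24-28", 24.0, 28.0),
    ("28-30", 28.0, 30.0),
    ("30-40", 30.0, np.inf),
)

COMORBIDITIES = (
    "digestive", "urological", "hypertension", "reproductive",
    "cerebrovascular", "bronchial", "endocrine", "sport_system", "diabetes",
    "heart_disease", "emphysema", "bullae", "coronary", "lung_infection",
    "tuberculosis", "breast", "immune_system", "cardiovascular", "vascular",
)

MARROW_FLAGS = ("inr", "hemoglobin", "erythrocyte", "leukocyte", "platelet")

RESIDENCES = ("provincial_capital", "prefecture", "county", "other")
INSURANCES = ("urban_employee", "urban_resident", "new_rural", "other")
HISTOLOGIES = ("squamous", "adenocarcinoma", "other")
STAGES = ("in_situ", "I", "II", "III", "IV")
SITES = (
    "upper_right", "right_middle", "lower_right", "upper_middle_right",
    "lower_middle_right", "left_lung", "upper_left", "bottom_left",
)


def bmi_band(bmi: float) -> str:
    """Return the BMI band label for a BMI in kg/m^2."""
    for label, lo, hi in BMI_BANDS:
        if lo <= bmi < hi:
            return label
    raise ValueError(f"BMI {bmi!r} is not a finite number")


def _band_indicator(label: str):
    return lambda df: (df["bmi_band"] == label).astype(float)


def _eq(column: str, value: str):
    return lambda df: (df[column] == value).astype(float)


def _flag(column: str):
    return lambda df: df[column].astype(float)


#: term name -> function(patients DataFrame) -> float Series
TERM_BUILDERS: dict = {
    "powered": _eq("group", "powered"),
    "male": _eq("sex", "male"),
    "age": lambda df: df["age"].astype(float),
    "bmi_under_18_5": _band_indicator("<18.5"),
    "bmi_18_5_24": _band_indicator("18.5-24"),
    "bmi_24_28": _band_indicator("24-28"),
    "bmi_28_30": _band_indicator("28-30"),
    "bmi_30_40": _band_indicator("30-40"),
    "county": _eq("residence", "county"),
    "married": _eq("marital", "married"),
    "urban_employee_insurance": _eq("insurance", "urban_employee"),
    "new_rural_insurance": _eq("insurance", "new_rural"),
    "adenocarcinoma": _eq("histology", "adenocarcinoma"),
    "stage_i": _eq("stage", "I"),
    "site_upper_left": _eq("site", "upper_left"),
}
TERM_BUILDERS.update({name: _flag(f"comorb_{name}") for name in COMORBIDITIES})
TERM_BUILDERS.update({f"abnormal_{name}": _flag(f"marrow_{name}") for name in MARROW_FLAGS})

#: Candidate covariates entered into univariable screening (everything the
#: builders can code except the stapler indicator, which is forced in).
SCREENING_CANDIDATES: tuple[str, ...] = tuple(
    name for name in TERM_BUILDERS if name != "powered"
)


def design_matrix(patients: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Build the model matrix (no intercept column) for the named terms.

    Raises ``KeyError`` naming the term if it is unknown, or the underlying
    column if the cohort table lacks it.
    """
    cols = {}
    for term in terms:
        try:
            builder = TERM_BUILDERS[term]
        except KeyError:
            raise KeyError(f"unknown covariate term {term!r}") from None
        cols[term] = builder(patients)
    return pd.DataFrame(cols, index=patients.index)


def missing_terms(patients: pd.DataFrame, terms: Iterable[str]) -> list[str]:
    """Names of terms whose source columns are absent from the cohort table."""
    out = []
    for term in terms:
        try:
            TERM_BUILDERS[term](patients.iloc[:0])
        except KeyError:
            out.append(term)
    return out
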