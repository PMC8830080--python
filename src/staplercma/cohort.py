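"""Patient-level cohort data model, CSV I/O and eligibility filtering.

A cohort is held as two aligned pandas DataFrames:

* a *patients* table, one row per surgical episode (demographics, comorbidity
  flags, tumor characteristics, lobectomy site, stapler group, device counts,
  and the operational fields the eligibility screen reads), and
* a *costs* table, one row per episode with the seven per-category hospital
  costs in CNY and their total.

On disk the two are a single UTF-8 comma-separated file, one row per episode,
costs as plain decimals without currency symbols. The full column dictionary
is in ``docs/methods.md``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import COMORBIDITIES, MARROW_FLAGS, BMI_BANDS

#: cost categories in reporting order; the first two are device acquisition
COST_CATEGORIES = (
    "stapler", "cartridge", "disposables", "drugs", "operation", "laboratory", "other",
)

COST_COLUMNS = (
    "stapler_cost", "cartridge_cost", "disposables_cost", "drug_cost",
    "operation_cost", "laboratory_cost", "other_cost", "total_cost",
)

PATIENT_COLUMNS = (
    ("patient_id", "group", "age", "sex", "bmi", "bmi_band", "residence",
     "insurance", "marital", "histology", "stage", "site")
    + tuple(f"comorb_{c}" for c in COMORBIDITIES)
    + tuple(f"marrow_{m}" for m in MARROW_FLAGS)
    + ("staplers_used", "cartridges_used", "operation_minutes",
       "length_of_stay", "bleeding_ml", "drainage_ml", "died_in_surgery",
       "discharge_routine")
)

#: columns a CSV must provide; everything else is preserved but unvalidated
MANDATORY_COLUMNS = ("patient_id", "group") + COST_COLUMNS

_TOTAL_RTOL = 1e-6


class SchemaError(ValueError):
    """A cohort table violates the column or value contract."""


@dataclass(frozen=True)
class EligibilityThresholds:
    """Exclusion thresholds for unusual clinical circumstances.

    All comparisons are strict (">"): an episode sitting exactly on a
    threshold is retained. Operation time is stored in minutes and the
    hour threshold converted internally to avoid unit ambiguity.
    """

    max_operation_hours: float = 8.0
    max_los_days: float = 21.0
    max_bleeding_ml: float = 600.0
    max_drainage_ml: float = 2400.0
    require_routine_discharge: bool = True
    exclude_surgical_death: bool = True

    def __post_init__(self) -> None:
        for name in ("max_operation_hours", "max_los_days",
                     "max_bleeding_ml", "max_drainage_ml"):
            if not getattr(self, name) > 0:
                raise ValueError(f"threshold {name} must be > 0")

    @property
    def max_operation_minutes(self) -> float:
        return self.max_operation_hours * 60.0


#: (column, predicate builder, reason) for each exclusion criterion
def _criteria(th: EligibilityThresholds):
    crits = [
        ("operation_minutes",
         lambda s: s > th.max_operation_minutes,
         f"operation time > {th.max_operation_hours:g} hours"),
        ("length_of_stay",
         lambda s: s > th.max_los_days,
         f"length of stay > {th.max_los_days:g} days"),
        ("bleeding_ml",
         lambda s: s > th.max_bleeding_ml,
         f"bleeding > {th.max_bleeding_ml:g} ml"),
        ("drainage_ml",
         lambda s: s > th.max_drainage_ml,
         f"drainage > {th.max_drainage_ml:g} ml"),
    ]
    if th.exclude_surgical_death:
        crits.append(("died_in_surgery", lambda s: s.astype(bool), "died during surgery"))
    if th.require_routine_discharge:
        crits.append(("discharge_routine", lambda s: ~s.astype(bool), "non-routine discharge"))
    return crits


def apply_eligibility_filters(
    patients: pd.DataFrame,
    thresholds: EligibilityThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a cohort into eligible episodes and an exclusion report.

    Returns ``(included, exclusions)`` where *included* preserves input order
    and *exclusions* has one row per excluded episode with a semicolon-joined
    list of every violated criterion. A record is excluded iff it violates at
    least one criterion; the two outputs partition the input exactly.
    """
    th = thresholds or EligibilityThresholds()
    if patients.empty:
        return patients.copy(), pd.DataFrame(columns=["patient_id", "reasons"])

    crits = _criteria(th)
    for column, _, _ in crits:
        if column not in patients.columns:
            raise SchemaError(f"eligibility filtering requires column {column!r}")
        bad = patients[column].isna()
        if bad.any():
            pid = patients.loc[bad, "patient_id"].iloc[0]
            raise SchemaError(
                f"record {pid!r} is missing eligibility field {column!r}")

    reasons = pd.Series([[] for _ in range(len(patients))], index=patients.index)
    for column, pred, reason in crits:
        hit = pred(patients[column])
        for idx in patients.index[np.asarray(hit, dtype=bool)]:
            reasons.loc[idx].append(reason)

    violated = reasons.map(len) > 0
    included = patients.loc[~violated].copy()
    exclusions = pd.DataFrame({
        "patient_id": patients.loc[violated, "patient_id"].to_numpy(),
        "reasons": ["; ".join(r) for r in reasons[violated]],
    })
    return included, exclusions


def validate_costs(costs: pd.DataFrame) -> None:
    """Enforce the cost-record invariant: total = sum of the seven components."""
    missing = [c for c in COST_COLUMNS if c not in costs.columns]
    if missing:
        raise SchemaError(f"cost table is missing column(s) {missing}")
    components = costs[list(COST_COLUMNS[:-1])].sum(axis=1)
    total = costs["total_cost"]
    bad = ~np.isclose(components, total, rtol=_TOTAL_RTOL, atol=1e-9)
    if bad.any():
        ids = costs.loc[bad, "patient_id"].tolist()
        raise SchemaError(
            f"total_cost differs from the sum of components beyond tolerance "
            f"for patient_id(s) {ids}")


def write_cohort(path, patients: pd.DataFrame, costs: pd.DataFrame) -> None:
    """Write a cohort as a single one-row-per-episode CSV."""
    validate_costs(costs)
    merged = patients.merge(costs, on="patient_id", validate="one_to_one")
    merged.to_csv(path, index=False)


def read_cohort(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort CSV back into (patients, costs) tables.

    Unknown columns are preserved on the patients table. Missing mandatory
    columns raise :class:`SchemaError` naming them; rows with unparseable
    numeric fields are reported with their file line numbers (header = line 1).
    """
    raw = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"cohort CSV is missing mandatory column(s) {missing}")

    numeric = [c for c in COST_COLUMNS if c in raw.columns]
    bad_lines = []
    for col in numeric:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        newly_bad = coerced.isna() & raw[col].notna()
        bad_lines.extend((int(i) + 2) for i in raw.index[newly_bad])
        raw[col] = coerced
    if bad_lines:
        raise SchemaError(
            f"malformed numeric value(s) on line(s) {sorted(set(bad_lines))}")

    cost_cols = ["patient_id", *COST_COLUMNS]
    costs = raw[cost_cols].copy()
    patients = raw.drop(columns=list(COST_COLUMNS))
    validate_costs(costs)
    if "bmi" in patients.columns and "bmi_band" in patients.columns:
        from .design import bmi_band
        mismatch = [
            pid for pid, b, band in zip(patients["patient_id"], patients["bmi"],
                                        patients["bmi_band"])
            if np.isfinite(b) and bmi_band(float(b)) != band
        ]
        if mismatch:
            raise SchemaError(f"bmi_band inconsistent with bmi for {mismatch}")
    return patients, costs
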