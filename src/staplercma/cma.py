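"""Decision-analytic cost-minimization engine.

Two scenarios (powered vs. manual stapler) are costed over seven categories:
device acquisition (stapler, cartridge) priced as mean devices per episode x
unit price, and five regression-driven categories (disposable supplies,
drugs, operation-related, laboratory tests, other) predicted from log-link
cost equations. The stapler-type coefficient acts multiplicatively: the
powered scenario's category cost is the manual baseline x exp(beta).

Two modes are supported. *aggregate_calibrated* takes published per-category
manual-scenario baseline costs as calibration and needs no patient data;
*patient_level* averages per-patient predictions exp(x'b) over a cohort with
the stapler indicator forced to each arm. The two agree whenever the
cohort's mean manual-arm category costs equal the calibration values.

Uncertainty propagation: one-way (tornado) sensitivity over coefficient CIs
and device prices, and Monte Carlo probabilistic sensitivity analysis (PSA)
drawing the stapler-type coefficients per patient per iteration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace, field
from importlib import resources

import numpy as np
import pandas as pd

from .design import design_matrix
from .regression import CoefficientTable, CostEquation

#: reporting order of the seven cost categories
CATEGORIES = ("stapler", "cartridge", "disposables", "drugs", "operation",
              "laboratory", "other")
REGRESSION_CATEGORIES = CATEGORIES[2:]


@dataclass(frozen=True)
class StaplerProduct:
    """A stapling device brand: unit prices and mean per-episode utilization."""

    name: str
    stapler_unit_price: float
    cartridge_unit_price: float
    mean_staplers: float
    mean_cartridges: float

    def __post_init__(self) -> None:
        if self.stapler_unit_price <= 0 or self.cartridge_unit_price <= 0:
            raise ValueError(f"product {self.name!r}: unit prices must be > 0")
        if self.mean_staplers < 0 or self.mean_cartridges < 0:
            raise ValueError(f"product {self.name!r}: mean counts must be >= 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """One arm of the decision model.

    ``mode='aggregate_calibrated'`` requires ``calibration`` (per-category
    manual-baseline costs in CNY); ``mode='patient_level'`` requires a
    ``cohort`` table. ``acquisition_override`` replaces the price x count
    acquisition arithmetic with explicit stapler/cartridge costs (used for
    the Victor Medical scenario, whose published acquisition cells are not
    the product of its unit prices and the manual utilization means).
    """

    product: StaplerProduct
    stapler_arm: str
    mode: str = "aggregate_calibrated"
    calibration: dict | None = None
    cohort: pd.DataFrame | None = None
    acquisition_override: dict | None = None

    def __post_init__(self) -> None:
        if self.stapler_arm not in ("powered", "manual"):
            raise ValueError(f"unknown stapler_arm {self.stapler_arm!r}")
        if self.mode == "aggregate_calibrated":
            if self.calibration is None:
                raise ValueError("aggregate_calibrated mode requires calibration")
            missing = [c for c in REGRESSION_CATEGORIES if c not in self.calibration]
            if missing:
                raise ValueError(f"calibration missing category(ies) {missing}")
        elif self.mode == "patient_level":
            if self.cohort is None:
                raise ValueError("patient_level mode requires a cohort")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class CmaComparison:
    """Base-case comparison of two scenarios (costs in CNY)."""

    label_a: str
    label_b: str
    costs_a: dict
    costs_b: dict
    difference: dict

    @property
    def total_a(self) -> float:
        return self.costs_a["total"]

    @property
    def total_b(self) -> float:
        return self.costs_b["total"]

    @property
    def total_difference(self) -> float:
        return self.difference["total"]

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, self.costs_a[c], self.costs_b[c], self.difference[c])
                for c in (*CATEGORIES, "total")]
        return pd.DataFrame(rows, columns=["category", self.label_a,
                                           self.label_b, "difference"])


@dataclass(frozen=True)
class TornadoEntry:
    """Total-difference swing from varying one parameter between its bounds."""

    parameter: str
    low_total_difference: float
    high_total_difference: float

    @property
    def span(self) -> float:
        return abs(self.high_total_difference - self.low_total_difference)


@dataclass(frozen=True)
class PsaSummary:
    """Monte Carlo PSA output: draws of the total difference and summaries."""

    n_iterations: int
    draws: np.ndarray
    median: float
    percentile_2_5: float
    percentile_97_5: float
    probability_saving: float
    seed: int | None

    def to_dict(self) -> dict:
        return {"n_iterations": self.n_iterations, "median": self.median,
                "percentile_2_5": self.percentile_2_5,
                "percentile_97_5": self.percentile_97_5,
                "probability_saving": self.probability_saving,
                "seed": self.seed}


def load_reference_products() -> dict:
    """The shipped device price list (ECHELON powered/manual, Victor)."""
    text = resources.files("staplercma.data").joinpath(
        "reference_products.json").read_text(encoding="utf-8")
    data = json.loads(text)["products"]
    return {key: StaplerProduct(**block) for key, block in data.items()}


def load_reference_calibration() -> dict:
    """Shipped aggregate-mode calibration: manual per-category baselines and
    the published Victor acquisition cells."""
    text = resources.files("staplercma.data").joinpath(
        "reference_calibration.json").read_text(encoding="utf-8")
    data = json.loads(text)
    return {"manual_baseline": data["manual_baseline"],
            "victor_acquisition": data["victor_acquisition"]}


def acquisition_cost(product: StaplerProduct) -> tuple[float, float]:
    """(stapler cost, cartridge cost) = mean devices per episode x unit price."""
    return (product.mean_staplers * product.stapler_unit_price,
            product.mean_cartridges * product.cartridge_unit_price)


def predict_category_cost(equation: CostEquation, reference_cost: float,
                          stapler_arm: str) -> float:
    """Apply the stapler-type coefficient to a manual-baseline category cost.

    The manual arm returns the baseline unchanged; the powered arm scales it
    by exp(beta) for that category's stapler term.
    """
    if reference_cost <= 0:
        raise ValueError("reference_cost must be > 0")
    if stapler_arm == "manual":
        return float(reference_cost)
    if stapler_arm == "powered":
        return float(reference_cost * np.exp(equation.stapler_term.coef))
    raise ValueError(f"unknown stapler_arm {stapler_arm!r}")


def _patient_level_category(equation: CostEquation, cohort: pd.DataFrame,
                            stapler_arm: str) -> float:
    """Mean over the cohort of exp(x'b) with the stapler indicator forced."""
    terms = [t for t in equation.terms if t.name != "powered"]
    eta = np.full(len(cohort), equation.intercept, dtype=float)
    if terms:
        X = design_matrix(cohort, [t.name for t in terms])
        eta += X.to_numpy(dtype=float) @ np.array([t.coef for t in terms])
    eta += equation.stapler_term.coef * (1.0 if stapler_arm == "powered" else 0.0)
    return float(np.exp(eta).mean())


def scenario_costs(spec: ScenarioSpec, equations: CoefficientTable) -> dict:
    """Per-category and total costs (CNY) for one scenario."""
    if spec.acquisition_override is not None:
        stapler = float(spec.acquisition_override["stapler"])
        cartridge = float(spec.acquisition_override["cartridge"])
    else:
        stapler, cartridge = acquisition_cost(spec.product)
    out = {"stapler": stapler, "cartridge": cartridge}
    for category in REGRESSION_CATEGORIES:
        eq = equations[category]
        if spec.mode == "aggregate_calibrated":
            out[category] = predict_category_cost(
                eq, float(spec.calibration[category]), spec.stapler_arm)
        else:
            out[category] = _patient_level_category(eq, spec.cohort,
                                                    spec.stapler_arm)
    out["total"] = sum(out[c] for c in CATEGORIES)
    return out


def run_comparison(spec_a: ScenarioSpec, spec_b: ScenarioSpec,
                   equations: CoefficientTable,
                   label_a: str = "scenario A",
                   label_b: str = "scenario B") -> CmaComparison:
    """Cost both scenarios and take category-wise differences A - B."""
    costs_a = scenario_costs(spec_a, equations)
    costs_b = scenario_costs(spec_b, equations)
    difference = {key: costs_a[key] - costs_b[key] for key in costs_a}
    return CmaComparison(label_a, label_b, costs_a, costs_b, difference)


def run_base_case(powered: ScenarioSpec, comparator: ScenarioSpec,
                  equations: CoefficientTable) -> CmaComparison:
    """Base-case CMA: powered scenario vs. manual comparator."""
    if powered.stapler_arm != "powered" or comparator.stapler_arm != "manual":
        raise ValueError("run_base_case expects a powered spec and a manual "
                         "comparator spec")
    return run_comparison(powered, comparator, equations,
                          powered.product.name, comparator.product.name)


def run_scenario_substitution(powered: ScenarioSpec, comparator: ScenarioSpec,
                              substitute_product: StaplerProduct,
                              equations: CoefficientTable,
                              substitute_acquisition: dict | None = None
                              ) -> CmaComparison:
    """Replace the comparator's device brand, keeping every regression-driven
    category identical to the original comparator scenario.

    ``substitute_acquisition`` supplies explicit stapler/cartridge costs for
    the substitute (published calibration); with ``None`` they are computed
    as the substitute's unit prices x the comparator's utilization means.
    """
    if substitute_acquisition is None:
        sub_product = replace(substitute_product,
                              mean_staplers=comparator.product.mean_staplers,
                              mean_cartridges=comparator.product.mean_cartridges)
        override = None
    else:
        sub_product = substitute_product
        override = dict(substitute_acquisition)
    sub_spec = replace(comparator, product=sub_product,
                       acquisition_override=override)
    return run_comparison(powered, sub_spec, equations,
                          powered.product.name, substitute_product.name)


def _stapler_se(equation: CostEquation) -> float:
    return equation.stapler_term.se


def one_way_sensitivity(powered: ScenarioSpec, comparator: ScenarioSpec,
                        equations: CoefficientTable,
                        price_fraction: float = 0.20) -> list[TornadoEntry]:
    """One-way (tornado) sensitivity of the total cost difference.

    Each stapler-type coefficient is varied across its 95% CI and each unit
    price by +/-``price_fraction``, one at a time with everything else at
    base case. Entries are sorted by swing (|high - low|), largest first,
    and always bracket the base-case difference.
    """
    entries: list[TornadoEntry] = []

    def total_diff(eqs: CoefficientTable, pw: ScenarioSpec,
                   cp: ScenarioSpec) -> float:
        return run_comparison(pw, cp, eqs).total_difference

    for category in REGRESSION_CATEGORIES:
        eq = equations[category]
        term = eq.stapler_term
        lo_eq = dict(equations.equations)
        hi_eq = dict(equations.equations)
        lo_eq[category] = eq.with_term_coef("powered", term.ci_low)
        hi_eq[category] = eq.with_term_coef("powered", term.ci_high)
        lo = total_diff(CoefficientTable(lo_eq, equations.family, equations.n),
                        powered, comparator)
        hi = total_diff(CoefficientTable(hi_eq, equations.family, equations.n),
                        powered, comparator)
        entries.append(TornadoEntry(
            f"{category} stapler coefficient", lo, hi))

    def scaled(spec: ScenarioSpec, which: str, factor: float) -> ScenarioSpec:
        if spec.acquisition_override is not None:
            override = dict(spec.acquisition_override)
            override[which] = override[which] * factor
            return replace(spec, acquisition_override=override)
        field_name = f"{which}_unit_price"
        product = replace(spec.product,
                          **{field_name: getattr(spec.product, field_name) * factor})
        return replace(spec, product=product)

    for side, spec in (("powered", powered), ("comparator", comparator)):
        for which in ("stapler", "cartridge"):
            lo_spec = scaled(spec, which, 1.0 - price_fraction)
            hi_spec = scaled(spec, which, 1.0 + price_fraction)
            if side == "powered":
                lo = total_diff(equations, lo_spec, comparator)
                hi = total_diff(equations, hi_spec, comparator)
            else:
                lo = total_diff(equations, powered, lo_spec)
                hi = total_diff(equations, powered, hi_spec)
            entries.append(TornadoEntry(f"{side} {which} unit price", lo, hi))

    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def run_psa(powered: ScenarioSpec, comparator: ScenarioSpec,
            equations: CoefficientTable, n_iterations: int = 10_000,
            n_patients: int = 388, seed: int | None = None,
            per_patient: bool = True, mean_preserving: bool = True,
            se_scale: float = 1.0) -> PsaSummary:
    """Monte Carlo probabilistic sensitivity analysis of the total difference.

    Per iteration each simulated patient receives an independent normal draw
    of each category's stapler-type coefficient (SE = CI width / 3.92) on the
    log scale; per-patient powered-scenario costs are computed and averaged
    over the ``n_patients`` model cohort, giving one total-difference draw
    per iteration. With ``mean_preserving=True`` (default) the draws are
    moment-matched so the expected cost multiplier equals the base-case
    multiplier exp(beta-hat), the standard parameterization when a log-scale
    parameter enters the model multiplicatively; with ``False`` the draws are
    centered on beta-hat itself. ``per_patient=False`` draws one coefficient
    per iteration for the whole cohort (much wider spread). Deterministic
    given ``seed``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if powered.stapler_arm != "powered" or comparator.stapler_arm != "manual":
        raise ValueError("run_psa expects a powered spec and a manual "
                         "comparator spec")
    base_a = scenario_costs(powered, equations)
    base_b = scenario_costs(comparator, equations)
    acquisition_diff = (base_a["stapler"] - base_b["stapler"]
                        + base_a["cartridge"] - base_b["cartridge"])

    rng = np.random.default_rng(seed)
    draws = np.full(n_iterations, acquisition_diff, dtype=float)
    for category in REGRESSION_CATEGORIES:
        eq = equations[category]
        beta = eq.stapler_term.coef
        se = _stapler_se(eq) * se_scale
        baseline = base_b[category]
        if se == 0.0:
            multiplier = np.full(n_iterations, np.exp(beta))
        else:
            loc = beta - 0.5 * se * se if mean_preserving else beta
            if per_patient:
                sample = rng.normal(loc, se, size=(n_iterations, n_patients))
                multiplier = np.exp(sample).mean(axis=1)
            else:
                multiplier = np.exp(rng.normal(loc, se, size=n_iterations))
        if not np.all(np.isfinite(multiplier)):
            raise FloatingPointError("non-finite PSA draw encountered")
        draws += baseline * (multiplier - 1.0)

    p2_5, med, p97_5 = np.percentile(draws, [2.5, 50.0, 97.5])
    return PsaSummary(
        n_iterations=n_iterations, draws=draws, median=float(med),
        percentile_2_5=float(p2_5), percentile_97_5=float(p97_5),
        probability_saving=float((draws < 0).sum() / n_iterations), seed=seed)


def reference_scenarios(mode: str = "aggregate_calibrated",
                        cohort: pd.DataFrame | None = None):
    """Convenience: the shipped powered / ECHELON-manual / Victor scenario
    specs built from the reference price list and calibration."""
    products = load_reference_products()
    calibration = load_reference_calibration()
    common = dict(mode=mode, cohort=cohort,
                  calibration=calibration["manual_baseline"]
                  if mode == "aggregate_calibrated" else None)
    powered = ScenarioSpec(products["echelon_powered"], "powered", **common)
    manual = ScenarioSpec(products["echelon_manual"], "manual", **common)
    victor = ScenarioSpec(products["victor_manual"], "manual", **common,
                          acquisition_override=calibration["victor_acquisition"])
    return powered, manual, victor
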