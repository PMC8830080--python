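"""Per-category log-link cost equations.

The cost model is a generalized linear model with gamma errors and a log
link: E[cost | x] = exp(b0 + x'b), the standard specification for positive,
right-skewed hospital-cost data. Coefficients act multiplicatively on cost,
which is what lets the decision model apply a stapler-type coefficient as a
cost multiplier. A log-normal alternative (OLS on log cost) is available
behind the ``family`` flag for sensitivity.

Model selection follows a univariable screen: every candidate covariate is
tested alone against each cost category, and those with p below the screening
alpha enter the multivariable fit. The stapler-type indicator is forced into
every multivariable equation regardless of screening, since it is the
decision variable of the analysis.

The estimators follow the scikit-learn protocol (``fit`` / ``predict``,
``get_params`` / ``set_params``, trailing-underscore fitted attributes) so
they compose with sklearn pipelines and model selection; the module-level
functions are thin wrappers over them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

try:
    from statsmodels.tools.sm_exceptions import \
        PerfectSeparationWarning as _PerfectSeparationWarning
except ImportError:  # older statsmodels
    class _PerfectSeparationWarning(UserWarning):
        pass

from .design import SCREENING_CANDIDATES, design_matrix

#: the five regression-modelled cost categories -> cohort cost column
CATEGORY_COLUMNS = {
    "disposables": "disposables_cost",
    "drugs": "drug_cost",
    "operation": "operation_cost",
    "laboratory": "laboratory_cost",
    "other": "other_cost",
}

_Z975 = 3.92 / 2.0  # normal 97.5% quantile implied by the CI-width convention


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


@dataclass(frozen=True)
class EquationTerm:
    """One covariate term of a cost equation (log-scale)."""

    name: str
    coef: float
    ci_low: float
    ci_high: float
    p_value: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.coef <= self.ci_high):
            raise ValueError(
                f"term {self.name!r}: coefficient {self.coef} outside its CI "
                f"[{self.ci_low}, {self.ci_high}]")

    @property
    def se(self) -> float:
        """Standard error implied by the 95% CI: (upper - lower)/3.92."""
        return (self.ci_high - self.ci_low) / 3.92


@dataclass(frozen=True)
class CostEquation:
    """A log-scale linear predictor for one cost category."""

    category: str
    intercept: float
    intercept_ci: tuple[float, float]
    terms: tuple[EquationTerm, ...]

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    def term(self, name: str) -> EquationTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"equation {self.category!r} has no term {name!r}")

    @property
    def stapler_term(self) -> EquationTerm:
        try:
            return self.term("powered")
        except KeyError:
            raise KeyError(
                f"equation {self.category!r} lacks the stapler-type term "
                f"'powered'") from None

    def linear_predictor(self, patients: pd.DataFrame) -> np.ndarray:
        """eta = b0 + x'b for every row of a patient table."""
        X = design_matrix(patients, self.term_names)
        beta = np.array([t.coef for t in self.terms])
        return self.intercept + X.to_numpy(dtype=float) @ beta

    def predict_mean(self, patients: pd.DataFrame) -> np.ndarray:
        return np.exp(self.linear_predictor(patients))

    def with_term_coef(self, name: str, coef: float) -> "CostEquation":
        """Copy of the equation with one term's point estimate replaced
        (its CI widened if needed so the term invariant still holds)."""
        new_terms = tuple(
            EquationTerm(t.name, coef, min(t.ci_low, coef), max(t.ci_high, coef),
                         t.p_value) if t.name == name else t
            for t in self.terms
        )
        return CostEquation(self.category, self.intercept, self.intercept_ci, new_terms)


@dataclass(frozen=True)
class CoefficientTable:
    """One cost equation per modelled category plus fitting metadata."""

    equations: dict
    family: str = "gamma"
    n: int | None = None
    alpha: float | None = None
    screened: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(CATEGORY_COLUMNS) - set(self.equations)
        if missing:
            raise ValueError(f"coefficient table missing categories {sorted(missing)}")
        for eq in self.equations.values():
            eq.stapler_term  # raises if the forced term is absent

    def __getitem__(self, category: str) -> CostEquation:
        return self.equations[category]

    def to_dict(self) -> dict:
        cats = {}
        for name, eq in self.equations.items():
            cats[name] = {
                "intercept": eq.intercept,
                "intercept_ci": list(eq.intercept_ci),
                "terms": [
                    {"name": t.name, "coef": t.coef, "ci": [t.ci_low, t.ci_high],
                     "p": t.p_value}
                    for t in eq.terms
                ],
            }
        return {"family": self.family, "link": "log", "n": self.n,
                "alpha": self.alpha, "screened": self.screened,
                "categories": cats}

    @classmethod
    def from_dict(cls, data: dict) -> "CoefficientTable":
        equations = {}
        for name, block in data["categories"].items():
            terms = tuple(
                EquationTerm(t["name"], float(t["coef"]), float(t["ci"][0]),
                             float(t["ci"][1]), t.get("p"))
                for t in block["terms"]
            )
            equations[name] = CostEquation(
                name, float(block["intercept"]),
                tuple(float(v) for v in block["intercept_ci"]), terms)
        return cls(equations=equations, family=data.get("family", "gamma"),
                   n=data.get("n"), alpha=data.get("alpha"),
                   screened=data.get("screened") or {})

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "CoefficientTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def load_reference_coefficients() -> CoefficientTable:
    """The shipped reference coefficient table (published estimates)."""
    text = resources.files("staplercma.data").joinpath(
        "reference_coefficients.json").read_text(encoding="utf-8")
    return CoefficientTable.from_dict(json.loads(text))


class LogLinkCostModel(BaseEstimator, RegressorMixin):
    """Gamma (or log-normal) log-link cost regression.

    Parameters
    ----------
    family : {"gamma", "lognormal"}
        "gamma" fits a gamma GLM with log link by IRLS (maximum likelihood;
        dispersion from the Pearson statistic / residual df; Wald z CIs from
        the observed information). "lognormal" fits OLS on log(cost) and
        predicts the geometric mean exp(x'b).
    tol : float
        IRLS convergence tolerance on the relative deviance change.
    max_iter : int
        IRLS iteration budget; exhaustion raises :class:`ConvergenceError`.

    Attributes
    ----------
    intercept_, coef_ : fitted log-scale parameters
    se_, conf_int_, p_values_ : Wald inference per coefficient (intercept last
        row of ``conf_int_`` is excluded; see ``intercept_ci_``)
    dispersion_ : estimated dispersion (Pearson X2 / df_resid)
    """

    def __init__(self, family: str = "gamma", tol: float = 1e-8,
                 max_iter: int = 100):
        self.family = family
        self.tol = tol
        self.max_iter = max_iter

    def _validate(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            if Xa.ndim == 1:
                Xa = Xa[:, None]
            names = [f"x{i}" for i in range(Xa.shape[1])]
        ya = np.asarray(y, dtype=float).ravel()
        if Xa.shape[0] != ya.shape[0]:
            raise ValueError("X and y have different lengths")
        if not np.all(np.isfinite(Xa)) or not np.all(np.isfinite(ya)):
            raise ValueError("non-finite values in the design or response")
        if np.any(ya <= 0):
            raise ValueError("costs must be strictly positive for a log link")
        Xc = np.column_stack([np.ones(len(ya)), Xa])
        rank = np.linalg.matrix_rank(Xc)
        if rank < Xc.shape[1]:
            # name a column whose removal restores full rank
            for j, name in enumerate(names):
                reduced = np.delete(Xc, j + 1, axis=1)
                if np.linalg.matrix_rank(reduced) == rank:
                    raise ValueError(
                        f"design matrix is rank deficient; column {name!r} is "
                        f"collinear with the others")
            raise ValueError("design matrix is rank deficient")
        return Xc, ya, names

    def fit(self, X, y):
        Xc, ya, names = self._validate(X, y)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        if self.family == "gamma" and np.ptp(ya) == 0.0 and Xc.shape[1] == 1:
            # constant response, intercept only: MLE is log of the common
            # value with a zero-width CI; IRLS cannot start from a perfect fit
            c = float(np.log(ya[0]))
            self.intercept_ = c
            self.coef_ = np.empty(0)
            self.intercept_ci_ = (c, c)
            self.intercept_p_ = 0.0
            self.conf_int_ = np.empty((0, 2))
            self.se_ = np.empty(0)
            self.p_values_ = np.empty(0)
            self.dispersion_ = 0.0
            self.n_iter_ = 0
            return self
        if self.family == "gamma":
            model = sm.GLM(ya, Xc, family=sm.families.Gamma(sm.families.links.Log()))
            with warnings.catch_warnings():
                # statsmodels emits this per IRLS step when the fit is exact
                # (our noise-free oracle data); it is not an error here.
                warnings.simplefilter("ignore", _PerfectSeparationWarning)
                res = model.fit(maxiter=self.max_iter, tol=self.tol, scale="X2")
            perfect_fit = res.deviance <= 1e-10 * len(ya)
            if not getattr(res, "converged", True) and not perfect_fit:
                raise ConvergenceError(
                    f"IRLS did not converge in {self.max_iter} iterations")
            self.dispersion_ = float(res.scale)
            self.n_iter_ = int(getattr(res, "fit_history", {}).get("iteration", 0))
        elif self.family == "lognormal":
            res = sm.OLS(np.log(ya), Xc).fit()
            self.dispersion_ = float(res.scale)
            self.n_iter_ = 1
        else:
            raise ValueError(f"unknown family {self.family!r}")
        params = np.asarray(res.params, dtype=float)
        ci = np.asarray(res.conf_int(), dtype=float)
        se = np.asarray(res.bse, dtype=float)
        pv = np.asarray(res.pvalues, dtype=float)
        self.intercept_ = params[0]
        self.coef_ = params[1:]
        self.intercept_ci_ = (float(ci[0, 0]), float(ci[0, 1]))
        self.intercept_p_ = float(pv[0])
        self.conf_int_ = ci[1:]
        self.se_ = se[1:]
        self.p_values_ = pv[1:]
        return self

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return np.exp(self.intercept_ + X @ self.coef_)

    def to_equation(self, category: str) -> CostEquation:
        terms = tuple(
            EquationTerm(str(name), float(b), float(lo), float(hi), float(p))
            for name, b, (lo, hi), p in zip(
                self.feature_names_in_, self.coef_, self.conf_int_, self.p_values_)
        )
        return CostEquation(category, float(self.intercept_),
                            self.intercept_ci_, terms)


def fit_glm_log_link(design, y, category: str = "cost",
                     family: str = "gamma") -> CostEquation:
    """Fit one log-link cost equation (functional wrapper)."""
    model = LogLinkCostModel(family=family).fit(design, y)
    return model.to_equation(category)


def univariable_screen(patients: pd.DataFrame, costs: pd.DataFrame,
                       category: str, alpha: float = 0.05,
                       candidates=None, family: str = "gamma") -> list[str]:
    """Single-covariate screening for one cost category.

    Returns the covariates whose univariable log-link GLM p-value is below
    ``alpha``, with the stapler-type indicator 'powered' always first and
    unconditionally included. Constant covariates are skipped with a warning.
    """
    y = costs[CATEGORY_COLUMNS[category]].to_numpy(dtype=float)
    kept = ["powered"]
    for name in (candidates if candidates is not None else SCREENING_CANDIDATES):
        if name == "powered":
            continue
        x = design_matrix(patients, [name])
        if x[name].nunique() < 2:
            warnings.warn(f"covariate {name!r} is constant; skipped from "
                          f"screening for {category!r}", stacklevel=2)
            continue
        model = LogLinkCostModel(family=family).fit(x, y)
        if model.p_values_[0] < alpha:
            kept.append(name)
    return kept


class CategoryEquationFitter(BaseEstimator):
    """Screen + multivariable fit for all five cost categories.

    ``fit(patients, costs)`` runs the univariable screen per category and the
    multivariable gamma log-link fit on the survivors (stapler type forced),
    leaving ``table_`` as a :class:`CoefficientTable`.
    """

    def __init__(self, alpha: float = 0.05, family: str = "gamma",
                 candidates=None):
        self.alpha = alpha
        self.family = family
        self.candidates = candidates

    def fit(self, patients: pd.DataFrame, costs: pd.DataFrame):
        equations, screened = {}, {}
        for category, column in CATEGORY_COLUMNS.items():
            terms = univariable_screen(patients, costs, category,
                                       alpha=self.alpha,
                                       candidates=self.candidates,
                                       family=self.family)
            X = design_matrix(patients, terms)
            y = costs[column].to_numpy(dtype=float)
            model = LogLinkCostModel(family=self.family).fit(X, y)
            equations[category] = model.to_equation(category)
            screened[category] = list(terms)
        self.table_ = CoefficientTable(
            equations=equations, family=self.family, n=len(patients),
            alpha=self.alpha, screened=screened)
        return self


def fit_category_equations(patients: pd.DataFrame, costs: pd.DataFrame,
                           alpha: float = 0.05,
                           family: str = "gamma") -> CoefficientTable:
    """Fit all five per-category cost equations (functional wrapper)."""
    return CategoryEquationFitter(alpha=alpha, family=family).fit(
        patients, costs).table_
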