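"""Synthetic patient-cohort generator with known ground truth.

The generator emulates the study conditions of the reference cohort: two
stapler groups (powered n=296, manual n=92) with the published covariate
marginals, device-utilization distributions, and a multiplicative cost
structure. Binary covariates are drawn independently within group (only
marginals are published); continuous age/BMI are truncated normals; stapler
and cartridge counts are truncated-at-zero rounded normals.

Costs follow the same mean model as the gamma log-link regression: each of
the five modelled categories is a gamma draw with mean exp(b0 + x'b) and a
fixed shape ("dispersion"), so fitted coefficients are directly comparable
to the generating ones. With ``dispersion=None`` (noise-free mode) costs
equal exp(x'b) exactly, which serves as the oracle for the regression
module. Device acquisition costs are counts x unit prices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .cohort import COST_COLUMNS
from .design import (BMI_BANDS, COMORBIDITIES, HISTOLOGIES, INSURANCES,
                     MARROW_FLAGS, RESIDENCES, SITES, STAGES, TERM_BUILDERS,
                     bmi_band)
from .regression import CoefficientTable, load_reference_coefficients

GROUPS = ("powered", "manual")

#: default acquisition unit prices per group (CNY), ECHELON products
DEFAULT_UNIT_PRICES = {
    "powered": (6790.0, 2441.0),
    "manual": (3970.0, 2441.0),
}


def _check_prob(value, name):
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"profile field {name!r} must be in [0, 1], got {value}")


def _check_mean_sd(pair, name):
    mean, sd = pair
    if sd < 0:
        raise ValueError(f"profile field {name!r} has negative SD {sd}")


@dataclass(frozen=True)
class GroupProfile:
    """Marginal distributions for one stapler group."""

    n: int
    age_mean_sd: tuple[float, float]
    bmi_mean_sd: tuple[float, float]
    male: float
    married: float
    residence: dict
    insurance: dict
    histology: dict
    stage: dict
    site: dict
    comorbidity: dict
    marrow: dict
    staplers_mean_sd: tuple[float, float]
    cartridges_mean_sd: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"profile field 'n' must be >= 1, got {self.n}")
        _check_prob(self.male, "male")
        _check_prob(self.married, "married")
        for name in ("age_mean_sd", "bmi_mean_sd", "staplers_mean_sd",
                     "cartridges_mean_sd"):
            _check_mean_sd(getattr(self, name), name)
        for block, labels in (("residence", RESIDENCES), ("insurance", INSURANCES),
                              ("histology", HISTOLOGIES), ("stage", STAGES),
                              ("site", SITES)):
            probs = getattr(self, block)
            unknown = set(probs) - set(labels)
            if unknown:
                raise ValueError(f"profile block {block!r} has unknown "
                                 f"level(s) {sorted(unknown)}")
            for label, p in probs.items():
                _check_prob(p, f"{block}.{label}")
        for block, labels in (("comorbidity", COMORBIDITIES),
                              ("marrow", MARROW_FLAGS)):
            probs = getattr(self, block)
            unknown = set(probs) - set(labels)
            if unknown:
                raise ValueError(f"profile block {block!r} has unknown "
                                 f"flag(s) {sorted(unknown)}")
            for label, p in probs.items():
                _check_prob(p, f"{block}.{label}")


#: operational-field envelopes: name -> (mean, sd, lo, hi)
DEFAULT_OPERATIONAL = {
    "operation_minutes": (180.0, 50.0, 30.0, 480.0),
    "length_of_stay": (10.0, 4.0, 2.0, 21.0),
    "bleeding_ml": (100.0, 80.0, 10.0, 600.0),
    "drainage_ml": (800.0, 400.0, 50.0, 2400.0),
}


@dataclass(frozen=True)
class CohortProfile:
    """Generation profile for a two-group cohort."""

    groups: dict
    dispersion: float | None = 4.94
    operational: dict = field(default_factory=lambda: dict(DEFAULT_OPERATIONAL))

    def __post_init__(self) -> None:
        if self.dispersion is not None and not self.dispersion > 0:
            raise ValueError(f"profile field 'dispersion' must be > 0, "
                             f"got {self.dispersion}")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group(s) {sorted(unknown)}")

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups.values())


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to regenerate a synthetic cohort and its costs."""

    equations: CoefficientTable
    profile: CohortProfile
    seed: int

    def save(self, path) -> None:
        payload = {
            "seed": self.seed,
            "profile": profile_to_dict(self.profile),
            "equations": self.equations.to_dict(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(equations=CoefficientTable.from_dict(payload["equations"]),
                   profile=profile_from_dict(payload["profile"]),
                   seed=int(payload["seed"]))


def profile_to_dict(profile: CohortProfile) -> dict:
    out = {"dispersion": profile.dispersion,
           "operational": {k: list(v) for k, v in profile.operational.items()},
           "groups": {}}
    for name, g in profile.groups.items():
        d = asdict(g)
        for key in ("age_mean_sd", "bmi_mean_sd", "staplers_mean_sd",
                    "cartridges_mean_sd"):
            d[key] = list(d[key])
        out["groups"][name] = d
    return out


def profile_from_dict(data: dict) -> CohortProfile:
    groups = {}
    for name, d in data["groups"].items():
        kwargs = dict(d)
        for key in ("age_mean_sd", "bmi_mean_sd", "staplers_mean_sd",
                    "cartridges_mean_sd"):
            kwargs[key] = tuple(float(v) for v in kwargs[key])
        kwargs["n"] = int(kwargs["n"])
        groups[name] = GroupProfile(**kwargs)
    operational = {k: tuple(float(x) for x in v)
                   for k, v in (data.get("operational") or DEFAULT_OPERATIONAL).items()}
    return CohortProfile(groups=groups, dispersion=data.get("dispersion"),
                         operational=operational)


def load_profile(path) -> CohortProfile:
    """Read a cohort profile from YAML or JSON."""
    with open(path, encoding="utf-8") as fh:
        return profile_from_dict(yaml.safe_load(fh))


def default_profile() -> CohortProfile:
    """The shipped profile transcribing the published cohort marginals."""
    text = resources.files("staplercma.data").joinpath(
        "default_profile.yaml").read_text(encoding="utf-8")
    return profile_from_dict(yaml.safe_load(text))


def _normalized(probs: dict, labels) -> tuple[list, np.ndarray]:
    keys = [k for k in labels if k in probs]
    p = np.array([probs[k] for k in keys], dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("categorical probabilities sum to zero")
    return keys, p / total


def _trunc_normal(rng, mean, sd, lo, hi, n):
    draw = rng.normal(mean, sd, n)
    return np.clip(draw, lo, hi)


def generate_cohort(profile: CohortProfile, seed: int) -> pd.DataFrame:
    """Draw a patient-level cohort table from a profile, deterministically.

    Returns one row per episode with every categorical field populated, the
    BMI band derived from the sampled continuous BMI, and device counts drawn
    from the profile's count distributions (truncated below at zero, rounded
    to integers).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for group in GROUPS:
        if group not in profile.groups:
            continue
        g = profile.groups[group]
        n = g.n
        rec = {
            "patient_id": [f"{group[0].upper()}{i:05d}" for i in range(1, n + 1)],
            "group": [group] * n,
        }
        rec["age"] = np.round(_trunc_normal(rng, *g.age_mean_sd, 18.0, 100.0, n), 1)
        bmi = np.round(_trunc_normal(rng, *g.bmi_mean_sd, 15.0, 45.0, n), 1)
        rec["bmi"] = bmi
        rec["bmi_band"] = [bmi_band(b) for b in bmi]
        rec["sex"] = np.where(rng.random(n) < g.male, "male", "female")
        rec["marital"] = np.where(rng.random(n) < g.married, "married", "single")
        for block, labels in (("residence", RESIDENCES), ("insurance", INSURANCES),
                              ("histology", HISTOLOGIES), ("stage", STAGES),
                              ("site", SITES)):
            keys, p = _normalized(getattr(g, block), labels)
            rec[block] = rng.choice(keys, size=n, p=p)
        for name in COMORBIDITIES:
            prev = g.comorbidity.get(name, 0.0)
            rec[f"comorb_{name}"] = (rng.random(n) < prev).astype(int)
        for name in MARROW_FLAGS:
            prev = g.marrow.get(name, 0.0)
            rec[f"marrow_{name}"] = (rng.random(n) < prev).astype(int)
        rec["staplers_used"] = np.rint(
            np.clip(rng.normal(*g.staplers_mean_sd, n), 0, None)).astype(int)
        rec["cartridges_used"] = np.rint(
            np.clip(rng.normal(*g.cartridges_mean_sd, n), 0, None)).astype(int)
        for name, (mean, sd, lo, hi) in profile.operational.items():
            rec[name] = np.round(_trunc_normal(rng, mean, sd, lo, hi, n), 1)
        rec["died_in_surgery"] = np.zeros(n, dtype=bool)
        rec["discharge_routine"] = np.ones(n, dtype=bool)
        frames.append(pd.DataFrame(rec))
    out = pd.concat(frames, ignore_index=True)
    return out


def generate_costs(patients: pd.DataFrame, truth: GroundTruth,
                   unit_prices: dict | None = None,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate per-category hospital costs for a cohort.

    Each modelled category is a gamma draw with mean exp(x'b) and shape
    ``truth.profile.dispersion``; with dispersion ``None`` or infinite the
    draw is replaced by its mean (noise-free mode). Acquisition costs are
    device counts x unit prices for the patient's group. The returned table
    satisfies the total-conservation invariant by construction.
    """
    prices = unit_prices or DEFAULT_UNIT_PRICES
    if rng is None:
        rng = np.random.default_rng(truth.seed + 1)

    needed = sorted({t for eq in truth.equations.equations.values()
                     for t in eq.term_names})
    for term in needed:
        try:
            TERM_BUILDERS[term](patients.iloc[:0])
        except KeyError as exc:
            first = patients["patient_id"].iloc[0] if len(patients) else "<empty>"
            raise KeyError(
                f"cohort (first record {first!r}) lacks data for covariate "
                f"{term!r}: {exc}") from None

    shape = truth.profile.dispersion
    noise_free = shape is None or not np.isfinite(shape)
    n = len(patients)
    out = {"patient_id": patients["patient_id"].to_numpy()}

    stapler_price = patients["group"].map({g: p[0] for g, p in prices.items()})
    cartridge_price = patients["group"].map({g: p[1] for g, p in prices.items()})
    out["stapler_cost"] = (patients["staplers_used"] * stapler_price).to_numpy(dtype=float)
    out["cartridge_cost"] = (patients["cartridges_used"] * cartridge_price).to_numpy(dtype=float)

    column_of = {"disposables": "disposables_cost", "drugs": "drug_cost",
                 "operation": "operation_cost", "laboratory": "laboratory_cost",
                 "other": "other_cost"}
    for category, column in column_of.items():
        mean = np.exp(truth.equations[category].linear_predictor(patients))
        if noise_free:
            draw = mean
        else:
            draw = rng.gamma(shape, mean / shape, size=n)
        out[column] = draw

    costs = pd.DataFrame(out)
    costs["total_cost"] = costs[list(COST_COLUMNS[:-1])].sum(axis=1)
    return costs


def generate_synthetic_cohort(profile: CohortProfile | None = None,
                              equations: CoefficientTable | None = None,
                              seed: int = 0):
    """Convenience: cohort + costs + ground truth in one call."""
    profile = profile or default_profile()
    equations = equations or load_reference_coefficients()
    truth = GroundTruth(equations=equations, profile=profile, seed=seed)
    patients = generate_cohort(profile, seed)
    costs = generate_costs(patients, truth)
    return patients, costs, truth
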