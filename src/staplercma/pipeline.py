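"""End-to-end orchestration: simulate -> filter -> describe -> fit -> CMA.

``run_pipeline`` executes every stage on a synthetic cohort, writes all
publication-style outputs (characteristics and cost comparison tables,
fitted coefficient table, base-case CMA table, tornado CSV, PSA draws and
summary) into an output directory, and returns a manifest with the SHA-256
checksum of every artifact. Reruns with an identical configuration produce
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cma import (load_reference_calibration, one_way_sensitivity,
                  reference_scenarios, run_base_case, run_psa,
                  run_scenario_substitution)
from .cohort import EligibilityThresholds, apply_eligibility_filters, write_cohort
from .descriptive import summarize_cohort
from .regression import CoefficientTable, fit_category_equations, \
    load_reference_coefficients
from .synthetic import (CohortProfile, GroundTruth, default_profile,
                        generate_cohort, generate_costs, load_profile)

log = logging.getLogger("staplercma")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (YAML-loadable)."""

    output_dir: str = "staplercma_run"
    seed: int = 1
    n_iterations: int = 10_000
    n_patients: int = 388
    alpha: float = 0.05
    profile_path: str | None = None
    coefficients_path: str | None = None
    fit_equations: bool = True
    thresholds: EligibilityThresholds = field(default_factory=EligibilityThresholds)

    def __post_init__(self) -> None:
        if self.seed < 0 or self.n_iterations < 1:
            raise ValueError("seed must be >= 0 and n_iterations >= 1")
        for name in ("profile_path", "coefficients_path"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        th = raw.pop("thresholds", None)
        if th is not None:
            raw["thresholds"] = EligibilityThresholds(**th)
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        profile = (load_profile(config.profile_path) if config.profile_path
                   else default_profile())
        equations = (CoefficientTable.load(config.coefficients_path)
                     if config.coefficients_path
                     else load_reference_coefficients())

        stage = "simulate"
        truth = GroundTruth(equations=equations, profile=profile,
                            seed=config.seed)
        patients = generate_cohort(profile, config.seed)
        costs = generate_costs(patients, truth)
        write_cohort(out / "cohort.csv", patients, costs)
        truth.save(out / "ground_truth.json")
        log.info("simulated %d episodes", len(patients))

        stage = "filter"
        included, exclusions = apply_eligibility_filters(patients,
                                                         config.thresholds)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        kept_costs = costs[costs["patient_id"].isin(included["patient_id"])]
        log.info("eligibility: %d included, %d excluded",
                 len(included), len(exclusions))

        stage = "describe"
        summary = summarize_cohort(included, kept_costs)
        chars = summary[~summary["test"].str.startswith("wilcoxon")]
        cost_rows = summary[summary["test"].str.startswith("wilcoxon")]
        chars.to_csv(out / "table_characteristics.csv", index=False)
        cost_rows.to_csv(out / "table_costs.csv", index=False)

        stage = "fit"
        if config.fit_equations:
            fitted = fit_category_equations(included, kept_costs,
                                            alpha=config.alpha)
            fitted.save(out / "fitted_coefficients.json")

        stage = "cma"
        powered, manual, victor = reference_scenarios()
        base = run_base_case(powered, manual, equations)
        base.to_frame().to_csv(out / "cma_base_case.csv", index=False)
        victor_cmp = run_scenario_substitution(
            powered, manual, victor.product, equations,
            substitute_acquisition=load_reference_calibration()["victor_acquisition"])
        victor_cmp.to_frame().to_csv(out / "cma_victor_scenario.csv", index=False)

        stage = "tornado"
        tornado = one_way_sensitivity(powered, manual, equations)
        pd.DataFrame([t.__dict__ for t in tornado]).to_csv(
            out / "tornado.csv", index=False)

        stage = "psa"
        psa = run_psa(powered, manual, equations,
                      n_iterations=config.n_iterations,
                      n_patients=config.n_patients, seed=config.seed)
        pd.DataFrame({"total_difference": psa.draws}).to_csv(
            out / "psa_draws.csv", index=False)
        with open(out / "psa_summary.json", "w", encoding="utf-8") as fh:
            json.dump(psa.to_dict(), fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    artifacts = sorted(p for p in out.iterdir()
                       if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {**{k: v for k, v in asdict(config).items()
                      if k != "thresholds"},
                   "thresholds": asdict(config.thresholds)},
        "outputs": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
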