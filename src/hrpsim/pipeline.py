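"""End-to-end simulation: population -> raking -> payment model -> insurer's
prediction -> pools at each size -> incentive report.

The flow mirrors how high-risk pooling would operate on top of prospective risk
equalization: the regulator's payment model is estimated on the full population;
the insurer trains a residual-spending predictor on 70% of survey responders and
prospectively assigns the top X% of predicted residual spending (in the held-out
30%) to the pool; pool compensation, financing, subgroup profits/losses, WMAR
and the Power reduction are all evaluated on that held-out sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation_metrics import build_report, default_group_sets, default_subgroups
from .high_risk_pool import PoolAssignment, PoolConfig, build_pool
from .residual_prediction import PredictorConfig, fit_predictor, score
from .risk_equalization import RiskEqModel, compute_residuals, fit_risk_equalization
from .survey_weighting import (
    SPENDING_BIN_COLUMN,
    RakingSpec,
    bin_spending_quantiles,
    population_margins,
    rake_weights,
)
from .synthetic_population import (
    AdjusterFamily,
    GeneratorConfig,
    SpendingParams,
    generate_population,
    split_train_test,
)

__all__ = ["RunConfig", "SimulationResult", "run_simulation", "write_outputs"]


@dataclass(frozen=True)
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    raking: RakingSpec = field(default_factory=RakingSpec)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    train_fraction: float = 0.70
    pool_fractions: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05)
    compensation_basis: str = "residual"
    compensation_share: float = 1.0
    power_shock: float = 0.10
    weighted_evaluation: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = dict(d.pop("generator", {}))
        if "adjuster_spec" in gen:
            gen["adjuster_spec"] = tuple(
                AdjusterFamily(a["name"], tuple(a["class_probs"]), tuple(a["class_effects"]))
                for a in gen["adjuster_spec"]
            )
        if "spending_noise" in gen:
            gen["spending_noise"] = SpendingParams(**gen["spending_noise"])
        for key in ("condition_loading", "condition_prevalence", "condition_effects"):
            if key in gen and isinstance(gen[key], list):
                gen[key] = tuple(gen[key])
        kwargs: dict = {"generator": GeneratorConfig(**gen)}
        if "raking" in d:
            rk = dict(d.pop("raking"))
            if "margin_variables" in rk:
                rk["margin_variables"] = tuple(rk["margin_variables"])
            kwargs["raking"] = RakingSpec(**rk)
        if "predictor" in d:
            kwargs["predictor"] = PredictorConfig(**d.pop("predictor"))
        if "pool_fractions" in d:
            d["pool_fractions"] = tuple(d["pool_fractions"])
        kwargs.update(d)
        return cls(**kwargs)


@dataclass
class SimulationResult:
    population: pd.DataFrame
    model: RiskEqModel
    residuals: pd.DataFrame  # whole population
    predictor: object
    train_ids: np.ndarray
    test_ids: np.ndarray
    test: pd.DataFrame  # test-sample responders with weights
    predictions: pd.DataFrame  # test-sample predicted residuals
    scenarios: dict[str, PoolAssignment | None]
    subgroup_results: pd.DataFrame
    incentive_report: pd.DataFrame
    manifest: dict


def run_simulation(config: RunConfig) -> SimulationResult:
    gen = config.generator
    population = generate_population(gen)
    population[SPENDING_BIN_COLUMN] = bin_spending_quantiles(
        population, config.raking.n_spending_quantiles
    )

    margins = population_margins(population, config.raking.margin_variables)
    survey = population.loc[population["survey_responded"]]
    weights = rake_weights(survey, margins, config.raking)
    population.loc[survey.index, "weight"] = weights

    families = [f.name for f in gen.adjuster_spec]
    model = fit_risk_equalization(population, families)
    residuals = compute_residuals(model, population)

    train_ids, test_ids = split_train_test(population, config.train_fraction, gen.seed + 1)
    by_id = population.set_index("person_id", drop=False)
    res_by_id = residuals.set_index("person_id", drop=False)
    train = by_id.loc[train_ids]
    test = by_id.loc[test_ids]

    predictor = fit_predictor(
        train, res_by_id.loc[train_ids, "residual_spending"], config.predictor
    )
    predictions = score(predictor, test, sample="test")

    res_test = res_by_id.loc[test_ids]
    scenarios: dict[str, PoolAssignment | None] = {"no_hrp": None}
    for frac in config.pool_fractions:
        pool_cfg = PoolConfig(
            fraction=frac,
            compensation_basis=config.compensation_basis,
            compensation_share=config.compensation_share,
        )
        scenarios[f"top_{round(frac * 100, 10):g}pct"] = build_pool(
            test, predictions, res_test, pool_cfg
        )

    subgroups = default_subgroups(gen.n_conditions)
    group_sets = default_group_sets(gen.n_conditions)
    eval_weights = test["weight"].to_numpy() if config.weighted_evaluation else None
    subgroup_results, incentive_report = build_report(
        test,
        res_test,
        scenarios,
        subgroups,
        group_sets,
        weights=eval_weights,
        shock=config.power_shock,
    )

    manifest = {
        "seed": gen.seed,
        "n_population": gen.n_population,
        "n_responders": int(survey.shape[0]),
        "n_train": int(train_ids.size),
        "n_test": int(test_ids.size),
        "train_fraction": config.train_fraction,
        "pool_fractions": list(config.pool_fractions),
        "compensation_basis": config.compensation_basis,
        "compensation_share": config.compensation_share,
        "power_shock": config.power_shock,
        "power_shock_scope": "all",
        "weighted_evaluation": config.weighted_evaluation,
        "predictor": predictor.manifest,
        "raking": {
            "margin_variables": list(config.raking.margin_variables),
            "n_spending_quantiles": config.raking.n_spending_quantiles,
            "tolerance": config.raking.tolerance,
        },
    }
    return SimulationResult(
        population=population,
        model=model,
        residuals=residuals,
        predictor=predictor,
        train_ids=train_ids,
        test_ids=test_ids,
        test=test,
        predictions=predictions,
        scenarios=scenarios,
        subgroup_results=subgroup_results,
        incentive_report=incentive_report,
        manifest=manifest,
    )


def write_outputs(result: SimulationResult, outdir: str | Path, write_population: bool = True) -> None:
    """Serialize a run: person-level CSV, model JSON, pool JSONs, report CSVs, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if write_population:
        result.population.to_csv(outdir / "population.csv", index=False)
    (outdir / "risk_eq_model.json").write_text(result.model.to_json())
    pools = {k: v.to_dict() for k, v in result.scenarios.items() if v is not None}
    (outdir / "pools.json").write_text(json.dumps(pools, indent=2))
    result.subgroup_results.to_csv(outdir / "subgroup_results.csv", index=False)
    result.incentive_report.to_csv(outdir / "incentive_report.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
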