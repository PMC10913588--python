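"""The insurer's model: predict residual spending from health-survey indicators.

Trained on the 70% training split of survey responders, using only the
self-reported condition flags and the general-health indicator — the risk
adjusters are already accounted for by the payment model whose residual is the
target.  Two learners are provided, mirroring common practice:

* forward-stepwise OLS (add the feature that most lowers AIC, stop when none does);
* a regression random forest (100 trees, minimum terminal-node size 100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "PredictorConfig",
    "StepwisePredictor",
    "ForestPredictor",
    "survey_feature_matrix",
    "fit_predictor",
    "top_fraction",
]


@dataclass(frozen=True)
class PredictorConfig:
    method: str = "random_forest"  # or "stepwise_linear"
    rf_n_trees: int = 100
    rf_min_node: int = 100
    stepwise_criterion: str = "aic"
    seed: int = 0
    features: tuple[str, ...] | None = None  # default: condition flags + general health

    def __post_init__(self) -> None:
        if self.method not in ("stepwise_linear", "random_forest"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.rf_n_trees < 1 or self.rf_min_node < 1:
            raise ValueError("rf_n_trees and rf_min_node must be >= 1")
        if self.stepwise_criterion != "aic":
            raise ValueError("only the AIC stepwise criterion is implemented")


def survey_feature_matrix(persons: pd.DataFrame, features: tuple[str, ...] | None = None) -> pd.DataFrame:
    """0/1 feature matrix from survey indicators.

    Defaults to every ``cond_XX`` column present plus a ``gh_fair_poor`` dummy.
    Raises if a requested feature column is missing or contains missing values
    (i.e. non-responders were passed in).
    """
    if features is None:
        conds = [c for c in persons.columns if c.startswith("cond_")]
        features = tuple(conds) + (("gh_fair_poor",) if "general_health" in persons.columns else ())
    out = {}
    for f in features:
        if f == "gh_fair_poor":
            col = persons["general_health"]
            if col.isna().any():
                raise ValueError("general_health missing for some persons (non-responders?)")
            out[f] = (col == "fair_poor").to_numpy(dtype=float)
        else:
            if f not in persons.columns:
                raise ValueError(f"missing feature column {f!r}")
            col = persons[f]
            if col.isna().any():
                raise ValueError(f"feature {f!r} missing for some persons (non-responders?)")
            out[f] = col.to_numpy(dtype=float)
    if not out:
        raise ValueError("no features available")
    return pd.DataFrame(out, index=persons.index)


@dataclass
class StepwisePredictor:
    """Forward-selection OLS on survey dummies, AIC stopping rule."""

    selected: list[str]
    intercept: float
    coefs: dict[str, float]
    features: tuple[str, ...]

    def predict(self, persons: pd.DataFrame) -> pd.Series:
        X = survey_feature_matrix(persons, self.features)
        pred = np.full(len(X), self.intercept)
        for f in self.selected:
            pred += self.coefs[f] * X[f].to_numpy()
        return pd.Series(pred, index=persons.index, name="predicted_residual")

    @property
    def manifest(self) -> dict:
        return {
            "method": "stepwise_linear",
            "criterion": "aic",
            "selected": list(self.selected),
            "features": list(self.features),
        }


@dataclass
class ForestPredictor:
    model: RandomForestRegressor
    features: tuple[str, ...]
    seed: int

    def predict(self, persons: pd.DataFrame) -> pd.Series:
        X = survey_feature_matrix(persons, self.features)
        if len(X) == 0:
            return pd.Series(np.empty(0), index=persons.index, name="predicted_residual")
        return pd.Series(self.model.predict(X.to_numpy()), index=persons.index, name="predicted_residual")

    @property
    def manifest(self) -> dict:
        p = self.model.get_params()
        return {
            "method": "random_forest",
            "n_trees": p["n_estimators"],
            "min_node": p["min_samples_leaf"],
            "max_features": p["max_features"],
            "bootstrap": p["bootstrap"],
            "seed": self.seed,
        }


def _ols_aic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    n = y.size
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * X.shape[1]
    return beta, aic


def fit_predictor(
    train: pd.DataFrame, target: np.ndarray | pd.Series, config: PredictorConfig
):
    """Fit the configured learner on the training sample; deterministic given seed.

    ``train`` must contain the survey feature columns; ``target`` is residual
    spending aligned with ``train``'s rows.
    """
    y = np.asarray(target, dtype=float)
    if len(train) == 0:
        raise ValueError("training sample is empty")
    if len(train) != y.size:
        raise ValueError("target length does not match training sample")
    X = survey_feature_matrix(train, config.features)
    feats = tuple(X.columns)

    if config.method == "random_forest":
        rf = RandomForestRegressor(
            n_estimators=config.rf_n_trees,
            min_samples_leaf=config.rf_min_node,
            random_state=config.seed,
            n_jobs=1,
        )
        rf.fit(X.to_numpy(), y)
        return ForestPredictor(rf, feats, config.seed)

    # forward stepwise, AIC
    remaining = list(feats)
    selected: list[str] = []
    design = np.ones((y.size, 1))
    _, best_aic = _ols_aic(design, y)
    while remaining:
        trial = [
            (_ols_aic(np.column_stack([design, X[f].to_numpy()]), y)[1], f)
            for f in remaining
        ]
        aic, f = min(trial)
        if aic < best_aic - 1e-10:
            best_aic = aic
            selected.append(f)
            remaining.remove(f)
            design = np.column_stack([design, X[f].to_numpy()])
        else:
            break
    beta, _ = _ols_aic(design, y)
    return StepwisePredictor(
        selected=selected,
        intercept=float(beta[0]),
        coefs={f: float(b) for f, b in zip(selected, beta[1:])},
        features=feats,
    )


def score(predictor, persons: pd.DataFrame, sample: str = "test") -> pd.DataFrame:
    """Score persons with a fitted predictor; no refitting."""
    pred = predictor.predict(persons)
    return pd.DataFrame(
        {
            "person_id": persons["person_id"].to_numpy(),
            "predicted_residual": pred.to_numpy(),
            "sample": sample,
        },
        index=persons.index,
    )


def top_fraction(predictions: pd.DataFrame, fraction: float) -> np.ndarray:
    """Person ids of the ``ceil(fraction * N)`` highest predicted residuals.

    Ties broken by lowest person id (stable sort on (-prediction, person_id)),
    so top sets are nested across fractions.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(predictions)
    if n == 0:
        raise ValueError("empty prediction set")
    k = math.ceil(fraction * n)
    order = np.lexsort(
        (predictions["person_id"].to_numpy(), -predictions["predicted_residual"].to_numpy())
    )
    return np.sort(predictions["person_id"].to_numpy()[order[:k]])
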