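"""Prospective risk-equalization model: least squares of spending on adjuster-class dummies.

The payment model is fully prospective: an insurer's revenue for a person is the
model's predicted spending, so residual spending (actual minus predicted) is the
insurer's per-person loss.  Fit with an intercept on the full population, the
model is zero-sum: mean residual on the estimation population is zero up to
floating point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RiskEqModel", "RiskEqError", "fit_risk_equalization", "compute_residuals"]


class RiskEqError(ValueError):
    pass


@dataclass(frozen=True)
class RiskEqModel:
    """Fitted payment model: intercept plus one euro coefficient per non-reference class."""

    intercept: float
    coefficients: dict[str, dict[str, float]]  # family -> class -> euro coefficient
    estimation_n: int

    def predict(self, persons: pd.DataFrame) -> pd.Series:
        pred = np.full(len(persons), self.intercept)
        for family, coefs in self.coefficients.items():
            if family not in persons.columns:
                raise RiskEqError(f"persons lack adjuster family {family!r}")
            col = persons[family].astype(str)
            unseen = set(col.unique()) - set(coefs)
            if unseen:
                raise RiskEqError(f"unseen classes in family {family!r}: {sorted(unseen)}")
            pred += col.map(coefs).to_numpy(dtype=float)
        return pd.Series(pred, index=persons.index, name="predicted_spending")

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "estimation_n": self.estimation_n,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RiskEqModel":
        d = json.loads(text)
        return cls(d["intercept"], d["coefficients"], d["estimation_n"])


def fit_risk_equalization(
    population: pd.DataFrame, families: list[str] | tuple[str, ...] | None = None
) -> RiskEqModel:
    """OLS of ``spending`` on class dummies (reference class per family) with intercept.

    ``families`` defaults to every categorical adjuster column present; each
    family must have at least two observed classes and the design must be full
    rank (an error lists the offending classes otherwise).
    """
    if families is None:
        families = [
            c
            for c in population.columns
            if isinstance(population[c].dtype, pd.CategoricalDtype)
            and c not in ("general_health",)
        ]
    if not families:
        raise RiskEqError("no adjuster families to fit on")

    n = len(population)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[tuple[str, str]] = [("", "_intercept")]
    references: dict[str, str] = {}
    for family in families:
        col = population[family].astype("category")
        counts = col.value_counts(sort=False)
        empty = [str(c) for c in counts.index[counts == 0]]
        if empty:
            raise RiskEqError(f"family {family!r} has empty classes: {empty}")
        observed = list(col.cat.categories)
        references[family] = observed[0]
        for cls_ in observed[1:]:
            cols.append((col == cls_).to_numpy(dtype=float))
            names.append((family, cls_))

    X = np.column_stack(cols)
    if n <= X.shape[1]:
        raise RiskEqError("population smaller than parameter count")
    y = population["spending"].to_numpy(dtype=float)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise RiskEqError(f"collinear design (rank {rank} < {X.shape[1]}); check {families}")

    coefficients: dict[str, dict[str, float]] = {
        f: {references[f]: 0.0} for f in families
    }
    for (family, cls_), b in zip(names[1:], beta[1:]):
        coefficients[family][cls_] = float(b)
    return RiskEqModel(float(beta[0]), coefficients, n)


def compute_residuals(model: RiskEqModel, persons: pd.DataFrame) -> pd.DataFrame:
    """Per-person predicted and residual spending (actual minus predicted)."""
    predicted = model.predict(persons)
    residual = persons["spending"].to_numpy(dtype=float) - predicted.to_numpy()
    return pd.DataFrame(
        {
            "person_id": persons["person_id"].to_numpy(),
            "predicted_spending": predicted.to_numpy(),
            "residual_spending": residual,
        },
        index=persons.index,
    )
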