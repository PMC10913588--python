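"""Raking (iterative proportional fitting) of the survey sample to population margins.

The survey subsample under-represents the sick because response propensity falls
with latent severity.  Raking assigns each responder a weight so that weighted
survey frequencies match the population on every margin variable — here all
risk-adjuster families, a spending-quantile bin and the mortality proxy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RakingSpec",
    "RakingError",
    "bin_spending_quantiles",
    "population_margins",
    "rake_weights",
]

SPENDING_BIN_COLUMN = "spending_q"


class RakingError(RuntimeError):
    pass


@dataclass(frozen=True)
class RakingSpec:
    margin_variables: tuple[str, ...] = ("agesex", "region", "morbidity", SPENDING_BIN_COLUMN, "died")
    n_spending_quantiles: int = 18
    tolerance: float = 1e-6  # max relative margin error at convergence
    max_iterations: int = 500
    weight_cap: float | None = None  # optional trim; off by default

    def __post_init__(self) -> None:
        if not self.margin_variables:
            raise ValueError("margin_variables must be non-empty")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.n_spending_quantiles < 2:
            raise ValueError("n_spending_quantiles must be >= 2")


def bin_spending_quantiles(population: pd.DataFrame, n_bins: int) -> pd.Series:
    """Label every person with a spending bin defined by *population* quantile cuts.

    Cut-points are the population quantiles of ``spending``; tied cut-points are
    collapsed deterministically (a warning reports the actual bin count).  Bins
    cover the full range, so the same cuts can label any subsample.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    spending = population["spending"].to_numpy()
    if np.isnan(spending).any():
        raise ValueError("spending must be present for all persons")
    qs = np.quantile(spending, np.linspace(0, 1, n_bins + 1))
    inner = np.unique(qs[1:-1])
    # drop inner edges equal to the extremes so intervals stay non-degenerate
    inner = inner[(inner > spending.min()) & (inner < spending.max())]
    n_actual = inner.size + 1
    if n_actual < n_bins:
        warnings.warn(
            f"spending quantile bins collapsed from {n_bins} to {n_actual} due to ties",
            stacklevel=2,
        )
    codes = np.searchsorted(inner, spending, side="right")
    labels = [f"q{k:02d}" for k in range(n_actual)]
    return pd.Series(
        pd.Categorical.from_codes(codes, categories=labels),
        index=population.index,
        name=SPENDING_BIN_COLUMN,
    )


def population_margins(
    population: pd.DataFrame, variables: tuple[str, ...] | list[str]
) -> dict[str, pd.Series]:
    """Per-variable class counts in the population, the raking targets."""
    return {v: population[v].value_counts(sort=False) for v in variables}


def rake_weights(
    survey: pd.DataFrame,
    margins: dict[str, pd.Series],
    spec: RakingSpec,
) -> pd.Series:
    """Iterative proportional fitting of survey weights to population margins.

    Weights start uniform at ``N_pop / n_survey`` and are multiplied, one margin
    variable at a time in the order of ``spec.margin_variables``, by the ratio of
    target to current weighted class counts, until every margin's maximum
    relative error falls below ``spec.tolerance``.  The converged weights are
    strictly positive and are normalized to sum exactly to the population size.

    Raises :class:`RakingError` on non-convergence (carrying the worst margin
    discrepancy) or when a population class has no survey members (listing the
    empty cells).
    """
    n_pop = float(next(iter(margins.values())).sum())
    for var in spec.margin_variables:
        if var not in margins:
            raise RakingError(f"margins missing variable {var!r}")
        if abs(float(margins[var].sum()) - n_pop) > 1e-6 * n_pop:
            raise RakingError(f"margin totals disagree across variables (at {var!r})")

    n_survey = len(survey)
    if n_survey == 0:
        raise RakingError("survey is empty")

    # Pre-extract integer codes per margin variable; verify no empty cells.
    codes: dict[str, np.ndarray] = {}
    targets: dict[str, np.ndarray] = {}
    empty_cells: list[str] = []
    for var in spec.margin_variables:
        target = margins[var]
        cats = list(target.index)
        col = survey[var]
        mapped = col.map({c: i for i, c in enumerate(cats)})
        if mapped.isna().any():
            bad = sorted(set(col[mapped.isna()].astype(str)))
            raise RakingError(f"survey variable {var!r} has classes absent from margins: {bad}")
        code = mapped.to_numpy(dtype=np.int64)
        present = np.bincount(code, minlength=len(cats))
        for i, c in enumerate(cats):
            if target.iloc[i] > 0 and present[i] == 0:
                empty_cells.append(f"{var}={c}")
        codes[var] = code
        targets[var] = target.to_numpy(dtype=float)
    if empty_cells:
        raise RakingError(f"population classes with zero survey members: {empty_cells}")

    w = np.full(n_survey, n_pop / n_survey)

    def worst_error() -> tuple[float, str]:
        worst, where = 0.0, ""
        for var in spec.margin_variables:
            cur = np.bincount(codes[var], weights=w, minlength=targets[var].size)
            nonzero = targets[var] > 0
            rel = np.abs(cur[nonzero] - targets[var][nonzero]) / targets[var][nonzero]
            if rel.size and rel.max() > worst:
                worst, where = float(rel.max()), var
        return worst, where

    converged = False
    for _ in range(spec.max_iterations):
        for var in spec.margin_variables:
            cur = np.bincount(codes[var], weights=w, minlength=targets[var].size)
            factor = np.ones_like(cur)
            nz = cur > 0
            factor[nz] = targets[var][nz] / cur[nz]
            w *= factor[codes[var]]
            if spec.weight_cap is not None:
                w = np.minimum(w, spec.weight_cap)
        err, _ = worst_error()
        if err < spec.tolerance:
            converged = True
            break
    if not converged:
        err, var = worst_error()
        raise RakingError(
            f"raking did not converge in {spec.max_iterations} iterations; "
            f"worst relative margin error {err:.3e} on {var!r}"
        )

    w *= n_pop / w.sum()
    return pd.Series(w, index=survey.index, name="weight")
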