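"""Selection-incentive and cost-control-incentive metrics.

* subgroup profits/losses: raking-weighted mean per-person profit for groups
  defined by survey indicators, with a weighted one-sample t-test against zero;
* WMAR (weighted mean absolute result): group-size-weighted mean of the
  absolute subgroup means — higher means stronger risk-selection incentives;
* Power reduction: the share of a marginal spending increase that flows back to
  the insurer through pool compensation, holding pool membership, threshold and
  financing fixed (the single-insurer, ceteris-paribus reading).  Zero under a
  fully prospective payment model without risk sharing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .high_risk_pool import PoolAssignment

__all__ = [
    "SubgroupDefinition",
    "SubgroupResult",
    "default_subgroups",
    "default_group_sets",
    "subgroup_profit_loss",
    "wmar",
    "power_reduction",
    "build_report",
]


@dataclass(frozen=True)
class SubgroupDefinition:
    """A named group of survey responders, via a boolean predicate on their rows."""

    name: str
    predicate: Callable[[pd.DataFrame], pd.Series]

    def mask(self, persons: pd.DataFrame) -> np.ndarray:
        m = self.predicate(persons)
        return np.asarray(m, dtype=bool)


@dataclass(frozen=True)
class SubgroupResult:
    name: str
    n_weighted: float
    n_persons: int
    mean_result: float  # euro; positive = profit (overcompensation)
    se: float
    significant: bool


def _any_chronic(df: pd.DataFrame) -> pd.Series:
    conds = [c for c in df.columns if c.startswith("cond_")]
    return df[conds].fillna(False).astype(bool).any(axis=1)


def default_subgroups(n_conditions: int) -> list[SubgroupDefinition]:
    """Per-condition groups, any/no chronic condition, and the two general-health groups."""
    groups = [
        SubgroupDefinition(
            f"cond_{j:02d}",
            lambda df, c=f"cond_{j:02d}": df[c].fillna(False).astype(bool),
        )
        for j in range(n_conditions)
    ]
    groups.append(SubgroupDefinition("any_chronic", _any_chronic))
    groups.append(SubgroupDefinition("no_chronic", lambda df: ~_any_chronic(df)))
    groups.append(
        SubgroupDefinition("gh_good", lambda df: df["general_health"] == "good")
    )
    groups.append(
        SubgroupDefinition("gh_fair_poor", lambda df: df["general_health"] == "fair_poor")
    )
    return groups


def default_group_sets(n_conditions: int, ever_conditions: tuple[str, ...] | None = None) -> dict[str, list[str]]:
    """The four group sets the WMAR is reported for.

    ``ever_conditions`` names the "ever suffered from" condition groups (the
    last four condition indicators by default, mirroring a survey with 19
    last-12-months conditions plus 4 lifetime ones).
    """
    if ever_conditions is None:
        ever_conditions = tuple(
            f"cond_{j:02d}" for j in range(max(n_conditions - 4, 0), n_conditions)
        )
    all_groups = [f"cond_{j:02d}" for j in range(n_conditions)]
    return {
        "no_chronic_plus_ever": ["no_chronic", *ever_conditions],
        "all_subgroups": all_groups + ["any_chronic", "no_chronic", "gh_good", "gh_fair_poor"],
        "yes_no_chronic": ["any_chronic", "no_chronic"],
        "general_health": ["gh_good", "gh_fair_poor"],
    }


def subgroup_profit_loss(
    revenues: pd.DataFrame,
    persons: pd.DataFrame,
    group: SubgroupDefinition,
    weights: np.ndarray | pd.Series | None = None,
    alpha: float = 0.05,
) -> SubgroupResult:
    """Weighted mean per-person profit for a subgroup, with weighted SE and a
    two-sided one-sample t-test against zero."""
    mask = group.mask(persons)
    if not mask.any():
        raise ValueError(f"subgroup {group.name!r} is empty")
    profit = revenues["profit"].to_numpy(dtype=float)[mask]
    if weights is None:
        w = np.ones(profit.size)
    else:
        w = np.asarray(weights, dtype=float)[mask]
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
    sw = w.sum()
    mean = float(np.dot(w, profit) / sw)
    se = float(np.sqrt(np.dot(w**2, (profit - mean) ** 2)) / sw)
    n = int(profit.size)
    if se == 0.0:
        significant = bool(mean != 0.0)
    else:
        tcrit = stats.t.ppf(1 - alpha / 2, df=max(n - 1, 1))
        significant = bool(abs(mean) / se > tcrit)
    return SubgroupResult(
        name=group.name,
        n_weighted=float(sw),
        n_persons=n,
        mean_result=mean,
        se=se,
        significant=significant,
    )


def wmar(results: list[SubgroupResult] | dict[str, SubgroupResult], group_set: list[str]) -> float:
    """Weighted mean absolute result over the named groups: sum_g N_g|e_g| / sum_g N_g."""
    by_name = results if isinstance(results, dict) else {r.name: r for r in results}
    missing = [g for g in group_set if g not in by_name]
    if missing:
        raise KeyError(f"unknown subgroup names: {missing}")
    num = sum(by_name[g].n_weighted * abs(by_name[g].mean_result) for g in group_set)
    den = sum(by_name[g].n_weighted for g in group_set)
    return float(num / den)


def power_reduction(
    persons: pd.DataFrame,
    residuals: pd.DataFrame,
    pool: PoolAssignment | None,
    shock: float = 0.10,
    shock_scope: str = "all",
    recompute_financing: bool = False,
) -> float:
    """Reduction in the payment system's Power under a proportional spending shock.

    Every person's spending (or only pool members', with ``shock_scope='pool'``)
    is inflated by ``shock``; pool membership, the threshold tau and the flat
    contribution are ex-ante quantities and stay fixed.  Returned is the total
    change in insurer revenues divided by the total change in spending — the
    share of marginal spending the insurer gets back, i.e. the loss in
    cost-control incentives.  0 without a pool (fully prospective payments);
    at most 1.

    With ``recompute_financing=True`` the flat contribution is re-solved after
    the shock (a market-wide shock under strict budget neutrality); the extra
    compensation is then exactly clawed back, so the total-revenue change is 0.
    """
    if shock <= 0:
        raise ValueError("shock must be > 0")
    if pool is None:
        return 0.0

    ids = persons["person_id"].to_numpy()
    res = residuals.set_index("person_id").loc[ids]
    spending = persons["spending"].to_numpy(dtype=float)
    is_member = np.isin(ids, pool.member_ids)

    if shock_scope == "all":
        shocked = np.ones(ids.size, dtype=bool)
    elif shock_scope == "pool":
        shocked = is_member
    else:
        raise ValueError("shock_scope must be 'all' or 'pool'")

    d_spending = float(np.sum(shock * spending[shocked]))
    if d_spending == 0.0:
        return 0.0

    new_spending = np.where(shocked, spending * (1 + shock), spending)
    share = pool.config.compensation_share
    tau = pool.threshold
    predicted = res["predicted_spending"].to_numpy(dtype=float)
    if pool.config.compensation_basis == "residual":
        basis_old = spending - predicted
        basis_new = new_spending - predicted
    else:
        basis_old, basis_new = spending, new_spending
    comp_old = np.where(is_member, share * np.maximum(basis_old - tau, 0.0), 0.0)
    comp_new = np.where(is_member, share * np.maximum(basis_new - tau, 0.0), 0.0)
    d_revenue = float(np.sum(comp_new - comp_old))
    if recompute_financing:
        d_revenue -= float(np.sum(comp_new - comp_old))  # flat contribution claws it back
    return d_revenue / d_spending


def build_report(
    persons: pd.DataFrame,
    residuals: pd.DataFrame,
    scenarios: dict[str, PoolAssignment | None],
    subgroups: list[SubgroupDefinition],
    group_sets: dict[str, list[str]],
    weights: np.ndarray | pd.Series | None = None,
    shock: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every scenario on one sample; return (subgroup table, incentive table).

    ``scenarios`` maps a scenario label (e.g. ``"no_hrp"``, ``"top_1pct"``) to a
    pool assignment or None.  The incentive table has one row per scenario and
    group set, with WMAR, the Power reduction, and both relative to the no-pool
    scenario.
    """
    from .high_risk_pool import compute_revenues

    baseline_wmar: dict[str, float] = {}
    sub_rows, inc_rows = [], []
    none_labels = [k for k, v in scenarios.items() if v is None]
    ordered = none_labels + [k for k in scenarios if k not in none_labels]

    for label in ordered:
        pool = scenarios[label]
        revenues = compute_revenues(persons, residuals, pool)
        results = {
            g.name: subgroup_profit_loss(revenues, persons, g, weights) for g in subgroups
        }
        for r in results.values():
            sub_rows.append(
                {
                    "scenario": label,
                    "group": r.name,
                    "n": r.n_persons,
                    "n_weighted": r.n_weighted,
                    "mean_result": r.mean_result,
                    "se": r.se,
                    "significant": r.significant,
                }
            )
        power_red = power_reduction(persons, residuals, pool, shock=shock)
        for set_name, names in group_sets.items():
            value = wmar(results, names)
            if pool is None:
                baseline_wmar[set_name] = value
            base = baseline_wmar.get(set_name)
            inc_rows.append(
                {
                    "scenario": label,
                    "group_set": set_name,
                    "wmar": value,
                    "power_reduction": power_red,
                    "wmar_change_vs_no_hrp": (value - base) / base if base else np.nan,
                }
            )
    return pd.DataFrame(sub_rows), pd.DataFrame(inc_rows)
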