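"""High-risk pool mechanics: threshold solving, compensation, financing, revenues.

Insurers prospectively assign the top X% of predicted residual spending to a
pool.  Pool members are retrospectively compensated for (by default) residual
spending above a threshold tau, with tau solved so that the pool's mean
post-compensation residual is exactly zero — the pool neither subsidizes nor
taxes its members in expectation.  The pool is financed by a flat per-person
contribution charged to the complementary group (everyone not in the pool), so
the scheme is budget-neutral within the evaluated sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .residual_prediction import top_fraction

__all__ = [
    "PoolConfig",
    "PoolAssignment",
    "InfeasiblePoolError",
    "solve_threshold",
    "build_pool",
    "compute_revenues",
]


class InfeasiblePoolError(ValueError):
    """No threshold can raise the pool's mean retained residual to zero."""


@dataclass(frozen=True)
class PoolConfig:
    fraction: float  # pool size as share of the evaluated sample, e.g. 0.01..0.05
    compensation_basis: str = "residual"  # or "actual"
    compensation_share: float = 1.0  # share of excess-over-threshold compensated
    solver_tolerance: float = 1e-6  # euro tolerance on the pool's retained mean

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        if not 0 < self.compensation_share <= 1:
            raise ValueError("compensation_share must be in (0, 1]")
        if self.compensation_basis not in ("residual", "actual"):
            raise ValueError("compensation_basis must be 'residual' or 'actual'")


@dataclass(frozen=True)
class PoolAssignment:
    member_ids: np.ndarray  # sorted person ids
    threshold: float  # tau, euro
    compensation: pd.Series  # euro >= 0, indexed by member person_id
    total_compensation: float
    flat_contribution: float  # euro per complementary-group person
    n_complement: int
    config: PoolConfig

    def to_dict(self) -> dict:
        return {
            "fraction": self.config.fraction,
            "basis": self.config.compensation_basis,
            "share": self.config.compensation_share,
            "threshold": self.threshold,
            "n_members": int(self.member_ids.size),
            "n_complement": self.n_complement,
            "total_compensation": self.total_compensation,
            "flat_contribution": self.flat_contribution,
        }


def _retained_mean(values: np.ndarray, share: float, tau: float) -> float:
    return float(np.mean(values - share * np.maximum(values - tau, 0.0)))


def solve_threshold(values: np.ndarray, share: float = 1.0, tolerance: float = 1e-6) -> float:
    """Smallest tau with mean over members of ``v - share*max(v - tau, 0)`` equal to zero.

    The retained mean is piecewise linear and non-decreasing in tau, so bisection
    on a bracket whose lower end is negative converges to the smallest root.
    Infeasible (mean of values < 0 cannot be raised to zero by compensating
    positive excesses) raises :class:`InfeasiblePoolError`.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty basis-value vector")
    hi = float(values.max())
    if _retained_mean(values, share, hi) < -tolerance:
        raise InfeasiblePoolError(
            "no threshold can raise pool mean to zero "
            f"(pool mean basis value {values.mean():.2f} < 0)"
        )
    # The smallest root can lie below min(values) (e.g. all values positive),
    # so bracket from below zero and widen until retained mean is negative.
    lo = min(float(values.min()), 0.0) - 1.0
    while _retained_mean(values, share, lo) > 0.0:
        lo = lo * 2.0 - 1.0
        if lo < -1e15:
            return lo  # retained mean is flat non-positive; degenerate
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _retained_mean(values, share, mid) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-12 * max(1.0, abs(hi)):
            break
    if abs(_retained_mean(values, share, hi)) > tolerance:
        raise InfeasiblePoolError(
            f"threshold solver stalled; retained mean {_retained_mean(values, share, hi):.3e}"
        )
    return hi


def build_pool(
    test_persons: pd.DataFrame,
    predictions: pd.DataFrame,
    residuals: pd.DataFrame,
    config: PoolConfig,
) -> PoolAssignment:
    """Assign the top-``fraction`` of predicted residual spending to the pool and
    solve its compensation threshold on the members' realized basis values.

    ``predictions`` and ``residuals`` must cover every person in ``test_persons``.
    """
    ids = test_persons["person_id"].to_numpy()
    pred = predictions.set_index("person_id").loc[ids]
    res = residuals.set_index("person_id").loc[ids]

    member_ids = top_fraction(pred.reset_index(), config.fraction)
    if member_ids.size < 1:
        raise ValueError("pool fraction yields no members")

    if config.compensation_basis == "residual":
        basis = res.loc[member_ids, "residual_spending"].to_numpy()
    else:
        basis = test_persons.set_index("person_id").loc[member_ids, "spending"].to_numpy()

    tau = solve_threshold(basis, config.compensation_share, config.solver_tolerance)
    comp = config.compensation_share * np.maximum(basis - tau, 0.0)
    total = float(comp.sum())
    n_complement = int(ids.size - member_ids.size)
    if n_complement == 0:
        raise ValueError("pool covers the whole sample; no complementary group to finance it")
    return PoolAssignment(
        member_ids=member_ids,
        threshold=tau,
        compensation=pd.Series(comp, index=pd.Index(member_ids, name="person_id")),
        total_compensation=total,
        flat_contribution=total / n_complement,
        n_complement=n_complement,
        config=config,
    )


def compute_revenues(
    persons: pd.DataFrame,
    residuals: pd.DataFrame,
    pool: PoolAssignment | None,
) -> pd.DataFrame:
    """Per-person revenue and profit.

    Revenue is the risk-equalization payment (predicted spending), plus the HRP
    compensation for pool members, minus the flat financing contribution for the
    complementary group.  Profit is revenue minus actual spending.
    """
    ids = persons["person_id"].to_numpy()
    res = residuals.set_index("person_id").loc[ids]
    revenue = res["predicted_spending"].to_numpy(dtype=float).copy()

    if pool is not None:
        missing = np.setdiff1d(pool.member_ids, ids)
        if missing.size:
            raise ValueError(f"pool members outside evaluated sample: {missing[:5]}")
        is_member = np.isin(ids, pool.member_ids)
        comp = pool.compensation.reindex(ids).fillna(0.0).to_numpy()
        revenue += comp
        revenue -= np.where(is_member, 0.0, pool.flat_contribution)

    spending = persons["spending"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "person_id": ids,
            "revenue": revenue,
            "profit": revenue - spending,
        },
        index=persons.index,
    )
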