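import numpy as np
import pandas as pd
import pytest

from hrpsim.evaluation_metrics import (
    SubgroupDefinition,
    SubgroupResult,
    build_report,
    default_group_sets,
    default_subgroups,
    power_reduction,
    subgroup_profit_loss,
    wmar,
)
from hrpsim.high_risk_pool import PoolAssignment, PoolConfig, build_pool, compute_revenues


def _revenues(profits):
    n = len(profits)
    return pd.DataFrame(
        {"person_id": np.arange(n), "revenue": np.asarray(profits, float), "profit": profits}
    )


def _group_all():
    return SubgroupDefinition("all", lambda df: pd.Series(True, index=df.index))


class TestSubgroupProfitLoss:
    def test_balanced_group_is_insignificant(self):
        persons = pd.DataFrame({"person_id": [0, 1]})
        r = subgroup_profit_loss(_revenues([10.0, -10.0]), persons, _group_all())
        assert r.mean_result == pytest.approx(0.0)
        assert not r.significant

    def test_weighted_mean_by_hand(self):
        persons = pd.DataFrame({"person_id": [0, 1]})
        r = subgroup_profit_loss(
            _revenues([100.0, -50.0]), persons, _group_all(), weights=np.array([1.0, 3.0])
        )
        assert r.mean_result == pytest.approx((100 - 150) / 4)
        assert r.n_weighted == pytest.approx(4.0)

    def test_whole_sample_no_hrp_profit_is_minus_mean_residual(self, toy_persons):
        persons, res, _ = toy_persons
        rev = compute_revenues(persons, res, None)
        r = subgroup_profit_loss(rev, persons, _group_all())
        assert r.mean_result == pytest.approx(-res["residual_spending"].mean())

    def test_empty_group_raises(self):
        persons = pd.DataFrame({"person_id": [0]})
        none = SubgroupDefinition("none", lambda df: pd.Series(False, index=df.index))
        with pytest.raises(ValueError, match="none"):
            subgroup_profit_loss(_revenues([1.0]), persons, none)

    def test_clear_loss_is_significant(self):
        rng = np.random.default_rng(0)
        n = 400
        persons = pd.DataFrame({"person_id": np.arange(n)})
        r = subgroup_profit_loss(
            _revenues(rng.normal(-100, 30, n)), persons, _group_all()
        )
        assert r.significant and r.mean_result < 0


class TestWmar:
    def _res(self, name, n, mean):
        return SubgroupResult(name, n, int(n), mean, 1.0, True)

    def test_hand_computed(self):
        results = [self._res("a", 10, -50.0), self._res("b", 30, 10.0)]
        assert wmar(results, ["a", "b"]) == pytest.approx((500 + 300) / 40)

    def test_zero_means_and_single_group(self):
        results = [self._res("a", 5, 0.0), self._res("b", 5, -7.0)]
        assert wmar(results, ["a"]) == 0.0
        assert wmar(results, ["b"]) == pytest.approx(7.0)

    def test_unknown_group_raises(self):
        with pytest.raises(KeyError):
            wmar([self._res("a", 1, 0.0)], ["zzz"])

    def test_matches_brute_force_from_person_level(self, toy_persons):
        persons, res, preds = toy_persons
        persons = persons.copy()
        rng = np.random.default_rng(7)
        persons["cond_00"] = rng.random(len(persons)) < 0.3
        persons["cond_01"] = rng.random(len(persons)) < 0.2
        rev = compute_revenues(persons, res, None)
        groups = [
            SubgroupDefinition("g0", lambda df: df["cond_00"]),
            SubgroupDefinition("g1", lambda df: df["cond_01"]),
        ]
        results = [subgroup_profit_loss(rev, persons, g) for g in groups]
        got = wmar(results, ["g0", "g1"])
        # brute force from person-level rows
        num = den = 0.0
        for g in ("cond_00", "cond_01"):
            mask = persons[g].to_numpy()
            num += mask.sum() * abs(rev.loc[mask, "profit"].mean())
            den += mask.sum()
        assert got == pytest.approx(num / den, rel=1e-12)


class TestPowerReduction:
    def _pool(self, member_ids, tau, basis="residual"):
        return PoolAssignment(
            member_ids=np.asarray(member_ids),
            threshold=tau,
            compensation=pd.Series(0.0, index=pd.Index(member_ids, name="person_id")),
            total_compensation=0.0,
            flat_contribution=0.0,
            n_complement=1,
            config=PoolConfig(fraction=0.5, compensation_basis=basis),
        )

    def test_no_pool_is_zero(self, toy_persons):
        persons, res, _ = toy_persons
        assert power_reduction(persons, res, None) == 0.0

    def test_hand_computed_two_person_case(self):
        """Member: spending 100, predicted 40, tau 50 -> residual 60 above tau.
        A 10% shock adds 10 to the member's compensation and 20 to total
        spending: reduction 0.5."""
        persons = pd.DataFrame({"person_id": [0, 1], "spending": [100.0, 100.0]})
        res = pd.DataFrame(
            {
                "person_id": [0, 1],
                "predicted_spending": [40.0, 100.0],
                "residual_spending": [60.0, 0.0],
            }
        )
        pool = self._pool([0], tau=50.0)
        assert power_reduction(persons, res, pool, shock=0.10) == pytest.approx(0.5)

    def test_member_below_threshold_contributes_nothing(self):
        persons = pd.DataFrame({"person_id": [0, 1], "spending": [100.0, 500.0]})
        res = pd.DataFrame(
            {
                "person_id": [0, 1],
                "predicted_spending": [200.0, 500.0],
                "residual_spending": [-100.0, 0.0],
            }
        )
        pool = self._pool([0], tau=50.0)  # shocked residual -90 still below tau
        assert power_reduction(persons, res, pool, shock=0.10) == 0.0

    def test_bounds_and_brute_force(self, toy_persons):
        persons, res, preds = toy_persons
        pool = build_pool(persons, preds, res, PoolConfig(fraction=0.05))
        got = power_reduction(persons, res, pool, shock=0.10)
        assert 0.0 <= got <= 1.0
        # per-person recomputation
        res_i = res.set_index("person_id")
        members = set(pool.member_ids)
        d_rev = d_sp = 0.0
        for _, row in persons.iterrows():
            pid = row["person_id"]
            d_sp += 0.10 * row["spending"]
            if pid in members:
                old = max(res_i.loc[pid, "residual_spending"] - pool.threshold, 0.0)
                new_res = row["spending"] * 1.1 - res_i.loc[pid, "predicted_spending"]
                d_rev += max(new_res - pool.threshold, 0.0) - old
        assert got == pytest.approx(d_rev / d_sp, rel=1e-9)

    def test_system_wide_financing_recompute_nets_to_zero(self, toy_persons):
        persons, res, preds = toy_persons
        pool = build_pool(persons, preds, res, PoolConfig(fraction=0.05))
        assert power_reduction(persons, res, pool, recompute_financing=True) == pytest.approx(0.0)

    def test_pool_scope_shocks_members_only(self, toy_persons):
        persons, res, preds = toy_persons
        pool = build_pool(persons, preds, res, PoolConfig(fraction=0.05))
        all_scope = power_reduction(persons, res, pool, shock_scope="all")
        pool_scope = power_reduction(persons, res, pool, shock_scope="pool")
        # same compensation change over a smaller spending change
        assert pool_scope >= all_scope


class TestBuildReport:
    def test_row_counts_and_no_hrp_baseline(self, delta_run):
        inc = delta_run.incentive_report
        n_scen = len(delta_run.scenarios)
        n_sets = inc["group_set"].nunique()
        assert len(inc) == n_scen * n_sets
        base = inc[inc["scenario"] == "no_hrp"]
        assert (base["power_reduction"] == 0).all()
        assert (base["wmar_change_vs_no_hrp"] == 0).all()

    def test_power_nondecreasing_in_pool_fraction(self, delta_run):
        inc = delta_run.incentive_report
        one_set = inc[inc["group_set"] == "yes_no_chronic"]
        ordered = one_set.set_index("scenario").loc[
            ["no_hrp", "top_1pct", "top_2pct", "top_3pct", "top_4pct", "top_5pct"],
            "power_reduction",
        ]
        assert (np.diff(ordered.to_numpy()) >= -1e-12).all()
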