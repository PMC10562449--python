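"""Mass-balance closure: trade, GDP bounds, other uses, left on field."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resalloc.allocation import (
    assemble_ledger,
    assign_other_uses,
    gdp_other_use_bound,
    left_on_field,
    trade_residues,
)
from resalloc.grid import CountryMask, LedgerError
from resalloc.params import AllocationParams
from conftest import toy_field
from trade_oracle import brute_force_trade


class TestGdpBound:
    def test_poor_country_bound(self):
        assert gdp_other_use_bound(800.0) == pytest.approx(0.30)

    def test_rich_country_bound(self):
        assert gdp_other_use_bound(20000.0) == pytest.approx(0.10)

    def test_linear_midpoint(self):
        mid = (1046.0 + 12735.0) / 2
        assert gdp_other_use_bound(mid) == pytest.approx(0.20)

    def test_continuous_at_thresholds(self):
        for t in (1046.0, 12735.0):
            lo = gdp_other_use_bound(t - 1e-6)
            hi = gdp_other_use_bound(t + 1e-6)
            assert abs(lo - hi) < 1e-9

    @settings(derandomize=True, max_examples=80)
    @given(st.floats(min_value=0, max_value=1e6),
           st.floats(min_value=0, max_value=1e6))
    def test_monotonically_non_increasing(self, g1, g2):
        lo, hi = sorted((g1, g2))
        assert gdp_other_use_bound(lo) >= gdp_other_use_bound(hi) - 1e-12

    def test_negative_gdp_rejected(self):
        with pytest.raises(ValueError):
            gdp_other_use_bound(-1.0)


class TestTrade:
    def test_no_deficit_is_identity_with_empty_log(self):
        prod = toy_field([[100.0, 100.0]])
        burnt = toy_field([[10.0, 10.0]])
        demand = toy_field([[20.0, 30.0]])
        usage, unmet, log = trade_residues(prod, burnt, demand)
        assert np.array_equal(usage.values, demand.values)
        assert unmet.total() == 0.0
        assert len(log) == 0

    def test_two_cell_hand_solution(self):
        # A needs 5 beyond its cap; the sole neighbour has capacity 10
        prod = toy_field([[10.0, 100.0]])
        burnt = toy_field([[0.0, 0.0]])
        demand = toy_field([[14.0, 0.0]])
        usage, unmet, log = trade_residues(prod, burnt, demand)
        assert usage.values[0, 0] == pytest.approx(9.0)   # own cap 0.9*10
        assert usage.values[0, 1] == pytest.approx(5.0)   # exported share
        assert unmet.total() == 0.0
        assert len(log) == 1
        assert log.iloc[0]["mass_mg"] == pytest.approx(5.0)

    def test_capacity_beyond_radius_unreachable(self):
        prod = np.zeros((1, 23))
        prod[0, 0] = 10.0
        prod[0, 21] = 1000.0  # Chebyshev distance 21 > radius 20
        demand = np.zeros((1, 23))
        demand[0, 0] = 14.0
        usage, unmet, log = trade_residues(
            toy_field(prod), toy_field(np.zeros((1, 23))), toy_field(demand)
        )
        assert unmet.values[0, 0] == pytest.approx(5.0)
        assert usage.values[0, 0] == pytest.approx(9.0)
        assert len(log) == 0

    def test_nearer_ring_has_priority(self):
        prod = np.zeros((1, 5))
        prod[0, 1] = 100.0   # distance 1 from the deficit cell at col 0
        prod[0, 3] = 100.0   # distance 3
        demand = np.zeros((1, 5))
        demand[0, 0] = 50.0
        usage, unmet, log = trade_residues(
            toy_field(prod), toy_field(np.zeros((1, 5))), toy_field(demand)
        )
        assert unmet.total() == 0.0
        assert usage.values[0, 1] == pytest.approx(50.0)
        assert usage.values[0, 3] == 0.0

    def test_mass_conserved_and_distances_bounded(self):
        rng = np.random.default_rng(4)
        prod = toy_field(rng.gamma(1.0, 50.0, (8, 8)))
        burnt = toy_field(0.2 * prod.values)
        demand = toy_field(rng.gamma(1.0, 40.0, (8, 8)))
        usage, unmet, log = trade_residues(prod, burnt, demand)
        traded = log["mass_mg"].sum() if len(log) else 0.0
        # total usage = local part + exports; demand reduced only by unmet
        assert usage.total() + unmet.total() == pytest.approx(
            demand.total(), rel=1e-9
        )
        if len(log):
            d = np.maximum(
                np.abs(log["from_i"] - log["to_i"]),
                np.abs(log["from_j"] - log["to_j"]),
            )
            assert d.max() <= 20
            assert traded > 0
        # cap respected everywhere
        assert (burnt.values + usage.values
                <= 0.9 * prod.values + 1e-9 * np.maximum(prod.values, 1)).all()

    def test_negative_demand_rejected(self):
        with pytest.raises(ValueError):
            trade_residues(toy_field([[1.0]]), toy_field([[0.0]]),
                           toy_field([[-1.0]]))

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force_oracle_on_small_grids(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(2, 7), rng.integers(2, 7))
        prod = rng.gamma(1.0, 30.0, shape)
        burnt = prod * rng.uniform(0, 0.5, shape)
        demand = rng.gamma(1.0, 30.0, shape)
        usage, unmet, _ = trade_residues(
            toy_field(prod), toy_field(burnt), toy_field(demand)
        )
        o_usage, o_unmet = brute_force_trade(prod, burnt, demand)
        assert usage.total() == pytest.approx(o_usage.sum(), rel=1e-9, abs=1e-9)
        assert unmet.total() == pytest.approx(o_unmet.sum(), rel=1e-9, abs=1e-9)
        assert np.allclose(usage.values, o_usage, rtol=1e-9, atol=1e-9)


class TestOtherUses:
    def test_availability_limited_in_poor_country(self):
        prod = toy_field([[100.0]])
        out = assign_other_uses(prod, toy_field([[0.0]]), toy_field([[80.0]]),
                                np.array([[0.30]]))
        assert out.values[0, 0] == pytest.approx(10.0)  # min(30, 90-80)

    def test_bound_limited_in_rich_country(self):
        prod = toy_field([[100.0]])
        out = assign_other_uses(prod, toy_field([[0.0]]), toy_field([[0.0]]),
                                np.array([[0.10]]))
        assert out.values[0, 0] == pytest.approx(10.0)

    def test_zero_production_zero_other(self):
        out = assign_other_uses(toy_field([[0.0]]), toy_field([[0.0]]),
                                toy_field([[0.0]]), np.array([[0.30]]))
        assert out.total() == 0.0

    def test_cap_violation_rejected(self):
        with pytest.raises(ValueError, match="trade"):
            assign_other_uses(toy_field([[100.0]]), toy_field([[50.0]]),
                              toy_field([[50.0]]), np.array([[0.1]]))


def region_mask(region):
    return CountryMask(np.zeros((1, 1), dtype=int), [0.25], [0.25], 0.5,
                       {"max_return": {0: region}})


class TestLeftOnField:
    def run(self, region, burnt, animal, other, production=100.0):
        return left_on_field(
            toy_field([[production]]), toy_field([[burnt]]),
            toy_field([[animal]]), toy_field([[other]]), region_mask(region)
        )

    def test_china_cap_moves_excess_to_other(self):
        left, other = self.run("china", 10.0, 10.0, 10.0)  # left would be 70 %
        assert left.values[0, 0] == pytest.approx(60.0)
        assert other.values[0, 0] == pytest.approx(20.0)

    def test_europe_cap(self):
        left, other = self.run("europe", 10.0, 10.0, 5.0)  # left would be 75 %
        assert left.values[0, 0] == pytest.approx(70.0)
        assert other.values[0, 0] == pytest.approx(10.0)

    def test_unrestricted_region_unchanged(self):
        left, other = self.run("other", 2.0, 2.0, 1.0)  # left 95 %
        assert left.values[0, 0] == pytest.approx(95.0)
        assert other.values[0, 0] == pytest.approx(1.0)

    def test_negative_left_signals_upstream_violation(self):
        with pytest.raises(ValueError, match="upstream"):
            self.run("other", 60.0, 40.0, 20.0)


class TestAssemble:
    def test_valid_components_assemble(self):
        ledger = assemble_ledger(
            toy_field([[100.0]]), toy_field([[10.0]]), toy_field([[40.0]]),
            toy_field([[10.0]]), toy_field([[40.0]])
        )
        assert ledger.production.values[0, 0] == 100.0

    def test_unbalanced_components_rejected(self):
        with pytest.raises(LedgerError):
            assemble_ledger(
                toy_field([[100.0]]), toy_field([[10.0]]), toy_field([[40.0]]),
                toy_field([[10.0]]), toy_field([[39.0]])
            )

    def test_insufficient_left_rejected(self):
        with pytest.raises(LedgerError):
            assemble_ledger(
                toy_field([[100.0]]), toy_field([[50.0]]), toy_field([[30.0]]),
                toy_field([[15.0]]), toy_field([[5.0]])
            )


class TestParams:
    def test_min_left_must_complement_cap(self):
        with pytest.raises(ValueError):
            AllocationParams(removal_cap=0.9, min_left_fraction=0.2)

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            AllocationParams(gdp_poor_threshold=20000.0)
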