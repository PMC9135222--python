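"""Volume-schedule compilation: mass balance, washouts, feasibility."""

from __future__ import annotations

import math

import numpy as np
import pytest

import pkreplay as pr
from pkreplay.errors import (InfeasibleTargetError, InvalidParameterError,
                             QuantizationError, SchedulingError)


def simulate_exchange(prev, op, config, stocks):
    """Independent step-by-step mixing oracle for one operation."""
    conc = dict(prev)
    r = config.carryover_fraction
    for _ in range(op.n_washouts):
        conc = {d: c * r for d, c in conc.items()}
    out = {}
    for d in conc:
        v = op.drug_volumes.get(d, 0.0)
        out[d] = (conc[d] * config.residual_volume + v * stocks[d]) \
            / config.working_volume
    return out


class TestCompileStep:
    def test_zero_target_from_blank_well_is_blank_refill(self, device):
        stocks = pr.StockSet({"a": 100.0})
        op = pr.compile_step({"a": 0.0}, {"a": 0.0}, device, stocks)
        assert op.n_washouts == 0
        assert op.drug_volumes["a"] == 0.0
        assert op.blank_volume == device.refill_volume

    def test_single_drug_volume_against_mass_balance_oracle(self, device):
        stocks = pr.StockSet({"a": 100.0})
        op = pr.compile_step({"a": 0.0}, {"a": 1.0}, device, stocks)
        assert op.drug_volumes["a"] == pytest.approx(10.0, rel=1e-12)
        assert op.blank_volume == pytest.approx(940.0, rel=1e-12)
        achieved = simulate_exchange({"a": 0.0}, op, device, stocks)
        assert achieved["a"] == pytest.approx(1.0, rel=1e-12)

    def test_large_drop_inserts_washouts_verified_by_simulation(self):
        # 10 -> 0.01 with 5% carryover: floor after k washouts + exchange is
        # 10 * 0.05^(k+1); k = 2 is the minimum making the dispense >= 0
        config = pr.DeviceConfig(min_dispense=0.01)
        stocks = pr.StockSet({"a": 100.0})
        op = pr.compile_step({"a": 10.0}, {"a": 0.01}, config, stocks)
        assert op.n_washouts == 2
        assert op.drug_volumes["a"] == pytest.approx(
            (0.01 * 1000 - 10 * 0.05**2 * 50) / 100, rel=1e-12)
        achieved = simulate_exchange({"a": 10.0}, op, config, stocks)
        assert achieved["a"] == pytest.approx(0.01, rel=1e-12)

    def test_two_drug_volumes_solve_both_balances(self, device):
        stocks = pr.StockSet({"a": 100.0, "b": 100.0})
        op = pr.compile_step({"a": 0.0, "b": 0.0}, {"a": 1.0, "b": 2.0},
                             device, stocks)
        assert op.drug_volumes["a"] == pytest.approx(10.0, rel=1e-12)
        assert op.drug_volumes["b"] == pytest.approx(20.0, rel=1e-12)
        assert op.blank_volume == pytest.approx(920.0, rel=1e-12)
        achieved = simulate_exchange({"a": 0.0, "b": 0.0}, op, device, stocks)
        assert achieved["a"] == pytest.approx(1.0, rel=1e-12)
        assert achieved["b"] == pytest.approx(2.0, rel=1e-12)

    def test_unreachable_target_names_the_limiting_drug(self, device):
        stocks = pr.StockSet({"a": 10.0, "b": 10.0})
        with pytest.raises(InfeasibleTargetError) as exc:
            # pure stock can reach at most 10 * 950/1000 = 9.5
            pr.compile_step({"a": 0.0}, {"a": 9.6}, device, stocks)
        assert exc.value.drug == "a"
        with pytest.raises(InfeasibleTargetError):
            # each drug alone is fine; together they exceed the refill
            pr.compile_step({"a": 0.0, "b": 0.0}, {"a": 5.0, "b": 5.0},
                            device, stocks)

    def test_sub_minimum_dispense_raises_with_suggestion(self, device):
        stocks = pr.StockSet({"a": 1000.0})
        with pytest.raises(QuantizationError) as exc:
            pr.compile_step({"a": 0.0}, {"a": 0.0005}, device, stocks)
        assert exc.value.suggested_target is not None
        # the suggestion itself must be compilable
        pr.compile_step({"a": 0.0}, {"a": exc.value.suggested_target},
                        device, stocks)

    def test_raising_stock_never_breaks_a_feasible_step(self):
        # min_dispense=0: quantization aside, a richer stock only shrinks
        # the required volume and can never make a step undeliverable
        device = pr.DeviceConfig(min_dispense=0.0)
        base = pr.StockSet({"a": 50.0})
        op = pr.compile_step({"a": 2.0}, {"a": 4.0}, device, base)
        for s in (100.0, 500.0, 5000.0):
            richer = pr.StockSet({"a": s})
            op2 = pr.compile_step({"a": 2.0}, {"a": 4.0}, device, richer)
            assert op2.drug_volumes["a"] < op.drug_volumes["a"]


class TestCompileProfile:
    def test_constant_profile_uses_closed_form_maintenance_volume(self, device):
        level, stock = 2.0, 100.0
        prof = pr.StepProfile(tuple(pr.Step(i, 1.0, level) for i in range(6)),
                              6.0, drug="a")
        sched = pr.compile_profile(prof, device, pr.StockSet({"a": stock}),
                                   wells=["A1"])
        steps = sched.wells[0].steps
        # first step doses a blank well; later steps maintain the level
        assert steps[0].drug_volumes["a"] == pytest.approx(
            level * device.working_volume / stock, rel=1e-12)
        maintenance = level * device.refill_volume / stock
        for op in steps[1:]:
            assert op.drug_volumes["a"] == pytest.approx(maintenance, rel=1e-12)

    def test_thirteen_step_profile_compiles_cleanly(self, device,
                                                    thirteen_step_profile):
        stock = 2.0 * max(thirteen_step_profile.targets)
        sched = pr.compile_profile(thirteen_step_profile, device,
                                   pr.StockSet({"erki": stock}), wells=["A1"])
        assert all(op.n_washouts == 0 for op in sched.wells[0].steps)

    def test_hundredfold_drop_needs_at_least_two_washouts(self, device):
        # k >= ceil(log(drop)/log(V_w/V_r)) - 1 with drop=100, ratio=20
        prof = pr.StepProfile((pr.Step(0.0, 1.0, 100.0), pr.Step(1.0, 1.0, 1.0)),
                              2.0, drug="a")
        sched = pr.compile_profile(prof, device, pr.StockSet({"a": 200.0}),
                                   wells=["A1"])
        k_bound = math.ceil(math.log(100.0) / math.log(20.0)) - 1
        assert sched.wells[0].steps[1].n_washouts >= k_bound

    def test_two_drug_profiles_must_share_a_tiling(self, device):
        a = pr.StepProfile((pr.Step(0.0, 1.0, 1.0), pr.Step(1.0, 1.0, 1.0)),
                           2.0, drug="a")
        b = pr.StepProfile((pr.Step(0.0, 2.0, 1.0),), 2.0, drug="b")
        with pytest.raises(InvalidParameterError):
            pr.compile_profile([a, b], device,
                               pr.StockSet({"a": 10.0, "b": 10.0}))

    def test_time_budget_violation_reports_minutes(self, thirteen_step_profile):
        slow = pr.DeviceConfig(flow_rate=2.4, n_wells=24)
        stock = 2.0 * max(thirteen_step_profile.targets)
        with pytest.raises(SchedulingError) as exc:
            pr.compile_profile(thirteen_step_profile, slow,
                               pr.StockSet({"erki": stock}))
        assert exc.value.required_min > exc.value.available_min

    def test_distinct_profiles_per_well(self, device):
        hi = pr.build_coverage_profile(0.9, 14.0, 24.0, 1.0, drug="a")
        lo = pr.build_coverage_profile(0.1, 14.0, 24.0, 1.0, drug="a")
        sched = pr.compile_wells({"A1": [hi], "A2": [lo]}, device,
                                 pr.StockSet({"a": 10.0}))
        vols = {w.well_id: w.steps[0].drug_volumes["a"] for w in sched.wells}
        assert vols["A1"] == pytest.approx(9.0 * vols["A2"], rel=1e-12)


class TestFixedDoseReference:
    def test_matches_highest_step_target(self, thirteen_step_profile):
        assert pr.fixed_dose_reference(thirteen_step_profile) == max(
            thirteen_step_profile.targets)

    def test_simple_profiles(self):
        const = pr.StepProfile(tuple(pr.Step(i, 1.0, 5.0) for i in range(3)),
                               3.0)
        assert pr.fixed_dose_reference(const) == 5.0
        stair = pr.StepProfile((pr.Step(0, 1, 1.0), pr.Step(1, 1, 3.0),
                                pr.Step(2, 1, 9.0)), 3.0)
        assert pr.fixed_dose_reference(stair) == 9.0


class TestStaircase:
    def test_two_level_staircase_plateaus(self, device):
        stocks = pr.StockSet({"f": 100.0})
        sched = pr.build_staircase_program(1.0, 3.0, 2, device, stocks)
        targets = [op.targets["f"] for op in sched.wells[0].steps]
        assert targets == [1.0, 3.0, 1.0]

    def test_top_level_above_stock_rejected(self, device):
        stocks = pr.StockSet({"f": 100.0})
        with pytest.raises(InfeasibleTargetError):
            pr.build_staircase_program(1.0, 3.0, 6, device, stocks)

    def test_device_invariants(self):
        with pytest.raises(InvalidParameterError):
            pr.DeviceConfig(residual_volume=1000.0, working_volume=1000.0)
        with pytest.raises(InvalidParameterError):
            pr.DeviceConfig(flow_rate=2000.0)
        with pytest.raises(InvalidParameterError):
            pr.DeviceConfig(n_wells=25)
        with pytest.raises(InvalidParameterError):
            pr.StockSet({"a": 0.0})
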