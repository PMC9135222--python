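"""Digital-twin execution: exact mixing, ledger, traces, audits."""

from __future__ import annotations

import numpy as np
import pytest

import pkreplay as pr
from pkreplay.compiler import StepOperation, WellSchedule
from pkreplay.errors import ValidationError


def make_schedule(device, stocks, ops_per_well, cycle_length=24.0, n_cycles=1):
    wells = tuple(WellSchedule(well_id=w, steps=tuple(ops))
                  for w, ops in ops_per_well.items())
    return pr.Schedule(device=device, stocks=stocks, cycle_length=cycle_length,
                       n_cycles=n_cycles, wells=wells)


class TestSimulate:
    def test_empty_schedule_yields_initial_state_only(self, device):
        sched = make_schedule(device, pr.StockSet({"a": 10.0}), {"A1": []})
        trace = pr.simulate(sched)
        s = trace.well_series("A1", "a")
        assert list(s.times) == [0.0] and list(s.concentrations) == [0.0]

    def test_single_step_hand_mass_balance(self, device):
        # dispense V_d with V_d*S/V_w = 1 into a blank well -> exactly 1
        stocks = pr.StockSet({"a": 100.0})
        op = StepOperation(start=0.0, duration=1.0, n_washouts=0,
                           blank_volume=940.0, drug_volumes={"a": 10.0},
                           targets={"a": 1.0}, achieved={"a": 1.0})
        trace = pr.simulate(make_schedule(device, stocks, {"A1": [op]}))
        assert trace.well_series("A1", "a").concentrations[-1] == pytest.approx(
            1.0, rel=1e-12)

    def test_multi_cycle_round_trip_hits_every_target(self, device,
                                                      thirteen_step_profile):
        stock = 2.0 * max(thirteen_step_profile.targets)
        sched = pr.compile_profile(thirteen_step_profile, device,
                                   pr.StockSet({"erki": stock}),
                                   n_cycles=14, wells=["A1"])
        trace = pr.simulate(sched)
        recs = trace.well_records("A1")
        assert len(recs) == 13 * 14
        for r in recs:
            assert r.achieved["erki"] == pytest.approx(r.targets["erki"],
                                                       rel=1e-9)

    def test_mass_ledger_balances_at_every_step(self, device,
                                                thirteen_step_profile):
        stock = 2.0 * max(thirteen_step_profile.targets)
        sched = pr.compile_profile(thirteen_step_profile, device,
                                   pr.StockSet({"erki": stock}),
                                   n_cycles=3, wells=["A1"])
        trace = pr.simulate(sched)
        for r in trace.well_records("A1"):
            scale = max(abs(v) for v in
                        (r.achieved["erki"] * device.working_volume, 1.0))
            assert abs(r.ledger_residual["erki"]) <= 1e-9 * scale

    def test_blank_exchange_carryover_law(self, device):
        # k washout exchanges + the final blank exchange multiply the
        # concentration by exactly (V_r/V_w)^(k+1)
        stocks = pr.StockSet({"a": 100.0})
        dose = StepOperation(start=0.0, duration=1.0, n_washouts=0,
                             blank_volume=890.0, drug_volumes={"a": 60.0},
                             targets={"a": 6.0}, achieved={"a": 6.0})
        for k in (0, 1, 2, 3):
            blank = StepOperation(start=1.0, duration=1.0, n_washouts=k,
                                  blank_volume=950.0, drug_volumes={},
                                  targets={"a": 0.0}, achieved={})
            trace = pr.simulate(make_schedule(device, stocks,
                                              {"A1": [dose, blank]}))
            end = trace.well_series("A1", "a").concentrations[-1]
            assert end == pytest.approx(6.0 * 0.05 ** (k + 1), rel=1e-12)

    def test_two_drug_independence(self, device):
        a = pr.build_coverage_profile(0.9, 14.0, 24.0, 2.0, drug="a")
        b = pr.build_coverage_profile(0.4, 8.0, 24.0, 2.0, drug="b")
        stocks = pr.StockSet({"a": 10.0, "b": 10.0})
        both = pr.simulate(pr.compile_profile([a, b], device, stocks,
                                              wells=["A1"]))
        alone = pr.simulate(pr.compile_profile(a, device,
                                               pr.StockSet({"a": 10.0}),
                                               wells=["A1"]))
        np.testing.assert_allclose(
            both.well_series("A1", "a").concentrations,
            alone.well_series("A1", "a").concentrations, rtol=1e-12)

    def test_determinism_bit_identical(self, device, thirteen_step_profile):
        stock = 2.0 * max(thirteen_step_profile.targets)
        sched = pr.compile_profile(thirteen_step_profile, device,
                                   pr.StockSet({"erki": stock}), wells=["A1"])
        t1, t2 = pr.simulate(sched), pr.simulate(sched)
        np.testing.assert_array_equal(t1.well_series("A1").concentrations,
                                      t2.well_series("A1").concentrations)

    def test_malformed_schedule_rejected_before_execution(self, device):
        stocks = pr.StockSet({"a": 100.0})
        bad = StepOperation(start=0.0, duration=1.0, n_washouts=0,
                            blank_volume=500.0, drug_volumes={"a": 10.0},
                            targets={}, achieved={})  # dispenses 510, not 950
        with pytest.raises(ValidationError):
            pr.simulate(make_schedule(device, stocks, {"A1": [bad]}))


class TestReplicationError:
    def test_self_comparison_constant(self, device):
        prof = pr.StepProfile(tuple(pr.Step(float(i), 1.0, 2.0)
                                    for i in range(24)), 24.0, drug="a")
        sched = pr.compile_profile(prof, device, pr.StockSet({"a": 10.0}),
                                   wells=["A1"])
        trace = pr.simulate(sched)
        rep = pr.replication_error(trace, lambda t: np.full_like(t, 2.0))
        assert rep.auc_ratio == pytest.approx(1.0, rel=1e-9)
        assert rep.cmax_ratio == pytest.approx(1.0, rel=1e-9)
        assert rep.max_step_deviation == pytest.approx(0.0, abs=1e-12)

    def test_reference_equal_to_own_step_profile(self, device,
                                                 thirteen_step_profile):
        prof = thirteen_step_profile
        stock = 2.0 * max(prof.targets)
        trace = pr.simulate(pr.compile_profile(
            prof, device, pr.StockSet({"erki": stock}), wells=["A1"]))
        starts = np.array([s.start for s in prof.steps])
        targets = np.array(prof.targets)

        def step_fn(t):
            idx = np.clip(np.searchsorted(starts, np.asarray(t), side="right")
                          - 1, 0, len(targets) - 1)
            return targets[idx]

        rep = pr.replication_error(trace, step_fn)
        assert rep.auc_ratio == pytest.approx(1.0, rel=1e-2)
        assert rep.cmax_ratio == pytest.approx(1.0, rel=1e-9)

    def test_bateman_reference_auc_within_ten_percent(self, device, params,
                                                      qd_curve,
                                                      thirteen_step_profile):
        stock = 2.0 * max(thirteen_step_profile.targets)
        trace = pr.simulate(pr.compile_profile(
            thirteen_step_profile, device, pr.StockSet({"erki": stock}),
            wells=["A1"]))
        rep = pr.replication_error(trace, qd_curve)
        assert rep.auc_ratio == pytest.approx(1.0, rel=0.10)

    def test_mismatched_span_rejected(self, device):
        prof = pr.build_coverage_profile(1.0, 24.0, 24.0, 1.0, drug="a")
        trace = pr.simulate(pr.compile_profile(
            prof, device, pr.StockSet({"a": 10.0}), wells=["A1"]))
        short_ref = pr.ConcentrationSeries(np.array([0.0, 12.0]),
                                           np.array([1.0, 1.0]))
        with pytest.raises(pr.InvalidParameterError):
            pr.replication_error(trace, short_ref)


class TestStaircaseAudit:
    def test_two_level_staircase(self, device):
        sched = pr.build_staircase_program(1.0, 3.0, 2, device,
                                           pr.StockSet({"f": 100.0}))
        audit = pr.staircase_audit(pr.simulate(sched))
        assert audit.dynamic_range == pytest.approx(3.0, rel=1e-12)
        assert audit.ascending_ratios == (pytest.approx(3.0, rel=1e-12),)

    def test_eight_level_range_matches_closed_form(self):
        config = pr.DeviceConfig(min_dispense=0.05)
        stocks = pr.StockSet({"f": 1.5 * 3.0**7})
        sched = pr.build_staircase_program(1.0, 3.0, 8, config, stocks)
        audit = pr.staircase_audit(pr.simulate(sched))
        assert audit.dynamic_range == pytest.approx(3.0**7, rel=1e-9)
        for ratio in audit.ascending_ratios:
            assert ratio == pytest.approx(3.0, rel=0.01)
        for ratio in audit.descending_ratios:
            assert ratio == pytest.approx(1.0 / 3.0, rel=0.01)

    def test_zero_plateaus_excluded_and_counted(self, device):
        prof = pr.build_coverage_profile(2.0, 12.0, 24.0, 2.0, drug="a")
        trace = pr.simulate(pr.compile_profile(
            prof, device, pr.StockSet({"a": 10.0}), wells=["A1"]))
        audit = pr.staircase_audit(trace)
        assert audit.n_zero_excluded == 1
        assert audit.dynamic_range == pytest.approx(1.0)
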