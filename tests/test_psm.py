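import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from psmcea import (
    AdverseEvent,
    CEResult,
    ModelSettings,
    StrategySpec,
    SurvivalTrace,
    WeibullCurve,
    accrue_costs,
    accrue_outcomes,
    build_trace,
    compute_icer,
    evaluate_base_case,
)
from psmcea.errors import InvalidArgumentError

from reference_psm import reference_evaluate

CTC_PFS = WeibullCurve(0.04, 1.28)
CTC_OS = WeibullCurve(0.01, 1.53)


def flat_trace(n_cycles, settings, pfs=1.0, pd=0.0):
    """A hand-built trace with constant occupancy (for rectangle-rule tests)."""
    t = settings.eval_times_months()
    ones = np.ones(n_cycles)
    disc = np.power(1 + settings.annual_discount, -t / 12.0)
    return SurvivalTrace(time_months=t, pfs=pfs * ones, pd=pd * ones,
                         dead=(1 - pfs - pd) * ones, discount=disc)


def simple_strategy(pfs_u=0.75, pd_u=0.59, induction_cost=0.0,
                    maintenance_cost=0.0, aes=()):
    return StrategySpec(
        name="X", induction=(("drug", induction_cost),),
        maintenance=("drug", maintenance_cost), maintenance_cap_months=24,
        adverse_events=tuple(aes), pfs_utility=pfs_u, pd_utility=pd_u)


class TestBuildTrace:
    def test_start_convention_begins_fully_progression_free(self):
        s = ModelSettings(cycle_eval="start")
        trace = build_trace(CTC_PFS, CTC_OS, s)
        assert (trace.pfs[0], trace.pd[0], trace.dead[0]) == (1.0, 0.0, 0.0)

    def test_identical_curves_leave_no_progressed_state(self):
        trace = build_trace(CTC_OS, CTC_OS, ModelSettings())
        assert np.all(trace.pd == 0.0)

    def test_progressed_fraction_is_curve_difference(self):
        """At one year, PD occupancy equals S_os(12) - S_pfs(12)."""
        s = ModelSettings(months_per_cycle=1.0, cycle_eval="start",
                          n_cycles=24)
        trace = build_trace(CTC_PFS, CTC_OS, s)
        i = 12  # start convention: cycle 12 evaluates at t=12 months
        assert trace.time_months[i] == 12.0
        expect = CTC_OS.survival(12.0) - CTC_PFS.survival(12.0)
        assert trace.pd[i] == pytest.approx(expect, abs=1e-14)

    @given(scale_p=st.floats(1e-3, 0.3), shape_p=st.floats(0.5, 2.5),
           scale_o=st.floats(1e-3, 0.3), shape_o=st.floats(0.5, 2.5),
           disc=st.floats(0.0, 0.2))
    def test_conservation_and_monotonicity(self, scale_p, shape_p,
                                           scale_o, shape_o, disc):
        s = ModelSettings(annual_discount=disc, n_cycles=80)
        trace = build_trace(WeibullCurve(scale_p, shape_p),
                            WeibullCurve(scale_o, shape_o), s)
        np.testing.assert_allclose(trace.pfs + trace.pd + trace.dead, 1.0,
                                   atol=1e-12)
        assert np.all(np.diff(trace.pfs) <= 1e-15)
        assert np.all(np.diff(trace.pfs + trace.pd) <= 1e-15)
        assert np.all(np.diff(trace.discount) <= 0)


class TestAccrual:
    def test_qaly_equals_ly_under_perfect_utility(self):
        s = ModelSettings(annual_discount=0.0)
        trace = build_trace(CTC_PFS, CTC_OS, s)
        out = accrue_outcomes(trace, simple_strategy(pfs_u=1.0, pd_u=1.0), s)
        assert out["qaly"] == pytest.approx(out["ly"], abs=1e-12)

    def test_rectangle_rule_one_year(self):
        """Occupancy pinned at PFS=1 for exactly one year, utility 0.75,
        no discounting: LY = 1.0 and QALY = 0.75."""
        s = ModelSettings(months_per_cycle=12.0 / 52.0, n_cycles=52,
                          annual_discount=0.0)
        trace = flat_trace(52, s)
        out = accrue_outcomes(trace, simple_strategy(pfs_u=0.75), s)
        assert out["ly"] == pytest.approx(1.0, abs=1e-12)
        assert out["qaly"] == pytest.approx(0.75, abs=1e-12)

    def test_component_sums(self, base_case):
        for res in base_case.results.values():
            assert res.ly == pytest.approx(res.pf_ly + res.pd_ly, abs=1e-9)
            assert res.qaly == pytest.approx(res.pfs_qaly + res.pd_qaly,
                                             abs=1e-9)
            assert res.total_cost == pytest.approx(
                res.drug_cost + res.ae_cost, abs=1e-9)

    def test_zero_prices_zero_cost(self):
        s = ModelSettings(annual_discount=0.0)
        trace = build_trace(CTC_PFS, CTC_OS, s)
        cost = accrue_costs(trace, simple_strategy(), s)
        assert cost["total_cost"] == 0.0

    def test_induction_cost_arithmetic(self):
        """Full PFS occupancy, no discounting: six induction cycles of the
        camrelizumab+paclitaxel+carboplatin bundle cost 6 x 1364.97."""
        s = ModelSettings(n_cycles=6, annual_discount=0.0)
        trace = flat_trace(6, s)
        strat = StrategySpec(
            name="CTC",
            induction=(("camrelizumab", 382.86), ("paclitaxel", 936.11),
                       ("carboplatin", 46.00)),
            maintenance=("camrelizumab", 382.86), maintenance_cap_months=24,
            adverse_events=(), pfs_utility=0.75, pd_utility=0.59)
        cost = accrue_costs(trace, strat, s)
        assert cost["drug_cost"] == pytest.approx(8189.82, abs=1e-9)

    def test_no_drug_cost_on_progressed_occupancy(self):
        s = ModelSettings(n_cycles=10, annual_discount=0.0)
        trace = flat_trace(10, s, pfs=0.0, pd=1.0)
        strat = simple_strategy(induction_cost=100.0, maintenance_cost=50.0)
        assert accrue_costs(trace, strat, s)["drug_cost"] == 0.0

    def test_maintenance_stops_at_cap(self):
        s = ModelSettings(months_per_cycle=1.0, n_cycles=60,
                          annual_discount=0.0)
        trace = flat_trace(60, s)
        strat = simple_strategy(maintenance_cost=100.0)
        cost = accrue_costs(trace, strat, s)
        # cycles 6..23 under a 24-month cap with 1-month cycles
        assert cost["drug_cost"] == pytest.approx(18 * 100.0, abs=1e-9)

    def test_one_off_ae_cost_mode(self):
        s = ModelSettings(ae_cost_mode="one_off", annual_discount=0.0)
        trace = build_trace(CTC_PFS, CTC_OS, s)
        ae = AdverseEvent("anemia", incidence=0.1, cost=138.75, disutility=0.11)
        cost = accrue_costs(trace, simple_strategy(aes=[ae]), s)
        assert cost["ae_cost"] == pytest.approx(13.875, abs=1e-12)


class TestIncremental:
    def r(self, cost, qaly, ly=1.0, name="A"):
        return CEResult(strategy=name, ly=ly, pf_ly=ly, pd_ly=0.0, qaly=qaly,
                        pfs_qaly=qaly, pd_qaly=0.0, total_cost=cost,
                        drug_cost=cost, ae_cost=0.0)

    def test_simple_ratio(self):
        inc = compute_icer(self.r(200, 2), self.r(100, 1, name="B"))
        assert inc.icer_qaly == pytest.approx(100.0)
        assert inc.classification == "ratio"

    def test_dominance(self):
        inc = compute_icer(self.r(99, 1.1), self.r(100, 1.0, name="B"))
        assert inc.classification == "dominant"

    def test_dominated(self):
        inc = compute_icer(self.r(101, 0.9), self.r(100, 1.0, name="B"))
        assert inc.classification == "dominated"

    def test_zero_qaly_difference_flagged_undefined(self):
        inc = compute_icer(self.r(200, 1.0), self.r(100, 1.0, name="B"))
        assert inc.classification == "undefined"
        assert math.isnan(inc.icer_qaly)


class TestModelProperties:
    def test_discount_monotonicity(self, config):
        """Raising the discount rate strictly lowers every discounted total
        (checked over the one-way sensitivity range)."""
        totals = []
        for rate in (0.03, 0.05, 0.08):
            raw = config.copy().raw
            raw["settings"]["annual_discount"]["baseline"] = rate
            res = evaluate_base_case(raw)
            totals.append([(r.ly, r.qaly, r.total_cost)
                           for r in res.results.values()])
        for low, high in zip(totals, totals[1:]):
            for arm_low, arm_high in zip(low, high):
                assert all(h < l for l, h in zip(arm_low, arm_high))

    def test_horizon_monotonicity(self, config):
        prev = None
        for n_cycles in (50, 100, 173):
            raw = config.copy().raw
            raw["settings"]["n_cycles"] = n_cycles
            res = evaluate_base_case(raw)
            cur = [(r.ly, r.qaly, r.total_cost) for r in res.results.values()]
            if prev is not None:
                for arm_prev, arm_cur in zip(prev, cur):
                    assert all(c >= p for p, c in zip(arm_prev, arm_cur))
            prev = cur

    def test_qaly_never_exceeds_ly(self, base_case):
        for res in base_case.results.values():
            assert res.qaly <= res.ly

    @pytest.mark.parametrize("overrides", [
        {},
        {"cycle_eval": "start"},
        {"ae_cost_mode": "one_off"},
        {"ae_disutility_mode": "induction_only"},
        {"hr_direction": "multiply"},
    ])
    def test_matches_independent_reference_loop(self, config, overrides):
        """The vectorized engine agrees with a separately written plain-
        Python per-cycle accrual to 1e-9 on the full default configuration,
        under every accrual convention."""
        raw = config.copy().raw
        raw["settings"].update(overrides)
        ours = evaluate_base_case(raw)
        expected = reference_evaluate(raw)
        for arm, exp in expected.items():
            got = ours.results[arm].to_row()
            for key, val in exp.items():
                assert got[key] == pytest.approx(val, abs=1e-9), (arm, key)


class TestValidation:
    def test_settings_bounds(self):
        with pytest.raises(InvalidArgumentError):
            ModelSettings(n_cycles=0)
        with pytest.raises(InvalidArgumentError):
            ModelSettings(annual_discount=1.5)

    def test_trace_invariants_enforced(self):
        with pytest.raises(InvalidArgumentError):
            SurvivalTrace(time_months=np.array([0.0]), pfs=np.array([0.6]),
                          pd=np.array([0.6]), dead=np.array([0.2]),
                          discount=np.array([1.0]))

    def test_negative_cost_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simple_strategy(induction_cost=-1.0)
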