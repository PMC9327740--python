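"""Markov engine: matrix assembly, propagation oracle, outcome accumulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from warfcea import (
    HealthState,
    STATE_ORDER,
    accumulate_outcomes,
    build_transition_matrix,
    default_base_case,
    evaluate_arm,
    initial_distribution,
    parameter_catalog,
    propagate,
    set_parameter,
)
from warfcea.errors import InfeasibleParameterError
from warfcea.markov import OccupancyTrace, TransitionMatrix
from warfcea.parameters import DiscountHorizonSpec, ParameterValue
from warfcea.states import STATE_INDEX

from conftest import random_transition_matrix

IDX = STATE_INDEX


def pv(x):
    return ParameterValue(base=x, low=x, high=x)


def closed_form_qaly(utility, annual_rate, n_cycles):
    """Geometric-series QALY total for a single persistent alive state."""
    t = np.arange(n_cycles)
    return utility / 12.0 * ((1.0 + annual_rate) ** (-t / 12.0)).sum()


class TestBuildMatrix:
    def test_intervention_rows_match_published_remainders(self, base_config):
        m = build_transition_matrix(
            base_config.arm_intervention, base_config.events, label="intervention"
        ).matrix
        w = IDX[HealthState.WITHIN_RANGE]
        assert m[w, IDX[HealthState.BELOW_RANGE]] == 0.0225
        assert m[w, IDX[HealthState.ABOVE_RANGE]] == 0.0191
        assert m[w, w] == pytest.approx(0.9584, abs=1e-12)
        b = IDX[HealthState.BELOW_RANGE]
        assert m[b, IDX[HealthState.TE]] == 0.0023
        assert m[b, b] == pytest.approx(1 - 0.4263 - 0.0023, abs=1e-12)

    def test_death_row_absorbing(self, base_config):
        m = build_transition_matrix(
            base_config.arm_control, base_config.events
        ).matrix
        expected = np.zeros(9)
        expected[IDX[HealthState.DEATH]] = 1.0
        assert np.array_equal(m[IDX[HealthState.DEATH]], expected)

    def test_recovery_death_carries_risk_ratio(self, base_config):
        """Post-TE recovery mortality is the recovery rate times the TE
        excess-death ratio: 0.00147 x 2.25 = 0.0033075."""
        m = build_transition_matrix(
            base_config.arm_intervention, base_config.events
        ).matrix
        rt = IDX[HealthState.RECOVERY_POST_TE]
        rb = IDX[HealthState.RECOVERY_POST_BLEED_OR_REOP]
        d = IDX[HealthState.DEATH]
        assert m[rt, d] == pytest.approx(0.0033075, abs=1e-15)
        assert m[rb, d] == pytest.approx(0.00147 * 1.5, abs=1e-15)

    def test_event_rows_route_residual_to_matching_recovery(self, base_config):
        m = build_transition_matrix(
            base_config.arm_intervention, base_config.events
        ).matrix
        te = IDX[HealthState.TE]
        assert m[te, IDX[HealthState.RECOVERY_POST_TE]] == pytest.approx(
            1 - 0.00228 - 0.00033 - 0.00374 - 0.08825, abs=1e-12
        )
        re = IDX[HealthState.REOPERATION]
        assert m[re, IDX[HealthState.RECOVERY_POST_BLEED_OR_REOP]] > 0.99

    def test_rows_are_stochastic(self, base_config):
        for arm in (base_config.arm_intervention, base_config.arm_control):
            m = build_transition_matrix(arm, base_config.events).matrix
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= 0).all() and (m <= 1).all()

    def test_infeasible_row_raises_naming_the_row(self, base_config):
        events = base_config.events.model_copy(
            update={"te_to_te": pv(0.999), "te_to_death": pv(0.5)}
        )
        with pytest.raises(InfeasibleParameterError, match="te row"):
            build_transition_matrix(base_config.arm_intervention, events)

    def test_initial_proportion_above_one_renormalized(self, base_config, caplog):
        """The published within-range bound 1.0937 leaves the simplex; the
        initial distribution clamps to [0,1] and renormalizes, logged."""
        arm = set_parameter(
            base_config, "intervention.initial_within", 1.0937
        ).arm_intervention
        with caplog.at_level("INFO", logger="warfcea.markov"):
            init = initial_distribution(arm)
        assert init.sum() == pytest.approx(1.0, abs=1e-12)
        assert (init <= 1.0).all() and (init >= 0.0).all()
        assert "renormaliz" in caplog.text

    def test_negative_bound_clamped_to_zero(self, base_config, caplog):
        """A negative probability (possible only via unvalidated ranges) is
        clamped to 0 at matrix-build time, with a log record."""
        arm = base_config.arm_intervention.model_copy(
            update={
                "p_within_to_below": ParameterValue(base=0.02, low=-0.1, high=0.1)
            }
        )
        with caplog.at_level("INFO", logger="warfcea.markov"):
            m = build_transition_matrix(arm, base_config.events, which="low").matrix
        assert m[IDX[HealthState.WITHIN_RANGE], IDX[HealthState.BELOW_RANGE]] == 0.0
        assert "clamp" in caplog.text


class TestPropagate:
    def test_identity_matrix_is_fixed_point(self):
        tm = TransitionMatrix(arm="toy", matrix=np.eye(9))
        init = np.zeros(9)
        init[0] = 0.7
        init[3] = 0.3
        trace = propagate(tm, init, 5)
        assert np.allclose(trace.occupancy, init)

    def test_two_state_symmetric_mixing(self):
        m = np.eye(9)
        m[0, 0] = m[1, 1] = 0.5
        m[0, 1] = m[1, 0] = 0.5
        tm = TransitionMatrix(arm="toy", matrix=m)
        init = np.zeros(9)
        init[0] = 1.0
        trace = propagate(tm, init, 1)
        assert trace.occupancy[1, 0] == pytest.approx(0.5)
        assert trace.occupancy[1, 1] == pytest.approx(0.5)

    def test_one_cycle_equals_hand_product(self, base_config):
        arm = base_config.arm_intervention
        tm = build_transition_matrix(arm, base_config.events)
        init = initial_distribution(arm)
        trace = propagate(tm, init, 1)
        assert np.allclose(trace.occupancy[1], init @ tm.matrix, atol=0)

    @given(seed=st.integers(0, 10_000), n=st.integers(1, 40))
    def test_agrees_with_matrix_power_oracle(self, seed, n):
        """Iterative propagation equals init @ P^n on random valid matrices."""
        rng = np.random.default_rng(seed)
        m = random_transition_matrix(rng)
        init = rng.dirichlet(np.ones(9))
        init /= init.sum()
        trace = propagate(TransitionMatrix(arm="rnd", matrix=m), init, n)
        oracle = init @ np.linalg.matrix_power(m, n)
        assert np.allclose(trace.occupancy[-1], oracle, atol=1e-12)

    @pytest.mark.parametrize("which", ["intervention", "control"])
    def test_mass_conservation_and_death_monotone_480(self, base_config, which):
        arm = base_config.arm(which)
        tm = build_transition_matrix(arm, base_config.events)
        trace = propagate(tm, initial_distribution(arm), 480)
        assert np.abs(trace.occupancy.sum(axis=1) - 1.0).max() < 1e-9
        assert (np.diff(trace.occupancy[:, IDX[HealthState.DEATH]]) >= -1e-15).all()

    def test_trace_invariants_enforced(self):
        bad = np.full((3, 9), 1.0 / 9)
        bad[1, 0] += 0.1
        with pytest.raises(ValueError, match="mass conservation"):
            OccupancyTrace(occupancy=bad)


def _persistent_state_setup(utility, n_cycles, rate, hcc):
    """One absorbing alive state with a given utility; no transitions."""
    cfg = default_base_case()
    m = np.eye(9)
    tm = TransitionMatrix(arm="toy", matrix=m)
    init = np.zeros(9)
    init[IDX[HealthState.WITHIN_RANGE]] = 1.0
    trace = propagate(tm, init, n_cycles)
    utilities = cfg.utilities.model_copy(update={"u_within_range": pv(utility)})
    spec = DiscountHorizonSpec(
        annual_discount_cost=pv(rate),
        annual_discount_qaly=pv(rate),
        horizon_cycles=n_cycles,
        half_cycle_correction=hcc,
    )
    return trace, utilities, cfg.costs, spec


class TestAccumulate:
    def test_full_health_year_is_one_qaly(self):
        trace, utilities, costs, spec = _persistent_state_setup(1.0, 12, 0.0, False)
        out = accumulate_outcomes(trace, utilities, costs, spec)
        assert out.total_qaly == pytest.approx(1.0, abs=1e-12)
        assert out.total_cost == 0.0
        assert out.life_years == pytest.approx(1.0)

    def test_bleeding_cycle_costs_published_amount(self, base_config):
        """A cohort parked in the bleeding state for one undiscounted cycle
        accrues exactly the published bleeding event cost."""
        tm = TransitionMatrix(arm="toy", matrix=np.eye(9))
        init = np.zeros(9)
        init[IDX[HealthState.BLEEDING]] = 1.0
        trace = propagate(tm, init, 1)
        spec = DiscountHorizonSpec(
            annual_discount_cost=pv(0.0),
            annual_discount_qaly=pv(0.0),
            horizon_cycles=1,
            half_cycle_correction=False,
        )
        out = accumulate_outcomes(trace, base_config.utilities, base_config.costs, spec)
        assert out.total_cost == pytest.approx(2777.78, abs=1e-9)

    @pytest.mark.parametrize("hcc", [True, False])
    def test_matches_geometric_series_closed_form(self, hcc):
        """Persistent state, utility 0.987, 3.5%/yr, 480 cycles -> the
        closed-form discounted sum (~21.4 QALYs)."""
        trace, utilities, costs, spec = _persistent_state_setup(
            0.987, 480, 0.035, hcc
        )
        out = accumulate_outcomes(trace, utilities, costs, spec)
        expected = closed_form_qaly(0.987, 0.035, 480)
        assert out.total_qaly == pytest.approx(expected, rel=1e-12)
        # frozen value of the geometric-series oracle at these settings
        assert expected == pytest.approx(21.47495, abs=1e-4)

    def test_events_zeroed_matches_closed_form(self, base_config):
        """With all event probabilities zeroed the cohort never leaves the
        INR bands, so the arm total equals the closed form exactly."""
        events = base_config.events
        zeroed = events.model_copy(
            update={
                name: pv(0.0)
                for name in type(events).model_fields
                if not name.startswith("rr_")
            }
        )
        cfg = base_config.model_copy(update={"events": zeroed})
        out = evaluate_arm(cfg, "intervention")
        assert out.total_qaly == pytest.approx(
            closed_form_qaly(0.987, 0.035, 480), rel=1e-12
        )
        assert out.total_cost == 0.0

    def test_horizon_mismatch_raises(self, base_config):
        trace, utilities, costs, spec = _persistent_state_setup(1.0, 12, 0.0, False)
        bad_spec = spec.model_copy(update={"horizon_cycles": 24})
        with pytest.raises(ValueError, match="horizon"):
            accumulate_outcomes(trace, utilities, costs, bad_spec)

    def test_per_entry_costs_below_per_cycle(self, base_config):
        """Charging on entry only omits repeat-cycle charges, so it cannot
        exceed per-cycle charging (stay probabilities are positive)."""
        per_cycle = evaluate_arm(base_config, "control")
        per_entry = evaluate_arm(base_config, "control", cost_timing="per_entry")
        assert per_entry.total_cost < per_cycle.total_cost
        assert per_entry.total_qaly == per_cycle.total_qaly


class TestOutcomeProperties:
    @pytest.mark.parametrize("which", ["intervention", "control"])
    def test_discounted_le_undiscounted(self, base_outcomes, which):
        out = base_outcomes[which]
        assert out.total_cost <= out.undiscounted_cost
        assert out.total_qaly <= out.undiscounted_qaly
        assert out.total_qaly <= 480 / 12

    @pytest.mark.parametrize(
        "name",
        [
            "events.p_above_to_bleeding",
            "events.p_below_to_te",
            "events.bleeding_to_death",
            "events.te_to_death",
            "events.recovery_to_death",
        ],
    )
    def test_raising_event_risk_never_raises_qalys(self, base_config, name, base_outcomes):
        cat = dict(parameter_catalog(base_config))
        bumped = set_parameter(base_config, name, cat[name].high)
        out = evaluate_arm(bumped, "control")
        assert out.total_qaly <= base_outcomes["control"].total_qaly + 1e-12

    @pytest.mark.parametrize("name", ["discount_rate_cost", "discount_rate_qaly"])
    def test_raising_discount_never_raises_totals(self, base_config, name, base_outcomes):
        bumped = set_parameter(base_config, name, 0.06)
        out = evaluate_arm(bumped, "control")
        base = base_outcomes["control"]
        assert out.total_cost <= base.total_cost + 1e-9
        assert out.total_qaly <= base.total_qaly + 1e-12

    def test_trace_export_csv(self, tmp_path, base_outcomes):
        path = tmp_path / "trace.csv"
        base_outcomes["intervention"].trace.to_csv(path)
        header = path.read_text().splitlines()[0].split(",")
        assert header == ["cycle"] + [s.value for s in STATE_ORDER]
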