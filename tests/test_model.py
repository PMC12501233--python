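"""Unit and property tests for the rate laws and ODE right-hand side."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitodyn import (
    DegenerateInputError,
    DynamicsConstants,
    ScenarioParams,
    StructuralParams,
    SystemState,
    atp_production_factor,
    biogenesis_rate,
    fission_rate,
    fusion_rate,
    state_derivative,
)

finite_pos = st.floats(0.01, 50.0, allow_nan=False)
finite_nonneg = st.floats(0.0, 50.0, allow_nan=False)


def scenario_with(constants=None, opa1=0.5, drp1=0.5, structural=None, **struct_kw):
    return ScenarioParams(
        cell_line="A4",
        condition="plus_serum",
        structural=structural or StructuralParams(**{**dict(c_w=0.5, c_n=0.5, c_jw=0.5, m_p=0.5), **struct_kw}),
        opa1=opa1,
        drp1=drp1,
        constants=constants or DynamicsConstants(),
    )


class TestAtpProductionFactor:
    @pytest.mark.parametrize(
        "c_n,m_p,c_w,c_jw,expected",
        [
            (0, 0, 1, 0, 1.0),
            (1, 0, 1, 1, 1.0),
            # OVCAR3 +S ultrastructure row
            (0.28, 0.99, 1, 0.62, (0.28 + math.exp(0.99)) / 1.62),
        ],
    )
    def test_printed_formula(self, c_n, m_p, c_w, c_jw, expected):
        theta = atp_production_factor(StructuralParams(c_w=c_w, c_n=c_n, c_jw=c_jw, m_p=m_p))
        assert theta == pytest.approx(expected, rel=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            StructuralParams(c_w=0, c_n=1, c_jw=0, m_p=1)

    def test_degenerate_error_names_input(self):
        bad = StructuralParams.__new__(StructuralParams)  # bypass validation
        object.__setattr__(bad, "c_w", 0.0)
        object.__setattr__(bad, "c_n", 1.0)
        object.__setattr__(bad, "c_jw", 0.0)
        object.__setattr__(bad, "m_p", 1.0)
        with pytest.raises(DegenerateInputError, match="c_w"):
            atp_production_factor(bad)

    @given(
        c_n=finite_nonneg, m_p=st.floats(0, 5), c_w=finite_pos, c_jw=finite_nonneg,
        bump=st.floats(1e-3, 10),
    )
    def test_monotone_in_all_four_arguments(self, c_n, m_p, c_w, c_jw, bump):
        base = atp_production_factor(StructuralParams(c_w, c_n, c_jw, m_p))
        up = StructuralParams(c_w, c_n + bump, c_jw, m_p)
        assert atp_production_factor(up) > base
        up = StructuralParams(c_w, c_n, c_jw, m_p + bump)
        assert atp_production_factor(up) > base
        down = StructuralParams(c_w + bump, c_n, c_jw, m_p)
        assert atp_production_factor(down) < base
        down = StructuralParams(c_w, c_n, c_jw + bump, m_p)
        assert atp_production_factor(down) < base


class TestFusionFissionRates:
    @pytest.mark.parametrize("F_0,opa1,expected", [(1, 0.5, 0.5), (0, 1, 0.0), (2, 0.93, 1.86)])
    def test_fusion(self, F_0, opa1, expected):
        assert fusion_rate(F_0, opa1) == pytest.approx(expected)

    @pytest.mark.parametrize("K_0,drp1,expected", [(1, 0.31, 0.31), (0, 1, 0.0), (1, 1, 1.0)])
    def test_fission(self, K_0, drp1, expected):
        assert fission_rate(K_0, drp1) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fusion_rate(-1, 0.5)
        with pytest.raises(ValueError):
            fission_rate(1, -0.5)


class TestBiogenesis:
    def test_equal_populations_equal_mitophagy(self):
        state = SystemState(1, 1, 1, 1, 0)
        c = DynamicsConstants(M_H=0.3, M_D=0.3)
        assert biogenesis_rate(state, c) == pytest.approx(0.3 / 2)

    def test_no_unfused_no_flux(self):
        state = SystemState(0, 0, 3, 2, 1)
        assert biogenesis_rate(state, DynamicsConstants()) == 0.0

    def test_weighted_average(self):
        state = SystemState(2, 1, 1, 0, 0)
        c = DynamicsConstants(M_H=0.1, M_D=0.5)
        assert biogenesis_rate(state, c) == pytest.approx(0.7 / 4)

    def test_constant_mode(self):
        state = SystemState(1, 1, 1, 1, 0)
        c = DynamicsConstants(biogenesis_mode="constant", B_const=0.42)
        assert biogenesis_rate(state, c) == 0.42


class TestStateDerivative:
    def test_empty_system_only_atp_drain(self):
        d = state_derivative(SystemState(0, 0, 0, 0, 0), scenario_with())
        assert np.allclose(d[:4], 0)
        assert d[4] == pytest.approx(-3.0)

    def test_reference_initial_conditions_symbolic(self):
        # at the reference ICs every [ATP]-scaled term vanishes
        sc = scenario_with()
        c = sc.constants
        theta = atp_production_factor(sc.structural)
        d = state_derivative(SystemState.initial(), sc)
        B = (c.M_H + c.M_D) / 4
        assert d[0] == pytest.approx(B - c.M_H)
        assert d[1] == pytest.approx(B - c.M_D)
        assert d[2] == pytest.approx(B)
        assert d[3] == pytest.approx(B)
        assert d[4] == pytest.approx(theta * (c.epsilon + 1) * (c.alpha + 1) - c.mu)

    def test_healthy_deviant_symmetry(self):
        sc = scenario_with(constants=DynamicsConstants(M_H=0.2, M_D=0.2, alpha=1.0))
        d = state_derivative(SystemState(0.7, 0.7, 1.3, 1.3, 2.0), sc)
        assert d[0] == pytest.approx(d[1])
        assert d[2] == pytest.approx(d[3])

    @given(
        pops=st.tuples(*([st.floats(0, 10)] * 4)),
        atp=st.floats(0, 100),
        stress=st.floats(0, 3),
    )
    def test_balance_mode_conserves_total(self, pops, atp, stress):
        sc = scenario_with(constants=DynamicsConstants(stress=stress))
        d = state_derivative(SystemState(*pops, atp), sc)
        assert abs(float(d[:4].sum())) < 1e-9 * max(1.0, sum(pops))

    @given(
        pops=st.tuples(*([st.floats(0, 10)] * 4)),
        atp=st.floats(0, 100),
    )
    def test_population_flux_identity(self, pops, atp):
        # d(total)/dt == B*total - M_H*n_hu - M_D*n_du in any mode
        c = DynamicsConstants(biogenesis_mode="constant", B_const=0.2)
        sc = scenario_with(constants=c)
        state = SystemState(*pops, atp)
        d = state_derivative(state, sc)
        expected = c.B_const * state.total - c.M_H * state.n_hu - c.M_D * state.n_du
        assert float(d[:4].sum()) == pytest.approx(expected, abs=1e-9)

    def test_fusion_fission_one_to_one_conversion(self):
        # removing mitophagy and biogenesis, HU loss equals HF gain exactly
        c = DynamicsConstants(M_H=0, M_D=0, stress=0.7)
        sc = scenario_with(constants=c)
        d = state_derivative(SystemState(2, 0, 1, 0, 3.0), sc)
        assert d[0] == pytest.approx(-d[2])

    def test_zero_stress_matches_unit_exponentials(self):
        sc0 = scenario_with(constants=DynamicsConstants(stress=0.0))
        d0 = state_derivative(SystemState(1, 2, 3, 4, 5), sc0)
        # hand evaluation with e^0 = 1
        theta = atp_production_factor(sc0.structural)
        F = 0.5 * 1.0
        K = 0.5 * 1.0
        B = (0.1 * 1 + 0.5 * 2) / 10
        assert d0[0] == pytest.approx((B - 0.1 - F * 5) * 1 + K * 5 * 3)
        assert d0[4] == pytest.approx(
            theta * (2 * (2 * 3 + 4) + (2 * 1 + 2)) - 3 - K * 5 * 7 - F * 5 * 2 - F * 5 * 1
        )


class TestValidation:
    def test_state_rejects_negative(self):
        with pytest.raises(ValueError):
            SystemState(-0.1, 1, 1, 1, 0)

    def test_efficiency_factors_at_least_one(self):
        with pytest.raises(ValueError):
            DynamicsConstants(alpha=0.5)
        with pytest.raises(ValueError):
            DynamicsConstants(epsilon=0.99)

    def test_scenario_requires_known_condition(self):
        with pytest.raises(ValueError):
            ScenarioParams(
                cell_line="A4", condition="starved",
                structural=StructuralParams(0.5, 0.5, 0.5, 0.5), opa1=1, drp1=1,
            )
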