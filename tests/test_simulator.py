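"""Integrator and preset-loader tests, including the independent Euler
oracle cross-check and step-size convergence."""

import numpy as np
import pytest

from mitodyn import (
    DivergenceError,
    DynamicsConstants,
    ScenarioParams,
    SchemaError,
    SolverSettings,
    StructuralParams,
    SystemState,
    integrate,
    load_presets,
    run_panel,
)
from mitodyn.model import PLUS_SERUM, SERUM_STARVED

from conftest import rel_error
from oracles import euler_oracle


def linear_limit_scenario():
    """Decoupled limit: no fusion/fission/mitophagy, theta = 1, alpha=eps=1,
    so populations stay put and ATP(t) = (1*(1+1)*2 - 3)*t = t exactly."""
    return ScenarioParams(
        cell_line="A4",
        condition="plus_serum",
        structural=StructuralParams(c_w=1, c_n=0, c_jw=0, m_p=0),  # theta = 1
        opa1=1.0,
        drp1=1.0,
        constants=DynamicsConstants(F_0=0, K_0=0, M_H=0, M_D=0, alpha=1, epsilon=1, mu=3),
    )


class TestIntegrate:
    @pytest.mark.parametrize("method", ["adaptive_rk", "fixed_rk4", "fixed_euler"])
    def test_linear_closed_form(self, method):
        traj = integrate(
            linear_limit_scenario(),
            settings=SolverSettings(t_end=10, method=method, dt=1e-3),
        )
        assert np.allclose(traj.states[:, :4], 1.0, atol=1e-9)
        assert np.allclose(traj.states[:, 4], traj.times, atol=1e-6)

    def test_zero_span_returns_initial(self, presets):
        sc = presets[("A4", PLUS_SERUM)]
        traj = integrate(sc, settings=SolverSettings(t_start=2.0, t_end=2.0))
        assert len(traj.times) == 1
        assert traj.final_state == SystemState.initial()

    def test_matches_independent_euler_oracle(self, presets):
        sc = presets[("OVMZ6", SERUM_STARVED)]
        traj = integrate(sc, settings=SolverSettings(t_end=5.0, n_out=101))
        t_o, y_o = euler_oracle(sc, t_end=5.0, dt=1e-4, n_save=101)
        assert np.allclose(traj.times, t_o, atol=1e-12)
        assert rel_error(traj.states, np.array(y_o)) < 2e-4

    def test_balance_mode_conserves_total(self, panel):
        for traj in panel.values():
            assert np.max(np.abs(traj.totals - 4.0)) / 4.0 < 1e-6

    def test_adaptive_and_rk4_agree(self, presets):
        sc = presets[("CAOV3", SERUM_STARVED)]
        a = integrate(sc, settings=SolverSettings(t_end=5.0, n_out=51))
        b = integrate(sc, settings=SolverSettings(t_end=5.0, n_out=51, method="fixed_rk4", dt=1e-3))
        assert rel_error(a.states, b.states) < 1e-7

    def test_euler_error_shrinks_linearly(self):
        # smooth scenario; global Euler error ~ O(dt)
        sc = linear_limit_scenario().with_constants(F_0=0.3, K_0=0.3, M_H=0.05, M_D=0.1)
        ref = integrate(sc, settings=SolverSettings(t_end=3.0, n_out=31))
        errs = []
        for dt in (4e-3, 2e-3, 1e-3):
            e = integrate(sc, settings=SolverSettings(t_end=3.0, n_out=31, method="fixed_euler", dt=dt))
            errs.append(rel_error(e.states, ref.states))
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.25)
        assert errs[1] / errs[2] == pytest.approx(2.0, rel=0.25)

    def test_divergence_error_in_constant_mode(self, presets):
        # constant biogenesis permits unbounded growth; cap must trip
        sc = presets[("OVMZ6", SERUM_STARVED)].with_constants(
            biogenesis_mode="constant", B_const=10.0
        )
        with pytest.raises(DivergenceError) as exc:
            integrate(sc, settings=SolverSettings(t_end=50.0, blowup_cap=1e6))
        assert 0.0 <= exc.value.last_valid_time <= 50.0

    def test_negativity_policy_error_mode(self, presets):
        # with clip_warn (default) marginal excursions are tolerated; the
        # trajectory must be nonnegative after policy application
        for traj in run_panel(
            {k: presets[k] for k in [("OVCAR3", SERUM_STARVED)]},
            SolverSettings(t_end=10.0),
        ).values():
            assert (traj.states >= 0).all()


class TestLoadPresets:
    def test_packaged_values_verbatim(self, presets):
        a4 = presets[("A4", PLUS_SERUM)]
        assert (a4.structural.c_w, a4.structural.c_n, a4.structural.c_jw, a4.structural.m_p) == (
            0.44, 0.54, 0.63, 0.54,
        )
        assert (a4.opa1, a4.drp1) == (0.44, 1.0)
        ovmz6 = presets[("OVMZ6", SERUM_STARVED)]
        assert (ovmz6.opa1, ovmz6.drp1) == (1.0, 0.16)

    def test_stress_defaults_by_condition(self, presets):
        assert presets[("A4", PLUS_SERUM)].constants.stress == 0.0
        assert presets[("A4", SERUM_STARVED)].constants.stress == 2.5

    def test_missing_cell_rejected_without_fill(self):
        with pytest.raises(SchemaError, match="OVCAR3 SS"):
            load_presets()

    def test_fill_rule_reuses_plus_serum_value(self, presets):
        assert presets[("OVCAR3", SERUM_STARVED)].structural.m_p == pytest.approx(0.99)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(SchemaError):
            load_presets(p)

    def test_schema_mismatch_lists_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("cell_line,condition,c_w\nA4,+S,0.4\n")
        with pytest.raises(SchemaError, match="missing columns"):
            load_presets(p)

    def test_non_numeric_cell_listed(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "cell_line,condition,c_w,c_n,c_jw,m_p,opa1,drp1\n"
            "A4,+S,0.44,xx,0.63,0.54,0.44,1\n"
        )
        with pytest.raises(SchemaError, match="A4"):
            load_presets(p)

    def test_unknown_condition_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "cell_line,condition,c_w,c_n,c_jw,m_p,opa1,drp1\n"
            "A4,serumfree,0.44,0.54,0.63,0.54,0.44,1\n"
        )
        with pytest.raises(SchemaError, match="condition"):
            load_presets(p)


class TestRunPanel:
    def test_full_panel_has_ten_trajectories(self, panel):
        assert len(panel) == 10

    def test_subset_of_one(self, presets):
        key = ("CAOV3", PLUS_SERUM)
        out = run_panel({key: presets[key]}, SolverSettings(t_end=1.0))
        assert set(out) == {key}

    def test_missing_required_scenario_named(self, presets):
        with pytest.raises(KeyError, match="NOSUCH"):
            run_panel(presets, require=[("NOSUCH", PLUS_SERUM)])

    def test_determinism(self, presets):
        s = SolverSettings(t_end=3.0)
        one = run_panel(presets, s)
        two = run_panel(presets, s)
        for k in one:
            assert np.array_equal(one[k].states, two[k].states)
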