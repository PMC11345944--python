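"""Apparatus twin: flow program, release kinetics, dissolution ODE, fitting."""

from __future__ import annotations

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given
from hypothesis import strategies as st

from gastropk import physiocell, synthdata
from gastropk.physiocell import (
    DissolutionScenario,
    FlowProgram,
    ReleaseDissolutionParams,
    default_scenarios,
    fit_release,
    fit_z,
    flow_rate,
    nw_rate,
    release_fraction,
    simulate_invitro,
)


class TestFlowProgram:
    def test_breakpoints_and_linear_ramp(self):
        prog = FlowProgram()
        assert flow_rate(0.0, prog) == pytest.approx(50.0)
        assert flow_rate(14.0, prog) == pytest.approx(8.0)
        assert flow_rate(7.0, prog) == pytest.approx(29.0)  # midpoint of the ramp
        assert flow_rate(60.0, prog) == pytest.approx(8.0)  # held flat beyond the end

    def test_get_refill_pulse_window(self):
        scen = default_scenarios()[2]
        prog = scen.with_get_pulse()
        assert flow_rate(scen.get_min + 0.1, prog) == pytest.approx(110.0)
        # 18 s = 0.3 min window
        assert flow_rate(scen.get_min + 0.31, prog) == pytest.approx(8.0)

    def test_invalid_programs_rejected(self):
        with pytest.raises(ValueError):
            FlowProgram(breakpoints=((0.0, 50.0), (0.0, 8.0)))
        with pytest.raises(ValueError):
            FlowProgram(breakpoints=((0.0, -1.0),))


class TestReleaseKinetics:
    def test_zero_before_lag_and_limits(self):
        p = ReleaseDissolutionParams(kind="weibull", t_lag=10.0, phases=((30.0, 1.2, 1.0),))
        assert release_fraction(10.0, p) == 0.0
        assert release_fraction(10.0 + 30.0, p) == pytest.approx(1 - np.exp(-1.0))
        assert release_fraction(1e4, p) == pytest.approx(1.0)

    @given(
        tau=st.floats(1.0, 120.0),
        b=st.floats(0.5, 4.0),
        tlag=st.floats(0.0, 20.0),
    )
    def test_monotone_nondecreasing_in_time(self, tau, b, tlag):
        p = ReleaseDissolutionParams(kind="weibull", t_lag=tlag, phases=((tau, b, 1.0),))
        t = np.linspace(0.0, 240.0, 200)
        f = release_fraction(t, p)
        assert np.all(np.diff(f) >= -1e-12)
        assert np.all((0.0 <= f) & (f <= 1.0))

    def test_double_weibull_mixture_weights(self):
        p = ReleaseDissolutionParams(
            kind="double_weibull", t_lag=0.0, phases=((10.0, 1.0, 0.25), (100.0, 1.0, 0.0))
        )
        # at t >> tau1 but t << tau2 the first phase saturates: F ~ w + (1-w)*F2
        f = release_fraction(40.0, p)
        expected = 0.25 * (1 - np.exp(-4.0)) + 0.75 * (1 - np.exp(-0.4))
        assert f == pytest.approx(expected)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ReleaseDissolutionParams(kind="weibull", t_lag=0.0, phases=((0.0, 1.0, 1.0),))
        with pytest.raises(ValueError):
            ReleaseDissolutionParams(kind="other", t_lag=0.0, phases=((1.0, 1.0, 1.0),))
        with pytest.raises(ValueError):
            ReleaseDissolutionParams(kind="double_weibull", t_lag=0.0, phases=((1.0, 1.0, 1.0),))


class TestNoyesWhitney:
    def test_saturation_clips_to_zero(self):
        p = ReleaseDissolutionParams(kind="weibull", t_lag=0.0, phases=((1.0, 1.0, 1.0),))
        assert nw_rate(50.0, 27.0 * 34.0, 34.0, p) == 0.0  # at solubility
        assert nw_rate(0.0, 0.0, 34.0, p) == 0.0  # no solid left
        with pytest.raises(ValueError):
            nw_rate(1.0, 0.0, 0.0, p)

    def test_rate_scales_linearly_with_z(self):
        p1 = ReleaseDissolutionParams(kind="weibull", t_lag=0.0, phases=((1.0, 1.0, 1.0),), z=1.08)
        p2 = replace(p1, z=2.16)
        assert nw_rate(10.0, 0.0, 34.0, p2) == pytest.approx(2 * nw_rate(10.0, 0.0, 34.0, p1))


class TestSimulateInvitro:
    @pytest.mark.parametrize("group", [1, 2, 3, 4, 5, 6])
    def test_mass_conserved_and_monotone_all_programs(self, group):
        scen = default_scenarios()[group]
        p = synthdata.default_release_params()[group]
        prof = simulate_invitro(scen, p)
        # 2-min grid over GET + 30 min (last sample is the final grid point)
        assert prof.times[0] == 0.0
        assert scen.total_minutes - prof.times[-1] < scen.sampling_interval
        assert np.all(np.diff(prof.times) == pytest.approx(2.0))
        # dissolved never exceeds the dose (to integrator tolerance) and is
        # complete by the end
        assert np.all(prof.dissolved <= p.x0 * (1 + 1e-6))
        assert np.all(np.diff(prof.dissolved) >= -1e-6 * p.x0)
        assert prof.dissolved[-1] == pytest.approx(p.x0, rel=1e-3)

    def test_get_flush_frees_encapsulated_drug(self):
        # slow spontaneous opening: a clear dissolution burst follows GET
        scen = default_scenarios()[1]
        p = synthdata.default_release_params()[1]
        prof = simulate_invitro(scen, p)
        pre = np.interp(scen.get_min, prof.times, prof.dissolved)
        post = np.interp(scen.get_min + 10.0, prof.times, prof.dissolved)
        assert post - pre > 10.0  # mg dissolved within 10 min of the flush
        assert pre < p.x0 * 0.9

    def test_instant_release_dissolves_fast(self):
        scen = default_scenarios()[4]
        fast = ReleaseDissolutionParams(kind="weibull", t_lag=0.0, phases=((0.5, 1.0, 1.0),))
        prof = simulate_invitro(scen, fast)
        # z = 1.08 mL/mg/h on 100 mg in sink conditions: half dissolved < 10 min
        assert np.interp(10.0, prof.times, prof.dissolved) > 50.0


class TestFitting:
    def test_fit_release_recovers_group2_parameters(self):
        scen = default_scenarios()[2]
        truth = synthdata.default_release_params()[2]
        clean = simulate_invitro(scen, truth)
        fitted = fit_release(clean, scen, kind="weibull", p_ref=truth)
        tau_t, b_t, _ = truth.phases[0]
        tau_f, b_f, _ = fitted.phases[0]
        assert tau_f == pytest.approx(tau_t, rel=0.10)
        assert b_f == pytest.approx(b_t, rel=0.10)
        assert fitted.t_lag == pytest.approx(truth.t_lag, abs=2.0)  # one grid step

    def test_fit_release_noisy_median_bias_small(self):
        scen = default_scenarios()[2]
        truth = synthdata.default_release_params()[2]
        clean = simulate_invitro(scen, truth)
        rng = np.random.default_rng(42)
        taus, bs = [], []
        for _ in range(11):
            noisy = replace(
                clean,
                dissolved=np.clip(
                    clean.dissolved + rng.standard_normal(clean.dissolved.shape) * 2.0,
                    0.0,
                    truth.x0,
                ),
            )
            f = fit_release(noisy, scen, kind="weibull", p_ref=truth)
            taus.append(f.phases[0][0])
            bs.append(f.phases[0][1])
        assert np.median(taus) == pytest.approx(truth.phases[0][0], rel=0.25)
        assert np.median(bs) == pytest.approx(truth.phases[0][1], rel=0.25)

    def test_fit_z_recovers_and_scales(self):
        scen = default_scenarios()[1]
        truth = synthdata.default_release_params()[1]
        z_hat = fit_z(simulate_invitro(scen, truth), scen, p_ref=truth)
        assert z_hat == pytest.approx(truth.z, rel=0.15)
        doubled = replace(truth, z=2 * truth.z)
        z2 = fit_z(simulate_invitro(scen, doubled), scen, p_ref=truth)
        assert z2 == pytest.approx(2 * z_hat, rel=0.15)

    def test_fit_release_needs_pre_get_points(self):
        scen = default_scenarios()[1]
        short = physiocell.InVitroProfile(
            times=np.array([0.0, 20.0, 40.0]), dissolved=np.array([0.0, 10.0, 30.0])
        )
        with pytest.raises(ValueError):
            fit_release(short, scen)


class TestScenarios:
    def test_table_defaults(self):
        scen = default_scenarios()
        assert [s.get_min for s in scen.values()] == [15.0, 30.0, 30.0, 30.0, 60.0, 90.0]
        assert [len(s.stress_events) for s in scen.values()] == [0, 2, 1, 0, 0, 0]
        assert {e.pressure for e in scen[2].stress_events} == {300.0}
        assert scen[3].stress_events[0].time == 5.0
        assert scen[3].stress_events[0].pressure == 200.0
        assert all(s.v_cell == 34.0 and s.v_reservoir == 466.0 for s in scen.values())

    def test_volume_invariant(self):
        with pytest.raises(ValueError):
            DissolutionScenario(group=1, get_min=15.0, v_cell=40.0, v_reservoir=466.0)
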