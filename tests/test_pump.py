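"""Pump mechanics, hydraulics and hydraulic-parameter identification."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from lvadhemo.errors import (
    IdentifiabilityError,
    InvalidStepError,
    NoOperatingPointError,
    StateError,
)
from lvadhemo.pump import (
    BenchDataset,
    HydraulicParams,
    MechParams,
    hydraulic_rhs,
    hydraulic_step,
    identify_hydraulic,
    mech_init,
    mech_step,
    static_head,
    steady_flow,
)
from lvadhemo.synth import generate_bench_data

DT = 0.0004


class TestMechanical:
    def test_unity_dc_gain_from_matched_state(self, mech):
        state = mech_init(8000.0, DT, mech)
        for _ in range(500):
            state = mech_step(state, 8000.0, DT, mech)
            assert state.n == pytest.approx(8000.0, abs=1e-9)

    def test_dead_time_delays_step_response(self, mech):
        state = mech_init(7000.0, DT, mech)
        n_delay = int(round(mech.dead_time / DT))
        for i in range(n_delay):
            state = mech_step(state, 8000.0, DT, mech)
            # reference change must not propagate before the dead time
            assert state.n == pytest.approx(7000.0, abs=1e-12), f"leak at step {i}"
        moved = False
        for _ in range(50):
            state = mech_step(state, 8000.0, DT, mech)
            moved = moved or state.n > 7000.0 + 1e-9
        assert moved

    def test_overdamped_step_response_monotone_and_settles(self, mech):
        # damping ratio of the printed coefficients is ~1.18: no overshoot
        assert mech.damping_ratio > 1
        state = mech_init(7000.0, DT, mech)
        trace = []
        for _ in range(int(0.3 / DT)):  # ~90 slow time constants
            state = mech_step(state, 8000.0, DT, mech)
            trace.append(state.n)
        trace = np.array(trace)
        assert np.all(np.diff(trace) >= -1e-9)
        assert np.max(trace) <= 8000.0 + 1e-9
        assert trace[-1] == pytest.approx(8000.0, abs=1e-6)

    def test_zoh_recurrence_matches_fine_ode_solution(self, mech):
        """Discrete step response agrees with a high-accuracy ODE solve."""

        def rhs(t, x):
            u = 8000.0 if t >= mech.dead_time else 7000.0
            return [x[1], (u - x[0] - mech.k1 * x[1]) / mech.k2]

        t_eval = np.arange(1, 26) * DT
        sol = solve_ivp(rhs, (0, t_eval[-1]), [7000.0, 0.0], t_eval=t_eval,
                        rtol=1e-11, atol=1e-9)
        state = mech_init(7000.0, DT, mech)
        ours = []
        for _ in t_eval:
            state = mech_step(state, 8000.0, DT, mech)
            ours.append(state.n)
        np.testing.assert_allclose(ours, sol.y[0], rtol=2e-5, atol=1e-3)

    def test_invalid_step_and_uninitialized_buffer_raise(self, mech):
        state = mech_init(7000.0, DT, mech)
        with pytest.raises(InvalidStepError):
            mech_step(state, 7000.0, -DT, mech)
        with pytest.raises(StateError):
            mech_step(state, 7000.0, DT / 4, mech)  # buffer sized for DT


class TestHydraulic:
    def test_static_head_hand_value(self, hyd):
        # -7.71*5 + 1.86e-6*8000^2 - 5.49e-13*25*8000^3 = 73.4628 mmHg
        assert static_head(5.0, 8000.0, hyd) == pytest.approx(73.4628, abs=1e-4)

    def test_fixed_point_has_zero_flow_derivative(self, hyd):
        dP = static_head(5.0, 8000.0, hyd)
        assert hydraulic_rhs(5.0, 8000.0, dP, hyd) == pytest.approx(0.0, abs=1e-12)

    def test_explicit_euler_tracks_reference_integration(self, hyd):
        """10 s at constant conditions: dt=0.0004 within 0.1% of solve_ivp."""
        n, dP, Q0 = 8000.0, 60.0, 1.0
        state_q = Q0
        for _ in range(int(10.0 / DT)):
            state_q = state_q + DT * hydraulic_rhs(state_q, n, dP, hyd)
        sol = solve_ivp(lambda t, q: [hydraulic_rhs(q[0], n, dP, hyd)], (0, 10.0),
                        [Q0], rtol=1e-10, atol=1e-12)
        assert state_q == pytest.approx(sol.y[0, -1], rel=1e-3)

    def test_hydraulic_step_rejects_bad_inputs(self, hyd):
        from lvadhemo.pump import mech_init

        state = mech_init(8000.0, DT)
        state.Q = 5.0
        with pytest.raises(InvalidStepError):
            hydraulic_step(state, 8000.0, 60.0, 0.0, hyd)
        with pytest.raises(FloatingPointError):
            hydraulic_step(state, np.nan, 60.0, DT, hyd)


class TestSteadyFlow:
    def test_inverts_static_head(self, hyd):
        assert steady_flow(8000.0, 73.4628, hyd) == pytest.approx(5.0, abs=1e-3)

    def test_zero_flow_gives_shutoff_head(self, hyd):
        assert steady_flow(8000.0, hyd.b * 8000.0**2, hyd) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_linear_limit_when_c_is_zero(self, hyd):
        p0 = HydraulicParams(L=hyd.L, a=hyd.a, b=hyd.b, c=0.0, x=2, y=3)
        dP = 70.0
        assert steady_flow(8000.0, dP, p0) == pytest.approx(
            (dP - p0.b * 8000.0**2) / p0.a
        )

    def test_root_continuous_in_c(self, hyd):
        # as c -> 0 the selected root approaches the linear a-only solution
        dP = 70.0
        p_small = HydraulicParams(L=hyd.L, a=hyd.a, b=hyd.b, c=hyd.c * 1e-9,
                                  x=2, y=3)
        q_lin = (dP - hyd.b * 8000.0**2) / hyd.a
        assert steady_flow(8000.0, dP, p_small) == pytest.approx(q_lin, rel=1e-6)

    def test_no_real_root_raises(self, hyd):
        # strong negative c and dP above shutoff head: negative discriminant
        p_bad = HydraulicParams(L=hyd.L, a=hyd.a, b=hyd.b, c=-1e-9, x=2, y=3)
        with pytest.raises(NoOperatingPointError):
            steady_flow(9000.0, p_bad.b * 9000.0**2 + 1.0, p_bad)


class TestIdentification:
    def test_exact_recovery_and_exponent_selection(self, hyd):
        """Noise-free self-generated data is an exact-recovery oracle."""
        data = generate_bench_data(hyd)
        rep = identify_hydraulic(data)
        assert (rep.params.x, rep.params.y) == (hyd.x, hyd.y)
        for name in ("L", "a", "b", "c"):
            assert getattr(rep.params, name) == pytest.approx(
                getattr(hyd, name), rel=5e-7
            ), name

    @pytest.mark.parametrize(
        "x,y", [(2, 3), (1, 1), (0, 1), (2, 0), (1, 2)]
    )
    def test_exact_recovery_across_exponent_grid(self, x, y):
        # scale c so the c-term contributes ~10 mmHg at mid-range
        c = -10.0 / (4.0**x * 7500.0**y)
        truth = HydraulicParams(L=0.74, a=-7.71, b=1.86e-6, c=c, x=x, y=y)
        data = generate_bench_data(truth, flows=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0),
                                   dwell_s=0.5, ramp_s=0.5, fs_hz=400.0)
        rep = identify_hydraulic(data)
        assert (rep.params.x, rep.params.y) == (x, y)
        for name in ("L", "a", "b", "c"):
            assert getattr(rep.params, name) == pytest.approx(
                getattr(truth, name), rel=5e-7
            ), name

    def test_noisy_data_recovers_steady_head_curve(self, hyd):
        """sigma = 1 mmHg head noise: recovered static curve within 2 mmHg RMSE."""
        speeds = np.repeat(np.linspace(6000, 9000, 7), 7)
        flows = np.tile(np.linspace(0.5, 6.5, 7), 7)
        data = generate_bench_data(hyd, noise_dp_mmhg=1.0, seed=7)
        rep = identify_hydraulic(data)
        truth = np.array([static_head(q, n, hyd) for q, n in zip(flows, speeds)])
        est = np.array([static_head(q, n, rep.params) for q, n in zip(flows, speeds)])
        assert np.sqrt(np.mean((est - truth) ** 2)) < 2.0

    def test_degenerate_design_raises(self):
        t = np.arange(100) * 0.01
        data = BenchDataset(t=t, n=np.full(100, 8000.0), Q=np.full(100, 4.0),
                            dP=np.full(100, 80.0))
        with pytest.raises(IdentifiabilityError):
            identify_hydraulic(data)
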