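"""Five-level density-matrix integrator and its closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import microsolv as m
from microsolv.exceptions import ConfigError, ParameterError, PreconditionError
from microsolv.kinetics import cascade_propagate


def excited_fraction(omega0, tau_irf_fs=381.0, **kw):
    pulse = m.ExcitationPulse(rabi_omega0=omega0, tau_irf_fs=tau_irf_fs)
    tr = m.integrate_bloch(m.LevelScheme(), pulse, -5.0, 5.0, **kw)
    return 1.0 - tr.populations[-1, 0]


class TestIntegrator:
    def test_no_coupling_keeps_all_population_in_ground_state(self):
        tr = m.integrate_bloch(m.LevelScheme(), m.ExcitationPulse(rabi_omega0=0.0))
        assert np.all(tr.populations[:, 0] == 1.0)
        assert np.all(tr.populations[:, 1:] == 0.0)
        assert np.all(tr.coherence == 0.0)

    def test_weak_field_excited_fraction_scales_quadratically_with_rabi(self):
        f1 = excited_fraction(0.05)
        f2 = excited_fraction(0.025)
        assert f1 / f2 == pytest.approx(4.0, rel=0.01)

    def test_population_conservation_on_default_parameters(self, default_trace):
        total = default_trace.populations.sum(axis=1)
        assert np.max(np.abs(total - 1.0)) <= 1e-8

    def test_populations_bounded_and_monotone_end_states(self, default_trace):
        pops = default_trace.populations
        assert np.all(pops >= -1e-8) and np.all(pops <= 1.0 + 1e-8)
        assert np.all(np.diff(pops[:, 0]) <= 1e-12)  # ground state only drains
        assert np.all(np.diff(pops[:, 4]) >= -1e-12)  # terminal state only fills

    def test_long_time_limit_funnels_excitation_into_terminal_state(self, truth):
        tr = m.integrate_bloch(truth.scheme, truth.pulse, -5.0, 1000.0)
        excited = 1.0 - tr.populations[-1, 0]
        assert tr.populations[-1, 4] == pytest.approx(excited, abs=1e-4)
        assert np.all(tr.populations[-1, 1:4] < 1e-4)

    def test_pulse_area_sets_excitation_in_weak_field_limit(self):
        # the area theorem holds when relaxation during the pulse is
        # negligible, so probe it with an effectively undecaying state 2
        def frac(omega0, tau_irf_fs):
            scheme = m.LevelScheme(1e9, 13.0, 96.0)
            pulse = m.ExcitationPulse(rabi_omega0=omega0, tau_irf_fs=tau_irf_fs)
            tr = m.integrate_bloch(scheme, pulse, -5.0, 5.0)
            return 1.0 - tr.populations[-1, 0]

        assert frac(0.2, 381.0) == pytest.approx(frac(0.4, 190.5), rel=0.01)

    def test_hybrid_and_full_ode_paths_agree(self, truth):
        tr_h = m.integrate_bloch(truth.scheme, truth.pulse, -5.0, 145.0, method="hybrid")
        tr_o = m.integrate_bloch(truth.scheme, truth.pulse, -5.0, 145.0, method="ode")
        assert np.max(np.abs(tr_h.populations - tr_o.populations)) <= 1e-6
        assert np.max(np.abs(tr_h.coherence - tr_o.coherence)) <= 1e-6

    def test_stored_coherence_pair_is_hermitian(self, default_trace):
        assert np.array_equal(
            default_trace.coherence_12, np.conj(default_trace.coherence)
        )

    def test_late_start_with_pulse_still_on_is_rejected(self):
        with pytest.raises(PreconditionError):
            m.integrate_bloch(m.LevelScheme(), m.ExcitationPulse(), -1.0, 5.0)

    def test_nonpositive_time_constants_are_rejected(self):
        with pytest.raises(ParameterError):
            m.LevelScheme(tau2_fs=-1.0)
        with pytest.raises(ParameterError):
            m.LevelScheme(tau3_ps=0.0)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        tau2=st.floats(100.0, 2000.0),
        tau3=st.floats(1.0, 50.0),
        tau4=st.floats(10.0, 300.0),
        omega0=st.floats(0.1, 5.0),
    )
    def test_conservation_holds_across_parameter_space(self, tau2, tau3, tau4, omega0):
        scheme = m.LevelScheme(tau2, tau3, tau4)
        pulse = m.ExcitationPulse(rabi_omega0=omega0)
        tr = m.integrate_bloch(scheme, pulse, -5.0, 30.0)
        assert np.max(np.abs(tr.populations.sum(axis=1) - 1.0)) <= 1e-8


class TestBatemanOracle:
    def test_zero_initial_population_stays_zero(self, truth):
        t = np.linspace(0.0, 100.0, 50)
        assert np.all(m.bateman_cascade(0.0, truth.scheme, t) == 0.0)

    def test_initial_condition_at_time_zero(self, truth):
        out = m.bateman_cascade(0.7, truth.scheme, [0.0])
        np.testing.assert_allclose(out[0], [0.7, 0.0, 0.0, 0.0], atol=1e-15)

    def test_blocked_downstream_rates_give_pure_exponential(self):
        # infinite downstream lifetimes freeze the chain after the first step
        scheme = m.LevelScheme(500.0, math.inf, math.inf)
        t = np.linspace(0.0, 5.0, 20)
        out = m.bateman_cascade(1.0, scheme, t)
        np.testing.assert_allclose(out[:, 0], np.exp(-2.0 * t), rtol=1e-12)
        assert np.all(out[:, 2:] == 0.0)

    def test_conserves_initial_excitation(self, truth):
        t = np.linspace(0.0, 400.0, 200)
        out = m.bateman_cascade(0.9, truth.scheme, t)
        np.testing.assert_allclose(out.sum(axis=1), 0.9, atol=1e-12)

    @pytest.mark.parametrize(
        "taus",
        [
            (500.0, 0.5, 13.0),  # rates of 2 and 3 equal
            (445.0, 2.0, 2.0),  # rates of 3 and 4 equal
            (500.0, 13.0, 0.5),  # outer pair equal
            (500.0, 0.5, 0.5),  # all three rates equal
            (445.0, 13.0, 96.0),  # distinct control
        ],
    )
    def test_closed_forms_match_direct_cascade_integration(self, taus):
        """Each limiting form (including coincident rates) must agree with
        a brute-force integration of the linear cascade ODEs."""
        from scipy.integrate import solve_ivp

        scheme = m.LevelScheme(*taus)
        g = (scheme.gamma22, scheme.gamma33, scheme.gamma44)

        def rhs(_, y):
            return [
                -g[0] * y[0],
                g[0] * y[0] - g[1] * y[1],
                g[1] * y[1] - g[2] * y[2],
                g[2] * y[2],
            ]

        t = np.linspace(0.0, 20.0, 100)
        sol = solve_ivp(
            rhs, (0.0, 20.0), [1.0, 0, 0, 0], t_eval=t, rtol=1e-11, atol=1e-12,
            method="LSODA",
        )
        closed = m.bateman_cascade(1.0, scheme, t)
        np.testing.assert_allclose(closed, sol.y.T, atol=1e-8)

    def test_all_equal_rates_limiting_form(self):
        scheme = m.LevelScheme(1000.0, 1.0, 1.0)  # all rates 1/ps
        t = np.array([0.5, 1.0, 3.0])
        out = m.bateman_cascade(1.0, scheme, t)
        np.testing.assert_allclose(out[:, 2], 0.5 * t**2 * np.exp(-t), rtol=1e-12)

    def test_post_pulse_bloch_dynamics_match_closed_form(self, truth):
        tr = m.integrate_bloch(truth.scheme, truth.pulse, -5.0, 120.0, method="ode")
        i0 = int(np.searchsorted(tr.t_ps, 4.0))  # pulse envelope < 1e-24 here
        dt = tr.t_ps[i0:] - tr.t_ps[i0]
        analytic = cascade_propagate(tr.populations[i0, 1:], truth.scheme, dt)
        assert np.max(np.abs(analytic - tr.populations[i0:, 1:])) <= 1e-6

    def test_negative_times_are_rejected(self, truth):
        with pytest.raises(PreconditionError):
            m.bateman_cascade(1.0, truth.scheme, [-1.0])


class TestRabiEstimator:
    def test_zero_dipole_gives_zero(self):
        pulse = m.ExcitationPulse(
            transition_dipole_mu12_epm=0.0, peak_intensity_w_cm2=2e9
        )
        assert m.estimate_rabi_frequency(pulse) == 0.0

    def test_scales_as_square_root_of_intensity(self):
        p1 = m.ExcitationPulse(
            transition_dipole_mu12_epm=15.0, peak_intensity_w_cm2=2e9
        )
        p2 = m.ExcitationPulse(
            transition_dipole_mu12_epm=15.0, peak_intensity_w_cm2=4e9
        )
        ratio = m.estimate_rabi_frequency(p2) / m.estimate_rabi_frequency(p1)
        assert ratio == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_typical_uv_pulse_parameters(self):
        # mu E0 / hbar with E0 = sqrt(2 I / eps0 c): 15 e pm at 2e9 W/cm^2
        pulse = m.ExcitationPulse(
            transition_dipole_mu12_epm=15.0, peak_intensity_w_cm2=2e9
        )
        assert m.estimate_rabi_frequency(pulse) == pytest.approx(2.796, abs=0.005)

    def test_missing_inputs_raise_configuration_error(self):
        with pytest.raises(ConfigError):
            m.estimate_rabi_frequency(m.ExcitationPulse())
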