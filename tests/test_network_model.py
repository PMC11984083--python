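import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kurastim._utils import TWO_PI, wrap_phase
from kurastim.network_model import (
    NetworkParams,
    PhaseState,
    StimProtocol,
    neg_sin,
    order_parameter,
    pulse_decisions,
    sample_natural_frequencies,
    simulate,
    step,
    wrapped_cauchy_phases,
)


def make_params(**kw):
    base = dict(omega0=TWO_PI * 30, gamma=TWO_PI, K=1.0, D=0.0, N=10)
    base.update(kw)
    return NetworkParams(**base)


class TestNetworkParams:
    @pytest.mark.parametrize(
        "field,value", [("gamma", -1.0), ("K", -0.1), ("D", -0.5), ("N", 0)]
    )
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            make_params(**{field: value})

    def test_non_periodic_z_rejected(self):
        with pytest.raises(ValueError, match="periodic"):
            make_params(Z=lambda th: th)

    def test_periodic_z_accepted(self):
        p = make_params(Z=lambda th: np.cos(th))
        assert not p.uses_default_z


class TestSampleFrequencies:
    def test_gamma_zero_degenerate(self):
        p = make_params(gamma=0.0, N=7)
        assert np.all(sample_natural_frequencies(p, seed=0) == p.omega0)

    def test_median_near_location(self):
        # Cauchy median equals the location parameter
        p = make_params(omega0=TWO_PI * 30, gamma=TWO_PI * 1, N=100_000)
        draw = sample_natural_frequencies(p, seed=42)
        assert abs(np.median(draw) - p.omega0) < TWO_PI * 0.05

    def test_half_iqr_near_gamma(self):
        # Cauchy interquartile range is exactly 2*gamma
        p = make_params(omega0=TWO_PI * 30, gamma=TWO_PI * 1, N=100_000)
        draw = sample_natural_frequencies(p, seed=42)
        q1, q3 = np.percentile(draw, [25, 75])
        assert abs(0.5 * (q3 - q1) - p.gamma) / p.gamma < 0.05

    def test_deterministic(self):
        p = make_params(N=100)
        a = sample_natural_frequencies(p, seed=7)
        b = sample_natural_frequencies(p, seed=7)
        assert np.array_equal(a, b)

    def test_quantile_method_deterministic_and_centred(self):
        p = make_params(N=1001)
        draw = sample_natural_frequencies(p, method="quantile")
        assert abs(np.median(draw) - p.omega0) < 1e-6


class TestOrderParameter:
    def test_identical_phases(self):
        op = order_parameter(np.array([0.7, 0.7, 0.7]))
        assert op.rho == pytest.approx(1.0)
        assert op.psi == pytest.approx(0.7)

    def test_antipodal_cancellation(self):
        op = order_parameter(np.array([0.0, np.pi]))
        assert op.rho == pytest.approx(0.0, abs=1e-12)
        assert op.psi == 0.0  # convention when rho ~ 0

    def test_two_vector_hand_value(self):
        op = order_parameter(np.array([0.0, np.pi / 2]))
        assert op.rho == pytest.approx(np.sqrt(2) / 2, abs=1e-12)
        assert op.psi == pytest.approx(np.pi / 4, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            order_parameter(np.array([]))

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=64))
    @settings(max_examples=100, deadline=None)
    def test_rho_in_unit_interval(self, thetas):
        op = order_parameter(np.array(thetas))
        assert 0.0 <= op.rho <= 1.0 + 1e-12


class TestStep:
    def test_single_oscillator_pure_drift(self):
        p = make_params(N=1, K=0.0, D=0.0)
        s0 = PhaseState(np.array([0.3]))
        s1 = step(s0, p, dt=0.01, omega=np.array([5.0]))
        assert s1.theta[0] == pytest.approx(0.3 + 5.0 * 0.01, abs=0)

    def test_two_oscillator_coupling_hand_value(self):
        # (K/N) sum sin(theta_j - theta_i) at theta=(0, pi/2), K=1:
        # osc 0 gets 0.5*sin(pi/2)=0.5, osc 1 gets 0.5*sin(-pi/2)=-0.5
        p = make_params(N=2, K=1.0, D=0.0)
        s0 = PhaseState(np.array([0.0, np.pi / 2]))
        s1 = step(s0, p, dt=0.1, omega=np.zeros(2))
        assert s1.theta == pytest.approx([0.05, np.pi / 2 - 0.05], abs=1e-12)

    def test_noise_variance_growth(self, rng):
        # Brownian increment variance is 2*D*dt per step
        p = make_params(N=10_000, K=0.0, D=1.0)
        s0 = PhaseState(np.zeros(10_000))
        dt = 1e-3
        s1 = step(s0, p, dt=dt, rng=rng, omega=np.zeros(10_000))
        var = np.var(s1.theta)
        assert var == pytest.approx(2.0 * p.D * dt, rel=0.06)

    def test_kick_applies_response_function(self):
        p = make_params(N=2, K=0.0, D=0.0)
        s0 = PhaseState(np.array([0.5, -0.5]))
        s1 = step(s0, p, dt=1e-9, omega=np.zeros(2), kick=True, pulse_magnitude=0.2)
        assert s1.theta == pytest.approx(
            [0.5 + 0.2 * neg_sin(0.5), -0.5 + 0.2 * neg_sin(-0.5)], abs=1e-8
        )


class TestController:
    def test_no_crossing_no_pulse(self):
        proto = StimProtocol(target_phase=2.0, pulse_magnitude=0.1,
                             block_layout=[(0.1, 1.0)])
        p = make_params()
        times = np.linspace(0, 1, 500)
        psi = np.full(500, 0.5)  # static, never crosses target 2.0
        fired = pulse_decisions(times, psi, proto, p)
        assert not fired.any()

    def test_uniform_rotation_one_pulse_per_cycle(self):
        p = make_params(omega0=TWO_PI * 30, gamma=0.0, K=0.0, N=5)
        proto = StimProtocol(target_phase=0.0, pulse_magnitude=0.0,
                             refractory_fraction=0.8, block_layout=[(0.5, 5.0)])
        traj = simulate(p, protocol=proto, duration=5.5, dt=5e-4, seed=0,
                        initial_theta=np.zeros(5))
        ipi = np.diff(traj.pulse_times)
        assert len(traj.pulse_times) == pytest.approx(5.0 * 30, abs=2)
        assert np.allclose(ipi, 1 / 30, atol=1e-3)

    def test_refractory_suppresses_second_crossing(self):
        # constructed mean phase crossing the target twice, 10 ms apart;
        # at omega0 = 2*pi*30 the refractory window is 0.8/30 s = 26.7 ms
        p = make_params(omega0=TWO_PI * 30)
        proto = StimProtocol(target_phase=0.0, pulse_magnitude=0.0,
                             refractory_fraction=0.8, block_layout=[(0.001, 10.0)])
        dt = 1e-3
        times = np.arange(0, 0.1, dt)
        psi = np.full(times.size, -0.2)
        psi[20:25] = 0.1   # first upward crossing at 20 ms
        psi[25:30] = -0.2
        psi[30:] = 0.1     # second crossing at 30 ms: only 10 ms later
        fired = pulse_decisions(times, psi, proto, p)
        assert fired.sum() == 1
        assert times[fired][0] == pytest.approx(0.020, abs=1.5 * dt)

    def test_pulse_gap_respects_refractory(self, beta_params):
        proto = StimProtocol(target_phase=1.0, pulse_magnitude=0.2,
                             refractory_fraction=0.8, block_layout=[(0.5, 8.0)])
        traj = simulate(beta_params, protocol=proto, duration=8.5, dt=5e-4, seed=3)
        assert len(traj.pulse_times) > 100
        assert np.diff(traj.pulse_times).min() > 0.8 * TWO_PI / beta_params.omega0


class TestSimulate:
    def test_bit_identical_given_seed(self, beta_params):
        a = simulate(beta_params, duration=1.0, dt=5e-4, seed=99)
        b = simulate(beta_params, duration=1.0, dt=5e-4, seed=99)
        for name in ("rho_series", "psi_series", "signal", "pulse_times", "times"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_rho_bounded(self, beta_params):
        traj = simulate(beta_params, duration=2.0, dt=5e-4, seed=5)
        assert traj.rho_series.min() >= 0.0
        assert traj.rho_series.max() <= 1.0 + 1e-12

    def test_incoherent_floor(self):
        # K=0: time-averaged resultant of N independent phases ~ sqrt(pi/(4N))
        p = make_params(omega0=TWO_PI * 30, gamma=TWO_PI, K=0.0, D=5.0, N=200)
        traj = simulate(p, duration=10.0, dt=5e-4, seed=8)
        assert traj.rho_series[2000:].mean() == pytest.approx(
            np.sqrt(np.pi / 800), abs=0.012
        )

    def test_free_run_phase_differences_conserved(self):
        # D=0, K=0: theta_i(t) = theta_i(0) + omega_i t exactly under Euler
        p = make_params(K=0.0, D=0.0, N=6)
        theta0 = np.linspace(-2, 2, 6)
        omega = np.linspace(10, 20, 6)
        traj = simulate(p, duration=1.0, dt=5e-4, seed=0, initial_theta=theta0,
                        omega=omega, store_theta=True)
        t = traj.times[-1]
        expected = theta0 + omega * t
        assert traj.theta_series[-1] == pytest.approx(expected, abs=1e-9)

    def test_dt_convergence(self):
        # halving dt from 0.5 ms changes time-averaged rho by < 1 %
        gamma = TWO_PI
        p = NetworkParams(omega0=TWO_PI * 27, gamma=gamma, K=4 * gamma, D=1.0, N=300)
        theta0 = wrapped_cauchy_phases(0.5, 0.0, 300)
        means = []
        for dt in (5e-4, 2.5e-4):
            traj = simulate(p, duration=8.0, dt=dt, seed=21, initial_theta=theta0,
                            frequency_sampling="quantile")
            k0 = int(1.0 / dt)
            means.append(traj.rho_series[k0:].mean())
        assert abs(means[0] - means[1]) / means[1] < 0.01

    def test_python_and_kernel_paths_agree_without_noise(self):
        p = make_params(K=3.0, D=0.0, N=20)
        theta0 = np.linspace(-1, 1, 20)
        omega = np.linspace(150, 190, 20)
        fast = simulate(p, duration=0.5, dt=5e-4, seed=0, initial_theta=theta0,
                        omega=omega)
        slow = simulate(p, duration=0.5, dt=5e-4, seed=0, initial_theta=theta0,
                        omega=omega, store_theta=True)  # forces the numpy path
        assert fast.rho_series == pytest.approx(slow.rho_series, abs=1e-10)


class TestStimulationDirection:
    def test_target_zero_amplifies_target_pi_suppresses(self):
        # with Z=-sin, pulses at mean phase 0 pack the oscillators, at pi
        # they spread them (assessed across noise seeds)
        gamma = TWO_PI
        p = NetworkParams(omega0=TWO_PI * 27, gamma=gamma, K=4 * gamma, D=1.0, N=100)
        layout = [(0.5, 4.0)]
        up, down, ref = [], [], []
        for seed in range(20):
            for target, acc in ((0.0, up), (np.pi, down), (None, ref)):
                proto = None
                if target is not None:
                    proto = StimProtocol(target_phase=target, pulse_magnitude=0.3,
                                         block_layout=layout)
                traj = simulate(p, protocol=proto, duration=4.5, dt=5e-4, seed=seed)
                acc.append(traj.rho_series[1000:].mean())
        assert np.mean(up) > np.mean(ref) > np.mean(down)


class TestNetworkSignal:
    def test_fully_locked_signal(self):
        p = make_params(gamma=0.0, K=0.0, D=0.0, N=50, omega0=TWO_PI * 20)
        traj = simulate(p, duration=1.0, dt=5e-4, seed=0,
                        initial_theta=np.zeros(50))
        assert traj.signal == pytest.approx(np.cos(p.omega0 * traj.times), abs=1e-8)

    def test_zero_synchrony_zero_signal(self):
        theta = wrap_phase(np.linspace(-np.pi, np.pi, 100, endpoint=False))
        op = order_parameter(theta)
        assert op.rho * np.cos(op.psi) == pytest.approx(0.0, abs=1e-12)

    def test_envelope_tracks_synchrony(self, beta_params):
        from scipy.signal import hilbert

        traj = simulate(beta_params, duration=10.0, dt=5e-4, seed=17)
        env = np.abs(hilbert(traj.signal))
        sl = slice(1000, -1000)  # away from Hilbert edges
        r = np.corrcoef(env[sl], traj.rho_series[sl])[0, 1]
        assert r > 0.9


class TestWrappedCauchyInit:
    @pytest.mark.parametrize("rho0,psi0", [(0.3, 0.0), (0.7, 1.2), (0.0, 0.0)])
    def test_order_parameter_matches_request(self, rho0, psi0):
        theta = wrapped_cauchy_phases(rho0, psi0, 5000)
        op = order_parameter(theta)
        assert op.rho == pytest.approx(rho0, abs=5e-3)
        if rho0 > 0:
            assert wrap_phase(op.psi - psi0) == pytest.approx(0.0, abs=5e-3)
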