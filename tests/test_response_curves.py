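import numpy as np
import pytest
from scipy import stats

from kurastim.response_curves import (
    AnalyticBand,
    BlockResponse,
    arc_prc_correlation,
    align_most_suppressive,
    analyze_trial,
    block_amplitude_dependence,
    block_arc,
    block_prc,
    curves_from_blocks,
    phase_dependence_anova,
    prc_derivative,
    pulse_arc,
    spearman_link,
)
from kurastim.synthetic_data import make_constructed_signal


FS = 2000.0


def band_from(env, phase, fs=FS):
    return AnalyticBand(envelope=np.asarray(env, float),
                        phase_unwrapped=np.asarray(phase, float), fs=fs)


def constant_band(value, duration, fs=FS, freq=27.0):
    n = int(duration * fs)
    t = np.arange(n) / fs
    return band_from(np.full(n, value), 2 * np.pi * freq * t, fs)


class TestBlockArc:
    def test_identical_epochs_zero(self):
        band = constant_band(1.0, 30.0)
        assert block_arc(band, (0, 5), (5, 25)) == pytest.approx(0.0)

    def test_difference_of_constants(self):
        n_off, n_on = int(5 * FS), int(20 * FS)
        env = np.concatenate([np.full(n_off, 1.0), np.full(n_on, 1.3),
                              np.full(int(FS), 1.0)])
        t = np.arange(env.size) / FS
        band = band_from(env, 2 * np.pi * 27 * t)
        assert block_arc(band, (0, 5), (5, 25)) == pytest.approx(0.3)

    def test_power_mode_squares_envelope(self):
        n_off, n_on = int(5 * FS), int(20 * FS)
        env = np.concatenate([np.full(n_off, 1.0), np.full(n_on, 2.0),
                              np.full(int(FS), 1.0)])
        band = band_from(env, np.zeros(env.size))
        assert block_arc(band, (0, 5), (5, 25), power=True) == pytest.approx(3.0)

    def test_short_epoch_rejected(self):
        band = constant_band(1.0, 4.0)
        with pytest.raises(ValueError, match="1 s"):
            block_arc(band, (0, 1.2), (1.2, 3.5))


class TestBlockPrc:
    def test_pure_ramp_returns_zero(self):
        band = constant_band(1.0, 30.0)
        assert block_prc(band, (0, 5), (5, 25), n_pulses=10) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_injected_advance_sign_conventions(self):
        # total phase injected during the on-epoch: n_pulses * delta
        n_pulses, delta = 30, 0.05
        n = int(26 * FS)
        t = np.arange(n) / FS
        phase = 2 * np.pi * 27 * t
        for j in range(n_pulses):
            tp = 5.0 + 20.0 * (j + 0.5) / n_pulses
            phase[int(tp * FS):] += delta
        band = band_from(np.ones(n), phase)
        adv = block_prc(band, (0, 5), (5, 25), n_pulses, convention="advance")
        dly = block_prc(band, (0, 5), (5, 25), n_pulses, convention="delay")
        assert adv == pytest.approx(delta, rel=1e-6)
        assert dly == pytest.approx(-delta, rel=1e-6)

    def test_zero_pulses_rejected(self):
        band = constant_band(1.0, 30.0)
        with pytest.raises(ValueError, match="n_pulses"):
            block_prc(band, (0, 5), (5, 25), n_pulses=0)

    def test_unbiased_under_phase_noise(self, rng):
        # symmetric white phase noise, no stimulation effect
        vals = []
        n = int(26 * FS)
        t = np.arange(n) / FS
        for _ in range(100):
            phase = 2 * np.pi * 27 * t + 0.05 * rng.standard_normal(n)
            band = band_from(np.ones(n), phase)
            vals.append(block_prc(band, (0, 5), (5, 25), n_pulses=30))
        vals = np.array(vals)
        sem = vals.std(ddof=1) / 10
        assert abs(vals.mean()) < 3 * sem + 1e-6


class TestPulseArc:
    def test_constant_envelope_zero_delta(self):
        band = constant_band(2.0, 5.0)
        pre, delta, _ = pulse_arc(band, [1.0, 2.0, 3.0])
        assert pre == pytest.approx([2.0, 2.0, 2.0])
        assert delta == pytest.approx([0.0, 0.0, 0.0], abs=1e-12)

    def test_step_at_pulse_measured(self):
        n = int(2 * FS)
        env = np.full(n, 1.0)
        env[int(1.0 * FS):] = 1.5
        band = band_from(env, np.zeros(n))
        pre, delta, _ = pulse_arc(band, [1.0])
        assert pre[0] == pytest.approx(1.0)
        assert delta[0] == pytest.approx(0.5)

    def test_overlapping_windows_flagged(self):
        band = constant_band(1.0, 3.0)
        _, _, overlap = pulse_arc(band, [1.0, 1.005], window_ms=10)
        assert overlap.all()

    def test_edge_pulses_dropped(self):
        band = constant_band(1.0, 1.0)
        pre, delta, _ = pulse_arc(band, [0.001, 0.5])
        assert pre.size == 1


class TestPrcDerivative:
    def test_constant_curve_zero(self):
        assert prc_derivative(np.ones(8)) == pytest.approx(np.zeros(8))

    def test_sinusoid_closed_form(self):
        # central difference of sin on a uniform grid: cos(phi)*sin(d)/d
        phis = -np.pi + 2 * np.pi * np.arange(8) / 8
        d = np.pi / 4
        got = prc_derivative(np.sin(phis))
        assert got == pytest.approx(np.cos(phis) * np.sin(d) / d, abs=1e-12)

    def test_linearity(self, rng):
        u, v = rng.standard_normal(8), rng.standard_normal(8)
        lhs = prc_derivative(2.5 * u - 1.5 * v)
        rhs = 2.5 * prc_derivative(u) - 1.5 * prc_derivative(v)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            prc_derivative(np.array([1.0, 2.0]))


def make_curves(arc):
    arc = np.asarray(arc, float)
    n = arc.size
    phases = -np.pi + 2 * np.pi * np.arange(n) / n
    prc = np.sin(phases)
    return curves_from_blocks(
        [
            BlockResponse(phases[i], arc[i] + 0.001 * j, prc[i], 10, 1.0)
            for i in range(n)
            for j in range(2)
        ]
    )


class TestAlignment:
    def test_identity_when_minimum_at_reference(self):
        cs = make_curves([-1.0, 0, 1, 2, 3, 2, 1, 0])
        aligned = align_most_suppressive(cs)
        assert aligned.alignment_offset == pytest.approx(0.0)
        assert aligned.arc_mean == pytest.approx(cs.arc_mean)

    def test_rotation_undone(self):
        base = np.array([-1.0, 0, 1, 2, 3, 2, 1, 0])
        rotated = np.roll(base, 3)
        aligned = align_most_suppressive(make_curves(rotated))
        assert aligned.arc_mean == pytest.approx(make_curves(base).arc_mean, abs=1e-3)

    def test_two_subjects_minima_coincide(self):
        base = np.array([-1.0, 0, 1, 2, 3, 2, 1, 0])
        a = align_most_suppressive(make_curves(np.roll(base, 2)))
        b = align_most_suppressive(make_curves(np.roll(base, 5)))
        assert int(np.argmin(a.arc_mean)) == int(np.argmin(b.arc_mean)) == 0


class TestAnova:
    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(1000):
            groups = [rng.standard_normal(12) for _ in range(8)]
            ps.append(phase_dependence_anova(groups))
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_power_with_large_effect(self, rng):
        groups = [rng.standard_normal(12) + 3 * np.sin(2 * np.pi * k / 8)
                  for k in range(8)]
        assert phase_dependence_anova(groups) < 1e-3

    def test_degenerate_groups_raise(self):
        with pytest.raises(ValueError):
            phase_dependence_anova([[1.0, 1.0], [1.0, 1.0]])


class TestCorrelations:
    def test_perfect_anticorrelation(self):
        d = np.array([1.0, 2, 0, -1, -2, 1, 0, -1])
        r, _ = arc_prc_correlation(-3.0 * d, d)
        assert r == pytest.approx(-1.0)

    def test_null_calibration(self, rng):
        hits = 0
        for _ in range(200):
            _, p = arc_prc_correlation(rng.standard_normal(8),
                                       rng.standard_normal(8))
            hits += p < 0.05
        assert 0 <= hits <= 24  # ~5% false positives expected

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            arc_prc_correlation(np.ones(8), np.arange(8.0))

    def test_spearman_link(self):
        # strength |R| decreasing as ANOVA p grows: perfect monotone link
        r = [0.9, 0.8, 0.5, 0.2]
        p = [0.001, 0.01, 0.2, 0.6]
        rs, _ = spearman_link(r, p)
        assert rs == pytest.approx(-1.0)


class TestAmplitudeDependence:
    def test_injected_offset_parallel_to_reference(self, rng):
        pre = rng.uniform(0.2, 0.8, 40)
        noise = 0.01 * rng.standard_normal(40)
        ref = [(p, -0.5 * p + 0.1 + n, "reference") for p, n in zip(pre, noise)]
        amp = [(p, -0.5 * p + 0.1 + 0.2 + n, "amplifying")
               for p, n in zip(pre, noise)]
        out = block_amplitude_dependence(ref + amp)
        assert out.lines["amplifying"].slope == pytest.approx(
            out.lines["reference"].slope, abs=0.02
        )
        rs = out.reference_subtracted["amplifying"]
        assert rs.intercept + rs.slope * pre.mean() == pytest.approx(0.2, abs=0.02)

    def test_few_blocks_warns(self):
        with pytest.warns(UserWarning, match="< 5 blocks"):
            block_amplitude_dependence([(0.1, 0.0, "reference"),
                                        (0.2, 0.1, "reference"),
                                        (0.3, 0.0, "reference")])


class TestEstimatorTruthRecovery:
    def test_eq6_eq7_unbiased_on_constructed_blocks(self):
        # 100 synthetic blocks with known injected effects
        rec, gt = make_constructed_signal(
            phase_jump=0.04, amp_step=0.004, n_blocks=25, pulses_per_on=30,
            noise_sd=0.01, seed=3,
        )
        blocks = analyze_trial(rec, band=(20, 35))
        prc_vals = np.array([b.prc_value for b in blocks])
        arc_vals = np.array([b.arc_value for b in blocks])
        assert abs(prc_vals.mean() - 0.04) < 0.05 * 0.04
        expected_arc = np.mean(gt.injected_arc)
        assert abs(arc_vals.mean() - expected_arc) < 0.05 * expected_arc
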