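"""Reservoir core: weights, accumulation, nonlinearity, quantizers, update."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgrc.config import InputLayerCircuit, NonlinearityParams, ReservoirConfig
from ecgrc.reservoir import (
    BinaryWeightMatrix,
    ReservoirState,
    adc_quantize,
    dac_reconstruct,
    input_accumulate,
    mackey_glass_deriv,
    mackey_glass_nl,
    make_input_weights,
    reservoir_update,
    run_reservoir,
)

from conftest import direct_reservoir_eq


class TestInputWeights:
    def test_density_limits_give_constant_matrices(self):
        assert (make_input_weights(2, 4, density=1.0, seed=3).entries == 1).all()
        assert (make_input_weights(2, 4, density=0.0, seed=3).entries == 0).all()

    def test_same_seed_is_bit_identical(self):
        a = make_input_weights(63, 6000, density=0.5, seed=7)
        b = make_input_weights(63, 6000, density=0.5, seed=7)
        assert (a.entries == b.entries).all()

    def test_empirical_density_within_3_sigma(self):
        w = make_input_weights(63, 6000, density=0.5, seed=0)
        n = w.entries.size
        sigma = np.sqrt(0.5 * 0.5 / n)
        assert abs(w.entries.mean() - 0.5) < 3 * sigma

    @pytest.mark.parametrize("n,d", [(0, 4), (4, 0), (-1, 4)])
    def test_nonpositive_dimensions_rejected(self, n, d):
        with pytest.raises(ValueError):
            make_input_weights(n, d, density=0.5, seed=0)

    def test_non_binary_entries_rejected(self):
        with pytest.raises(ValueError):
            BinaryWeightMatrix(entries=np.array([[0.5, 1.0]]), seed=0, density=0.5)


class TestInputAccumulate:
    def test_zero_weights_give_exact_zero(self, default_circuit):
        cfg = ReservoirConfig(n_neurons=1, segment_len=4)
        out = input_accumulate([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0], default_circuit, cfg)
        assert out == 0.0

    def test_ideal_hand_sum(self, default_circuit):
        # gain 10f/400f = 0.025; masked sum 1+3+4 = 8 -> 0.2
        cfg = ReservoirConfig(n_neurons=1, segment_len=4)
        out = input_accumulate([1, 2, 3, 4], [1, 0, 1, 1], default_circuit, cfg)
        assert out == pytest.approx(0.2, abs=1e-15)

    def test_behavioral_settling_factor_closed_form(self, default_circuit):
        # default tau = T_s/8/D and slot T_s/D so t/tau = 8 for any D
        cfg = ReservoirConfig(n_neurons=1, segment_len=2, mode="behavioral")
        assert cfg.settle_time_per_sample / cfg.settling_tau == pytest.approx(8.0)
        out = input_accumulate([1.0, 1.0], [1, 1], default_circuit, cfg)
        expected = 2.0 * -np.expm1(-8.0) * default_circuit.gain
        assert out == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_raises(self, default_circuit):
        cfg = ReservoirConfig(n_neurons=1, segment_len=3)
        with pytest.raises(ValueError, match="length"):
            input_accumulate([1.0, 2.0], [1, 0, 1], default_circuit, cfg)


class TestMackeyGlass:
    def test_odd_symmetry_and_zero_at_offset(self):
        p = NonlinearityParams(amplitude=1.0, sharpness=1.0, exponent=2.0,
                               input_offset=0.3)
        assert mackey_glass_nl(0.3, p) == 0.0
        u = np.linspace(-2, 2, 41)
        np.testing.assert_allclose(
            mackey_glass_nl(0.3 + u, p), -mackey_glass_nl(0.3 - u, p), atol=1e-15
        )

    def test_unit_parameters_at_one(self):
        p = NonlinearityParams(amplitude=1.0, sharpness=1.0, exponent=2.0)
        assert mackey_glass_nl(1.0, p) == pytest.approx(0.5)

    def test_bounded_by_half_for_unit_parameters(self):
        # calculus: u/(1+u^2) has maximum 1/2 at |u| = 1
        p = NonlinearityParams(amplitude=1.0, sharpness=1.0, exponent=2.0)
        u = np.linspace(-50, 50, 20001)
        assert np.abs(mackey_glass_nl(u, p)).max() <= 0.5 + 1e-15

    def test_analytic_derivative_matches_finite_difference(self):
        p = NonlinearityParams(amplitude=1.3, sharpness=2.0, exponent=2.0)
        u = np.linspace(-3, 3, 101)
        h = 1e-6
        fd = (mackey_glass_nl(u + h, p) - mackey_glass_nl(u - h, p)) / (2 * h)
        np.testing.assert_allclose(mackey_glass_deriv(u, p), fd, atol=1e-8)


class TestQuantizer:
    def test_lower_rail_clips_to_code_zero(self):
        assert adc_quantize(-1.0, bits=10, full_scale=1.0) == 0
        assert adc_quantize(-5.0, bits=10, full_scale=1.0) == 0

    def test_one_bit_levels_are_half_scale(self):
        codes = [adc_quantize(v, 1, 1.0) for v in (-0.7, 0.7)]
        assert codes == [0, 1]
        assert dac_reconstruct(0, 1, 1.0) == -0.5
        assert dac_reconstruct(1, 1, 1.0) == 0.5

    @pytest.mark.parametrize("bits", range(1, 17))
    def test_half_lsb_bound_and_monotonicity(self, bits):
        fs = 1.0
        lsb = 2 * fs / 2**bits
        v = np.linspace(-fs, fs - 1e-12, 2000)
        codes = adc_quantize(v, bits, fs)
        recon = dac_reconstruct(codes, bits, fs)
        assert np.abs(recon - v).max() <= lsb / 2 + 1e-12
        assert (np.diff(codes) >= 0).all()

    @given(st.floats(-2.0, 2.0), st.integers(1, 16))
    @settings(deadline=None, max_examples=200)
    def test_reconstruction_always_in_range(self, v, bits):
        r = dac_reconstruct(adc_quantize(v, bits, 1.0), bits, 1.0)
        assert -1.0 < r < 1.0


class TestReservoirUpdate:
    def test_open_loop_limit_is_pure_projection(self, unit_gain_circuit):
        cfg = ReservoirConfig(n_neurons=2, segment_len=3, feedback_gain=0.0, seed=0)
        w = BinaryWeightMatrix(np.array([[1, 0, 1], [0, 1, 1]]), seed=0, density=0.5)
        prev = ReservoirState(values=np.array([5.0, -7.0]))
        new = reservoir_update([1.0, 2.0, 3.0], prev, w, unit_gain_circuit, cfg,
                               nonlinearity=lambda u: u)
        np.testing.assert_allclose(new.values, 0.6 * np.array([4.0, 5.0]))

    def test_hand_evaluated_update(self, unit_gain_circuit):
        # G_i=0.6, G_f=0.1, identity H, prev=[0.5,-0.2]:
        # [0.6*4 + 0.05, 0.6*5 - 0.02] = [2.45, 2.98]
        cfg = ReservoirConfig(n_neurons=2, segment_len=3, seed=0)
        w = BinaryWeightMatrix(np.array([[1, 0, 1], [0, 1, 1]]), seed=0, density=0.5)
        prev = ReservoirState(values=np.array([0.5, -0.2]))
        new = reservoir_update([1.0, 2.0, 3.0], prev, w, unit_gain_circuit, cfg,
                               nonlinearity=lambda u: u)
        np.testing.assert_allclose(new.values, [2.45, 2.98], atol=1e-14)

    def test_matches_direct_equation_on_random_instances(self, default_circuit):
        rng = np.random.default_rng(11)
        nlp = NonlinearityParams()
        for _ in range(100):
            n = int(rng.integers(1, 6))
            d = int(rng.integers(1, 11))
            cfg = ReservoirConfig(n_neurons=n, segment_len=d, seed=0)
            w = BinaryWeightMatrix((rng.random((n, d)) < 0.5).astype(int),
                                   seed=0, density=0.5)
            seg = rng.normal(size=d)
            prev = ReservoirState(values=rng.normal(size=n))
            got = reservoir_update(seg, prev, w, default_circuit, cfg).values
            want = direct_reservoir_eq(
                seg, prev.values, w.entries, default_circuit.gain, 0.6, 0.1,
                lambda u: mackey_glass_nl(u, nlp),
            )
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_echo_state_contraction_at_chip_operating_point(self, default_circuit):
        # G_f * max|H'| = 0.1 < 1: two trajectories on the same input converge
        cfg = ReservoirConfig(n_neurons=63, segment_len=100, seed=2)
        w = make_input_weights(63, 100, seed=2)
        rng = np.random.default_rng(3)
        seg = rng.normal(scale=0.3, size=100)
        s1 = ReservoirState(values=rng.uniform(-1, 1, 63))
        s2 = ReservoirState(values=rng.uniform(-1, 1, 63))
        dist = np.linalg.norm(s1.values - s2.values)
        for _ in range(8):
            s1 = reservoir_update(seg, s1, w, default_circuit, cfg)
            s2 = reservoir_update(seg, s2, w, default_circuit, cfg)
            new_dist = np.linalg.norm(s1.values - s2.values)
            assert new_dist < dist
            dist = new_dist

    def test_behavioral_drift_from_ideal_is_bounded(self, default_circuit):
        # noise off: differences come only from incomplete settling and
        # the loop quantizer, both with closed-form bounds
        n, d = 8, 50
        rng = np.random.default_rng(5)
        w = make_input_weights(n, d, seed=4)
        seg = rng.normal(scale=0.2, size=d)
        prev = ReservoirState(values=rng.uniform(-0.2, 0.2, n))
        ideal_cfg = ReservoirConfig(n_neurons=n, segment_len=d, seed=4)
        behav_cfg = ReservoirConfig(n_neurons=n, segment_len=d, seed=4,
                                    mode="behavioral")
        ideal = reservoir_update(seg, prev, w, default_circuit, ideal_cfg).values
        behav = reservoir_update(seg, prev, w, default_circuit, behav_cfg).values
        acc = default_circuit.gain * (w.entries @ seg)
        lsb = 2 * behav_cfg.full_scale / 2**behav_cfg.adc_bits
        slope = behav_cfg.nl_params.amplitude  # max |H'|
        bound = slope * (
            0.6 * (1 - behav_cfg.settling_factor) * np.abs(acc) + 0.1 * lsb / 2
        )
        assert (np.abs(behav - ideal) <= bound + 1e-12).all()


class TestRunReservoir:
    def test_empty_dataset_gives_empty_matrix(self, default_circuit):
        cfg = ReservoirConfig(n_neurons=4, segment_len=10)
        w = make_input_weights(4, 10, seed=0)
        out = run_reservoir([], w, default_circuit, cfg)
        assert out.shape == (0, 4)

    def test_single_segment_equals_one_update_from_zero(self, default_circuit):
        cfg = ReservoirConfig(n_neurons=4, segment_len=10, feedback_gain=0.0, seed=1)
        w = make_input_weights(4, 10, seed=1)
        seg = np.random.default_rng(0).normal(size=10)
        row = run_reservoir([seg], w, default_circuit, cfg)[0]
        direct = reservoir_update(
            seg, ReservoirState(values=np.zeros(4)), w, default_circuit, cfg
        ).values
        np.testing.assert_array_equal(row, direct)

    def test_behavioral_runs_are_deterministic_given_seed(self):
        circuit = InputLayerCircuit(noise_enabled=True)
        cfg = ReservoirConfig(n_neurons=4, segment_len=20, seed=9, mode="behavioral")
        w = make_input_weights(4, 20, seed=9)
        segs = np.random.default_rng(1).normal(size=(3, 20))
        a = run_reservoir(segs, w, circuit, cfg)
        b = run_reservoir(segs, w, circuit, cfg)
        np.testing.assert_array_equal(a, b)
        assert np.std(a) > 0

    def test_ragged_segments_rejected(self, default_circuit):
        cfg = ReservoirConfig(n_neurons=4, segment_len=10)
        w = make_input_weights(4, 10, seed=0)
        with pytest.raises(ValueError, match="length"):
            run_reservoir([np.zeros(10), np.zeros(7)], w, default_circuit, cfg)
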