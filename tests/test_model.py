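"""Unit tests for the oscillator network, coupling construction, drive, and integrator."""

import math

import numpy as np
import pytest

from dbskuramoto import (
    ConfigurationError,
    InvalidNetworkError,
    NumericalOverflowError,
    PlasticitySignature,
    StimulusSpec,
    build_coupling_matrix,
    coupling_strength,
    dbs_waveform,
    draw_natural_frequencies,
    drive_series,
    euler_step,
    integrate_block,
)

from conftest import make_coupling, make_state


class TestPlasticitySignature:
    def test_defaults(self):
        sig = PlasticitySignature(alpha_p=1.0, alpha_d=2.0)
        assert sig.tau_p == 0.5
        assert sig.tau_d == 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha_p": -1.0, "alpha_d": 0.0},
            {"alpha_p": 0.0, "alpha_d": -0.5},
            {"alpha_p": 1.0, "alpha_d": 1.0, "tau_p": 0.0},
            {"alpha_p": 1.0, "alpha_d": 1.0, "tau_d": -0.5},
            {"alpha_p": float("nan"), "alpha_d": 1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            PlasticitySignature(**kwargs)


class TestNaturalFrequencies:
    def test_n100_open_interval(self, rng):
        w = draw_natural_frequencies(100, rng)
        assert w.shape == (100,)
        assert np.all(w > 0) and np.all(w < 1)

    def test_deterministic_under_seed(self):
        a = draw_natural_frequencies(2, np.random.default_rng(42))
        b = draw_natural_frequencies(2, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_law_of_large_numbers_mean(self):
        # independent Monte-Carlo oracle: U(0,1) mean is 0.5
        w = draw_natural_frequencies(10_000, np.random.default_rng(7))
        assert abs(w.mean() - 0.5) < 0.02

    @pytest.mark.parametrize("n", [0, 1, -3])
    def test_too_small_network_rejected(self, n, rng):
        with pytest.raises(InvalidNetworkError):
            draw_natural_frequencies(n, rng)


class TestCouplingStrength:
    def test_symmetric_terms_cancel(self):
        sig = PlasticitySignature(alpha_p=8.0, alpha_d=8.0)
        assert coupling_strength(sig, 0.3, 0.3) == 0.0

    def test_pure_potentiation_scalar_value(self):
        # oracle: 8 * exp(0.5 * 0.5) evaluated directly
        sig = PlasticitySignature(alpha_p=8.0, alpha_d=0.0)
        expected = 8.0 * math.exp(0.25)
        assert coupling_strength(sig, 0.5, 0.9) == pytest.approx(expected, rel=1e-15)

    def test_depotentiation_dominates_gives_negative(self):
        sig = PlasticitySignature(alpha_p=0.001, alpha_d=8.0)
        assert coupling_strength(sig, 0.2, 0.9) < 0

    def test_damped_form(self):
        sig = PlasticitySignature(alpha_p=2.0, alpha_d=1.0)
        expected = 2.0 * math.exp(-0.4 / 0.5) - 1.0 * math.exp(-0.8 / 0.5)
        got = coupling_strength(sig, 0.4, 0.8, exp_form="damped")
        assert got == pytest.approx(expected, rel=1e-15)

    def test_unknown_form_rejected(self):
        sig = PlasticitySignature(alpha_p=1.0, alpha_d=1.0)
        with pytest.raises(ConfigurationError):
            coupling_strength(sig, 0.1, 0.2, exp_form="bogus")


class TestCouplingMatrix:
    def test_high_potentiation_all_positive(self, rng, condition_high_pot):
        # lower bound: 8*exp(0) - 0.001*exp(0.5) > 0, so every entry is positive
        cm = build_coupling_matrix(condition_high_pot, 100, rng)
        off = cm.strengths[~np.eye(100, dtype=bool)]
        assert np.all(off > 0)
        np.testing.assert_array_equal(cm.strengths, cm.strengths.T)
        assert np.all(np.diag(cm.strengths) == 0)

    def test_zero_rates_give_zero_matrix(self, rng):
        sig = PlasticitySignature(alpha_p=0.0, alpha_d=0.0)
        cm = build_coupling_matrix(sig, 10, rng)
        assert np.all(cm.strengths == 0)

    def test_deterministic_under_seed(self, condition_high_pot):
        a = build_coupling_matrix(condition_high_pot, 20, np.random.default_rng(3))
        b = build_coupling_matrix(condition_high_pot, 20, np.random.default_rng(3))
        np.testing.assert_array_equal(a.strengths, b.strengths)

    def test_draws_in_open_interval_and_distinct(self, rng, condition_high_pot):
        cm = build_coupling_matrix(condition_high_pot, 30, rng)
        mask = ~np.eye(30, dtype=bool)
        assert np.all(cm.draws_r1[mask] > 0) and np.all(cm.draws_r1[mask] < 1)
        assert np.all(cm.draws_r2[mask] > 0) and np.all(cm.draws_r2[mask] < 1)
        assert np.all(cm.draws_r1[mask] != cm.draws_r2[mask])

    def test_entries_match_scalar_formula(self, rng, condition_high_pot):
        cm = build_coupling_matrix(condition_high_pot, 8, rng)
        for i in range(8):
            for j in range(i + 1, 8):
                expected = coupling_strength(
                    condition_high_pot, cm.draws_r1[i, j], cm.draws_r2[i, j]
                )
                assert cm.strengths[i, j] == expected


class TestDbsWaveform:
    def test_off_is_zero(self, default_spec):
        assert all(dbs_waveform(default_spec, t, False) == 0.0 for t in range(50))

    def test_amplitude_during_pulse(self, default_spec):
        # t=0 is always an onset
        assert dbs_waveform(default_spec, 0, True) == 3.0

    def test_onset_count_2000_iterations(self, default_spec):
        # brute-force count over the iteration grid: floor(2.0 s * 130 Hz) = 260
        onsets = sum(
            math.floor(t * 0.001 * 130.0) > math.floor((t - 1) * 0.001 * 130.0)
            for t in range(2000)
        )
        assert onsets == 260
        drives = drive_series(default_spec, 0, 2000, True)
        assert int(np.sum(drives > 0)) == 260

    def test_series_matches_pointwise(self, default_spec):
        series = drive_series(default_spec, 0, 300, True)
        pointwise = np.array([dbs_waveform(default_spec, t, True) for t in range(300)])
        np.testing.assert_array_equal(series, pointwise)

    def test_series_matches_pointwise_nonzero_start_wide_pulse(self):
        spec = StimulusSpec(frequency=60.0, pulse_width_iterations=3)
        start = 137
        series = drive_series(spec, start, 200, True)
        pointwise = np.array(
            [dbs_waveform(spec, t, True) for t in range(start, start + 200)]
        )
        np.testing.assert_array_equal(series, pointwise)

    def test_negative_iteration_rejected(self, default_spec):
        with pytest.raises(ConfigurationError):
            dbs_waveform(default_spec, -1, True)

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ConfigurationError):
            StimulusSpec(frequency=130.0, pulse_width_iterations=8)


def scalar_euler_oracle(phases, omega, strengths, drive, dt, attractive=True):
    """Independent plain-Python single-step implementation."""
    n = len(phases)
    out = []
    for i in range(n):
        acc = 0.0
        for j in range(n):
            diff = phases[j] - phases[i]
            acc += strengths[i][j] * (math.sin(diff) if attractive else -math.sin(diff))
        out.append(phases[i] + dt * (omega[i] + acc / n + drive[i]))
    return out


class TestEulerStep:
    def test_pure_linear_advance(self):
        state = make_state([0.1, 0.1, 0.1], [0.0, 0.0, 0.0])
        coupling = make_coupling(np.zeros((3, 3)))
        new = euler_step(state, coupling, 0.0, dt=1.0)
        np.testing.assert_allclose(new.ensemble.phases, [0.1, 0.1, 0.1], rtol=0)
        assert new.iteration == 1

    def test_three_oscillator_hand_oracle(self):
        phases = [0.3, 1.1, -0.4]
        omega = [0.2, 0.5, 0.8]
        strengths = [[0.0, 2.0, -1.0], [2.0, 0.0, 0.5], [-1.0, 0.5, 0.0]]
        drive = [3.0, 3.0, 3.0]
        expected = scalar_euler_oracle(phases, omega, strengths, drive, dt=1.0)
        state = make_state(omega, phases)
        new = euler_step(state, make_coupling(strengths), np.array(drive))
        np.testing.assert_allclose(new.ensemble.phases, expected, rtol=1e-13, atol=1e-13)

    def test_repulsive_convention_hand_oracle(self):
        phases = [0.3, 1.1, -0.4]
        omega = [0.2, 0.5, 0.8]
        strengths = [[0.0, 2.0, -1.0], [2.0, 0.0, 0.5], [-1.0, 0.5, 0.0]]
        expected = scalar_euler_oracle(
            phases, omega, strengths, [0.0] * 3, dt=1.0, attractive=False
        )
        state = make_state(omega, phases)
        new = euler_step(
            state, make_coupling(strengths), 0.0, sign_convention="repulsive"
        )
        np.testing.assert_allclose(new.ensemble.phases, expected, rtol=1e-13, atol=1e-13)

    def test_identical_oscillators_stay_identical(self):
        state = make_state([0.25] * 5, [1.3] * 5)
        coupling = make_coupling(np.random.default_rng(0).normal(size=(5, 5)) * 0)
        # nonzero symmetric coupling, zero diagonal
        k = np.full((5, 5), 2.0)
        np.fill_diagonal(k, 0.0)
        new = euler_step(state, make_coupling(k), 1.0)
        assert np.unique(new.ensemble.phases).size == 1

    def test_dimension_mismatch(self):
        state = make_state([0.1, 0.2], [0.0, 0.0])
        with pytest.raises(ConfigurationError):
            euler_step(state, make_coupling(np.zeros((3, 3))), 0.0)

    def test_overflow_guard(self):
        state = make_state([0.1, 0.2], [1e10, 0.0])
        with pytest.raises(NumericalOverflowError):
            euler_step(state, make_coupling(np.zeros((2, 2))), 0.0)


class TestIntegrateBlock:
    def test_records_every_iteration(self, zero_coupling_state, default_spec):
        state, coupling = zero_coupling_state
        traj, new_state = integrate_block(state, coupling, default_spec, True, 2000)
        assert traj.phases.shape == (2000, 4)
        assert new_state.iteration == 2000

    def test_zero_coupling_closed_form(self, zero_coupling_state, default_spec):
        state, coupling = zero_coupling_state
        omega = state.ensemble.natural_frequencies
        traj, _ = integrate_block(state, coupling, default_spec, False, 500)
        t = np.arange(1, 501)[:, None]
        np.testing.assert_array_equal(traj.phases, t * omega[None, :])

    def test_chaining_blocks_bit_identical(self, rng, condition_high_pot, default_spec):
        n = 10
        omega = draw_natural_frequencies(n, rng)
        coupling = build_coupling_matrix(condition_high_pot, n, rng)
        phases0 = rng.uniform(0, 2 * np.pi, n)

        s0 = make_state(omega, phases0)
        whole, _ = integrate_block(s0, coupling, default_spec, True, 2000)

        s0 = make_state(omega, phases0)
        first, mid = integrate_block(s0, coupling, default_spec, True, 1000)
        second, _ = integrate_block(mid, coupling, default_spec, True, 1000)
        np.testing.assert_array_equal(
            np.vstack([first.phases, second.phases]), whole.phases
        )
        assert second.iteration_offset == 1000

    def test_matches_repeated_euler_step(self, rng, condition_high_pot, default_spec):
        n = 5
        omega = draw_natural_frequencies(n, rng)
        coupling = build_coupling_matrix(condition_high_pot, n, rng)
        state = make_state(omega, rng.uniform(0, 2 * np.pi, n))

        traj, _ = integrate_block(state, coupling, default_spec, True, 50)
        step_state = state
        for t in range(50):
            drive = dbs_waveform(default_spec, step_state.iteration, True)
            step_state = euler_step(step_state, coupling, drive)
            np.testing.assert_array_equal(step_state.ensemble.phases, traj.phases[t])

    def test_static_coupling_checksum(self, rng, condition_high_pot, default_spec):
        coupling = build_coupling_matrix(condition_high_pot, 6, rng)
        before = coupling.checksum()
        state = make_state(draw_natural_frequencies(6, rng), np.zeros(6))
        integrate_block(state, coupling, default_spec, True, 200)
        assert coupling.checksum() == before

    def test_target_subset_only_drives_targets(self, default_spec):
        spec = StimulusSpec(targets=(0,))
        state = make_state([0.0, 0.0], [0.0, 0.0])
        coupling = make_coupling(np.zeros((2, 2)))
        traj, _ = integrate_block(state, coupling, spec, True, 1)
        assert traj.phases[0, 0] == 3.0  # t=0 onset hits target
        assert traj.phases[0, 1] == 0.0

    def test_bad_iteration_count(self, zero_coupling_state, default_spec):
        state, coupling = zero_coupling_state
        with pytest.raises(ConfigurationError):
            integrate_block(state, coupling, default_spec, True, 0)
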