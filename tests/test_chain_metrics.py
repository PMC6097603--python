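"""Trajectory analysis: unwrapping, slip/wobble detectors, order parameter."""

import numpy as np
import pytest

from rotorchain import PhysicalParams
from rotorchain.chain_metrics import (
    detect_slips,
    detect_wobbles,
    drift_per_beat,
    end_to_end_drift_rate,
    kymograph,
    order_parameter,
    unwrap_and_diff,
)
from rotorchain.rotor_simulator import Trajectory


def make_traj(t, phi_columns, params=None):
    """Synthetic trajectory from explicit per-rotor phase series."""
    phi = np.column_stack(phi_columns)
    n = phi.shape[1]
    if params is None:
        params = PhysicalParams(N=n, D=1.0, h=11.7e-6)
    return Trajectory(t=t, phi=phi, rho=np.full_like(phi, params.R), params=params)


@pytest.fixture()
def omega():
    return 7.0  # rad/s, close to the physical rotation rate


@pytest.fixture()
def times():
    return np.arange(0.0, 120.0, 0.008)  # ~112 samples per period at 7 rad/s


def smooth_step(t, t0, width, height=2 * np.pi):
    """C1 ramp of given height centred at t0 (a controlled phase excursion)."""
    return height / (1.0 + np.exp(-(t - t0) / width))


class TestUnwrapAndDiff:
    def test_constant_frequency_chain_has_constant_chi(self, times, omega):
        traj = make_traj(times, [omega * times, omega * times + 0.5, omega * times + 1.0])
        chi, ete = unwrap_and_diff(traj)
        np.testing.assert_allclose(chi, 0.5, atol=1e-12)
        np.testing.assert_allclose(ete, 1.0, atol=1e-12)

    def test_wrapped_input_is_unwrapped(self, times, omega):
        """Phases stored modulo 2*pi round-trip to the smooth original."""
        smooth = omega * times
        traj = make_traj(times, [np.mod(smooth, 2 * np.pi), smooth + 0.3])
        chi, _ = unwrap_and_diff(traj)
        np.testing.assert_allclose(chi[:, 0], 0.3 - smooth[0] + smooth[0], atol=1e-9)

    def test_inserted_2pi_ramp_appears_once_in_chi(self, times, omega):
        phi0 = omega * times
        phi1 = omega * times + smooth_step(times, 60.0, 0.4)
        traj = make_traj(times, [phi0, phi1])
        chi, _ = unwrap_and_diff(traj)
        assert chi[0, 0] == pytest.approx(0.0, abs=1e-3)
        assert chi[-1, 0] == pytest.approx(2 * np.pi, abs=1e-3)

    def test_undersampled_rejected(self):
        t = np.arange(0.0, 50.0, 0.5)  # < 2 samples per period at 7 rad/s
        traj = make_traj(t, [7.0 * t, 7.0 * t])
        with pytest.raises(ValueError, match="undersampled"):
            unwrap_and_diff(traj)


class TestDetectSlips:
    def test_locked_wave_has_no_slips(self, times, omega):
        traj = make_traj(times, [omega * times, omega * times + 0.8, omega * times + 1.6])
        assert detect_slips(traj).slip_count == 0

    def test_bounded_oscillation_does_not_count(self, times, omega):
        wob = 1.2 * np.sin(0.5 * times)
        traj = make_traj(times, [omega * times, omega * times + wob])
        assert detect_slips(traj).slip_count == 0

    def test_single_ramp_counts_once_with_direction(self, times, omega):
        up = smooth_step(times, 40.0, 0.4)
        down = -smooth_step(times, 80.0, 0.4)
        traj = make_traj(times, [omega * times, omega * times + up + down])
        ev = detect_slips(traj).frame
        assert len(ev) == 2
        assert list(ev["direction"]) == [1, -1]
        assert ev["time"].iloc[0] == pytest.approx(40.0, abs=1.0)

    def test_steady_drift_count_matches_rate(self, times):
        """A pair drifting at rate nu accumulates round(nu T / 2 pi) slips."""
        nu = 0.45
        traj = make_traj(times, [7.0 * times, 7.45 * times])
        expected = nu * times[-1] / (2 * np.pi)
        assert abs(detect_slips(traj).slip_count - expected) <= 1

    def test_global_phase_shift_invariance(self, times, omega):
        phi1 = omega * times + smooth_step(times, 50.0, 0.4)
        a = make_traj(times, [omega * times, phi1])
        b = make_traj(times, [omega * times + 2.1, phi1 + 2.1])
        assert detect_slips(a).frame.equals(detect_slips(b).frame)

    def test_time_reversal_flips_direction(self, times, omega):
        phi1 = omega * times + smooth_step(times, 50.0, 0.4)
        phi0 = omega * times
        fwd = make_traj(times, [phi0, phi1])
        rev = make_traj(times, [phi0[::-1], phi1[::-1]])
        d_fwd = detect_slips(fwd).frame["direction"].sum()
        d_rev = detect_slips(rev).frame["direction"].sum()
        assert d_fwd == -d_rev != 0

    def test_slip_count_consistent_with_end_to_end_drift(self, times):
        """Summed signed slips track the net end-to-end drift within one slip."""
        traj = make_traj(times, [7.0 * times, 7.45 * times, 7.45 * times + 0.3])
        _, ete = unwrap_and_diff(traj)
        net = (ete[-1] - ete[0]) / (2 * np.pi)
        signed = detect_slips(traj).frame["direction"].sum()
        assert abs(signed - net) <= 1

    def test_position_histogram(self, times, omega):
        phi2 = omega * times + smooth_step(times, 60.0, 0.4)
        traj = make_traj(times, [omega * times, omega * times, phi2])
        hist = detect_slips(traj).position_histogram(2)
        assert list(hist) == [0, 1]


class TestDetectWobbles:
    def test_locked_wave_has_no_wobbles(self, times, omega):
        traj = make_traj(times, [omega * times, omega * times + 0.8])
        assert len(detect_wobbles(traj)) == 0

    def test_synthetic_pulse_measured(self, times, omega):
        """An injected 1.2 rad excursion is found with W ~ 1.2 and no slip."""
        pulse = 1.2 * np.exp(-((times - 60.0) ** 2) / (2 * 1.5**2))
        traj = make_traj(times, [omega * times, omega * times + pulse])
        ev = detect_wobbles(traj).frame
        assert len(ev) == 1
        assert ev["W"].iloc[0] == pytest.approx(1.2, abs=0.1)
        assert np.isnan(ev["terminal_rotor"].iloc[0])

    def test_recurrence_time_between_onsets(self, times, omega):
        pulses = sum(
            1.0 * np.exp(-((times - t0) ** 2) / (2 * 1.0**2)) for t0 in (40.0, 70.0, 100.0)
        )
        traj = make_traj(times, [omega * times, omega * times + pulses])
        ev = detect_wobbles(traj).frame
        assert len(ev) == 3
        taus = ev["tau"].dropna()
        np.testing.assert_allclose(taus, 30.0, atol=2.0)

    def test_sub_threshold_excursions_ignored(self, times, omega):
        pulse = 0.3 * np.exp(-((times - 60.0) ** 2) / (2 * 1.5**2))
        traj = make_traj(times, [omega * times, omega * times + pulse])
        assert len(detect_wobbles(traj)) == 0

    def test_wobble_terminating_in_slip_records_position(self, times, omega):
        # excursion on the measurement pair followed by a slip at pair 1
        pulse = 1.5 * np.exp(-((times - 50.0) ** 2) / (2 * 1.5**2))
        ramp = smooth_step(times, 55.0, 0.4)
        traj = make_traj(
            times, [omega * times, omega * times + pulse, omega * times + pulse + ramp]
        )
        ev = detect_wobbles(traj).frame
        assert len(ev) >= 1
        assert ev["terminal_rotor"].iloc[0] == 1


class TestWobblesOnSimulatedChain:
    def test_wobble_statistics_at_intermediate_height(self):
        """A six-rotor chain at h = 11.7 um shows rad-scale wobbles that
        propagate toward the fast end of the chain, recurring every few
        to ~10 mean periods."""
        from rotorchain.rotor_simulator import mean_period, simulate

        p = PhysicalParams(
            N=6, D=1.01, h=11.7e-6, lambda_=2.21 * 2.06e-6, t_end=400.0, seed=1
        )
        traj = simulate(p)
        ev = detect_wobbles(traj).frame
        assert len(ev) >= 3
        assert ev["W"].between(0.5, 3.5).all()
        taus = ev["tau"].dropna() / mean_period(p)
        assert (taus > 0).all()
        assert 1.0 < taus.median() < 20.0
        # propagating wobbles terminate deeper into the chain, toward the
        # intrinsically fastest rotors
        terminals = ev["terminal_rotor"].dropna()
        assert len(terminals) > 0
        assert terminals.median() >= 1


class TestOrderParameter:
    def test_in_phase_chain(self, times, omega):
        traj = make_traj(times, [omega * times] * 4)
        ops = order_parameter(traj, t_burn=10.0)
        assert ops.A_bar == pytest.approx(1.0, abs=1e-12)
        assert ops.Psi_bar_abs == pytest.approx(0.0, abs=1e-12)

    def test_uniform_wave(self, times, omega):
        c = 0.7
        traj = make_traj(times, [omega * times + n * c for n in range(5)])
        ops = order_parameter(traj, t_burn=10.0)
        assert ops.A_bar == pytest.approx(1.0, abs=1e-12)
        assert ops.Psi_bar_abs == pytest.approx(c, abs=1e-12)

    def test_symmetric_chevron_has_zero_angle(self, times, omega):
        """chi = (+c, +c, -c, -c) averages to Psi = 0 but A < 1."""
        c = 0.6
        offsets = np.cumsum([0.0, c, c, -c, -c])
        traj = make_traj(times, [omega * times + o for o in offsets])
        ops = order_parameter(traj, t_burn=10.0)
        assert ops.Psi_bar_abs == pytest.approx(0.0, abs=1e-12)
        assert ops.A_bar == pytest.approx(np.cos(c), abs=1e-12)

    def test_amplitude_one_iff_uniform_differences(self, times, omega):
        traj = make_traj(times, [omega * times, omega * times + 0.4, omega * times + 1.1])
        ops = order_parameter(traj, t_burn=10.0)
        assert ops.A_bar < 1.0 - 1e-6

    def test_single_rotor_rejected(self, times, omega):
        traj = make_traj(times, [omega * times])
        with pytest.raises(ValueError):
            order_parameter(traj)


class TestDriftPerBeat:
    def test_locked_chain_has_zero_drift(self, times, omega):
        traj = make_traj(times, [omega * times, omega * times + 0.5])
        assert drift_per_beat(traj, t_burn=10.0) == pytest.approx(0.0, abs=1e-12)

    def test_known_drift_rate(self, times):
        """Two rotors at 7.0 and 7.45 rad/s: drift per beat = 0.45/7.225."""
        traj = make_traj(times, [7.0 * times, 7.45 * times])
        period = 2 * np.pi / np.mean([7.0, 7.45])
        expected = 0.45 / np.mean([7.0, 7.45])
        assert drift_per_beat(traj, t_burn=10.0, period=period) == pytest.approx(
            expected, rel=1e-6
        )
        assert end_to_end_drift_rate(traj, t_burn=10.0) == pytest.approx(0.45, rel=1e-9)

    def test_burn_in_must_leave_samples(self, times, omega):
        traj = make_traj(times, [omega * times, omega * times])
        with pytest.raises(ValueError):
            drift_per_beat(traj, t_burn=1e4)


class TestKymograph:
    def test_shape_values_and_trivial_cases(self, times, omega):
        traj = make_traj(times, [omega * times, omega * times + 1.0])
        k = kymograph(traj)
        assert k.shape == (2, times.size)
        assert np.all((k >= -1) & (k <= 1))
        np.testing.assert_allclose(k[0], np.sin(omega * times), atol=1e-12)
        flat = make_traj(times, [np.zeros_like(times)])
        assert np.array_equal(kymograph(flat), np.zeros((1, times.size)))
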