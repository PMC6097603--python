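"""Analysis of N-rotor trajectories: phase differences, defects, wobbles,
order parameter, drift and kymographs.

The central objects are the pairwise phase differences
``chi_n = phi_{n+1} - phi_n`` between neighbouring rotors.  A frequency-
locked chain keeps every ``chi_n`` bounded; a *phase slip* (defect) is a
completed 2*pi excursion of one ``chi_n``, and a *wobble* is a transient
excursion of the phase profile that returns to baseline without completing a
slip.  Metachronal order is summarised by the complex order parameter

    Z = A e^{i Psi} = (1/(N-1)) * sum_{n=0}^{N-2} e^{i chi_n}

built from the pairwise differences (not the raw phases): a uniform
travelling wave has A = 1 and Psi equal to the per-pair phase lag, while a
symmetric chevron profile has Psi = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from rotorchain.rotor_simulator import Trajectory, mean_period

__all__ = [
    "EventTable",
    "OrderParameterSeries",
    "unwrap_and_diff",
    "detect_slips",
    "detect_wobbles",
    "order_parameter",
    "drift_per_beat",
    "end_to_end_drift_rate",
    "kymograph",
]


@dataclass
class EventTable:
    """Detected slip or wobble events.

    ``frame`` has one row per event with columns: ``kind`` ('slip' or
    'wobble'), ``time`` (onset, s), ``index`` (rotor pair for slips,
    measurement rotor for wobbles), ``direction`` (+-1, slips only),
    ``W`` (peak excursion amplitude in rad, wobbles only), ``tau``
    (recurrence time since the previous wobble onset, s, wobbles only) and
    ``terminal_rotor`` (chain position where a propagating wobble ended in a
    slip, NaN if it healed).
    """

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def slip_count(self) -> int:
        if self.frame.empty:
            return 0
        return int((self.frame["kind"] == "slip").sum())

    def position_histogram(self, n_positions: int) -> np.ndarray:
        """Event count per chain position (slip pair index or terminal rotor)."""
        counts = np.zeros(n_positions, dtype=int)
        if self.frame.empty:
            return counts
        if (self.frame["kind"] == "slip").any():
            idx = self.frame.loc[self.frame["kind"] == "slip", "index"]
        else:
            idx = self.frame["terminal_rotor"].dropna()
        for i in idx.astype(int):
            if 0 <= i < n_positions:
                counts[i] += 1
        return counts


@dataclass
class OrderParameterSeries:
    """Time series of the metachronal order parameter Z = A e^{i Psi}."""

    t: np.ndarray
    A: np.ndarray
    Psi: np.ndarray
    A_bar: float
    Psi_bar_abs: float
    t_burn: float


def _unwrapped_phases(traj: Trajectory, min_samples_per_period: float = 50.0) -> np.ndarray:
    """Continuous per-rotor phases; rejects undersampled trajectories.

    Simulator output is already continuous; wrapped input (e.g. phases read
    back from a file modulo 2*pi) is unwrapped along time.  A rotor whose
    mean advance exceeds 2*pi per ``min_samples_per_period`` samples cannot
    be unwrapped unambiguously and is rejected.
    """
    phi = np.unwrap(np.asarray(traj.phi, dtype=float), axis=0)
    n_steps = phi.shape[0] - 1
    if n_steps < 1:
        raise ValueError("trajectory has fewer than two samples")
    periods = np.abs(phi[-1] - phi[0]) / (2.0 * np.pi)
    turning = periods > 0
    if turning.any():
        spp = n_steps / periods[turning]
        if np.min(spp) < min_samples_per_period:
            raise ValueError(
                "trajectory is undersampled: fewer than "
                f"{min_samples_per_period:.0f} samples per rotation period"
            )
    return phi


def unwrap_and_diff(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Continuous pairwise differences ``chi_n(t)`` and the end-to-end difference.

    Returns ``(chi, end_to_end)`` where ``chi`` has shape (n_samples, N-1)
    with ``chi[:, n] = phi_{n+1} - phi_n`` free of artificial 2*pi jumps, and
    ``end_to_end = phi_{N-1} - phi_0``.
    """
    phi = _unwrapped_phases(traj)
    chi = np.diff(phi, axis=1)
    return chi, phi[:, -1] - phi[:, 0]


def detect_slips(traj: Trajectory, window_periods: float = 5.0) -> EventTable:
    """Detect phase slips: completed 2*pi excursions of any ``chi_n``.

    Each ``chi_n`` is referenced to its initial plateau and a slip is
    registered every time it crosses the midpoint between successive locking
    plateaus (odd multiples of pi), so bounded oscillations of amplitude
    below pi never count and every 2*pi excursion counts exactly once.
    ``direction`` is the sign of the jump; ``index`` is the rotor pair n.
    """
    chi, _ = unwrap_and_diff(traj)
    t = traj.t
    rows = []
    for n in range(chi.shape[1]):
        c = chi[:, n] - chi[0, n]
        level = np.round(c / (2.0 * np.pi)).astype(int)
        jumps = np.nonzero(np.diff(level))[0]
        for k in jumps:
            step = level[k + 1] - level[k]
            for _ in range(abs(step)):
                rows.append(
                    {
                        "kind": "slip",
                        "time": t[k + 1],
                        "index": n,
                        "direction": int(np.sign(step)),
                        "W": np.nan,
                        "tau": np.nan,
                        "terminal_rotor": np.nan,
                    }
                )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values("time", ignore_index=True)
    return EventTable(frame=frame)


def detect_wobbles(
    traj: Trajectory,
    W_min: float = 0.5,
    baseline_periods: float = 20.0,
    measurement_rotor: int = 1,
) -> EventTable:
    """Detect wobbles: transient phase-profile excursions without a net slip.

    The signal is ``phi_i - phi_0`` for the measurement rotor (default the
    initiating pair, i = 1), detrended by a rolling-median baseline over
    ``baseline_periods`` mean periods.  A wobble is a locally-peaked
    excursion of at least ``W_min`` rad; its amplitude ``W`` is the peak
    excursion and ``tau`` the time since the previous wobble onset.  If a
    slip occurs anywhere in the chain within one baseline window after the
    onset, the wobble is recorded as terminating at that slip's chain
    position (``terminal_rotor``); otherwise it healed.
    """
    phi = _unwrapped_phases(traj)
    if phi.shape[1] < 2:
        return EventTable(frame=pd.DataFrame())
    if not 1 <= measurement_rotor < phi.shape[1]:
        raise ValueError("measurement rotor must be a chain index >= 1")
    t = traj.t
    dt = float(np.median(np.diff(t)))
    T = mean_period(traj.params)
    win = max(int(round(baseline_periods * T / dt)), 3)

    d = phi[:, measurement_rotor] - phi[:, 0]
    baseline = (
        pd.Series(d).rolling(win, center=True, min_periods=1).median().to_numpy()
    )
    exc = d - baseline

    # peaks of |excursion|; a minimum separation of one period avoids
    # double-counting a single event
    peaks, props = find_peaks(
        np.abs(exc), height=W_min, distance=max(int(T / dt), 1)
    )
    slips = detect_slips(traj).frame

    rows = []
    prev_onset = None
    for p, height in zip(peaks, props["peak_heights"]):
        # onset: last time before the peak that |exc| was below W_min/2
        before = np.nonzero(np.abs(exc[:p]) < W_min / 2.0)[0]
        onset_idx = before[-1] if before.size else 0
        onset = t[onset_idx]
        # require return towards baseline after the peak (no net slip at the
        # measurement pair itself within the window)
        after = np.abs(exc[p : min(p + win, exc.size)])
        if after.size == 0 or after.min() > W_min / 2.0:
            continue
        if prev_onset is not None and onset <= prev_onset:
            # same excursion as the previous event (onset did not advance):
            # keep only the first crossing
            continue
        terminal = np.nan
        if not slips.empty:
            in_window = slips[
                (slips["time"] >= onset) & (slips["time"] <= onset + baseline_periods * T)
            ]
            if not in_window.empty:
                terminal = float(in_window.iloc[0]["index"])
        tau = np.nan if prev_onset is None else onset - prev_onset
        rows.append(
            {
                "kind": "wobble",
                "time": onset,
                "index": measurement_rotor,
                "direction": np.nan,
                "W": float(height),
                "tau": tau,
                "terminal_rotor": terminal,
            }
        )
        prev_onset = onset
    return EventTable(frame=pd.DataFrame(rows))


def order_parameter(traj: Trajectory, t_burn: float = 200.0) -> OrderParameterSeries:
    """Complex order parameter ``Z(t)`` of the chain and its time averages.

    ``Z = (1/(N-1)) sum_n exp(i chi_n)`` over the N-1 neighbouring pairs.
    ``A_bar`` is the time average of ``|Z|`` and ``Psi_bar_abs`` the modulus
    of the circular mean of ``arg Z``, both over ``t > t_burn`` (transient
    discarded).
    """
    if traj.n_rotors < 2:
        raise ValueError("order parameter requires at least two rotors")
    chi, _ = unwrap_and_diff(traj)
    Z = np.mean(np.exp(1j * chi), axis=1)
    A = np.abs(Z)
    Psi = np.angle(Z)
    mask = traj.t > t_burn
    if not mask.any():
        mask = np.ones_like(traj.t, dtype=bool)
    A_bar = float(np.mean(A[mask]))
    # circular mean of the angle: Psi is wrapped, so average the phasor
    mean_phasor = np.mean(np.exp(1j * Psi[mask]))
    Psi_bar_abs = float(abs(np.angle(mean_phasor)))
    return OrderParameterSeries(
        t=traj.t, A=A, Psi=Psi, A_bar=A_bar, Psi_bar_abs=Psi_bar_abs, t_burn=t_burn
    )


def end_to_end_drift_rate(traj: Trajectory, t_burn: float = 200.0) -> float:
    """Net drift rate of ``phi_{N-1} - phi_0`` over ``t > t_burn`` (rad/s)."""
    _, ete = unwrap_and_diff(traj)
    mask = traj.t > t_burn
    if mask.sum() < 2:
        raise ValueError("burn-in removes the whole trajectory")
    t = traj.t[mask]
    e = ete[mask]
    return float((e[-1] - e[0]) / (t[-1] - t[0]))


def drift_per_beat(
    traj: Trajectory, t_burn: float = 200.0, period: float | None = None
) -> float:
    """End-to-end phase drift per mean beat, measured in beats.

    The net change of the unwrapped ``phi_{N-1} - phi_0`` over
    ``(t_burn, t_end)`` in units of 2*pi, divided by the number of beats of
    duration ``period`` in the same window.  ``period`` defaults to the
    nominal chain period ``2*pi/<omega_i>`` set by the drive parameters;
    note the observed rotation is a few percent faster than nominal because
    every rotor is advected by its neighbours' flow fields, so the nominal
    period is the convention that keeps the beat unit independent of the
    coupling strength.
    """
    phi = _unwrapped_phases(traj)
    mask = traj.t > t_burn
    if mask.sum() < 2:
        raise ValueError("burn-in removes the whole trajectory")
    if period is None:
        period = mean_period(traj.params)
    p = phi[mask]
    t = traj.t[mask]
    drift_beats = ((p[-1, -1] - p[-1, 0]) - (p[0, -1] - p[0, 0])) / (2.0 * np.pi)
    n_beats = (t[-1] - t[0]) / period
    return float(drift_beats / n_beats)


def kymograph(traj: Trajectory) -> np.ndarray:
    """Matrix of ``sin(phi_i)`` with shape (n_rotors, n_samples), for plotting."""
    return np.sin(np.asarray(traj.phi, dtype=float)).T
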