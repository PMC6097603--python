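"""Deterministic dynamics of N driven rotors on compliant circular orbits.

Each rotor is a bead held on a circular trajectory of radius ``R`` parallel
to a no-slip wall at height ``h``.  The trap exerts a constant tangential
driving force ``F_i = F_dr * D**(i - 0.5)`` and a radial harmonic restoring
force of stiffness ``lambda_``; the mild geometric detuning ``D`` makes
successive rotors intrinsically faster along the chain.  Beads are coupled
through the Blake point-force tensor (see :mod:`rotorchain.hydrodynamics`);
motion is confined to the orbit plane at height ``h`` (two degrees of
freedom per rotor: orbital phase ``phi_i`` and radial excursion ``rho_i``),
and thermal fluctuations are neglected.

Orbit compliance is the synchronization mechanism: hydrodynamic forcing
deforms the orbit radius, which modulates the instantaneous angular
velocity and lets neighbouring rotors adjust their phases.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from rotorchain.hydrodynamics import (
    FluidContext,
    blake_velocity,
    bulk_drag,
    mobility_velocities,
    wall_drag_correction,
)

__all__ = [
    "GAMMA_FEEDBACK",
    "PhysicalParams",
    "RotorState",
    "Trajectory",
    "driving_force",
    "intrinsic_frequency",
    "mean_period",
    "external_force",
    "rhs",
    "simulate",
]

#: Feedback-delay correction factor: a compliance ``lambda_exp`` realised with
#: delayed-feedback traps behaves like an ideal harmonic trap of stiffness
#: ``GAMMA_FEEDBACK * lambda_exp``.
GAMMA_FEEDBACK = 2.21


@dataclass(frozen=True)
class PhysicalParams:
    """Physical constants and model switches for one scenario (SI units).

    Defaults are the reference colloidal-rotor configuration: silica beads of
    radius 1.74 um on orbits of radius 1.59 um spaced 9.19 um apart in a
    fluid of viscosity 6 mPa s, driven at 2.23 pN with detuning D = 1.01.
    """

    a: float = 1.74e-6  # bead radius (m)
    R: float = 1.59e-6  # orbit radius (m)
    ell: float = 9.19e-6  # centre-to-centre spacing (m)
    h: float = 4.2e-6  # height above the wall (m)
    mu: float = 6.0e-3  # dynamic viscosity (Pa s)
    lambda_: float = 2.06e-6  # radial trap stiffness (N/m)
    F_dr: float = 2.23e-12  # driving-force scale (N)
    D: float = 1.01  # detuning factor (dimensionless)
    N: int = 6  # number of rotors
    truncation: str = "none"  # 'none' or 'nearest_neighbor'
    t_end: float = 2000.0  # integration horizon (s)
    seed: int = 0  # seed for random initial phases
    samples_per_period: int = 100  # output sampling density (per intrinsic period)
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "DOP853"  # any scipy solve_ivp method; use a stiff solver
    #                         (LSODA/Radau) for extreme stiffness values

    def __post_init__(self) -> None:
        for name in ("a", "R", "ell", "h", "mu", "lambda_", "F_dr"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (self.D > 0):
            raise ValueError(f"detuning must be positive, got D={self.D}")
        if self.N < 1:
            raise ValueError(f"need at least one rotor, got N={self.N}")
        if not (self.R < self.ell / 2):
            raise ValueError("orbit radius must be smaller than half the spacing")
        if self.truncation not in ("none", "nearest_neighbor"):
            raise ValueError(f"unknown truncation mode: {self.truncation!r}")
        if not (self.h > self.a):
            raise ValueError("orbit height must exceed the bead radius")
        if self.samples_per_period < 50:
            raise ValueError("need at least 50 samples per period to resolve the orbits")

    @property
    def fluid(self) -> FluidContext:
        return FluidContext(mu=self.mu, a=self.a)

    def replace(self, **kwargs) -> "PhysicalParams":
        return dataclasses.replace(self, **kwargs)

    def with_feedback_corrected_lambda(self, gamma: float = GAMMA_FEEDBACK) -> "PhysicalParams":
        """Convert an experimentally calibrated stiffness to its simulation
        equivalent, ``lambda_sim = gamma * lambda_exp``, compensating the
        softening introduced by trap feedback delay."""
        return self.replace(lambda_=gamma * self.lambda_)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhysicalParams":
        d = dict(d)
        if d.pop("lambda_is_experimental", False):
            d["lambda_"] = GAMMA_FEEDBACK * d["lambda_"]
        return cls(**d)


@dataclass
class RotorState:
    """Instantaneous chain state: orbital phases (rad) and radial excursions (m)."""

    phi: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if self.phi.shape != self.rho.shape:
            raise ValueError("phi and rho must have the same length")
        if np.any(self.rho <= 0):
            raise ValueError("radial excursions must be positive")


@dataclass
class Trajectory:
    """Sampled chain trajectory: times (s), phases (rad) and radii (m) per rotor."""

    t: np.ndarray
    phi: np.ndarray  # shape (n_samples, N)
    rho: np.ndarray  # shape (n_samples, N)
    params: PhysicalParams

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.phi.shape != self.rho.shape or self.phi.shape[0] != self.t.size:
            raise ValueError("inconsistent trajectory shapes")

    @property
    def n_rotors(self) -> int:
        return self.phi.shape[1]

    def to_frame(self) -> pd.DataFrame:
        n = self.n_rotors
        data = {"time": self.t}
        for i in range(n):
            data[f"phi_{i}"] = self.phi[:, i]
        for i in range(n):
            data[f"rho_{i}"] = self.rho[:, i]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        """Write the trajectory as CSV with a JSON parameter sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        path.with_suffix(".params.json").write_text(
            json.dumps(self.params.to_dict(), indent=2)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        df = pd.read_csv(path)
        n = sum(1 for c in df.columns if c.startswith("phi_"))
        sidecar = path.with_suffix(".params.json")
        if sidecar.exists():
            params = PhysicalParams.from_dict(json.loads(sidecar.read_text()))
        else:
            params = PhysicalParams(N=n)
        phi = df[[f"phi_{i}" for i in range(n)]].to_numpy()
        rho = df[[f"rho_{i}" for i in range(n)]].to_numpy()
        return cls(t=df["time"].to_numpy(), phi=phi, rho=rho, params=params)


def driving_force(i: int, params: PhysicalParams) -> float:
    """Tangential driving force ``F_i = F_dr * D**(i - 0.5)`` on rotor ``i`` (N).

    The half-integer exponent centres the geometric frequency ladder on
    ``F_dr`` so that the product ``F_i F_{i+1} = F_dr^2 D^{2i}`` is close to
    ``F_dr^2`` for every neighbouring pair.
    """
    if not 0 <= i < params.N:
        raise IndexError(f"rotor index {i} outside 0..{params.N - 1}")
    return params.F_dr * params.D ** (i - 0.5)


def intrinsic_frequency(i: int, params: PhysicalParams) -> float:
    """Angular velocity ``omega_i = F_i / (R zeta0 zeta_w(h))`` of rotor ``i``
    in isolation (rad/s)."""
    zeta0 = bulk_drag(params.fluid)
    zw = wall_drag_correction(params.a, params.h)
    return driving_force(i, params) / (params.R * zeta0 * zw)


def mean_period(params: PhysicalParams) -> float:
    """Chain-averaged intrinsic rotation period 2*pi/<omega_i> (s)."""
    omegas = [intrinsic_frequency(i, params) for i in range(params.N)]
    return 2.0 * np.pi / np.mean(omegas)


def external_force(state_i: tuple[float, float], i: int, params: PhysicalParams) -> np.ndarray:
    """Net trap force on rotor ``i``: constant tangential drive plus radial spring.

    ``state_i`` is the pair ``(phi_i, rho_i)``.  Returns the 3-vector
    ``F_i * t_hat - lambda_ * (rho_i - R) * r_hat`` in the orbit plane
    (zero wall-normal component).
    """
    phi, rho = state_i
    if rho <= 0:
        raise ValueError("radial excursion must be positive (tangent undefined at rho=0)")
    tangent = np.array([-np.sin(phi), np.cos(phi), 0.0])
    radial = np.array([np.cos(phi), np.sin(phi), 0.0])
    return driving_force(i, params) * tangent - params.lambda_ * (rho - params.R) * radial


@lru_cache(maxsize=32)
def _sim_constants(params: PhysicalParams):
    """Precomputed per-scenario constants for the right-hand side."""
    n = params.N
    zeta0 = bulk_drag(params.fluid)
    zw = wall_drag_correction(params.a, params.h)
    forces = np.array([driving_force(i, params) for i in range(n)])
    centers = np.zeros((n, 3))
    centers[:, 0] = np.arange(n) * params.ell
    centers[:, 2] = params.h
    ii, jj = np.nonzero(~np.eye(n, dtype=bool))
    if params.truncation == "nearest_neighbor":
        keep = np.abs(ii - jj) == 1
        ii, jj = ii[keep], jj[keep]
    return zeta0 * zw, forces, centers, ii, jj


def rhs(t: float, state: np.ndarray, params: PhysicalParams) -> np.ndarray:
    """Time derivatives ``(phi_dot_0..N-1, rho_dot_0..N-1)`` of the chain.

    Bead velocities follow the mobility relation
    ``v_i = F_i^ext/(zeta0 zeta_w) + sum_{j != i} G(x_j, x_i) . F_j^ext``
    with the trap force as the only external force; the wall-normal velocity
    component is discarded (planar confinement) and the in-plane velocity is
    projected on the local tangent and radial directions.
    """
    n = params.N
    phi = state[:n]
    rho = state[n:]
    drag, fdrive, centers, ii, jj = _sim_constants(params)

    cos_p = np.cos(phi)
    sin_p = np.sin(phi)
    pos = centers.copy()
    pos[:, 0] += rho * cos_p
    pos[:, 1] += rho * sin_p

    spring = params.lambda_ * (rho - params.R)
    forces = np.zeros((n, 3))
    forces[:, 0] = -fdrive * sin_p - spring * cos_p
    forces[:, 1] = fdrive * cos_p - spring * sin_p

    v = forces / drag
    if ii.size:
        v = v + _pair_velocities(pos, forces, ii, jj, params.mu, params.h)

    phi_dot = (-v[:, 0] * sin_p + v[:, 1] * cos_p) / rho
    rho_dot = v[:, 0] * cos_p + v[:, 1] * sin_p
    return np.concatenate([phi_dot, rho_dot])


def _pair_velocities(pos, forces, ii, jj, mu, h):
    """Coupling flow at each bead from all partner beads (wall-image kernel).

    Inlined version of the Blake kernel of :mod:`rotorchain.hydrodynamics`
    specialised to in-plane forces at a common height ``h``; verified against
    :func:`rotorchain.hydrodynamics.mobility_velocities` in the test suite.
    """
    n = pos.shape[0]
    src = pos[jj]
    tgt = pos[ii]
    f = forces[jj]

    r = tgt - src
    R = r.copy()
    R[:, 2] = 2.0 * h  # image separation: targets at z=h, images at z=-h

    def stokeslet(rv):
        d2 = np.einsum("pi,pi->p", rv, rv)
        d = np.sqrt(d2)
        rf = np.einsum("pi,pi->p", rv, f)
        return f / d[:, None] + rv * (rf / (d * d2))[:, None]

    u = stokeslet(r) - stokeslet(R)

    R2 = np.einsum("pi,pi->p", R, R)
    Rn = np.sqrt(R2)
    R3 = Rn * R2
    R5 = R3 * R2
    RdotF = np.einsum("pi,pi->p", R, f)  # forces are in-plane: mirror force == force
    Rz = R[:, 2]

    doublet = f / R3[:, None] - 3.0 * R * (RdotF / R5)[:, None]
    sdoublet = (f * Rz[:, None]) / R3[:, None] - 3.0 * R * (Rz * RdotF / R5)[:, None]
    sdoublet[:, 2] -= RdotF / R3

    u += 2.0 * h * (h * doublet - sdoublet)
    u /= 8.0 * np.pi * mu

    out = np.zeros((n, 3))
    np.add.at(out, ii, u)
    return out


def initial_state(params: PhysicalParams, initial: RotorState | int | None = None) -> RotorState:
    """Resolve an initial condition: explicit state, seed, or the params seed.

    Default initial condition: every bead exactly on its orbit
    (``rho_i = R``) with phases drawn uniformly from [0, 2*pi).
    """
    if isinstance(initial, RotorState):
        if initial.phi.size != params.N:
            raise ValueError("initial state size does not match rotor count")
        return initial
    seed = params.seed if initial is None else int(initial)
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2.0 * np.pi, size=params.N)
    return RotorState(phi=phi0, rho=np.full(params.N, params.R))


def simulate(params: PhysicalParams, initial: RotorState | int | None = None) -> Trajectory:
    """Integrate the chain over ``[0, t_end]`` and sample it densely.

    Uses an adaptive high-order Runge-Kutta scheme (DOP853) at tight
    tolerances; output is sampled on a uniform grid with
    ``samples_per_period`` points per mean intrinsic period.  The result is
    deterministic for a given ``(params, initial)``.
    """
    state0 = initial_state(params, initial)
    y0 = np.concatenate([state0.phi, state0.rho])
    dt = mean_period(params) / params.samples_per_period
    n_samples = max(int(np.floor(params.t_end / dt)), 2)
    t_eval = np.linspace(0.0, params.t_end, n_samples + 1)

    sol = solve_ivp(
        rhs,
        (0.0, params.t_end),
        y0,
        args=(params,),
        method=params.method,
        rtol=params.rtol,
        atol=params.atol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed for params={params}: {sol.message}"
        )
    n = params.N
    return Trajectory(t=sol.t, phi=sol.y[:n].T, rho=sol.y[n:].T, params=params)
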