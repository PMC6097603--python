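"""Green's functions and drag coefficients for Stokes flow near a plane no-slip wall.

The wall is the plane z = 0 and the fluid occupies z > 0.  A point force
(Stokeslet) at height ``h`` above the wall generates the flow of the Blake
image system: the free-space Stokeslet plus an image Stokeslet, a Stokes
doublet and a source doublet located at the mirror point ``z = -h``.  The
resulting velocity field vanishes identically on the wall plane.

Beads are treated as point forces for mutual coupling (far field); the
finite bead size enters only through the self-drag ``zeta0 * zeta_w(h)``,
with the wall correction truncated at first order in ``a/h``.

All quantities are SI: positions in metres, forces in newtons, viscosity in
pascal-seconds, velocities in metres per second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FluidContext",
    "bulk_drag",
    "wall_drag_correction",
    "oseen_tensor",
    "blake_velocity",
    "blake_tensor",
    "mobility_velocities",
]

_MIRROR = np.array([1.0, 1.0, -1.0])


@dataclass(frozen=True)
class FluidContext:
    """Fluid and bead properties shared by all hydrodynamic operations.

    Parameters
    ----------
    mu : float
        Dynamic viscosity of the suspending fluid (Pa s).
    a : float
        Bead radius (m).
    """

    mu: float
    a: float

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise ValueError(f"viscosity must be positive, got mu={self.mu}")
        if not (self.a > 0):
            raise ValueError(f"bead radius must be positive, got a={self.a}")


def bulk_drag(ctx: FluidContext) -> float:
    """Stokes drag coefficient ``zeta0 = 6 pi mu a`` of a sphere in bulk fluid (N s/m)."""
    return 6.0 * np.pi * ctx.mu * ctx.a


def wall_drag_correction(a: float, h: float) -> float:
    """Wall-parallel drag enhancement ``zeta_w(h) = 1 + (9/16)(a/h)`` for a sphere
    translating parallel to a no-slip wall at height ``h``.

    The correction is the leading term of the method-of-reflections series;
    it decreases monotonically to 1 as ``h -> inf``.  Requires ``h > a``
    (bead centre above the wall by more than one radius).
    """
    a = float(a)
    h = float(h)
    if not (a > 0):
        raise ValueError(f"bead radius must be positive, got a={a}")
    if not (h > a):
        raise ValueError(f"height must exceed bead radius, got h={h}, a={a}")
    return 1.0 + (9.0 / 16.0) * (a / h)


def oseen_tensor(r: np.ndarray, mu: float) -> np.ndarray:
    """Free-space Oseen tensor ``(I/|r| + r r^T/|r|^3) / (8 pi mu)`` for separation ``r``."""
    r = np.asarray(r, dtype=float)
    d = np.linalg.norm(r)
    if d == 0.0:
        raise ValueError("Oseen tensor is singular at zero separation")
    return (np.eye(3) / d + np.outer(r, r) / d**3) / (8.0 * np.pi * mu)


def _stokeslet_apply(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Apply the unscaled Stokeslet kernel ``I/|r| + r r^T/|r|^3`` to forces.

    ``r`` and ``f`` have shape (..., 3); the 1/(8 pi mu) prefactor is left out.
    """
    d = np.sqrt(np.einsum("...i,...i->...", r, r))
    rf = np.einsum("...i,...i->...", r, f)
    return f / d[..., None] + r * (rf / d**3)[..., None]


def blake_velocity(
    sources: np.ndarray,
    targets: np.ndarray,
    forces: np.ndarray,
    mu: float,
) -> np.ndarray:
    """Velocity at ``targets`` induced by point forces at ``sources`` above a no-slip wall.

    Vectorised over leading dimensions: all three arrays broadcast to shape
    (..., 3) and the result has the broadcast shape.  Each source must lie
    strictly above the wall; targets may lie on the wall (where the returned
    velocity is zero to rounding) but not below it.

    This is the Blake image construction: writing ``y* `` for the mirror
    image of the source and ``R = x - y*``, the field is the free-space
    Stokeslet minus an image Stokeslet plus Stokes-doublet and
    source-doublet corrections proportional to the source height.
    """
    sources = np.asarray(sources, dtype=float)
    targets = np.asarray(targets, dtype=float)
    forces = np.asarray(forces, dtype=float)
    sources, targets, forces = np.broadcast_arrays(sources, targets, forces)

    hs = sources[..., 2]
    if np.any(hs <= 0.0):
        raise ValueError("source points must lie strictly above the wall (z > 0)")
    if np.any(targets[..., 2] < 0.0):
        raise ValueError("target points must not lie below the wall (z >= 0)")

    r = targets - sources
    if np.any(np.einsum("...i,...i->...", r, r) == 0.0):
        raise ValueError("source and target coincide; the Stokeslet is singular")

    image = sources * _MIRROR  # mirror point y* = (y1, y2, -h)
    R = targets - image
    Rsq = np.einsum("...i,...i->...", R, R)
    Rn = np.sqrt(Rsq)
    R3 = Rn * Rsq
    R5 = R3 * Rsq

    f_m = forces * _MIRROR  # mirror-reflected force
    RdotFm = np.einsum("...i,...i->...", R, f_m)

    u = _stokeslet_apply(r, forces) - _stokeslet_apply(R, forces)

    # Source doublet at the image point: 2 h^2 * grad of (R_i / R^3), contracted
    # with the mirrored force.
    doublet = f_m / R3[..., None] - 3.0 * R * (RdotFm / R5)[..., None]

    # Stokes doublet (gradient of the vertical Stokeslet column).
    Rz = R[..., 2]
    sdoublet = np.zeros_like(u)
    sdoublet += (f_m * Rz[..., None] + R * f_m[..., 2:3]) / R3[..., None]
    sdoublet -= 3.0 * R * (Rz * RdotFm / R5)[..., None]
    sdoublet[..., 2] -= RdotFm / R3

    u += 2.0 * hs[..., None] * (hs[..., None] * doublet - sdoublet)
    return u / (8.0 * np.pi * mu)


def blake_tensor(source: np.ndarray, target: np.ndarray, ctx: FluidContext) -> np.ndarray:
    """3x3 Green's function G(source, target) of Stokes flow above a no-slip wall.

    ``G[i, k]`` is the i-component of velocity at ``target`` per unit k-force
    at ``source`` (units m / (N s)).  Satisfies the reciprocal relation
    ``G(x, y) = G(y, x)^T`` and reduces to the free-space Oseen tensor when
    both points are far from the wall.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    cols = blake_velocity(
        np.broadcast_to(source, (3, 3)),
        np.broadcast_to(target, (3, 3)),
        np.eye(3),
        ctx.mu,
    )
    return cols.T.copy()


def mobility_velocities(
    positions: np.ndarray,
    forces: np.ndarray,
    ctx: FluidContext,
    truncation: str = "none",
) -> np.ndarray:
    """Bead velocities from the force balance above a no-slip wall.

    ``v_i = F_i / (zeta0 * zeta_w(h_i)) + sum_{j != i} G(x_j, x_i) . F_j``

    Self-mobility uses the explicit wall-corrected drag; the cross terms use
    the point-force Blake coupling.  With ``truncation='nearest_neighbor'``
    the sum is restricted to ``|i - j| = 1`` (list order defines chain order).

    Parameters
    ----------
    positions, forces : (N, 3) arrays
        Bead centres (z > 0) and the net external force on each bead.
    truncation : {'none', 'nearest_neighbor'}
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    forces = np.atleast_2d(np.asarray(forces, dtype=float))
    if positions.shape != forces.shape or positions.shape[1] != 3:
        raise ValueError("positions and forces must both have shape (N, 3)")
    if truncation not in ("none", "nearest_neighbor"):
        raise ValueError(f"unknown truncation mode: {truncation!r}")
    n = positions.shape[0]

    zeta0 = bulk_drag(ctx)
    zw = np.array([wall_drag_correction(ctx.a, h) for h in positions[:, 2]])
    v = forces / (zeta0 * zw[:, None])
    if n == 1:
        return v

    ii, jj = np.nonzero(~np.eye(n, dtype=bool))
    if truncation == "nearest_neighbor":
        keep = np.abs(ii - jj) == 1
        ii, jj = ii[keep], jj[keep]

    sep = positions[ii] - positions[jj]
    if np.any(np.einsum("pi,pi->p", sep, sep) == 0.0):
        raise ValueError("overlapping bead positions")

    u = blake_velocity(positions[jj], positions[ii], forces[jj], ctx.mu)
    np.add.at(v, ii, u)
    return v
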