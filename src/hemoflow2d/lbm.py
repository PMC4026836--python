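"""D2Q9 lattice-Boltzmann solver with Guo body forcing.

Single-relaxation-time (BGK) collision with a per-node relaxation time (the
indicator field switches between plasma and cytoplasm viscosity), Guo's
second-order body-force scheme with the half-step velocity correction, and
the two wall treatments needed here: periodic sides, and halfway bounce-back
walls that may translate tangentially (Couette shear driver).

Everything in this module is in lattice units (h = dt = 1, c_s^2 = 1/3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "CX",
    "CY",
    "W",
    "OPP",
    "CS2",
    "DomainSpec",
    "FluidState",
    "SimulationDiverged",
    "equilibrium",
    "guo_force_term",
    "macroscopics",
    "collide_and_stream",
]

CX = np.array([0, 1, 0, -1, 0, 1, -1, -1, 1], dtype=np.int64)
CY = np.array([0, 0, 1, 0, -1, 1, 1, -1, -1], dtype=np.int64)
W = np.array(
    [4 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 36, 1 / 36, 1 / 36, 1 / 36]
)
OPP = np.array([0, 3, 4, 1, 2, 7, 8, 5, 6], dtype=np.int64)
CS2 = 1.0 / 3.0


class SimulationDiverged(RuntimeError):
    """NaN or negative-population blow-up, annotated with the step index."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


@dataclass
class DomainSpec:
    """Lattice extents and boundary descriptors.

    x is always periodic.  ``y_boundary`` is ``"periodic"`` or ``"wall"``
    (halfway bounce-back at y = 0 and y = Ny, optionally translating with
    tangential velocities ``u_wall_bottom`` / ``u_wall_top`` in lattice
    units).  Lattice node (i, j) sits at position ((i+0.5) h, (j+0.5) h).
    """

    Nx: int
    Ny: int
    y_boundary: str = "periodic"
    u_wall_bottom: float = 0.0
    u_wall_top: float = 0.0

    def __post_init__(self) -> None:
        if self.Nx < 8 or self.Ny < 8:
            raise ValueError("lattice extents must be at least 8")
        if self.y_boundary not in ("periodic", "wall"):
            raise ValueError(f"unknown y boundary {self.y_boundary!r}")
        if self.y_boundary == "periodic" and (
            self.u_wall_bottom or self.u_wall_top
        ):
            raise ValueError("wall velocities require y_boundary='wall'")


class FluidState:
    """D2Q9 distributions plus macroscopic and forcing fields."""

    def __init__(self, spec: DomainSpec, tau: float = 1.0):
        shape = (spec.Nx, spec.Ny)
        self.spec = spec
        self.f = np.empty((9,) + shape)
        self._f_post = np.empty_like(self.f)
        self.rho = np.ones(shape)
        self.u = np.zeros((2,) + shape)
        self.F_f = np.zeros((2,) + shape)
        self.tau_field = np.full(shape, float(tau))
        self.f[:] = equilibrium(self.rho, self.u)

    def initialize(self, rho=1.0, u=(0.0, 0.0)) -> None:
        self.rho[:] = rho
        u = np.asarray(u, dtype=float)
        if u.ndim == 1:
            self.u[0], self.u[1] = u
        else:
            self.u[:] = u
        self.f[:] = equilibrium(self.rho, self.u)

    def check_health(self, step: int | None = None) -> None:
        if not np.all(np.isfinite(self.f)):
            raise SimulationDiverged("non-finite distribution", step)
        if np.any(self.f < 0):
            raise SimulationDiverged("negative population", step)


def equilibrium(rho, u):
    """Second-order equilibrium distributions f_i^eq(rho, u).

    Moments sum(f_eq) = rho and sum(f_eq c_i) = rho u hold algebraically.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    cu = CX.reshape(9, *([1] * u[0].ndim)) * u[0] + CY.reshape(
        9, *([1] * u[1].ndim)
    ) * u[1]
    usq = u[0] ** 2 + u[1] ** 2
    w = W.reshape(9, *([1] * rho.ndim))
    return w * rho * (1.0 + cu / CS2 + 0.5 * (cu / CS2) ** 2 - 0.5 * usq / CS2)


def guo_force_term(u, F_f, tau):
    """Guo forcing contributions B_i for velocity u, body force F_f, tau.

    sum(B_i) = 0 and sum(B_i c_i) = (1 - 1/(2 tau)) F_f algebraically.
    """
    u = np.asarray(u, dtype=float)
    F = np.asarray(F_f, dtype=float)
    nd = u[0].ndim
    cx = CX.reshape(9, *([1] * nd))
    cy = CY.reshape(9, *([1] * nd))
    w = W.reshape(9, *([1] * nd))
    cu = cx * u[0] + cy * u[1]
    bx = (cx - u[0]) / CS2 + cu * cx / CS2**2
    by = (cy - u[1]) / CS2 + cu * cy / CS2**2
    return (1.0 - 0.5 / tau) * w * (bx * F[0] + by * F[1])


def macroscopics(f, F_f=None):
    """Density and velocity moments with the half-step force correction."""
    f = np.asarray(f, dtype=float)
    rho = f.sum(axis=0)
    nd = rho.ndim
    cx = CX.reshape(9, *([1] * nd))
    cy = CY.reshape(9, *([1] * nd))
    mx = (f * cx).sum(axis=0)
    my = (f * cy).sum(axis=0)
    if F_f is not None:
        F = np.asarray(F_f, dtype=float)
        mx = mx + 0.5 * F[0]
        my = my + 0.5 * F[1]
    return rho, np.stack([mx / rho, my / rho])


@njit(cache=True)
def _collide(f, f_post, tau_field, Fx, Fy, rho, ux, uy):
    Nx = f.shape[1]
    Ny = f.shape[2]
    cx = (0, 1, 0, -1, 0, 1, -1, -1, 1)
    cy = (0, 0, 1, 0, -1, 1, 1, -1, -1)
    w = (
        4.0 / 9.0, 1.0 / 9.0, 1.0 / 9.0, 1.0 / 9.0, 1.0 / 9.0,
        1.0 / 36.0, 1.0 / 36.0, 1.0 / 36.0, 1.0 / 36.0,
    )
    for x in range(Nx):
        for y in range(Ny):
            r = 0.0
            mx = 0.0
            my = 0.0
            for i in range(9):
                fi = f[i, x, y]
                r += fi
                mx += fi * cx[i]
                my += fi * cy[i]
            fx = Fx[x, y]
            fy = Fy[x, y]
            vx = (mx + 0.5 * fx) / r
            vy = (my + 0.5 * fy) / r
            rho[x, y] = r
            ux[x, y] = vx
            uy[x, y] = vy
            tau = tau_field[x, y]
            om = 1.0 / tau
            bpre = 1.0 - 0.5 * om
            usq = vx * vx + vy * vy
            for i in range(9):
                cu = cx[i] * vx + cy[i] * vy
                feq = w[i] * r * (
                    1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq
                )
                bi = bpre * w[i] * (
                    (3.0 * (cx[i] - vx) + 9.0 * cu * cx[i]) * fx
                    + (3.0 * (cy[i] - vy) + 9.0 * cu * cy[i]) * fy
                )
                f_post[i, x, y] = f[i, x, y] - om * (f[i, x, y] - feq) + bi


@njit(cache=True)
def _stream(f, f_post, rho, walls, u_bot, u_top):
    Nx = f.shape[1]
    Ny = f.shape[2]
    cx = (0, 1, 0, -1, 0, 1, -1, -1, 1)
    cy = (0, 0, 1, 0, -1, 1, 1, -1, -1)
    opp = (0, 3, 4, 1, 2, 7, 8, 5, 6)
    w = (
        4.0 / 9.0, 1.0 / 9.0, 1.0 / 9.0, 1.0 / 9.0, 1.0 / 9.0,
        1.0 / 36.0, 1.0 / 36.0, 1.0 / 36.0, 1.0 / 36.0,
    )
    for x in range(Nx):
        for y in range(Ny):
            for i in range(9):
                xs = x - cx[i]
                if xs < 0:
                    xs += Nx
                elif xs >= Nx:
                    xs -= Nx
                ys = y - cy[i]
                if 0 <= ys < Ny:
                    f[i, x, y] = f_post[i, xs, ys]
                elif walls:
                    # halfway bounce-back with Ladd moving-wall correction
                    uw = u_bot if ys < 0 else u_top
                    f[i, x, y] = (
                        f_post[opp[i], x, y]
                        + 6.0 * w[i] * rho[x, y] * cx[i] * uw
                    )
                else:  # periodic in y
                    ys = ys % Ny
                    f[i, x, y] = f_post[i, xs, ys]


def collide_and_stream(state: FluidState, spec: DomainSpec | None = None) -> None:
    """Advance the fluid one time step (BGK collision + Guo forcing + streaming).

    Updates ``state.rho`` and ``state.u`` to the pre-streaming moments
    (including the half-step force correction) as a side effect.
    """
    spec = spec or state.spec
    _collide(
        state.f,
        state._f_post,
        state.tau_field,
        state.F_f[0],
        state.F_f[1],
        state.rho,
        state.u[0],
        state.u[1],
    )
    _stream(
        state.f,
        state._f_post,
        state.rho,
        spec.y_boundary == "wall",
        spec.u_wall_bottom,
        spec.u_wall_top,
    )
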