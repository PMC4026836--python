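"""Immersed-boundary coupling between membrane nodes and the lattice.

Velocity interpolation and force spreading use the 2D cosine discrete delta
function with a 4h x 4h support,

    phi(r) = 1/(4 h^2) (1 + cos(pi r_x / 2h)) (1 + cos(pi r_y / 2h)),

which satisfies the partition of unity exactly on the lattice.  Spreading
and interpolation use the identical kernel, so the two operators are exact
adjoints of each other.  Near bounce-back walls the part of the kernel
support that falls outside the fluid is folded back by mirror reflection
(identically in both directions, preserving both the adjointness and the
total spread force).

The indicator field labels every lattice node as plasma or as cytoplasm of
a specific cell by a scanline interior fill of each membrane polygon, and
drives the per-node relaxation-time (viscosity) switch.

Lattice node (i, j) sits at position ((i+0.5) h, (j+0.5) h); all positions
in this module are in lattice units (h = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "delta_phi",
    "interpolate_velocity",
    "spread_force",
    "update_indicator",
    "IndicatorField",
]

_MAX_CROSS = 64


@njit(cache=True)
def _phi1(r):
    if r < -2.0 or r > 2.0:
        return 0.0
    return 0.25 * (1.0 + math.cos(0.5 * math.pi * r))


@njit(cache=True)
def _fold_y(j, Ny, walls):
    """Map a raw row index into the lattice: mirror at walls, else wrap."""
    if walls:
        if j < 0:
            return -1 - j
        if j >= Ny:
            return 2 * Ny - 1 - j
        return j
    return j % Ny


@njit(cache=True)
def _interpolate(ux, uy, X, out, walls):
    Nx, Ny = ux.shape
    n = X.shape[0]
    for m in range(n):
        px, py = X[m, 0], X[m, 1]
        ib = int(math.floor(px - 0.5)) - 1
        jb = int(math.floor(py - 0.5)) - 1
        sx = 0.0
        sy = 0.0
        for di in range(4):
            i = ib + di
            wx = _phi1(i + 0.5 - px)
            if wx == 0.0:
                continue
            ii = i % Nx
            for dj in range(4):
                j = jb + dj
                wy = _phi1(j + 0.5 - py)
                if wy == 0.0:
                    continue
                jj = _fold_y(j, Ny, walls)
                w = wx * wy
                sx += w * ux[ii, jj]
                sy += w * uy[ii, jj]
        out[m, 0] = sx
        out[m, 1] = sy


@njit(cache=True)
def _spread(Fx, Fy, X, Fm, walls):
    Nx, Ny = Fx.shape
    n = X.shape[0]
    for m in range(n):
        px, py = X[m, 0], X[m, 1]
        fx, fy = Fm[m, 0], Fm[m, 1]
        ib = int(math.floor(px - 0.5)) - 1
        jb = int(math.floor(py - 0.5)) - 1
        for di in range(4):
            i = ib + di
            wx = _phi1(i + 0.5 - px)
            if wx == 0.0:
                continue
            ii = i % Nx
            for dj in range(4):
                j = jb + dj
                wy = _phi1(j + 0.5 - py)
                if wy == 0.0:
                    continue
                jj = _fold_y(j, Ny, walls)
                w = wx * wy
                Fx[ii, jj] += w * fx
                Fy[ii, jj] += w * fy


@njit(cache=True)
def _fill_labels(labels, Xc):
    """Scanline interior fill of every cell polygon into ``labels``.

    ``Xc`` is (n_cells, n_nodes, 2) in lattice units; x may be unwrapped
    (the fill wraps columns periodically).  Returns 0 on success, or
    (cell_id + 1) when a row meets an odd crossing count, the signature of a
    degenerate / self-intersecting polygon.
    """
    Nx, Ny = labels.shape
    labels[:] = 0
    xs = np.empty(_MAX_CROSS)
    nc, nn = Xc.shape[0], Xc.shape[1]
    for c in range(nc):
        ylo = Xc[c, 0, 1]
        yhi = ylo
        for m in range(1, nn):
            y = Xc[c, m, 1]
            if y < ylo:
                ylo = y
            if y > yhi:
                yhi = y
        jlo = int(math.floor(ylo - 0.5))
        jhi = int(math.ceil(yhi - 0.5))
        for j in range(max(jlo, 0), min(jhi, Ny - 1) + 1):
            yline = j + 0.5
            ncr = 0
            for m in range(nn):
                m1 = (m + 1) % nn
                y0 = Xc[c, m, 1]
                y1 = Xc[c, m1, 1]
                if (y0 <= yline < y1) or (y1 <= yline < y0):
                    x0 = Xc[c, m, 0]
                    x1 = Xc[c, m1, 0]
                    if ncr >= _MAX_CROSS:
                        return c + 1
                    xs[ncr] = x0 + (yline - y0) * (x1 - x0) / (y1 - y0)
                    ncr += 1
            if ncr % 2 == 1:
                return c + 1
            # insertion sort of the crossings
            for a in range(1, ncr):
                v = xs[a]
                b = a - 1
                while b >= 0 and xs[b] > v:
                    xs[b + 1] = xs[b]
                    b -= 1
                xs[b + 1] = v
            for k in range(0, ncr, 2):
                i0 = int(math.ceil(xs[k] - 0.5))
                i1 = int(math.floor(xs[k + 1] - 0.5))
                if xs[k + 1] - 0.5 == i1:  # node exactly on the boundary
                    i1 -= 1
                for i in range(i0, i1 + 1):
                    labels[i % Nx, j] = c + 1
    return 0


def delta_phi(r, h: float = 1.0):
    """Cosine discrete delta phi(r) for a 2-vector displacement ``r``.

    phi(r) = 1/(16 h^2) (1 + cos(pi r_x/2h)) (1 + cos(pi r_y/2h)) on the
    4h x 4h support.  The 1/(16 h^2) prefactor is the normalization for
    which the kernel is an exact partition of unity on the lattice,
    sum_grid phi(x_f - X) h^2 = 1 for every X; the peak value is
    phi(0) = 1/(4 h^2).
    """
    r = np.asarray(r, dtype=float)
    px = np.where(
        np.abs(r[..., 0]) <= 2 * h,
        1.0 + np.cos(0.5 * np.pi * r[..., 0] / h),
        0.0,
    )
    py = np.where(
        np.abs(r[..., 1]) <= 2 * h,
        1.0 + np.cos(0.5 * np.pi * r[..., 1] / h),
        0.0,
    )
    out = px * py / (16.0 * h * h)
    return out if out.ndim else float(out)


def interpolate_velocity(u_field, X, walls: bool = False):
    """Interpolate a lattice velocity field at membrane positions ``X``.

    ``u_field`` is (2, Nx, Ny); ``X`` is (n, 2) (or (2,)) in lattice units.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty_like(X)
    _interpolate(
        np.ascontiguousarray(u_field[0]),
        np.ascontiguousarray(u_field[1]),
        np.ascontiguousarray(X),
        out,
        walls,
    )
    return out if out.shape[0] > 1 else out[0]


def spread_force(F_m, X, shape, walls: bool = False):
    """Spread nodal forces onto a fresh (2, Nx, Ny) body-force field.

    Total spread force equals the total nodal force to machine precision
    (including near walls, where out-of-domain weights are folded back).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    F_m = np.atleast_2d(np.asarray(F_m, dtype=float))
    F_f = np.zeros((2,) + tuple(shape))
    _spread(F_f[0], F_f[1], np.ascontiguousarray(X), np.ascontiguousarray(F_m), walls)
    return F_f


@dataclass
class IndicatorField:
    """Per-lattice-node label: 0 = plasma, c+1 = cytoplasm of cell c."""

    labels: np.ndarray

    def cell_area(self, cell_id: int) -> int:
        return int(np.count_nonzero(self.labels == cell_id + 1))

    def tau_field(self, tau_plasma: float, tau_cyto: float) -> np.ndarray:
        return np.where(self.labels > 0, tau_cyto, tau_plasma)


def update_indicator(meshes_X, shape, walls: bool = False) -> IndicatorField:
    """Label lattice nodes inside each membrane polygon as that cell's cytoplasm.

    ``meshes_X`` is (n_cells, n_nodes, 2) in lattice units (x possibly
    unwrapped across the periodic boundary).  Raises ``ValueError`` naming
    the cell when a polygon is degenerate or self-intersecting — the
    buckling failure signal.
    """
    from .membrane import _self_intersects

    labels = np.zeros(tuple(shape), dtype=np.int32)
    Xc = np.ascontiguousarray(np.asarray(meshes_X, dtype=float))
    if Xc.ndim == 2:
        Xc = Xc[None]
    for c in range(Xc.shape[0]):
        if _self_intersects(Xc[c]):
            raise ValueError(f"membrane polygon of cell {c} is self-intersecting")
    bad = _fill_labels(labels, Xc)
    if bad:
        raise ValueError(f"membrane polygon of cell {bad - 1} is degenerate")
    return IndicatorField(labels=labels)
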