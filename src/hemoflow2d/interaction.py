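"""Morse-potential aggregation and repulsion between cells.

Depletion-mediated attraction and steric repulsion between membrane nodes of
distinct cells follow the Morse pair potential

    phi(r) = D_e [e^(2 beta (r0 - r)) - 2 e^(beta (r0 - r))],

with force F(r) = -dphi/dr = 2 beta D_e [e^(2 beta (r0-r)) - e^(beta (r0-r))]
(positive = repulsion).  In the strain-hardened model the repulsive branch
(r <= r0) is additionally multiplied by alpha(lambda_C) of the paired cell,
so crowded, stretched cells resist interpenetration; the attractive branch
is never scaled.  Beyond the active distance ``R_active`` the force is cut
off to zero.

Each membrane node is paired with at most one partner: the nearest foreign
node within ``R_active`` (spatial-hash query, exact lowest-(cell, node)
tie-break); forces are applied equal and opposite along the connecting line,
so the interaction conserves momentum exactly.

``morse_potential`` / ``morse_force`` work in the native micrometre-based
units of the parameters; the flow engine converts the force scale into its
lattice system (see docs/methods.md on the surface-energy unit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .membrane import CaseFlags, _alpha
from .units import PhysicalParams

__all__ = [
    "InteractionParams",
    "morse_potential",
    "morse_force",
    "pair_nodes",
]


@dataclass(frozen=True)
class InteractionParams:
    """Morse parameters: well depth, decay rate, zero-force and cutoff radii."""

    D_e: float = 1.3e-7
    beta_morse: float = 3.84
    r_0: float = 0.49
    R_active: float = 0.49 + 5.0 / 3.84

    def __post_init__(self) -> None:
        if self.R_active <= self.r_0:
            raise ValueError("R_active must exceed r_0")

    @classmethod
    def from_physical(cls, p: PhysicalParams) -> "InteractionParams":
        return cls(p.D_e, p.beta_morse, p.r_0, p.R_active)


def morse_potential(r, p: InteractionParams):
    """Interaction energy phi(r); minimum -D_e at r = r_0."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    e = np.exp(p.beta_morse * (p.r_0 - r))
    out = p.D_e * (e * e - 2.0 * e)
    return out if out.ndim else float(out)


def morse_force(
    r,
    p: InteractionParams,
    lam_C: float = 1.0,
    D_LD: float = 0.0,
    beta_LD: float = 0.0,
    ld_on: bool = False,
):
    """Pair force F(r) = -dphi/dr with hardened repulsive branch.

    Positive values repel, negative attract; zero at r = r_0 and cut off to
    zero for r >= R_active.  With ``ld_on`` the repulsion (r <= r_0) is
    multiplied by alpha(lambda_C).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    e = np.exp(p.beta_morse * (p.r_0 - r))
    F = 2.0 * p.beta_morse * p.D_e * (e * e - e)
    if ld_on:
        F = np.where(r <= p.r_0, F * _alpha(lam_C, D_LD, beta_LD), F)
    F = np.where(r >= p.R_active, 0.0, F)
    return F if F.ndim else float(F)


@njit(cache=True)
def _min_image_dx(dx, Lx):
    if Lx > 0.0:
        if dx > 0.5 * Lx:
            dx -= Lx
        elif dx < -0.5 * Lx:
            dx += Lx
    return dx


@njit(cache=True)
def _pair_nodes_hash(X, cell_of, R, Lx, partner, dist):
    """Nearest foreign node within R for every node, via a spatial hash.

    ``X`` is (n, 2) flattened over cells, ``cell_of`` the owning cell per
    node.  x is treated periodically when Lx > 0.  Ties broken by lowest
    (cell id, node id).  ``partner`` gets -1 when no foreign node is in
    range.
    """
    n = X.shape[0]
    if Lx > 0.0:
        nbx = max(1, int(Lx / R))
        binw_x = Lx / nbx
    else:
        xmin = X[:, 0].min()
        xmax = X[:, 0].max()
        nbx = max(1, int((xmax - xmin) / R) + 1)
        binw_x = R
    ymin = X[:, 1].min()
    ymax = X[:, 1].max()
    nby = max(1, int((ymax - ymin) / R) + 1)

    head = np.full(nbx * nby, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    bx = np.empty(n, dtype=np.int64)
    by = np.empty(n, dtype=np.int64)
    for m in range(n):
        x = X[m, 0]
        if Lx > 0.0:
            x = x % Lx
            ix = min(int(x / binw_x), nbx - 1)
        else:
            ix = min(int((x - xmin) / binw_x), nbx - 1)
        iy = min(int((X[m, 1] - ymin) / R), nby - 1)
        bx[m] = ix
        by[m] = iy
        b = iy * nbx + ix
        nxt[m] = head[b]
        head[b] = m

    for m in range(n):
        best = -1
        bestd = R
        cm = cell_of[m]
        for dy in range(-1, 2):
            iy = by[m] + dy
            if iy < 0 or iy >= nby:
                continue
            for dxb in range(-1, 2):
                ix = bx[m] + dxb
                if Lx > 0.0:
                    ix = ix % nbx
                elif ix < 0 or ix >= nbx:
                    continue
                q = head[iy * nbx + ix]
                while q >= 0:
                    if cell_of[q] != cm:
                        ddx = _min_image_dx(X[m, 0] - X[q, 0], Lx)
                        ddy = X[m, 1] - X[q, 1]
                        d = math.sqrt(ddx * ddx + ddy * ddy)
                        take = d < bestd
                        if (not take) and d == bestd and best >= 0:
                            cq, cb = cell_of[q], cell_of[best]
                            take = cq < cb or (cq == cb and q < best)
                        if take:
                            best = q
                            bestd = d
                    q = nxt[q]
        partner[m] = best
        dist[m] = bestd if best >= 0 else np.inf


def pair_nodes(meshes_X, R_active: float, Lx: float = 0.0):
    """Pair every membrane node with its nearest foreign node within range.

    ``meshes_X`` is (n_cells, n_nodes, 2).  Returns a list of tuples
    ``((cell, node), (cell', node'), r)``; empty when nothing is in range.
    """
    Xc = np.ascontiguousarray(np.asarray(meshes_X, dtype=float))
    nc, nn = Xc.shape[0], Xc.shape[1]
    if nc < 2:
        return []
    X = Xc.reshape(nc * nn, 2)
    cell_of = np.repeat(np.arange(nc, dtype=np.int64), nn)
    partner = np.empty(nc * nn, dtype=np.int64)
    dist = np.empty(nc * nn)
    _pair_nodes_hash(X, cell_of, float(R_active), float(Lx), partner, dist)
    out = []
    for m in range(nc * nn):
        q = partner[m]
        if q >= 0:
            out.append(
                ((m // nn, m % nn), (int(q) // nn, int(q) % nn), float(dist[m]))
            )
    return out


@njit(cache=True)
def _self_contact_forces(
    X, lamC, ds0, Fm,
    r0, beta, amp,
    D_LD, beta_LD, ld_on, Lx, arc_gap,
):
    """Repulsion-only contact barrier between distant nodes of one ring.

    When a membrane folds onto itself the two approaching sections have no
    mutual hydrodynamic resistance below the kernel scale; this guard
    applies the repulsive Morse branch (r < r0 only, never the attraction)
    between same-cell node pairs at least ``arc_gap`` nodes apart along the
    ring, preventing nonphysical self-penetration.  Returns the minimum
    self-gap found.
    """
    nc, nn = X.shape[0], X.shape[1]
    min_gap = np.inf
    for c in range(nc):
        for m in range(nn):
            for q in range(m + 1, nn):
                sep = q - m
                if sep > nn - sep:
                    sep = nn - sep
                if sep < arc_gap:
                    continue
                dx = _min_image_dx(X[c, m, 0] - X[c, q, 0], Lx)
                dy = X[c, m, 1] - X[c, q, 1]
                r = math.sqrt(dx * dx + dy * dy)
                if r < min_gap:
                    min_gap = r
                if r >= r0 or r <= 0.0:
                    continue
                e = math.exp(beta * (r0 - r))
                fmag = amp * (e * e - e)  # > 0 here (repulsion)
                if ld_on:
                    fmag *= _alpha(lamC[c], D_LD, beta_LD)
                fmag *= 0.5 * ds0[c, m]
                fx = fmag * dx / r
                fy = fmag * dy / r
                Fm[c, m, 0] += fx
                Fm[c, m, 1] += fy
                Fm[c, q, 0] -= fx
                Fm[c, q, 1] -= fy
    return min_gap


@njit(cache=True)
def _interaction_forces(
    X, lamC, ds0, Fm,
    r0, beta, amp, Ract,
    D_LD, beta_LD, ld_on, Lx,
):
    """Accumulate Morse nodal forces into ``Fm`` (lattice units).

    ``X``: (nc, nn, 2); ``ds0``: rest node arclengths; ``amp`` is the line
    force per unit length scale 2 beta D_e in lattice stress units.  Returns
    (pair count, minimum separation found).
    """
    nc, nn = X.shape[0], X.shape[1]
    n = nc * nn
    Xf = X.reshape(n, 2)
    cell_of = np.empty(n, dtype=np.int64)
    for c in range(nc):
        for m in range(nn):
            cell_of[c * nn + m] = c
    partner = np.empty(n, dtype=np.int64)
    dist = np.empty(n)
    _pair_nodes_hash(Xf, cell_of, Ract, Lx, partner, dist)
    npairs = 0
    min_sep = np.inf
    for m in range(n):
        q = partner[m]
        if q < 0:
            continue
        r = dist[m]
        if r < min_sep:
            min_sep = r
        if r <= 0.0:
            continue
        npairs += 1
        e = math.exp(beta * (r0 - r))
        f = amp * (e * e - e)
        if ld_on and r <= r0:
            f *= _alpha(lamC[cell_of[m]], D_LD, beta_LD)
        f *= 0.5 * ds0[m // nn, m % nn]  # half: each directed pair applied once
        dx = _min_image_dx(Xf[m, 0] - Xf[q, 0], Lx) / r
        dy = (Xf[m, 1] - Xf[q, 1]) / r
        Fm[m // nn, m % nn, 0] += f * dx
        Fm[m // nn, m % nn, 1] += f * dy
        Fm[q // nn, q % nn, 0] -= f * dx
        Fm[q // nn, q % nn, 1] -= f * dy
    return npairs, min_sep
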