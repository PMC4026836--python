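"""Coupled fluid-structure time integration.

One engine step advances the whole system by one lattice time unit:

1. membrane nodal forces (tension / bending / pressure penalty) per cell,
   plus Morse interaction forces between cells;
2. spreading of nodal forces onto the lattice body-force field (on top of
   any uniform pressure-equivalent drive g_x);
3. BGK collision with Guo forcing and streaming with the domain boundaries;
4. interpolation of the new velocity at the membrane nodes and forward-Euler
   advection of the nodes;
5. scanline indicator update assigning cytoplasm/plasma relaxation times.

Everything inside the loop is in lattice units.  The loop runs fully under
numba; metric frames are recorded into preallocated buffers every
``record_every`` steps.  A detected membrane self-intersection (the
buckling / over-stretch failure mode) or a NaN / Mach blow-up terminates
the loop with a status code rather than an exception, so an aborted run is
a recorded outcome.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .ibm import _fill_labels, _interpolate, _phi1, _spread
from .interaction import _interaction_forces, _self_contact_forces
from .lbm import _collide, _stream
from .membrane import _assemble_forces, _self_intersects

__all__ = ["STATUS_OK", "STATUS_SELF_INTERSECT", "STATUS_DIVERGED", "run_steps"]

STATUS_OK = 0
STATUS_SELF_INTERSECT = 1
STATUS_DIVERGED = 2

#: lattice Mach guard: |u| beyond this (in units of c_s ~ 0.577) aborts
MAX_LATTICE_SPEED = 0.3


@njit(cache=True)
def _velocity_gradients(ux, uy, walls, u_bot, u_top, dudx, dudy, dvdx, dvdy):
    """Central-difference velocity gradients; ghost rows enforce no-slip."""
    Nx, Ny = ux.shape
    for x in range(Nx):
        xp = (x + 1) % Nx
        xm = (x - 1) % Nx
        for y in range(Ny):
            dudx[x, y] = 0.5 * (ux[xp, y] - ux[xm, y])
            dvdx[x, y] = 0.5 * (uy[xp, y] - uy[xm, y])
            if y == 0:
                if walls:
                    ug = 2.0 * u_bot - ux[x, 0]
                    vg = -uy[x, 0]
                else:
                    ug = ux[x, Ny - 1]
                    vg = uy[x, Ny - 1]
                dudy[x, y] = 0.5 * (ux[x, 1] - ug)
                dvdy[x, y] = 0.5 * (uy[x, 1] - vg)
            elif y == Ny - 1:
                if walls:
                    ug = 2.0 * u_top - ux[x, Ny - 1]
                    vg = -uy[x, Ny - 1]
                else:
                    ug = ux[x, 0]
                    vg = uy[x, 0]
                dudy[x, y] = 0.5 * (ug - ux[x, Ny - 2])
                dvdy[x, y] = 0.5 * (vg - uy[x, Ny - 2])
            else:
                dudy[x, y] = 0.5 * (ux[x, y + 1] - ux[x, y - 1])
                dvdy[x, y] = 0.5 * (uy[x, y + 1] - uy[x, y - 1])


@njit(cache=True)
def _max_node_shear_stress(dudx, dudy, dvdx, dvdy, Xc, mu):
    """Per-cell max over nodes of the local viscous shear-stress magnitude.

    The rate-of-strain tensor is interpolated to each node with the IBM
    kernel; the reported scalar is mu * sqrt((du/dx - dv/dy)^2 +
    (du/dy + dv/dx)^2), the maximum shear stress (Mohr-circle radius) of
    the viscous stress tensor.
    """
    Nx, Ny = dudx.shape
    nc, nn = Xc.shape[0], Xc.shape[1]
    out = np.zeros(nc)
    for c in range(nc):
        best = 0.0
        for m in range(nn):
            px, py = Xc[c, m, 0], Xc[c, m, 1]
            ib = int(math.floor(px - 0.5)) - 1
            jb = int(math.floor(py - 0.5)) - 1
            a = 0.0
            b = 0.0
            d = 0.0
            e = 0.0
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
                    jj = j
                    if jj < 0:
                        jj = -1 - jj
                    elif jj >= Ny:
                        jj = 2 * Ny - 1 - jj
                    w = wx * wy
                    a += w * dudx[ii, jj]
                    b += w * dudy[ii, jj]
                    d += w * dvdx[ii, jj]
                    e += w * dvdy[ii, jj]
            s = mu * math.sqrt((a - e) ** 2 + (b + d) ** 2)
            if s > best:
                best = s
        out[c] = best
    return out


@njit(cache=True)
def run_steps(
    # fluid arrays
    f, f_post, rho, ux, uy, Fx, Fy, tau_field, labels,
    walls, u_bot, u_top, gx, tau_p, tau_c,
    # membrane arrays (nc, nn, ...)
    X, l0, kappa0, A_ref, L0, ds0, Fm, Um,
    # constitutive constants (lattice units)
    Es, Eb, kp, DLD, bLD,
    ld_shear, ld_bend, ld_vol, ld_int,
    # interaction (lattice units)
    morse_on, r0m, betam, ampm, Ractm, wrap_x,
    # stress metric
    mu_ext,
    # control
    n_steps, record_every, frame0, step0, isect_streak0,
    # frame buffers
    rec_step, rec_lamC, rec_area, rec_comx, rec_comy, rec_perim,
    rec_taumax, rec_rmin, rec_Q, rec_cflb, rec_cflt, rec_minsep, rec_npairs,
    # scratch gradients
    dudx, dudy, dvdx, dvdy,
):
    """Advance ``n_steps`` steps.

    Returns (status, fail_cell, step, frame, isect_streak); the streak of
    consecutive frame checks with a self-intersection is carried across
    calls via ``isect_streak0``.
    """
    Nx, Ny = rho.shape
    nc, nn = X.shape[0], X.shape[1]
    Xflat = X.reshape(nc * nn, 2)
    Fmflat = Fm.reshape(nc * nn, 2)
    Umflat = Um.reshape(nc * nn, 2)
    lamC_cur = np.empty(nc)
    area_cur = np.empty(nc)
    minsep = np.inf
    npairs = 0
    frame = frame0
    max_frames = rec_step.shape[0]
    # a self-intersection must persist over consecutive frame checks to
    # count as the buckling failure; a single crossing segment of a
    # resolving fold heals under the bending and contact forces
    isect_streak = isect_streak0
    isect_cell = -1

    for it in range(n_steps):
        step = step0 + it

        # --- membrane and interaction forces -----------------------------
        for c in range(nc):
            A, lc = _assemble_forces(
                X[c], l0[c], kappa0[c], A_ref[c], L0[c],
                Es, Eb, kp, DLD, bLD,
                ld_shear, ld_bend, ld_vol,
                Fm[c],
            )
            area_cur[c] = A
            lamC_cur[c] = lc
        if morse_on and nc > 1:
            npairs, minsep = _interaction_forces(
                X, lamC_cur, ds0, Fm,
                r0m, betam, ampm, Ractm,
                DLD, bLD, ld_int, wrap_x,
            )
        if nc > 0:
            _self_contact_forces(
                X, lamC_cur, ds0, Fm,
                r0m, betam, ampm,
                DLD, bLD, ld_int, wrap_x, 2,
            )

        # --- spread onto the lattice body force --------------------------
        for x in range(Nx):
            for y in range(Ny):
                Fx[x, y] = gx
                Fy[x, y] = 0.0
        if nc > 0:
            _spread(Fx, Fy, Xflat, Fmflat, walls)

        # --- fluid update -------------------------------------------------
        _collide(f, f_post, tau_field, Fx, Fy, rho, ux, uy)
        _stream(f, f_post, rho, walls, u_bot, u_top)

        # --- membrane advection (velocity of the step just computed) ------
        if nc > 0:
            _interpolate(ux, uy, Xflat, Umflat, walls)
            for m in range(nc * nn):
                Xflat[m, 0] += Umflat[m, 0]
                Xflat[m, 1] += Umflat[m, 1]
            if wrap_x > 0.0:
                for c in range(nc):
                    cx = 0.0
                    for m in range(nn):
                        cx += X[c, m, 0]
                    shift = math.floor(cx / nn / wrap_x) * wrap_x
                    if shift != 0.0:
                        for m in range(nn):
                            X[c, m, 0] -= shift

            # --- indicator / viscosity update -----------------------------
            bad = _fill_labels(labels, X)
            if bad:
                pass  # degenerate fill (grazing or crossing): keep previous
                # labels this step; the frame check below decides failure
            else:
                for x in range(Nx):
                    for y in range(Ny):
                        tau_field[x, y] = tau_c if labels[x, y] > 0 else tau_p

        # --- recording and health checks ----------------------------------
        if record_every > 0 and step % record_every == 0 and frame < max_frames:
            umax = 0.0
            ok = True
            for x in range(Nx):
                for y in range(Ny):
                    s = abs(ux[x, y]) + abs(uy[x, y])
                    if s > umax:
                        umax = s
                    if not math.isfinite(s):
                        ok = False
            if (not ok) or umax > MAX_LATTICE_SPEED:
                return STATUS_DIVERGED, -1, step, frame, isect_streak
            crossed = -1
            for c in range(nc):
                if _self_intersects(X[c]):
                    crossed = c
                    break
            if crossed >= 0:
                isect_streak += 1
                isect_cell = crossed
                if isect_streak >= 5:
                    return (
                        STATUS_SELF_INTERSECT, isect_cell, step, frame,
                        isect_streak,
                    )
            else:
                isect_streak = 0
            _velocity_gradients(
                ux, uy, walls, u_bot, u_top, dudx, dudy, dvdx, dvdy
            )
            taumax = _max_node_shear_stress(dudx, dudy, dvdx, dvdy, X, mu_ext)
            Qtot = 0.0
            for x in range(Nx):
                for y in range(Ny):
                    Qtot += ux[x, y]
            rec_step[frame] = step
            rec_Q[frame] = Qtot / Nx
            ymin_all = 1.0e30
            ymax_all = -1.0e30
            for c in range(nc):
                rec_lamC[frame, c] = lamC_cur[c]
                rec_area[frame, c] = area_cur[c]
                rec_perim[frame, c] = lamC_cur[c] * L0[c]
                rec_taumax[frame, c] = taumax[c]
                sx = 0.0
                sy = 0.0
                ylo = 1.0e30
                yhi = -1.0e30
                for m in range(nn):
                    sx += X[c, m, 0]
                    yv = X[c, m, 1]
                    sy += yv
                    if yv < ylo:
                        ylo = yv
                    if yv > yhi:
                        yhi = yv
                rec_comx[frame, c] = sx / nn
                rec_comy[frame, c] = sy / nn
                rec_rmin[frame, c] = min(ylo, Ny - yhi)
                if ylo < ymin_all:
                    ymin_all = ylo
                if yhi > ymax_all:
                    ymax_all = yhi
            if nc > 0:
                rec_cflb[frame] = ymin_all
                rec_cflt[frame] = Ny - ymax_all
            else:
                rec_cflb[frame] = float(Ny)
                rec_cflt[frame] = float(Ny)
            rec_minsep[frame] = minsep
            rec_npairs[frame] = npairs
            frame += 1

    return STATUS_OK, -1, step0 + n_steps - 1, frame, isect_streak
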