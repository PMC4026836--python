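"""Experiment drivers: single-cell simple shear and multi-cell channel flow.

Both drivers assemble lattice-unit state arrays from a
:class:`~hemoflow2d.config.SimulationConfig`, advance the coupled system
with the numba engine in chunks of one metric frame, and return a
:class:`~hemoflow2d.metrics.MetricsSeries` in physical units.

Simple shear: a square domain with tangentially moving halfway bounce-back
walls at +/-U imposes u = k y (k = U/Y) on a single centred cell; the run
integrates until the Taylor index is steady and reports steady D_xy and
circumferential strain.

Channel flow: cells packed at the target hematocrit in a periodic channel
are driven by a uniform body force G_x equivalent to a pressure drop
dP = G_x L over the periodic length (an open pressure boundary is
incompatible with recycling the cells through the periodic ends).  During a
development window a slow controller tunes G_x to the requested pseudoshear
(mean velocity / width); G_x is then frozen and the analysis window of
``transit_cycles`` material transit times is recorded.  A Case-I style
over-stretch failure (membrane self-intersection) ends the run with the
outcome recorded on the series rather than raising.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from . import engine
from .config import ExperimentConfig, SimulationConfig
from .fixtures import channel_packing, single_cell
from .lbm import DomainSpec, FluidState
from .membrane import CaseFlags, MembraneMesh
from .metrics import MetricsSeries, taylor_index
from .units import CP_TO_POISE, MORSE_ENERGY_TO_CGS, UM_TO_CM

__all__ = [
    "run_simple_shear",
    "run_channel",
    "shear_rate_for_G",
    "similarity_speedup",
]

_OUTCOME = {
    engine.STATUS_OK: "completed",
    engine.STATUS_SELF_INTERSECT: "failed_self_intersection",
    engine.STATUS_DIVERGED: "diverged",
}


def similarity_speedup(cfg: SimulationConfig, S: float) -> SimulationConfig:
    """Rescale the problem onto a faster dynamically similar one.

    Multiplying every membrane force scale (E_s, E_b, k_p, D_e) and every
    imposed rate (shear rate, pseudoshear) by the same factor S leaves all
    dimensionless groups of the Stokes-regime problem unchanged — G, G*,
    lambda_C, D_xy, CFL fraction and mu_rel are invariant — while the
    simulated physical window shrinks by S, so S times fewer lattice steps
    cover the same number of shear units or transit cycles.  Valid while
    the Reynolds and lattice Mach numbers stay small; the drivers' stability
    guard still applies.  Set the nominal pseudoshear on the experiment
    first, then apply the speedup.
    """
    import dataclasses

    p = cfg.physical
    p2 = dataclasses.replace(
        p, E_s=p.E_s * S, E_b=p.E_b * S, k_p=p.k_p * S, D_e=p.D_e * S
    )
    exp2 = dataclasses.replace(
        cfg.experiment, pseudoshear=cfg.experiment.pseudoshear * S
    )
    return dataclasses.replace(cfg, physical=p2, experiment=exp2)


def shear_rate_for_G(G: float, cfg: SimulationConfig) -> float:
    """Shear rate k [1/s] giving dimensionless shear rate G for this config."""
    p = cfg.physical
    return G * p.E_s / (p.mu_plasma * CP_TO_POISE * p.a_cell * UM_TO_CM)


class _CoupledRun:
    """Lattice-unit state and chunked execution of the coupled engine."""

    def __init__(
        self,
        cfg: SimulationConfig,
        spec: DomainSpec,
        meshes: list[MembraneMesh],
        gx_lat: float = 0.0,
        morse_on: bool = False,
        wrap_x: bool = False,
    ):
        p = cfg.physical
        scales = cfg.scales()
        self.cfg = cfg
        self.scales = scales
        self.spec = spec
        self.h = scales.h  # um
        self.dt = scales.dt  # s

        from .units import relaxation_time

        self.tau_p = relaxation_time(p.nu_plasma, scales)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tau_cyto may exceed 2 by design
            self.tau_c = relaxation_time(p.nu_cyto, scales)

        self.fluid = FluidState(spec, tau=self.tau_p)
        self.labels = np.zeros((spec.Nx, spec.Ny), dtype=np.int32)
        self.gx = gx_lat

        # membranes in lattice units
        nc = len(meshes)
        nn = meshes[0].n_nodes if nc else 8
        self.X = np.zeros((nc, nn, 2))
        self.l0 = np.ones((nc, nn))
        self.kappa0 = np.zeros((nc, nn))
        self.A_ref = np.ones(nc)
        self.L0 = np.ones(nc)
        self.ds0 = np.ones((nc, nn))
        for c, m in enumerate(meshes):
            self.X[c] = m.X / self.h
            self.l0[c] = m.l0 / self.h
            self.kappa0[c] = m.kappa0 * self.h
            self.A_ref[c] = m.A_ref / self.h**2
            self.L0[c] = m.L0 / self.h
            self.ds0[c] = 0.5 * (np.roll(m.l0, 1) + m.l0) / self.h
        self.Fm = np.zeros_like(self.X)
        self.Um = np.zeros_like(self.X)

        # constitutive constants in lattice units
        self.Es = p.E_s / scales.factor("tension")
        self.Eb = p.E_b / scales.factor("energy")
        self.kp = p.k_p / scales.factor("stress")
        self.DLD = p.D_LD
        self.bLD = p.beta_LD
        self.flags = cfg.case

        # Morse interaction in lattice units
        amp_cgs = 2.0 * (p.beta_morse / UM_TO_CM) * (p.D_e * MORSE_ENERGY_TO_CGS)
        self.morse_on = morse_on and nc > 1
        self.r0m = p.r_0 / self.h
        self.betam = p.beta_morse * self.h
        self.ampm = amp_cgs / scales.factor("stress")
        self.Ractm = p.R_active / self.h
        self.wrap_x = float(spec.Nx) if wrap_x else 0.0

        self.mu_ext = (self.tau_p - 0.5) / 3.0  # lattice dynamic viscosity

        self.grad = [np.zeros((spec.Nx, spec.Ny)) for _ in range(4)]
        self.step = 0
        self._streak = 0
        self.status = engine.STATUS_OK
        self.fail_cell = -1

        if nc:
            from .ibm import _fill_labels

            _fill_labels(self.labels, self.X)
            self.fluid.tau_field[:] = np.where(
                self.labels > 0, self.tau_c, self.tau_p
            )

    def alloc_frames(self, n: int, nc: int):
        self.rec = {
            "step": np.zeros(n, dtype=np.int64),
            "lamC": np.zeros((n, nc)),
            "area": np.zeros((n, nc)),
            "comx": np.zeros((n, nc)),
            "comy": np.zeros((n, nc)),
            "perim": np.zeros((n, nc)),
            "taumax": np.zeros((n, nc)),
            "rmin": np.zeros((n, nc)),
            "Q": np.zeros(n),
            "cflb": np.zeros(n),
            "cflt": np.zeros(n),
            "minsep": np.zeros(n),
            "npairs": np.zeros(n, dtype=np.int64),
        }
        self.frame = 0

    def run_chunk(self, n_steps: int, record_every: int) -> int:
        r = self.rec
        fl = self.fluid
        status, fail_cell, step, frame, streak = engine.run_steps(
            fl.f, fl._f_post, fl.rho, fl.u[0], fl.u[1],
            fl.F_f[0], fl.F_f[1], fl.tau_field, self.labels,
            self.spec.y_boundary == "wall",
            self.spec.u_wall_bottom, self.spec.u_wall_top,
            self.gx, self.tau_p, self.tau_c,
            self.X, self.l0, self.kappa0, self.A_ref, self.L0, self.ds0,
            self.Fm, self.Um,
            self.Es, self.Eb, self.kp, self.DLD, self.bLD,
            self.flags.ld_on_shear, self.flags.ld_on_bending,
            self.flags.ld_on_volume, self.flags.ld_on_interaction,
            self.morse_on, self.r0m, self.betam, self.ampm, self.Ractm,
            self.wrap_x, self.mu_ext,
            n_steps, record_every, self.frame, self.step, self._streak,
            r["step"], r["lamC"], r["area"], r["comx"], r["comy"], r["perim"],
            r["taumax"], r["rmin"], r["Q"], r["cflb"], r["cflt"],
            r["minsep"], r["npairs"],
            self.grad[0], self.grad[1], self.grad[2], self.grad[3],
        )
        self.step = step + 1
        self.frame = frame
        self.status = status
        self.fail_cell = fail_cell
        self._streak = streak
        return status

    def to_series(
        self,
        analysis_start: int,
        H_um: float,
        L_um: float,
        dP: float,
        meta: dict | None = None,
    ) -> MetricsSeries:
        p = self.cfg.physical
        s = self.scales
        n = self.frame
        r = self.rec
        stress = s.factor("stress")
        h = self.h
        analysis_start = max(0, min(analysis_start, n - 1)) if n else 0
        com = np.stack([r["comx"][:n] * h, r["comy"][:n] * h], axis=-1)
        return MetricsSeries(
            time=r["step"][:n] * self.dt,
            lam_C=r["lamC"][:n],
            area=r["area"][:n] * h**2,
            com=com,
            tau_max_frame=r["taumax"][:n] * stress,
            r_min_wall=r["rmin"][:n] * h,
            perimeter=r["perim"][:n] * h,
            Q=r["Q"][:n] * s.h_cm**2 / self.dt,
            cfl_bottom=r["cflb"][:n] * h,
            cfl_top=r["cflt"][:n] * h,
            min_separation=r["minsep"][:n] * h,
            n_pairs=r["npairs"][:n],
            H=H_um,
            L_channel=L_um,
            dP=dP,
            E_s=p.E_s,
            mu_plasma=p.mu_plasma * CP_TO_POISE,
            outcome=_OUTCOME[self.status],
            fail_step=self.step if self.status else -1,
            fail_cell=self.fail_cell,
            meta=meta or {},
            analysis_start=analysis_start,
        )


def run_simple_shear(
    exp: ExperimentConfig,
    cfg: SimulationConfig,
    n_nodes: int | None = None,
    store_trajectory: bool = False,
) -> MetricsSeries:
    """Single cell in simple shear at dimensionless shear rate ``exp.G``.

    Integrates until the Taylor index is steady (change of its mean over
    successive windows of one shear time 1/k below 2e-3), or until the step
    budget set by ``exp.shear_duration`` runs out (then the trailing average
    is reported with a warning).  Steady ``D_xy``, ``lam_C`` and strain are
    stored in ``series.meta``.
    """
    p = cfg.physical
    scales = cfg.scales()
    h, dt = scales.h, scales.dt
    Y = exp.domain_half_height  # um
    H = 2.0 * Y
    Ny = max(8, int(round(H / h)))
    Nx = Ny
    k = shear_rate_for_G(exp.G, cfg)  # 1/s
    U = k * Y * UM_TO_CM  # wall speed, cm/s
    u_lat = U * dt / scales.h_cm
    spec = DomainSpec(Nx, Ny, "wall", u_wall_bottom=-u_lat, u_wall_top=u_lat)

    mesh = single_cell((Nx * h / 2.0, H / 2.0), p.a_cell, n_nodes or exp.n_nodes)
    run = _CoupledRun(cfg, spec, [mesh], morse_on=False, wrap_x=False)

    # linear Couette start state u_x(y) = k (y - Y), zero at the midline
    y = (np.arange(Ny) + 0.5) * h  # um
    ux0 = k * (y - Y) * UM_TO_CM * dt / scales.h_cm
    u0 = np.stack([np.broadcast_to(ux0, (Nx, Ny)).copy(), np.zeros((Nx, Ny))])
    run.fluid.initialize(1.0, u0)

    if k > 0:
        t_shear = 1.0 / k  # s
    elif exp.shear_duration > 0:
        t_shear = exp.shear_duration / 4.0
    else:
        raise ValueError("G = 0 requires an explicit shear_duration")
    duration = exp.shear_duration if exp.shear_duration > 0 else 12.0 * t_shear
    n_steps = int(duration / dt)
    record_every = exp.record_every or max(1, int(t_shear / dt / 25))
    n_frames = n_steps // record_every + 2
    run.alloc_frames(n_frames, 1)

    frames_per_window = max(2, int(t_shear / dt / record_every))
    dxy = []
    traj = []
    steady = False
    while run.step < n_steps:
        status = run.run_chunk(record_every, record_every)
        dxy.append(taylor_index(run.X[0]))
        if store_trajectory:
            traj.append((run.step, run.X[0] * h))
        if status != engine.STATUS_OK:
            break
        if len(dxy) >= 3 * frames_per_window:
            cur = float(np.mean(dxy[-frames_per_window:]))
            prev = float(
                np.mean(dxy[-2 * frames_per_window : -frames_per_window])
            )
            if abs(cur - prev) < 2e-3:
                steady = True
                break
    if not steady and run.status == engine.STATUS_OK:
        warnings.warn(
            f"shear run at G={exp.G} not steady within budget; "
            "reporting trailing average",
            stacklevel=2,
        )

    nwin = min(frames_per_window, max(1, len(dxy)))
    meta = {
        "G": exp.G,
        "k": k,
        "D_xy_series": np.asarray(dxy),
        "D_xy": float(np.mean(dxy[-nwin:])) if dxy else 0.0,
        "steady": steady,
    }
    if store_trajectory:
        meta["trajectory"] = traj
    series = run.to_series(
        analysis_start=max(0, run.frame - nwin),
        H_um=H,
        L_um=Nx * h,
        dP=0.0,
        meta=meta,
    )
    w = series.window()
    meta["lam_C"] = float(series.lam_C[w].mean()) if series.n_frames else 1.0
    meta["eps"] = meta["lam_C"] - 1.0
    return series


def run_channel(
    exp: ExperimentConfig,
    cfg: SimulationConfig,
    dev_cycles: float = 2.0,
    store_trajectory: bool = False,
) -> MetricsSeries:
    """Multi-cell pressure-driven channel flow at a target pseudoshear rate.

    Cells are packed at ``exp.hematocrit``, recycled through the periodic
    ends, and driven by the body-force pressure equivalent.  The analysis
    window spans ``exp.transit_cycles`` material transit times after a
    ``dev_cycles``-transit development window.
    """
    p = cfg.physical
    scales = cfg.scales()
    h, dt = scales.h, scales.dt
    L, H = exp.channel_length, exp.channel_width
    Nx, Ny = int(round(L / h)), int(round(H / h))
    spec = DomainSpec(Nx, Ny, "wall")

    meshes = (
        channel_packing(
            exp.n_cells, exp.hematocrit, L, H, exp.n_nodes, seed=exp.seed
        )
        if exp.n_cells
        else []
    )

    U_mean = exp.pseudoshear * H * UM_TO_CM  # cm/s
    mu_guess = p.mu_plasma * CP_TO_POISE * (1.1 if meshes else 1.0)
    gx_phys = 12.0 * mu_guess * U_mean / (H * UM_TO_CM) ** 2  # dyn/cm^3
    fvol = scales.factor("force") / scales.factor("length") ** 3
    gx_lat = gx_phys / fvol

    run = _CoupledRun(
        cfg, spec, meshes, gx_lat=gx_lat, morse_on=True, wrap_x=True
    )

    # plasma Poiseuille start state
    nu_lat = (run.tau_p - 0.5) / 3.0
    yl = np.arange(Ny) + 0.5
    ux0 = run.gx * yl * (Ny - yl) / (2.0 * nu_lat)
    u0 = np.stack(
        [np.broadcast_to(ux0, (Nx, Ny)).copy(), np.zeros((Nx, Ny))]
    )
    run.fluid.initialize(1.0, u0)

    transit = L * UM_TO_CM / U_mean  # s
    steps_per_transit = max(1, int(transit / dt))
    n_dev = int(dev_cycles * steps_per_transit)
    n_ana = int(exp.transit_cycles * steps_per_transit)
    record_every = exp.record_every or max(1, steps_per_transit // 40)
    n_frames = (n_dev + n_ana) // record_every + 4
    run.alloc_frames(n_frames, len(meshes))

    Q_target = U_mean / (scales.h_cm / dt) * Ny  # lattice per-column flux
    adjust_every = max(1, int(1500 / record_every))
    traj = []

    chunks_done = 0
    failed = False
    while run.step < n_dev:
        status = run.run_chunk(record_every, record_every)
        chunks_done += 1
        if store_trajectory:
            traj.append((run.step, run.X * h))
        if status != engine.STATUS_OK:
            failed = True
            break
        if chunks_done % adjust_every == 0 and run.frame > 0:
            Q_meas = float(np.mean(run.rec["Q"][max(0, run.frame - 3) : run.frame]))
            if Q_meas > 0:
                run.gx *= float(np.clip((Q_target / Q_meas) ** 0.7, 0.5, 2.0))
    analysis_start = run.frame
    if not failed:
        while run.step < n_dev + n_ana:
            status = run.run_chunk(record_every, record_every)
            if store_trajectory:
                traj.append((run.step, run.X * h))
            if status != engine.STATUS_OK:
                break

    dP = run.gx * fvol * L * UM_TO_CM  # dyn/cm^2 over the periodic length
    meta = {
        "pseudoshear_target": exp.pseudoshear,
        "gx": run.gx * fvol,
        "steps_per_transit": steps_per_transit,
        "seed": exp.seed,
    }
    if store_trajectory:
        meta["trajectory"] = traj
    return run.to_series(
        analysis_start=analysis_start, H_um=H, L_um=L, dP=dP, meta=meta
    )
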