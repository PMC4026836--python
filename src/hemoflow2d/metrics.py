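"""Deformation and rheology metrics.

Shape and stress diagnostics for single cells (Taylor index, dimensionless
shear rate G) and suspensions (perimeter extension ratio lambda_C and
circumferential strain eps = lambda_C - 1, cell-free layer width, apparent
and relative viscosity by plane-Poiseuille inversion, and the local
dimensionless shear rate G* built from the time-averaged maximum membrane
shear stress).  The saturating exponential strain law eps = A (1 - e^(-b G*))
is fitted by nonlinear least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .membrane import MembraneMesh

__all__ = [
    "taylor_index",
    "dimensionless_G",
    "g3d_to_g2d",
    "circumferential_strain",
    "cfl_width",
    "apparent_viscosity",
    "fit_strain_curve",
    "MetricsSeries",
]

#: coefficients of the empirical quadratic mapping a 3D dimensionless shear
#: rate onto the 2D value producing matching capsule deformation
G2D_COEFFS = (-0.008417, 0.45073, 0.75662)


def taylor_index(X: np.ndarray) -> float:
    """Taylor deformation index D_xy = (L - B)/(L + B) of a node ring.

    Major/minor diameters L and B are the extremal extents along the
    principal axes of the node second-moment (gyration) tensor; 0 for a
    circle, approaching 1 for a needle.  Meaningful only for near-elliptical
    profiles and highly sensitive to L and B at low deformation.
    """
    X = np.asarray(X, dtype=float)
    if len(X) < 3:
        raise ValueError("need at least 3 nodes")
    Y = X - X.mean(axis=0)
    if np.allclose(Y, 0):
        raise ValueError("degenerate ring: all nodes coincide")
    C = Y.T @ Y / len(Y)
    _, vecs = np.linalg.eigh(C)
    proj = Y @ vecs
    ext = proj.max(axis=0) - proj.min(axis=0)
    L, B = max(ext), min(ext)
    return float((L - B) / (L + B))


def dimensionless_G(mu: float, k: float, a: float, E_s: float) -> float:
    """G = mu k a / E_s (CGS: mu [P], k [1/s], a [cm], E_s [dyn/cm])."""
    if mu < 0 or k < 0 or a <= 0 or E_s <= 0:
        raise ValueError("arguments must be positive (k may be zero)")
    return mu * k * a / E_s


def g3d_to_g2d(G3D: float) -> float:
    """Empirical quadratic mapping of a 3D G onto the matching 2D G.

    Warns when the result is non-positive (the mapping is not meaningful at
    very low shear).
    """
    if G3D < 0:
        raise ValueError("G3D must be non-negative")
    c0, c1, c2 = G2D_COEFFS
    out = c0 + c1 * G3D + c2 * G3D**2
    if out <= 0:
        warnings.warn(
            "2D G conversion is non-positive; not meaningful at very low shear",
            stacklevel=2,
        )
    return out


def circumferential_strain(mesh: MembraneMesh) -> tuple[float, float]:
    """(lambda_C, eps): perimeter extension ratio and strain eps = lambda_C - 1."""
    lam_C = mesh.perimeter() / mesh.L0
    return lam_C, lam_C - 1.0


def cfl_width(node_y: list[np.ndarray] | np.ndarray, H: float) -> float:
    """Cell-free-layer fraction of the channel width.

    Per frame and per wall, the distance from the wall to the nearest
    membrane point anywhere along the channel; the top and bottom layers are
    summed, averaged over frames, and reported as a fraction of the width
    ``H``.  ``node_y`` holds the membrane-node y coordinates per frame (any
    shape per frame); with no cells the channel is wholly cell-free and the
    fraction is 1.
    """
    frames = node_y if isinstance(node_y, list) else [node_y]
    fracs = []
    for y in frames:
        y = np.asarray(y, dtype=float).ravel()
        if y.size == 0:
            fracs.append(1.0)
        else:
            fracs.append((y.min() + (H - y.max())) / H)
    return float(np.mean(fracs))


def apparent_viscosity(
    Q: float, dP: float, H: float, L_channel: float, mu_plasma: float
) -> tuple[float, float]:
    """(mu_app, mu_rel) by plane-Poiseuille inversion.

    mu_app = dP H^3 / (12 Q L_channel) with Q the per-unit-depth flow rate;
    mu_rel = mu_app / mu_plasma.  Consistent units required (CGS: Q [cm^2/s],
    dP [dyn/cm^2], lengths [cm], mu [P]).
    """
    if Q <= 0:
        raise ValueError("flow rate must be positive")
    mu_app = dP * H**3 / (12.0 * Q * L_channel)
    return mu_app, mu_app / mu_plasma


def fit_strain_curve(points, labels=None):
    """Fit eps = A (1 - e^(-b G*)) to (G*, eps) pairs by least squares.

    ``points`` is (n, 2).  Returns (A, b, r2) where ``r2`` maps each label
    to the R^2 of that subset against the joint fit (single key "all" when
    no labels are given).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 5:
        raise ValueError("need at least 5 points")
    g, eps = pts[:, 0], pts[:, 1]
    if g.max() <= 0 or g.max() / max(g[g > 0].min(), 1e-300) < 10:
        warnings.warn("G* points span less than a decade", stacklevel=2)

    def model(x, A, b):
        return A * (1.0 - np.exp(-b * x))

    p0 = (max(eps.max(), 1e-3), 1.0 / max(np.mean(g), 1e-12))
    try:
        popt, _ = curve_fit(model, g, eps, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"strain-curve fit did not converge (initial guess {p0})"
        ) from err
    A, b = float(popt[0]), float(popt[1])
    if labels is None:
        labels = np.full(len(pts), "all")
    labels = np.asarray(labels)
    r2 = {}
    for lab in np.unique(labels):
        m = labels == lab
        resid = eps[m] - model(g[m], A, b)
        ss_tot = np.sum((eps[m] - eps[m].mean()) ** 2)
        r2[str(lab)] = float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    return A, b, r2


@dataclass
class MetricsSeries:
    """Per-frame and time-averaged diagnostics of a run (physical units).

    Per-frame, per-cell arrays are (n_frames, n_cells); per-frame globals
    are (n_frames,).  ``outcome`` is "completed", "failed_self_intersection"
    or "diverged" (with ``fail_step``/``fail_cell`` set for failures) — an
    aborted over-stretch run is a recorded outcome, not a crash.
    """

    time: np.ndarray  # [s]
    lam_C: np.ndarray
    area: np.ndarray  # [um^2]
    com: np.ndarray  # (n_frames, n_cells, 2) [um]
    tau_max_frame: np.ndarray  # per-frame max membrane shear stress [dyn/cm^2]
    r_min_wall: np.ndarray  # per-frame min membrane-wall distance [um]
    perimeter: np.ndarray  # [um]
    Q: np.ndarray  # per-depth flow rate [cm^2/s]
    cfl_bottom: np.ndarray  # [um]
    cfl_top: np.ndarray  # [um]
    min_separation: np.ndarray  # min inter-cell node distance [um]
    n_pairs: np.ndarray
    H: float  # channel width / domain height [um]
    L_channel: float  # [um]
    dP: float  # pressure drop over L_channel [dyn/cm^2]
    E_s: float
    mu_plasma: float  # [P]
    outcome: str = "completed"
    fail_step: int = -1
    fail_cell: int = -1
    meta: dict = field(default_factory=dict)
    analysis_start: int = 0  # first frame of the analysis window

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def n_cells(self) -> int:
        return self.lam_C.shape[1] if self.lam_C.ndim == 2 else 0

    def window(self):
        return slice(self.analysis_start, self.n_frames)

    @property
    def eps(self) -> np.ndarray:
        return self.lam_C - 1.0

    def lam_C_cells(self) -> np.ndarray:
        """Time-averaged lambda_C per cell over the analysis window."""
        return self.lam_C[self.window()].mean(axis=0)

    def ensemble_lam_C(self) -> tuple[float, float]:
        """Ensemble mean and SD over cells of the time-averaged lambda_C."""
        per_cell = self.lam_C_cells()
        return float(per_cell.mean()), float(per_cell.std(ddof=1))

    def g_star(self) -> np.ndarray:
        """Per-cell G* = tau_max L_C / E_s over the analysis window.

        tau_max is the time average of the per-frame maximum membrane shear
        stress, L_C the time-averaged perimeter.
        """
        w = self.window()
        tau_max = self.tau_max_frame[w].mean(axis=0)
        L_C = self.perimeter[w].mean(axis=0) * 1e-4  # um -> cm
        return tau_max * L_C / self.E_s

    def r_min_cells(self) -> np.ndarray:
        return self.r_min_wall[self.window()].mean(axis=0)

    def cfl_fraction(self) -> float:
        w = self.window()
        frac = (self.cfl_bottom[w] + self.cfl_top[w]) / self.H
        return float(np.minimum(frac, 1.0).mean())

    def hematocrit(self) -> np.ndarray:
        """Per-frame area fraction of cells in the domain."""
        return self.area.sum(axis=1) / (self.H * self.L_channel)

    def apparent_viscosity(self) -> tuple[float, float]:
        w = self.window()
        return apparent_viscosity(
            float(self.Q[w].mean()),
            self.dP,
            self.H * 1e-4,
            self.L_channel * 1e-4,
            self.mu_plasma,
        )

    def pseudoshear(self) -> float:
        """Mean velocity / channel width over the analysis window [1/s]."""
        w = self.window()
        H_cm = self.H * 1e-4
        return float(self.Q[w].mean() / H_cm / H_cm)
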