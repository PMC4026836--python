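"""Large-deformation (strain-hardening) 2D membrane model.

A red blood cell is a closed ring of Lagrangian nodes joined by nonlinear
spring segments.  Four modalities shape the ring:

* in-plane shear: a 2D neo-Hookean tension tau = E_s (lambda^3 - 1) /
  lambda^(3/2) per segment, optionally multiplied by the strain-hardening
  coefficient alpha(lambda);
* bending: a linear resistance E_b (kappa - kappa_0), optionally alpha-scaled,
  discretized as the gradient of the discrete bending energy;
* area (cytoplasmic volume) conservation: a pressure penalty
  p = k_p (1 - A/A_ref), optionally scaled by alpha(lambda_C);
* cell-cell interaction (see :mod:`hemoflow2d.interaction`).

alpha(lambda) = 1 + D_LD (e^(lambda beta_LD) - e^(beta_LD)) equals 1 at rest
and grows exponentially with stretch; under compression (lambda < 1) it is
clamped at 1 so hardening never softens the compressive response.

The nodal-force kernels are unit-agnostic: they produce consistent outputs
for any consistent input unit system (the flow engine feeds them lattice
units; the public API feeds CGS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .units import UM_TO_CM, PhysicalParams

__all__ = [
    "CaseFlags",
    "MembraneMesh",
    "ld_coefficient",
    "segment_tension",
    "discrete_curvature",
    "bending_tension",
    "enclosed_area",
    "internal_pressure",
    "assemble_nodal_forces",
]


@dataclass(frozen=True)
class CaseFlags:
    """Which modalities receive the strain-hardening multiplier.

    Case I (plain neo-Hookean) sets all four False, Case II hardens only the
    shear response, Case III (the full model) hardens all four.
    """

    ld_on_shear: bool = True
    ld_on_bending: bool = True
    ld_on_volume: bool = True
    ld_on_interaction: bool = True

    @classmethod
    def case(cls, name: str) -> "CaseFlags":
        table = {
            "I": cls(False, False, False, False),
            "II": cls(True, False, False, False),
            "III": cls(True, True, True, True),
        }
        try:
            return table[name]
        except KeyError:
            raise ValueError(f"unknown case {name!r}") from None


# ---------------------------------------------------------------------------
# scalar kernels (unit-agnostic, numba-compiled)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _alpha(lam, D_LD, beta_LD):
    a = 1.0 + D_LD * (math.exp(lam * beta_LD) - math.exp(beta_LD))
    return a if a > 1.0 else 1.0


@njit(cache=True)
def _alpha_raw(lam, D_LD, beta_LD):
    return 1.0 + D_LD * (math.exp(lam * beta_LD) - math.exp(beta_LD))


@njit(cache=True)
def _tension(lam, E_s, D_LD, beta_LD, ld_on):
    t = E_s * (lam * lam * lam - 1.0) / lam**1.5
    if ld_on:
        t *= _alpha(lam, D_LD, beta_LD)
    return t


@njit(cache=True)
def _turning_angle_and_grad(ax, ay, bx, by, cx, cy):
    """Signed turning angle at b of the polyline (a, b, c) and its gradient.

    theta = atan2(cross(u, v), dot(u, v)) with u = b - a, v = c - b;
    positive for a locally convex counter-clockwise triplet and approaching
    +/-pi for a complete fold-back (so, unlike the circumscribed-circle
    curvature, it detects cusps).  Returns
    (theta, gax, gay, gbx, gby, gcx, gcy).
    """
    ux, uy = bx - ax, by - ay
    vx, vy = cx - bx, cy - by
    z = ux * vy - uy * vx
    d = ux * vx + uy * vy
    r2 = z * z + d * d
    if r2 == 0.0:
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    th = math.atan2(z, d)
    inv = 1.0 / r2
    # grad z: a -> (-vy, vx); c -> (-uy, ux); grad d: a -> -v; c -> u
    gax = (-d * vy + z * vx) * inv
    gay = (d * vx + z * vy) * inv
    gcx = (-d * uy - z * ux) * inv
    gcy = (d * ux - z * uy) * inv
    gbx = -(gax + gcx)
    gby = -(gay + gcy)
    return th, gax, gay, gbx, gby, gcx, gcy


@njit(cache=True)
def _shoelace(X):
    n = X.shape[0]
    s = 0.0
    for i in range(n):
        j = (i + 1) % n
        s += X[i, 0] * X[j, 1] - X[j, 0] * X[i, 1]
    return 0.5 * s


@njit(cache=True)
def _assemble_forces(
    X, l0, kappa0, A_ref, L0,
    E_s, E_b, k_p, D_LD, beta_LD,
    ld_shear, ld_bend, ld_vol,
    F,
):
    """Nodal forces from tension, bending and the pressure penalty.

    ``X`` is (N, 2); ``F`` is the (N, 2) output, overwritten.  Returns
    (A, lam_C) of the current configuration.  Unit-agnostic.
    """
    n = X.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0

    # segment stretch and tension
    L = 0.0
    for i in range(n):
        j = (i + 1) % n
        dx = X[j, 0] - X[i, 0]
        dy = X[j, 1] - X[i, 1]
        l = math.sqrt(dx * dx + dy * dy)
        L += l
        lam = l / l0[i]
        t = _tension(lam, E_s, D_LD, beta_LD, ld_shear)
        tx = t * dx / l
        ty = t * dy / l
        F[i, 0] += tx
        F[i, 1] += ty
        F[j, 0] -= tx
        F[j, 1] -= ty

    lam_C = L / L0
    A = _shoelace(X)

    # pressure penalty, via the node-normal arclength vector
    # n_ds_i = 0.5 * rot(X_{i+1} - X_{i-1}) (outward for CCW ordering)
    p = k_p * (1.0 - A / A_ref)
    if ld_vol:
        p *= _alpha(lam_C, D_LD, beta_LD)
    for i in range(n):
        ip = (i + 1) % n
        im = (i - 1) % n
        dx = X[ip, 0] - X[im, 0]
        dy = X[ip, 1] - X[im, 1]
        F[i, 0] += p * 0.5 * dy
        F[i, 1] -= p * 0.5 * dx

    # bending: F = -grad of sum_j 0.5 E_b (kappa_j - kappa0_j)^2 ds0_j with
    # kappa_j = theta_j / ds0_j (turning angle over rest node arclength);
    # the hardening multiplier scales the tension-like prefactor
    for i in range(n):
        ip = (i + 1) % n
        im = (i - 1) % n
        th, gax, gay, gbx, gby, gcx, gcy = _turning_angle_and_grad(
            X[im, 0], X[im, 1], X[i, 0], X[i, 1], X[ip, 0], X[ip, 1]
        )
        ds0 = 0.5 * (l0[im] + l0[i])
        k = th / ds0
        c = E_b * (k - kappa0[i])
        if ld_bend:
            # hardening argument: the larger of local and whole-cell
            # stretch, so bending stiffens in locally *compressed* (pinching)
            # regions of a globally stretched cell — the buckling guard
            lim = math.sqrt(
                (X[i, 0] - X[im, 0]) ** 2 + (X[i, 1] - X[im, 1]) ** 2
            ) / l0[im]
            lip = math.sqrt(
                (X[ip, 0] - X[i, 0]) ** 2 + (X[ip, 1] - X[i, 1]) ** 2
            ) / l0[i]
            lam_b = 0.5 * (lim + lip)
            if lam_C > lam_b:
                lam_b = lam_C
            c *= _alpha(lam_b, D_LD, beta_LD)
        F[im, 0] -= c * gax
        F[im, 1] -= c * gay
        F[i, 0] -= c * gbx
        F[i, 1] -= c * gby
        F[ip, 0] -= c * gcx
        F[ip, 1] -= c * gcy

    return A, lam_C


@njit(cache=True)
def _self_intersects(X):
    """True if any two non-adjacent segments of the closed ring cross."""
    n = X.shape[0]
    for i in range(n):
        i1 = (i + 1) % n
        p0x, p0y = X[i, 0], X[i, 1]
        p1x, p1y = X[i1, 0], X[i1, 1]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            j1 = (j + 1) % n
            q0x, q0y = X[j, 0], X[j, 1]
            q1x, q1y = X[j1, 0], X[j1, 1]
            d1x, d1y = p1x - p0x, p1y - p0y
            d2x, d2y = q1x - q0x, q1y - q0y
            denom = d1x * d2y - d1y * d2x
            if denom == 0.0:
                continue
            rx, ry = q0x - p0x, q0y - p0y
            t = (rx * d2y - ry * d2x) / denom
            s = (rx * d1y - ry * d1x) / denom
            if 0.0 < t < 1.0 and 0.0 < s < 1.0:
                return True
    return False


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def ld_coefficient(lam, D_LD: float, beta_LD: float, clamp: bool = True):
    """Strain-hardening coefficient alpha(lambda).

    alpha = 1 + D_LD (e^(lambda beta_LD) - e^(beta_LD)); exactly 1 at
    lambda = 1 and monotone increasing for positive coefficients.  With
    ``clamp`` (the default) alpha is floored at 1 under compression, so the
    hardening never weakens the compressive response.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch ratio must be positive")
    a = 1.0 + D_LD * (np.exp(lam * beta_LD) - np.exp(beta_LD))
    if clamp:
        a = np.maximum(a, 1.0)
    return a if a.ndim else float(a)


def segment_tension(lam, params: PhysicalParams, flags: CaseFlags):
    """Neo-Hookean segment tension [dyn cm^-1], alpha-scaled when hardened."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch ratio must be positive")
    t = params.E_s * (lam**3 - 1.0) / lam**1.5
    if flags.ld_on_shear:
        t = t * ld_coefficient(lam, params.D_LD, params.beta_LD)
    return t if t.ndim else float(t)


def discrete_curvature(X: np.ndarray, i: int) -> float:
    """Signed curvature at node ``i`` of a closed ring [1/length-unit of X].

    Turning angle of the triplet around node i divided by the mean adjacent
    segment length; positive where a counter-clockwise ring is locally
    convex, 0 for collinear triplets, and diverging toward +/-pi/ds for a
    fold-back cusp (which a circumscribed-circle estimator would read as
    zero curvature — the failure mode of buckling membranes).
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    im, ip = (i - 1) % n, (i + 1) % n
    th = _turning_angle_and_grad(
        X[im, 0], X[im, 1], X[i, 0], X[i, 1], X[ip, 0], X[ip, 1]
    )[0]
    ds = 0.5 * (
        math.hypot(X[i, 0] - X[im, 0], X[i, 1] - X[im, 1])
        + math.hypot(X[ip, 0] - X[i, 0], X[ip, 1] - X[i, 1])
    )
    return float(th / ds) if ds > 0 else 0.0


def bending_tension(
    kappa, kappa0, lam_local, params: PhysicalParams, flags: CaseFlags
):
    """Bending resistance E_b (kappa - kappa_0), alpha-scaled when hardened."""
    t = params.E_b * (np.asarray(kappa, dtype=float) - kappa0)
    if flags.ld_on_bending:
        t = t * ld_coefficient(lam_local, params.D_LD, params.beta_LD)
    return t if np.ndim(t) else float(t)


def enclosed_area(X: np.ndarray) -> float:
    """Polygon area of the node ring (Green's theorem / shoelace), exact."""
    X = np.ascontiguousarray(X, dtype=float)
    if _self_intersects(X):
        raise ValueError("membrane polygon is self-intersecting")
    return abs(_shoelace(X))


def internal_pressure(
    A: float, A_ref: float, lam_C: float, params: PhysicalParams, flags: CaseFlags
) -> float:
    """Pressure penalty p_int [dyn cm^-2]; positive (outward) when A < A_ref."""
    if A <= 0 or A_ref <= 0:
        raise ValueError("areas must be positive")
    p = params.k_p * (1.0 - A / A_ref)
    if flags.ld_on_volume:
        p *= ld_coefficient(lam_C, params.D_LD, params.beta_LD)
    return float(p)


@dataclass
class MembraneMesh:
    """Closed Lagrangian node ring with its reference geometry.

    ``X`` is (N, 2) in um, counter-clockwise.  ``l0`` are per-segment rest
    lengths (segment i joins node i to i+1), ``kappa0`` the spontaneous
    curvature per node [um^-1], ``A_ref`` the rest enclosed area [um^2] and
    ``L0`` the rest circumference [um].
    """

    X: np.ndarray
    l0: np.ndarray
    kappa0: np.ndarray
    A_ref: float
    L0: float

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=float)
        self.l0 = np.asarray(self.l0, dtype=float)
        self.kappa0 = np.asarray(self.kappa0, dtype=float)
        if not math.isclose(self.l0.sum(), self.L0, rel_tol=1e-12):
            raise ValueError("rest segment lengths must sum to L0")
        if _shoelace(self.X) <= 0:
            raise ValueError("node ring must be ordered counter-clockwise")

    @classmethod
    def circle(
        cls, center: tuple[float, float], radius: float, n_nodes: int
    ) -> "MembraneMesh":
        """Regular-polygon discretization of a circular rest shape.

        The rest area is the polygon area (O(N^-2) below pi r^2) and the
        spontaneous curvature is 1/radius at every node.
        """
        th = 2.0 * np.pi * np.arange(n_nodes) / n_nodes
        X = np.column_stack(
            [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
        )
        l_seg = 2.0 * radius * math.sin(math.pi / n_nodes)
        l0 = np.full(n_nodes, l_seg)
        L0 = n_nodes * l_seg
        A_ref = 0.5 * n_nodes * radius**2 * math.sin(2.0 * math.pi / n_nodes)
        kappa0 = np.full(n_nodes, 1.0 / radius)
        return cls(X=X, l0=l0, kappa0=kappa0, A_ref=A_ref, L0=L0)

    @property
    def n_nodes(self) -> int:
        return len(self.X)

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.X, self.X[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def area(self) -> float:
        return enclosed_area(self.X)


def assemble_nodal_forces(
    mesh: MembraneMesh, params: PhysicalParams, flags: CaseFlags
) -> np.ndarray:
    """Per-node line forces [dyn cm^-1] from the three membrane modalities.

    The mesh coordinates (um) are converted to CGS internally; tension acts
    along each adjacent segment, bending along the energy gradient, and the
    pressure penalty along outward node normals.  The three contributions
    individually carry zero net force and zero net torque for a closed ring.
    """
    X_cm = np.ascontiguousarray(mesh.X * UM_TO_CM)
    F = np.empty_like(X_cm)
    A, lam_C = _assemble_forces(
        X_cm,
        mesh.l0 * UM_TO_CM,
        mesh.kappa0 / UM_TO_CM,
        mesh.A_ref * UM_TO_CM**2,
        mesh.L0 * UM_TO_CM,
        params.E_s,
        params.E_b,
        params.k_p,
        params.D_LD,
        params.beta_LD,
        flags.ld_on_shear,
        flags.ld_on_bending,
        flags.ld_on_volume,
        F,
    )
    if not np.all(np.isfinite(F)):
        raise FloatingPointError("non-finite membrane force")
    return F
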