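"""Physical constants, lattice scaling and unit conversion.

All physical quantities in this package are carried in CGS units (cm, s, g,
dyn) except where a field is documented in micrometre-based units.  The
lattice-Boltzmann solver works in lattice units (h = dt = 1, reference
density 1); :class:`LatticeScales` owns the conversion contract between the
two systems.

The 2D world is understood per unit depth: "force" on a membrane node is a
line force [dyn cm^-1], a body-force density is [dyn cm^-3], and membrane
tension shares the dyn cm^-1 unit with the shear modulus ``E_s``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "PhysicalParams",
    "LatticeScales",
    "relaxation_time",
    "to_lattice",
    "to_physical",
    "UM_TO_CM",
    "CP_TO_POISE",
]

UM_TO_CM = 1.0e-4
CP_TO_POISE = 1.0e-2  # 1 cP = 0.01 g cm^-1 s^-1

#: Morse surface-energy conversion into CGS (erg cm^-2).  The pair-potential
#: amplitude is quoted in its native micrometre-based surface-energy unit;
#: physically meaningful depletion-mediated adhesion energies for red cells
#: are of order 1e-7..1e-6 J m^-2, so the native unit is mapped as J m^-2
#: (1 J m^-2 = 1e3 erg cm^-2).  See docs/methods.md for the discussion.
MORSE_ENERGY_TO_CGS = 1.0e3


@dataclass
class PhysicalParams:
    """Constitutive constants of the membrane/fluid model.

    Attributes
    ----------
    E_s : float
        Membrane shear elastic modulus [dyn cm^-1].
    E_b : float
        Membrane bending modulus [dyn cm] (energy per unit depth x length).
    k_p : float
        Area-incompressibility (pressure penalty) coefficient [dyn cm^-2].
    D_LD, beta_LD : float
        Amplitude and exponent rate of the large-deformation (strain
        hardening) coefficient alpha(lambda) = 1 + D_LD (e^(lambda beta) -
        e^beta), both dimensionless.
    D_e : float
        Morse surface energy, native micrometre-based unit.
    beta_morse : float
        Morse decay rate [um^-1].
    r_0 : float
        Morse zero-force distance [um].
    R_active : float
        Interaction cutoff distance [um].
    mu_plasma, mu_cyto : float
        Dynamic viscosities of suspending plasma and cytoplasm [cP].
    a_cell : float
        Equivalent cell radius [um] used in dimensionless shear rates.
    """

    E_s: float = 6.0e-3
    E_b: float = 1.0e-10
    k_p: float = 2.0e2
    D_LD: float = 2.34e-4
    beta_LD: float = 8.0
    D_e: float = 1.3e-7
    beta_morse: float = 3.84
    r_0: float = 0.49
    R_active: float = 0.49 + 5.0 / 3.84
    mu_plasma: float = 1.2
    mu_cyto: float = 6.0
    a_cell: float = 4.17

    def __post_init__(self) -> None:
        for name in ("E_s", "E_b", "k_p", "mu_plasma", "mu_cyto", "a_cell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.r_0 >= self.R_active:
            raise ValueError("r_0 must be smaller than the cutoff R_active")

    @property
    def nu_plasma(self) -> float:
        """Plasma kinematic viscosity [cm^2 s^-1] at unit density."""
        return self.mu_plasma * CP_TO_POISE

    @property
    def nu_cyto(self) -> float:
        """Cytoplasm kinematic viscosity [cm^2 s^-1] at unit density."""
        return self.mu_cyto * CP_TO_POISE


@dataclass
class LatticeScales:
    """Physical <-> lattice unit conversion.

    Parameters
    ----------
    h : float
        Lattice spacing [um].
    dt : float
        Time step [s].
    rho0 : float
        Reference mass density [g cm^-3]; both fluids share it, only the
        viscosity contrast is modelled.
    """

    h: float = 0.25
    dt: float = 1.0
    rho0: float = 1.0
    c_s: float = field(init=False)

    def __post_init__(self) -> None:
        if self.h <= 0 or self.dt <= 0 or self.rho0 <= 0:
            raise ValueError("h, dt and rho0 must be strictly positive")
        self.c_s = self.h_cm / (math.sqrt(3.0) * self.dt)

    @property
    def h_cm(self) -> float:
        return self.h * UM_TO_CM

    @classmethod
    def from_tau(
        cls,
        tau_plasma: float,
        h: float,
        nu_plasma: float,
        rho0: float = 1.0,
    ) -> "LatticeScales":
        """Fix the time step so the plasma relaxation time equals ``tau_plasma``.

        ``nu_plasma`` is the physical plasma kinematic viscosity [cm^2 s^-1];
        ``h`` the lattice spacing [um].
        """
        if tau_plasma <= 0.5:
            raise ValueError("tau_plasma must exceed 1/2")
        h_cm = h * UM_TO_CM
        dt = (tau_plasma - 0.5) * h_cm**2 / (3.0 * nu_plasma)
        return cls(h=h, dt=dt, rho0=rho0)

    def factor(self, unit: str) -> float:
        """CGS magnitude of one lattice unit of the tagged quantity."""
        L, T, R = self.h_cm, self.dt, self.rho0
        try:
            return {
                "length": L,
                "time": T,
                "velocity": L / T,
                "force": R * L**4 / T**2,
                "stress": R * L**2 / T**2,
                "pressure": R * L**2 / T**2,
                "tension": R * L**3 / T**2,
                "viscosity": R * L**2 / T,
                "energy": R * L**5 / T**2,
            }[unit]
        except KeyError:
            raise ValueError(f"unknown unit tag {unit!r}") from None


def relaxation_time(nu: float, scales: LatticeScales) -> float:
    """Dimensionless BGK relaxation time for kinematic viscosity ``nu``.

    ``nu = (tau - 1/2) c_s^2 dt`` inverted for tau; ``nu`` in cm^2 s^-1.
    Values tau <= 1/2 are unstable and rejected; tau >= 2 triggers an
    accuracy warning (the BGK truncation error grows with tau).
    """
    if nu <= 0:
        raise ValueError("kinematic viscosity must be positive")
    tau = nu / (scales.c_s**2 * scales.dt) + 0.5
    if tau <= 0.5:
        raise ValueError(f"relaxation time {tau} <= 1/2 is unstable")
    if tau >= 2.0:
        warnings.warn(
            f"relaxation time {tau:.3g} >= 2; BGK accuracy degrades",
            stacklevel=2,
        )
    return tau


def to_lattice(value: float, unit: str, scales: LatticeScales) -> float:
    """Convert a physical CGS quantity to lattice units."""
    return value / scales.factor(unit)


def to_physical(value: float, unit: str, scales: LatticeScales) -> float:
    """Convert a lattice-unit quantity back to physical CGS units."""
    return value * scales.factor(unit)
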