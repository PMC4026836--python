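"""Structured text configuration.

A run is described by a TOML file with four sections::

    [physical]   # fields of PhysicalParams
    [lattice]    # h [um], tau_plasma (dt is derived), rho0
    [experiment] # kind = "shear" | "channel", plus driver fields
    [case]       # name = "I" | "II" | "III", or the four LD flags

Unknown keys anywhere are errors: silent typos in constitutive constants are
worse than a crash.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from typing import Any

from .membrane import CaseFlags
from .units import LatticeScales, PhysicalParams

__all__ = ["LatticeConfig", "ExperimentConfig", "SimulationConfig", "load_config"]


@dataclass
class LatticeConfig:
    h: float = 0.25
    tau_plasma: float = 0.8
    rho0: float = 1.0

    def scales(self, params: PhysicalParams) -> LatticeScales:
        return LatticeScales.from_tau(
            self.tau_plasma, self.h, params.nu_plasma, self.rho0
        )


@dataclass
class ExperimentConfig:
    kind: str = "channel"
    # shear driver
    G: float = 0.5
    domain_half_height: float = 10.0  # [um]
    shear_duration: float = 0.0  # [s]; 0 -> driver default
    # channel driver
    pseudoshear: float = 150.0  # [s^-1]
    channel_length: float = 80.0  # [um]
    channel_width: float = 20.0  # [um]
    n_cells: int = 12
    hematocrit: float = 0.38
    transit_cycles: float = 10.0
    n_nodes: int = 80
    seed: int = 0
    record_every: int = 0  # steps between metric frames; 0 -> auto

    def __post_init__(self) -> None:
        if self.kind not in ("shear", "channel"):
            raise ValueError(f"unknown experiment kind {self.kind!r}")


_CASE_TABLE = {
    "I": CaseFlags(False, False, False, False),
    "II": CaseFlags(True, False, False, False),
    "III": CaseFlags(True, True, True, True),
}


@dataclass
class SimulationConfig:
    physical: PhysicalParams = field(default_factory=PhysicalParams)
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    case: CaseFlags = field(default_factory=lambda: _CASE_TABLE["III"])

    def scales(self) -> LatticeScales:
        return self.lattice.scales(self.physical)


def _build(cls: type, section: dict[str, Any], name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
    return cls(**section)


def _build_case(section: dict[str, Any]) -> CaseFlags:
    section = dict(section)
    name = section.pop("name", None)
    if name is not None:
        if section:
            raise ValueError("[case] gives both a name and explicit flags")
        try:
            return _CASE_TABLE[name]
        except KeyError:
            raise ValueError(f"unknown case name {name!r}") from None
    return _build(CaseFlags, section, "case")


def load_config(path: str) -> SimulationConfig:
    """Load a TOML run configuration; unknown sections or keys are errors."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {"physical", "lattice", "experiment", "case"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return SimulationConfig(
        physical=_build(PhysicalParams, raw.get("physical", {}), "physical"),
        lattice=_build(LatticeConfig, raw.get("lattice", {}), "lattice"),
        experiment=_build(ExperimentConfig, raw.get("experiment", {}), "experiment"),
        case=_build_case(raw.get("case", {})),
    )
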