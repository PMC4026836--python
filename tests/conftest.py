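import dataclasses
import warnings

import numpy as np
import pytest

from hemoflow2d.config import ExperimentConfig, LatticeConfig, SimulationConfig
from hemoflow2d.membrane import CaseFlags


@pytest.fixture
def params():
    from hemoflow2d.units import PhysicalParams

    return PhysicalParams()


@pytest.fixture
def scales():
    from hemoflow2d.units import LatticeScales, PhysicalParams

    p = PhysicalParams()
    return LatticeScales.from_tau(0.8, 0.5, p.nu_plasma)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def shear_config(G: float, S: float = 30.0) -> SimulationConfig:
    """Scaled-down single-cell shear study conditions."""
    from hemoflow2d.drivers import similarity_speedup

    cfg = SimulationConfig(lattice=LatticeConfig(h=0.5, tau_plasma=1.1))
    cfg = dataclasses.replace(
        cfg,
        experiment=ExperimentConfig(
            kind="shear", G=G, domain_half_height=12.5, n_nodes=48
        ),
    )
    return similarity_speedup(cfg, S)


CHANNEL_SPEEDUP = {50.0: 18.0, 150.0: 6.0, 500.0: 1.8}


def channel_config(
    case: str, pseudoshear: float, seed: int = 1, n_cells: int = 12
) -> SimulationConfig:
    """Scaled-down multi-cell channel study conditions."""
    from hemoflow2d.drivers import similarity_speedup

    cfg = SimulationConfig(
        lattice=LatticeConfig(h=1.0, tau_plasma=0.8),
        case=CaseFlags.case(case),
    )
    cfg = dataclasses.replace(
        cfg,
        experiment=ExperimentConfig(
            kind="channel",
            pseudoshear=pseudoshear,
            n_nodes=36,
            transit_cycles=3.0,
            n_cells=n_cells,
            seed=seed,
        ),
    )
    return similarity_speedup(cfg, CHANNEL_SPEEDUP[pseudoshear])


def run_channel_quiet(cfg, **kw):
    from hemoflow2d.drivers import run_channel

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_channel(cfg.experiment, cfg, **kw)


def run_shear_quiet(cfg, **kw):
    from hemoflow2d.drivers import run_simple_shear

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_simple_shear(cfg.experiment, cfg, **kw)
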