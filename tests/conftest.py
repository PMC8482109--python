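"""Shared fixtures: field parameters, metabolite tables, designed SSRF
pulses (session-scoped, design is deterministic), phantoms and helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hpepi import (
    FieldParams,
    Geometry2D,
    Metabolite,
    MetaboliteTable,
    build_rat_phantom,
    default_metabolites,
    design_ssrf_pulse,
    load_config,
    make_flyback_trajectory,
)


@pytest.fixture(scope="session")
def field() -> FieldParams:
    return FieldParams()


@pytest.fixture(scope="session")
def metabolites() -> MetaboliteTable:
    return default_metabolites()


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def pyruvate_pulse(config, field):
    return design_ssrf_pulse(config.design_spec_for("pyruvate"), field,
                             metabolite="pyruvate")


@pytest.fixture(scope="session")
def lactate_pulse(config, field):
    return design_ssrf_pulse(config.design_spec_for("lactate"), field,
                             metabolite="lactate")


@pytest.fixture(scope="session")
def geom16() -> Geometry2D:
    return Geometry2D((16, 16), (80.0, 80.0))


@pytest.fixture(scope="session")
def traj16(geom16, field):
    return make_flyback_trajectory(geom16, field)


@pytest.fixture()
def phantom16(geom16):
    return build_rat_phantom(geom16, seed=3)


@pytest.fixture(scope="session")
def no_relax_metabolites() -> MetaboliteTable:
    """Relaxation-free table for closed-form magnetization ledgers."""
    inf = math.inf
    return MetaboliteTable(
        [
            Metabolite("pyruvate", 172.0, inf, inf),
            Metabolite("lactate", 184.3, inf, inf),
            Metabolite("urea", 163.5, 44.0, 0.1),
        ]
    )


class UnitPulse:
    """Idealized excitation stand-in: unit excitation weight everywhere.

    Used where a closed-form magnetization ledger or pure Fourier
    round-trip is the point and the SSRF passband shape is not.
    """

    def __init__(self, metabolite: str, flip: float, center_offset_hz: float = 0.0):
        self.metabolite = metabolite
        self.flip = flip
        self.center_offset_hz = center_offset_hz
        grid = np.arange(-5000.0, 5001.0, 2.0)
        self.meta = {"weight_curve": (grid, np.ones_like(grid))}

    def retuned(self, center_offset_hz: float) -> "UnitPulse":
        return UnitPulse(self.metabolite, self.flip, center_offset_hz)


@pytest.fixture()
def unit_pulse():
    return UnitPulse
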