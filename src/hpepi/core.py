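"""Shared physical constants, metabolite table and acquisition geometry.

Unit conventions used throughout the package:

* magnetic field amplitudes in gauss (G), gradients in G/cm
* gyromagnetic ratio in Hz/G
* times in seconds, frequencies in Hz, chemical shifts in ppm
* distances: image-space geometry in mm, gradient/k-space arithmetic in cm

The ppm scale is anchored to the scanner carrier: a species at chemical
shift ``s`` ppm sits ``(s - carrier_ppm) * f0`` Hz away from the carrier,
with ``f0`` in MHz (so that one ppm equals ``f0`` Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Iterator, Mapping

import yaml

__all__ = [
    "FieldParams",
    "Metabolite",
    "MetaboliteTable",
    "Geometry2D",
    "ppm_to_hz",
    "resolution",
    "default_field",
    "default_metabolites",
    "load_packaged_defaults",
    "InvalidGeometryError",
]

#: 13C gyromagnetic ratio in Hz/G (gamma/2pi).
GAMMA_13C_HZ_PER_G = 1070.8

#: 1H gyromagnetic ratio in Hz/G, used only by the profile-measurement
#: fixture (water phantom scanned in proton mode).
GAMMA_1H_HZ_PER_G = 4257.6


class InvalidGeometryError(ValueError):
    """Raised for degenerate image geometries (zero matrix size etc.)."""


@dataclass(frozen=True)
class FieldParams:
    """Static field / transmit chain parameters.

    Attributes
    ----------
    b0:
        Main field strength in tesla.
    f0:
        Carrier frequency in MHz.  This value governs all ppm<->Hz
        conversions (1 ppm == ``f0`` Hz).
    gamma:
        Gyromagnetic ratio of the imaged nucleus in Hz/G.
    b1_max:
        Maximum achievable RF amplitude in gauss.
    """

    b0: float = 4.7
    f0: float = 50.7
    gamma: float = GAMMA_13C_HZ_PER_G
    b1_max: float = 2.0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("carrier frequency f0 must be positive")
        if self.gamma <= 0:
            raise ValueError("gyromagnetic ratio must be positive")
        if self.b1_max <= 0:
            raise ValueError("b1_max must be positive")


def ppm_to_hz(shift_ppm: float, field: FieldParams) -> float:
    """Convert a chemical-shift offset in ppm to Hz.

    Positive ppm means higher frequency.  With ``f0`` in MHz the
    conversion is exactly ``shift_ppm * f0`` Hz.
    """
    return shift_ppm * field.f0


@dataclass(frozen=True)
class Metabolite:
    """A spectral species: chemical shift and relaxation constants.

    ``t1``/``t2`` are longitudinal/transverse relaxation times in
    seconds; ``t2 <= t1`` is enforced.
    """

    name: str
    shift_ppm: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(f"{self.name}: relaxation times must be positive")
        if self.t2 > self.t1:
            raise ValueError(f"{self.name}: t2 must not exceed t1")


class MetaboliteTable(Mapping[str, Metabolite]):
    """Ordered mapping of metabolite name -> :class:`Metabolite`.

    Shifts must be unique: two species at the same ppm cannot be
    distinguished spectrally and indicate a config error.
    """

    def __init__(self, metabolites: Iterator[Metabolite] | list[Metabolite]):
        self._table: dict[str, Metabolite] = {}
        for m in metabolites:
            if m.name in self._table:
                raise ValueError(f"duplicate metabolite {m.name!r}")
            self._table[m.name] = m
        shifts = [m.shift_ppm for m in self._table.values()]
        if len(set(shifts)) != len(shifts):
            raise ValueError("chemical shifts must be unique per metabolite")

    def __getitem__(self, name: str) -> Metabolite:
        return self._table[name]

    def __iter__(self):
        return iter(self._table)

    def __len__(self) -> int:
        return len(self._table)

    def offset_hz(self, name: str, field: FieldParams, carrier_ppm: float) -> float:
        """Frequency offset of ``name`` from a carrier placed at ``carrier_ppm``."""
        return ppm_to_hz(self[name].shift_ppm - carrier_ppm, field)

    def offsets_hz(self, field: FieldParams, carrier_ppm: float) -> dict[str, float]:
        return {n: self.offset_hz(n, field, carrier_ppm) for n in self._table}


@dataclass(frozen=True)
class Geometry2D:
    """2D Cartesian acquisition geometry.

    ``matrix`` is (n_phase, n_read) samples, ``fov`` the matching field
    of view in mm, ``slice_thickness`` in mm.
    """

    matrix: tuple[int, int]
    fov: tuple[float, float]
    slice_thickness: float = 20.0

    def __post_init__(self) -> None:
        if any(int(m) < 1 for m in self.matrix):
            raise InvalidGeometryError(f"matrix entries must be >= 1, got {self.matrix}")
        if any(f <= 0 for f in self.fov):
            raise InvalidGeometryError(f"fov entries must be positive, got {self.fov}")
        if self.slice_thickness <= 0:
            raise InvalidGeometryError("slice thickness must be positive")


def resolution(geom: Geometry2D) -> tuple[float, float]:
    """Per-dimension voxel size in mm (``fov / matrix``, exact)."""
    return tuple(f / m for f, m in zip(geom.fov, geom.matrix))


# ---------------------------------------------------------------------------
# Packaged defaults
# ---------------------------------------------------------------------------

def load_packaged_defaults() -> dict:
    """Raw dict of the packaged default configuration."""
    text = resources.files("hpepi.data").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def field_from_dict(d: Mapping) -> FieldParams:
    return FieldParams(**dict(d))


def metabolites_from_dict(d: Mapping) -> MetaboliteTable:
    return MetaboliteTable(
        [Metabolite(name=name, **dict(params)) for name, params in d.items()]
    )


def default_field() -> FieldParams:
    return field_from_dict(load_packaged_defaults()["field"])


def default_metabolites() -> MetaboliteTable:
    return metabolites_from_dict(load_packaged_defaults()["metabolites"])
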