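"""Run configuration: schema-checked loading of the packaged defaults,
optionally overridden by a user YAML file.

Unknown keys anywhere in the tree are rejected (fail-loud, with the
offending key path), so typos cannot silently fall back to defaults.
All randomness in a run flows from the single ``seed`` entry.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import yaml

from .core import (
    FieldParams,
    Geometry2D,
    MetaboliteTable,
    field_from_dict,
    load_packaged_defaults,
    metabolites_from_dict,
)
from .phantom import InflowParams, PhantomParams
from .pulses import SSRFDesignSpec, stopbands_for
from .scanner import CSIProtocol, ProtocolSchedule, SlabProtocol

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration schema violation, reporting the field path."""


def _merge(defaults: dict, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict) and isinstance(value, Mapping):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass(frozen=True)
class EPIConfig:
    geom: Geometry2D
    read_grad: float
    noise_sigma: float


@dataclass(frozen=True)
class PulseRequest:
    flip: float
    stopband_targets: tuple[str, ...]


@dataclass(frozen=True)
class ProfileQC:
    sweep_hz: float = 600.0
    n_steps: int = 121
    z_range_cm: float = 3.0
    n_z: int = 121


@dataclass(frozen=True)
class RunConfig:
    """Fully-typed configuration of one virtual experiment."""

    field: FieldParams
    carrier_ppm: float
    metabolites: MetaboliteTable
    design: SSRFDesignSpec          # base spec; per-pulse flip/stopbands applied
    pulses: dict[str, PulseRequest]
    epi: EPIConfig
    schedule: ProtocolSchedule
    csi: CSIProtocol
    slab: SlabProtocol
    phantom_grid: Geometry2D
    phantom_params: PhantomParams
    t2star: float
    calibration_search_hz: float
    calibration_min_snr: float
    apodization_hz: float
    window_halfwidth_ppm: float
    profile_qc: ProfileQC
    seed: int
    raw: dict = dc_field(repr=False, default_factory=dict)

    def design_spec_for(self, name: str) -> SSRFDesignSpec:
        req = self.pulses[name]
        base = self.design
        return SSRFDesignSpec(
            flip=req.flip,
            pass_halfwidth_ppm=base.pass_halfwidth_ppm,
            stopbands_ppm=stopbands_for(
                name, list(req.stopband_targets), self.metabolites,
                halfwidth_ppm=self.raw["pulse_design"]["stop_halfwidth_ppm"],
            ),
            tbw_spectral=base.tbw_spectral,
            max_ripple=base.max_ripple,
            slice_thickness=base.slice_thickness,
            tbw_spatial=base.tbw_spatial,
            grad_max=base.grad_max,
            slew_max=base.slew_max,
            dwell=base.dwell,
            max_duration=base.max_duration,
        )


def _build(cfg: dict) -> RunConfig:
    pd = cfg["pulse_design"]
    design = SSRFDesignSpec(
        flip=20.0,
        pass_halfwidth_ppm=pd["pass_halfwidth_ppm"],
        stopbands_ppm=(),
        tbw_spectral=pd["tbw_spectral"],
        max_ripple=pd["max_ripple"],
        slice_thickness=pd["slice_thickness"],
        tbw_spatial=pd["tbw_spatial"],
        grad_max=pd["grad_max"],
        slew_max=pd["slew_max"],
        dwell=pd["dwell"],
        max_duration=pd["max_duration"],
    )
    epi = cfg["epi"]
    csi = cfg["csi"]
    ph = cfg["phantom"]
    inflow = InflowParams(**ph["inflow"])
    try:
        return RunConfig(
            field=field_from_dict(cfg["field"]),
            carrier_ppm=float(cfg["carrier_ppm"]),
            metabolites=metabolites_from_dict(cfg["metabolites"]),
            design=design,
            pulses={
                name: PulseRequest(
                    flip=float(p["flip"]),
                    stopband_targets=tuple(p["stopband_targets"]),
                )
                for name, p in cfg["pulses"].items()
            },
            epi=EPIConfig(
                geom=Geometry2D(
                    tuple(epi["matrix"]), tuple(epi["fov"]), epi["slice_thickness"]
                ),
                read_grad=float(epi["read_grad"]),
                noise_sigma=float(epi["noise_sigma"]),
            ),
            schedule=ProtocolSchedule(
                interval=float(cfg["schedule"]["interval"]),
                duration=float(cfg["schedule"]["duration"]),
                flips=tuple(cfg["schedule"]["flips"].items()),
                start_delay=float(cfg["schedule"]["start_delay"]),
            ),
            csi=CSIProtocol(
                geom=Geometry2D(tuple(csi["matrix"]), tuple(csi["fov"])),
                flip=float(csi["flip"]),
                sw=float(csi["sw"]),
                n_points=int(csi["n_points"]),
                tr=float(csi["tr"]),
                n_frames=int(csi["n_frames"]),
                noise_sigma=float(csi["noise_sigma"]),
            ),
            slab=SlabProtocol(
                flip=float(cfg["slab"]["flip"]),
                sw=float(cfg["slab"]["sw"]),
                n_points=int(cfg["slab"]["n_points"]),
                noise_sigma=float(cfg["slab"]["noise_sigma"]),
            ),
            phantom_grid=Geometry2D(
                tuple(ph["matrix"]), tuple(ph["fov"]), ph["slice_thickness"]
            ),
            phantom_params=PhantomParams(
                b0_rms=float(ph["b0_rms"]),
                b0_max=float(ph["b0_max"]),
                b0_corr_mm=float(ph["b0_corr_mm"]),
                chest_offset_hz=float(ph["chest_offset_hz"]),
                kpl_tissue=float(ph["kpl_tissue"]),
                kpl_kidney=float(ph["kpl_kidney"]),
                urea_signal=float(ph["urea_signal"]),
                inflow=inflow,
            ),
            t2star=float(ph["t2star"]),
            calibration_search_hz=float(cfg["calibration"]["search_halfwidth_hz"]),
            calibration_min_snr=float(cfg["calibration"]["min_snr"]),
            apodization_hz=float(cfg["recon"]["apodization_hz"]),
            window_halfwidth_ppm=float(cfg["recon"]["window_halfwidth_ppm"]),
            profile_qc=ProfileQC(
                sweep_hz=float(cfg["profile_qc"]["sweep_hz"]),
                n_steps=int(cfg["profile_qc"]["n_steps"]),
                z_range_cm=float(cfg["profile_qc"]["z_range_cm"]),
                n_z=int(cfg["profile_qc"]["n_z"]),
            ),
            seed=int(cfg["seed"]),
            raw=cfg,
        )
    except (KeyError, TypeError, ValueError) as err:
        if isinstance(err, ConfigError):
            raise
        raise ConfigError(f"invalid configuration: {err}") from err


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> RunConfig:
    """Packaged defaults, overridden by a YAML file and/or a dict.

    Unknown keys raise :class:`ConfigError` with the field path.
    """
    cfg = load_packaged_defaults()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, Mapping):
            raise ConfigError(f"{path}: top level must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return _build(cfg)
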