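"""End-to-end orchestration of the virtual experiment.

Stage order mirrors a scan session: pulse design, excitation-profile
quality control, phantom synthesis, injection, slab pre-scan with
automatic center-frequency calibration, dynamic metabolite-specific
EPI, a matched dynamic CSI run (fresh injection), reconstruction, ROI
curve extraction, and an HTML/PNG report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import bloch, io as hpio
from .calibrate import CalibrationResult, compute_offsets, find_pyruvate_peak
from .config import RunConfig, load_config
from .core import ppm_to_hz
from .phantom import DigitalPhantom, HPState, build_rat_phantom, evolve_hp_state, initial_state
from .pulses import SSRFPulse, design_ssrf_pulse
from .recon import (
    MetaboliteImageSeries,
    extract_roi_curves,
    recon_csi,
    recon_epi_series,
    resample_mask,
)
from .scanner import (
    ScannerContext,
    SpectralGrid,
    acquire_csi,
    acquire_slab_spectrum,
    make_flyback_trajectory,
    measure_pulse_profile,
    run_dynamic_epi,
)

__all__ = ["ExperimentResult", "run_full_experiment", "design_pulses"]

log = logging.getLogger("hpepi")


@dataclass
class ExperimentResult:
    config: RunConfig
    pulses: dict[str, SSRFPulse]
    profiles_sim: dict[str, bloch.MagnetizationProfile]
    profiles_meas: dict[str, bloch.MagnetizationProfile]
    profile_rms: dict[str, float]
    phantom: DigitalPhantom | None = None
    calibration: CalibrationResult | None = None
    slab_spectrum: SpectralGrid | None = None
    epi_series: MetaboliteImageSeries | None = None
    csi_series: MetaboliteImageSeries | None = None
    roi_curves_epi: dict | None = None
    roi_curves_csi: dict | None = None
    outputs: dict[str, Path] = dc_field(default_factory=dict)


def design_pulses(config: RunConfig) -> dict[str, SSRFPulse]:
    """Design every pulse requested by the configuration."""
    out = {}
    for name in config.pulses:
        log.info("designing %s SSRF pulse", name)
        out[name] = design_ssrf_pulse(
            config.design_spec_for(name), config.field, metabolite=name
        )
        log.info(
            "%s: %d sub-pulses, %.2f ms, B1peak %.3f G",
            name, out[name].n_subpulses, out[name].duration * 1e3,
            out[name].b1_peak,
        )
    return out


def _profile_qc(config: RunConfig, pulses: dict[str, SSRFPulse]):
    qc = config.profile_qc
    z = np.linspace(-qc.z_range_cm, qc.z_range_cm, qc.n_z)
    f = np.linspace(-qc.sweep_hz, qc.sweep_hz, qc.n_steps)
    sims, meas, rms = {}, {}, {}
    for name, pulse in pulses.items():
        base = pulse.retuned(0.0)
        sims[name] = bloch.simulate_profile(base, z, f, config.field)
        measured = measure_pulse_profile(
            base, qc.sweep_hz, qc.n_steps, config.field, z_grid=z
        )
        meas[name] = bloch.regrid_profile(measured, z, f)
        diff = np.abs(meas[name].mxy) - np.abs(sims[name].mxy)
        rms[name] = float(
            np.sqrt(np.mean(diff**2)) / np.max(np.abs(sims[name].mxy))
        )
        log.info("profile congruence %s: RMS %.2f%% of peak", name, 100 * rms[name])
    return sims, meas, rms


def run_full_experiment(
    config: RunConfig | None = None,
    out_dir: str | Path = "hpepi_out",
    seed: int | None = None,
    make_report: bool = True,
    pulses: dict[str, SSRFPulse] | None = None,
) -> ExperimentResult:
    """Execute the full pipeline and write the output bundle.

    ``seed`` overrides the config seed; pre-designed ``pulses`` may be
    supplied to skip the (deterministic) design stage.
    """
    config = config or load_config()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(4)]

    # 1. pulse design + waveform export
    pulses = pulses or design_pulses(config)
    outputs: dict[str, Path] = {}
    for name, pulse in pulses.items():
        outputs.update(
            {f"{name}_{k}": v for k, v in hpio.write_pulse(pulse, out_dir / "waveforms", name).items()}
        )

    # 2. excitation-profile QC
    sims, meas, rms = _profile_qc(config, pulses)
    for name in pulses:
        outputs[f"profile_sim_{name}"] = hpio.write_profile_h5(
            sims[name], out_dir / "profiles" / f"{name}_sim.h5"
        )
        outputs[f"profile_meas_{name}"] = hpio.write_profile_h5(
            meas[name], out_dir / "profiles" / f"{name}_meas.h5"
        )

    result = ExperimentResult(
        config=config, pulses=pulses, profiles_sim=sims,
        profiles_meas=meas, profile_rms=rms, outputs=outputs,
    )
    if config.schedule.n_frames == 0:
        log.info("schedule duration 0: design/QC only")
        if make_report:
            from .report import write_report

            outputs["report"] = write_report(result, out_dir / "report")
        return result

    # 3. phantom + injection
    phantom = build_rat_phantom(config.phantom_grid, seeds[0], config.phantom_params)
    outputs["phantom"] = hpio.write_phantom_h5(phantom, out_dir / "phantom.h5")
    metab = config.metabolites
    state = initial_state(phantom, metab)

    # 4. slab pre-scan + autocalibration + dynamic EPI
    scanner = ScannerContext(
        field=config.field, metab=metab, carrier_ppm=config.carrier_ppm
    )
    state = evolve_hp_state(state, config.schedule.start_delay, metab)
    slab_spec, state = acquire_slab_spectrum(
        phantom, state, config.slab, scanner,
        t2star=config.t2star, seed=seeds[1],
    )
    nominal = scanner.metabolite_offset_hz("pyruvate")
    freq, snr = find_pyruvate_peak(
        slab_spec,
        (nominal - config.calibration_search_hz, nominal + config.calibration_search_hz),
        min_snr=config.calibration_min_snr,
    )
    calib = compute_offsets(freq, metab, config.field, pulses, peak_snr=snr)
    scanner.carrier_shift_hz += freq
    log.info("autocal: pyruvate at %+.1f Hz (SNR %.0f)", freq, snr)
    tuned = {n: p.retuned(calib.pulse_offsets[n]) for n, p in pulses.items()}
    traj = make_flyback_trajectory(
        config.epi.geom, config.field,
        grad_max=config.design.grad_max, slew_max=config.design.slew_max,
        dwell=config.design.dwell, read_grad=config.epi.read_grad,
    )
    frames, state = run_dynamic_epi(
        phantom, state, config.schedule, tuned, traj, scanner,
        noise_sigma=config.epi.noise_sigma, seed=seeds[2],
    )
    epi_series = recon_epi_series(frames, calib.recon_shifts)
    outputs.update(
        {f"epi_{k}": v for k, v in hpio.write_image_series_nifti(
            epi_series, out_dir / "epi"
        ).items()}
    )

    # 5. dynamic CSI (fresh injection, same phantom)
    csi_scanner = ScannerContext(
        field=config.field, metab=metab, carrier_ppm=config.carrier_ppm,
        carrier_shift_hz=scanner.carrier_shift_hz,
    )
    csi_state = initial_state(phantom, metab)
    csi_state = evolve_hp_state(csi_state, config.schedule.start_delay, metab)
    grids, _ = acquire_csi(
        phantom, csi_state, config.csi, csi_scanner,
        t2star=config.t2star, seed=seeds[3],
    )
    csi_series = recon_csi(
        grids, config.apodization_hz, metab, config.field, config.carrier_ppm,
        window_halfwidth_ppm=config.window_halfwidth_ppm,
        species=list(pulses) + (["urea"] if "urea" in metab else []),
        carrier_shift_hz=csi_scanner.carrier_shift_hz,
    )
    outputs.update(
        {f"csi_{k}": v for k, v in hpio.write_image_series_nifti(
            csi_series, out_dir / "csi"
        ).items()}
    )

    # 6. ROI curves
    rois = {}
    for roi in ("liver", "kidney_L", "kidney_R"):
        rois[roi] = phantom.masks[roi]
    epi_masks = {
        r: resample_mask(m, epi_series.geometry.matrix) for r, m in rois.items()
    }
    csi_masks = {
        r: resample_mask(m, csi_series.geometry.matrix) for r, m in rois.items()
    }
    curves_epi = extract_roi_curves(epi_series, {r: m for r, m in epi_masks.items() if m.any()})
    curves_csi = extract_roi_curves(csi_series, {r: m for r, m in csi_masks.items() if m.any()})
    curves_path = out_dir / "roi_curves.json"
    curves_path.write_text(
        json.dumps(
            {
                "epi": {r: {m: list(map(float, c)) for m, c in d.items()}
                        for r, d in curves_epi.items()},
                "csi": {r: {m: list(map(float, c)) for m, c in d.items()}
                        for r, d in curves_csi.items()},
                "calibration": {
                    "pyruvate_freq_hz": calib.pyruvate_freq,
                    "pulse_offsets_hz": calib.pulse_offsets,
                    "recon_shifts_hz": calib.recon_shifts,
                    "peak_snr": calib.peak_snr,
                },
            },
            indent=2,
        )
    )
    outputs["roi_curves"] = curves_path

    result.phantom = phantom
    result.calibration = calib
    result.slab_spectrum = slab_spec
    result.epi_series = epi_series
    result.csi_series = csi_series
    result.roi_curves_epi = curves_epi
    result.roi_curves_csi = curves_csi

    if make_report:
        from .report import write_report

        outputs["report"] = write_report(result, out_dir / "report")
    return result
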