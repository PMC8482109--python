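"""File formats: waveform text files, HDF5 containers, NIfTI image series.

Waveforms travel as plain text (magnitude / phase-degrees columns for
RF, one G/cm column for the gradient) with a JSON sidecar header; all
round-trips are exact at 9 significant digits.  Profiles, phantoms and
raw data use HDF5; reconstructed metabolite image series are written as
NIfTI (one file per metabolite, time as the 4th dimension).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .bloch import MagnetizationProfile
from .core import Geometry2D, resolution
from .phantom import DigitalPhantom, PhantomParams, InflowParams
from .pulses import SSRFPulse
from .recon import MetaboliteImageSeries

__all__ = [
    "write_pulse",
    "read_pulse",
    "write_profile_h5",
    "read_profile_h5",
    "write_phantom_h5",
    "read_phantom_h5",
    "write_image_series_nifti",
]

_FMT = "%.9g"


def write_pulse(pulse: SSRFPulse, out_dir: str | Path, stem: str | None = None) -> dict[str, Path]:
    """Write RF (magnitude, phase-degrees), gradient and JSON header."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or (pulse.metabolite or "pulse")
    rf_path = out_dir / f"{stem}_rf.txt"
    gr_path = out_dir / f"{stem}_grad.txt"
    hdr_path = out_dir / f"{stem}_header.json"
    mag = np.abs(pulse.rf)
    phase = np.degrees(np.angle(pulse.rf))
    np.savetxt(rf_path, np.column_stack([mag, phase]), fmt=_FMT,
               header="B1 magnitude (G), phase (degrees)")
    np.savetxt(gr_path, pulse.grad, fmt=_FMT, header="gradient (G/cm)")
    header = {
        "dwell_s": pulse.dwell,
        "duration_s": pulse.duration,
        "flip_deg": pulse.flip,
        "b1_peak_g": pulse.b1_peak,
        "center_offset_hz": pulse.center_offset_hz,
        "n_subpulses": pulse.n_subpulses,
        "metabolite": pulse.metabolite,
    }
    hdr_path.write_text(json.dumps(header, indent=2))
    return {"rf": rf_path, "grad": gr_path, "header": hdr_path}


def read_pulse(out_dir: str | Path, stem: str) -> SSRFPulse:
    """Round-trip reader for :func:`write_pulse` outputs."""
    out_dir = Path(out_dir)
    try:
        hdr = json.loads((out_dir / f"{stem}_header.json").read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"malformed header for {stem!r}: {err}") from err
    rf_cols = np.loadtxt(out_dir / f"{stem}_rf.txt", ndmin=2)
    if rf_cols.shape[1] != 2:
        raise ValueError(f"{stem}_rf.txt: expected 2 columns, got {rf_cols.shape[1]}")
    grad = np.loadtxt(out_dir / f"{stem}_grad.txt", ndmin=1)
    rf = rf_cols[:, 0] * np.exp(1j * np.radians(rf_cols[:, 1]))
    return SSRFPulse(
        rf=rf,
        grad=grad,
        dwell=hdr["dwell_s"],
        flip=hdr["flip_deg"],
        center_offset_hz=hdr["center_offset_hz"],
        n_subpulses=hdr["n_subpulses"],
        metabolite=hdr["metabolite"],
    )


def write_profile_h5(profile: MagnetizationProfile, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("z_grid", data=profile.z_grid)
        f.create_dataset("f_grid", data=profile.f_grid)
        f.create_dataset("mxy", data=profile.mxy)
        f.create_dataset("mz", data=profile.mz)
        f.attrs["m0"] = profile.m0
    return path


def read_profile_h5(path: str | Path) -> MagnetizationProfile:
    with h5py.File(path, "r") as f:
        return MagnetizationProfile(
            z_grid=f["z_grid"][()],
            f_grid=f["f_grid"][()],
            mxy=f["mxy"][()],
            mz=f["mz"][()],
            m0=float(f.attrs["m0"]),
        )


def write_phantom_h5(phantom: DigitalPhantom, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = phantom.seed
        f.attrs["matrix"] = phantom.grid.matrix
        f.attrs["fov_mm"] = phantom.grid.fov
        f.attrs["slice_thickness_mm"] = phantom.grid.slice_thickness
        f.create_dataset("b0_map", data=phantom.b0_map)
        if phantom.body is not None:
            f.create_dataset("body", data=phantom.body)
        g = f.create_group("masks")
        for name, m in phantom.masks.items():
            g.create_dataset(name, data=m)
        p = phantom.params
        f.attrs["params"] = json.dumps(
            {
                "b0_rms": p.b0_rms,
                "b0_max": p.b0_max,
                "b0_corr_mm": p.b0_corr_mm,
                "chest_offset_hz": p.chest_offset_hz,
                "kpl_tissue": p.kpl_tissue,
                "kpl_kidney": p.kpl_kidney,
                "urea_signal": p.urea_signal,
                "inflow": vars(p.inflow) | {},
            }
        )
    return path


def read_phantom_h5(path: str | Path) -> DigitalPhantom:
    with h5py.File(path, "r") as f:
        grid = Geometry2D(
            matrix=tuple(int(v) for v in f.attrs["matrix"]),
            fov=tuple(float(v) for v in f.attrs["fov_mm"]),
            slice_thickness=float(f.attrs["slice_thickness_mm"]),
        )
        raw = json.loads(f.attrs["params"])
        inflow = InflowParams(**raw.pop("inflow"))
        params = PhantomParams(inflow=inflow, **raw)
        return DigitalPhantom(
            grid=grid,
            masks={k: f["masks"][k][()].astype(bool) for k in f["masks"]},
            b0_map=f["b0_map"][()],
            seed=int(f.attrs["seed"]),
            params=params,
            body=f["body"][()].astype(bool) if "body" in f else None,
        )


def write_image_series_nifti(
    series: MetaboliteImageSeries, out_dir: str | Path
) -> dict[str, Path]:
    """One 4D NIfTI per metabolite; voxel sizes from the geometry (mm)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dy, dx = resolution(series.geometry)
    dz = series.geometry.slice_thickness
    paths = {}
    for met, imgs in series.images.items():
        # (t, y, x) -> (x, y, z=1, t)
        data = imgs.transpose(2, 1, 0)[:, :, None, :]
        affine = np.diag([dx, dy, dz, 1.0])
        img = nib.Nifti1Image(np.ascontiguousarray(data), affine)
        ts = series.timestamps[met]
        if ts.size > 1:
            img.header["pixdim"][4] = float(np.median(np.diff(ts)))
        path = out_dir / f"{met}.nii"
        nib.save(img, path)
        sidecar = out_dir / f"{met}.json"
        sidecar.write_text(
            json.dumps({"timestamps_s": list(map(float, ts)), "units": "SNR"}, indent=2)
        )
        paths[met] = path
    return paths


# ---------------------------------------------------------------------------
# Raw acquisition containers
# ---------------------------------------------------------------------------

def write_epi_raw_h5(frames, path, protocol_echo: dict | None = None) -> Path:
    """EPI k-space frames + enough trajectory metadata to rebuild it."""
    from .scanner import KSpaceFrame  # noqa: F401  (documented type)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traj = frames[0].traj
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=np.stack([fr.samples for fr in frames]))
        f.create_dataset(
            "metabolite",
            data=np.array([fr.metabolite for fr in frames], dtype=h5py.string_dtype()),
        )
        f.create_dataset("t_acq", data=np.array([fr.t_acq for fr in frames]))
        f.create_dataset("noise_sigma", data=np.array([fr.noise_sigma for fr in frames]))
        f.attrs["matrix"] = traj.geom.matrix
        f.attrs["fov_mm"] = traj.geom.fov
        f.attrs["slice_thickness_mm"] = traj.geom.slice_thickness
        f.attrs["read_grad"] = traj.read_grad
        f.attrs["esp"] = traj.esp
        f.attrs["bw_read"] = traj.bw_read
        f.attrs["bw_phase"] = traj.bw_phase
        if protocol_echo:
            f.attrs["protocol"] = json.dumps(protocol_echo)
    return path


def read_epi_raw_h5(path, field=None, grad_max: float = 10.0,
                    slew_max: float = 50.0, dwell: float = 4.0e-6):
    """Round-trip reader: rebuilds the trajectory from stored metadata."""
    from .core import FieldParams
    from .scanner import KSpaceFrame, make_flyback_trajectory

    with h5py.File(path, "r") as f:
        geom = Geometry2D(
            matrix=tuple(int(v) for v in f.attrs["matrix"]),
            fov=tuple(float(v) for v in f.attrs["fov_mm"]),
            slice_thickness=float(f.attrs["slice_thickness_mm"]),
        )
        traj = make_flyback_trajectory(
            geom, field or FieldParams(), grad_max=grad_max, slew_max=slew_max,
            dwell=dwell, read_grad=float(f.attrs["read_grad"]),
        )
        samples = f["samples"][()]
        mets = [m.decode() if isinstance(m, bytes) else str(m) for m in f["metabolite"][()]]
        t_acq = f["t_acq"][()]
        sigma = f["noise_sigma"][()]
    return [
        KSpaceFrame(samples=samples[i], metabolite=mets[i], t_acq=float(t_acq[i]),
                    noise_sigma=float(sigma[i]), traj=traj)
        for i in range(samples.shape[0])
    ]


def write_csi_raw_h5(grids, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g0 = grids[0]
    with h5py.File(path, "w") as f:
        f.create_dataset("fids", data=np.stack([g.fids for g in grids]))
        f.create_dataset("t_acq", data=np.array([g.t_acq for g in grids]))
        f.attrs["sw"] = g0.sw
        f.attrs["n_points"] = g0.n_points
        f.attrs["tr"] = g0.tr
        f.attrs["flip"] = g0.flip
        if g0.geom is not None:
            f.attrs["matrix"] = g0.geom.matrix
            f.attrs["fov_mm"] = g0.geom.fov
    return path


def read_csi_raw_h5(path):
    from .scanner import SpectralGrid

    with h5py.File(path, "r") as f:
        fids = f["fids"][()]
        t_acq = f["t_acq"][()]
        geom = None
        if "matrix" in f.attrs:
            geom = Geometry2D(
                matrix=tuple(int(v) for v in f.attrs["matrix"]),
                fov=tuple(float(v) for v in f.attrs["fov_mm"]),
            )
        return [
            SpectralGrid(
                fids=fids[i], sw=float(f.attrs["sw"]),
                n_points=int(f.attrs["n_points"]), tr=float(f.attrs["tr"]),
                flip=float(f.attrs["flip"]), t_acq=float(t_acq[i]), geom=geom,
            )
            for i in range(fids.shape[0])
        ]
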