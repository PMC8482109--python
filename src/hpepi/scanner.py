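"""Virtual acquisitions: flyback EPI, dynamic CSI, slab spectrum, and the
swept-frequency pulse-profile measurement.

The scanner consumes phantom magnetization per RF event through
:mod:`hpepi.phantom` and synthesizes raw data by explicit Fourier
summation over phantom voxels with per-sample off-resonance phase
accrual, so chemical-shift displacement and T2/T2* decay arise from the
physics rather than being painted in.

Trajectory convention: acquired sample ``m`` of line ``p`` sits exactly
on the Cartesian grid point ``k = (index - N/2) * dk`` with
``dk = 1/FOV``; sample times follow the flyback timing (plateau
sampling only, rewinders between same-polarity readout lobes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import bloch
from .core import FieldParams, Geometry2D, MetaboliteTable
from .phantom import DigitalPhantom, HPState, apply_rf_consumption, evolve_hp_state
from .pulses import SSRFPulse, _min_time_lobe

__all__ = [
    "ScannerContext",
    "FlybackTrajectory",
    "KSpaceFrame",
    "SpectralGrid",
    "ProtocolSchedule",
    "CSIProtocol",
    "SlabProtocol",
    "make_flyback_trajectory",
    "acquire_epi_frame",
    "run_dynamic_epi",
    "acquire_csi",
    "acquire_slab_spectrum",
    "measure_pulse_profile",
    "excitation_weights",
]


@dataclass
class ScannerContext:
    """Field, metabolite table and current carrier placement.

    ``carrier_shift_hz`` is the retuning applied by the calibration
    stage: the carrier sits at ``carrier_ppm`` plus this many Hz.
    """

    field: FieldParams
    metab: MetaboliteTable
    carrier_ppm: float = 172.0
    carrier_shift_hz: float = 0.0

    def metabolite_offset_hz(self, name: str) -> float:
        """Offset of a species from the current carrier, ignoring B0."""
        return (
            self.metab.offset_hz(name, self.field, self.carrier_ppm)
            - self.carrier_shift_hz
        )

    def offset_map(self, phantom: DigitalPhantom, name: str) -> np.ndarray:
        """Per-voxel frequency offset of ``name`` from the carrier (Hz)."""
        return self.metabolite_offset_hz(name) + phantom.b0_map


# ---------------------------------------------------------------------------
# Flyback EPI trajectory
# ---------------------------------------------------------------------------

@dataclass
class FlybackTrajectory:
    """Cartesian flyback EPI readout description.

    ``kx``/``ky`` (1/cm) and ``t`` (s) are per acquired sample, shape
    (n_phase, n_read); data are acquired only on the plateaus of
    same-polarity readout lobes (``flat_intervals`` per line).
    """

    geom: Geometry2D
    kx: np.ndarray
    ky: np.ndarray
    t: np.ndarray
    esp: float              # echo spacing, s
    bw_read: float          # Hz (= 1/ADC dwell)
    bw_phase: float         # Hz (= 1/esp)
    readout_duration: float # s
    read_grad: float        # G/cm plateau amplitude
    flat_intervals: list[tuple[float, float]] = dc_field(default_factory=list)

    @property
    def adc_dwell(self) -> float:
        return 1.0 / self.bw_read


def make_flyback_trajectory(
    geom: Geometry2D,
    field: FieldParams | None = None,
    grad_max: float = 10.0,
    slew_max: float = 50.0,
    dwell: float = 4.0e-6,
    read_grad: float = 5.0,
) -> FlybackTrajectory:
    """Build an N-line flyback EPI train covering a full Cartesian grid.

    Readout lobes are all positive; flyback rewinders (with the phase
    blip) separate them.  ``dk = 1/FOV`` exactly in both dimensions.
    """
    field = field or FieldParams()
    if read_grad <= 0 or read_grad > grad_max:
        raise ValueError("read_grad must be in (0, grad_max]")
    n_ph, n_rd = geom.matrix
    fov_y_cm, fov_x_cm = geom.fov[0] / 10.0, geom.fov[1] / 10.0
    dkx = 1.0 / fov_x_cm
    dky = 1.0 / fov_y_cm

    gamma = field.gamma
    adc_dwell = dkx / (gamma * read_grad)
    t_flat = n_rd * adc_dwell
    n_ramp = max(1, math.ceil(read_grad / (slew_max * 1e3 * dwell)))
    t_ramp = n_ramp * dwell
    # flyback rewinder cancels the full readout lobe; the phase blip
    # (area dky/gamma) plays during it and must fit inside
    lobe_area = read_grad * (t_flat + t_ramp)
    rew = _min_time_lobe(-lobe_area, grad_max, slew_max, dwell)
    t_rew = rew.size * dwell
    blip = _min_time_lobe(dky / gamma, grad_max, slew_max, dwell)
    if blip.size * dwell > t_rew:
        raise ValueError("phase blip does not fit within the flyback rewinder")
    esp = 2 * t_ramp + t_flat + t_rew

    m = np.arange(n_rd)
    p = np.arange(n_ph)
    kx = np.broadcast_to((m - n_rd // 2) * dkx, (n_ph, n_rd)).copy()
    ky = np.broadcast_to(((p - n_ph // 2) * dky)[:, None], (n_ph, n_rd)).copy()
    t = (
        p[:, None] * esp
        + t_ramp
        + (m[None, :] + 0.5) * adc_dwell
    )
    flats = [(pp * esp + t_ramp, pp * esp + t_ramp + t_flat) for pp in p]
    return FlybackTrajectory(
        geom=geom,
        kx=kx,
        ky=ky,
        t=t,
        esp=esp,
        bw_read=1.0 / adc_dwell,
        bw_phase=1.0 / esp,
        readout_duration=n_ph * esp,
        read_grad=read_grad,
        flat_intervals=flats,
    )


# ---------------------------------------------------------------------------
# Raw data containers
# ---------------------------------------------------------------------------

@dataclass
class KSpaceFrame:
    """One metabolite-specific EPI frame of raw k-space samples."""

    samples: np.ndarray       # complex, (n_phase, n_read)
    metabolite: str
    t_acq: float              # s since injection start
    noise_sigma: float
    traj: FlybackTrajectory
    pulse: SSRFPulse | None = None


@dataclass
class SpectralGrid:
    """CSI raw data (FID per phase encode) or a single slab FID."""

    fids: np.ndarray          # complex, (n_ph, n_rd, n_points) or (n_points,)
    sw: float                 # Hz
    n_points: int
    tr: float                 # s
    flip: float               # degrees
    t_acq: float = 0.0
    geom: Geometry2D | None = None

    def __post_init__(self) -> None:
        if self.n_points < 1 or self.sw <= 0:
            raise ValueError("need n_points >= 1 and sw > 0")

    @property
    def dwell(self) -> float:
        return 1.0 / self.sw

    @property
    def freq_axis(self) -> np.ndarray:
        """Spectral axis in Hz (fftshifted, ascending)."""
        return np.fft.fftshift(np.fft.fftfreq(self.n_points, self.dwell))


@dataclass(frozen=True)
class ProtocolSchedule:
    """Dynamic imaging schedule: one pyruvate+lactate pair per interval."""

    interval: float = 3.0
    duration: float = 60.0
    flips: tuple[tuple[str, float], ...] = (("pyruvate", 20.0), ("lactate", 90.0))
    start_delay: float = 20.0

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration / self.interval))


@dataclass(frozen=True)
class CSIProtocol:
    geom: Geometry2D = Geometry2D((8, 8), (80.0, 80.0))
    flip: float = 10.0
    sw: float = 25000.0
    n_points: int = 2048
    tr: float = 0.082
    n_frames: int = 6
    noise_sigma: float = 0.0

    @property
    def excitations_per_frame(self) -> int:
        return self.geom.matrix[0] * self.geom.matrix[1]

    @property
    def frame_period(self) -> float:
        return self.excitations_per_frame * self.tr


@dataclass(frozen=True)
class SlabProtocol:
    flip: float = 5.0
    sw: float = 10000.0
    n_points: int = 2048
    noise_sigma: float = 0.0


# ---------------------------------------------------------------------------
# EPI acquisition
# ---------------------------------------------------------------------------

def excitation_weights(
    pulse: SSRFPulse,
    offsets_hz: np.ndarray,
    field: FieldParams,
    cache_range: float = 800.0,
    cache_step: float = 2.0,
) -> np.ndarray:
    """Per-voxel excitation weight from the pulse's Bloch spectral profile.

    The slice-center excitation fraction |Mxy|/sin(flip) of the baseband
    design is computed once on a dense frequency grid, cached on the
    pulse, and linearly interpolated at ``offsets_hz - center_offset``.
    """
    from .pulses import spectral_excitation_fraction

    key = "weight_curve"
    if key not in pulse.meta:
        fmax = max(cache_range, float(np.max(np.abs(offsets_hz))) + 50.0)
        grid = np.arange(-fmax, fmax + cache_step, cache_step)
        base = pulse.retuned(0.0)
        frac = spectral_excitation_fraction(base, grid, field)
        pulse.meta[key] = (grid, np.clip(frac, 0.0, 1.0))
    grid, frac = pulse.meta[key]
    rel = np.asarray(offsets_hz, dtype=float) - pulse.center_offset_hz
    if np.min(rel) < grid[0] or np.max(rel) > grid[-1]:
        del pulse.meta[key]
        return excitation_weights(
            pulse, offsets_hz, field,
            cache_range=float(np.max(np.abs(rel))) + 100.0, cache_step=cache_step,
        )
    return np.interp(rel, grid, frac)


def _voxel_coords_cm(phantom: DigitalPhantom) -> tuple[np.ndarray, np.ndarray]:
    y_mm, x_mm = phantom.coords_mm()
    return y_mm / 10.0, x_mm / 10.0


def acquire_epi_frame(
    phantom: DigitalPhantom,
    state: HPState,
    pulse: SSRFPulse,
    traj: FlybackTrajectory,
    scanner: ScannerContext,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[KSpaceFrame, HPState]:
    """One metabolite-specific excitation + flyback EPI readout.

    The excitation weight at each voxel comes from the pulse's Bloch
    profile evaluated at the voxel's metabolite + B0 offset; the readout
    accrues per-sample off-resonance phase and T2 decay.
    """
    met = pulse.metabolite
    if met is None or met not in state.mz:
        raise ValueError(f"pulse metabolite {met!r} not present in state")
    offmap = scanner.offset_map(phantom, met)
    w = excitation_weights(pulse, offmap, scanner.field)
    state2, sigmap = apply_rf_consumption(state, met, pulse.flip, w)

    ycm, xcm = _voxel_coords_cm(phantom)
    rho = sigmap.ravel().astype(complex)
    nz = rho != 0
    off = offmap.ravel()[nz]
    x = xcm.ravel()[nz]
    y = ycm.ravel()[nz]
    rho = rho[nz]
    t2 = scanner.metab[met].t2
    ks = traj.kx.ravel()
    kp = traj.ky.ravel()
    ts = traj.t.ravel()
    if rho.size:
        enc = np.exp(-2j * np.pi * (np.outer(ks, x) + np.outer(kp, y)))
        phase = np.exp((2j * np.pi * np.outer(ts, off)) - np.outer(ts, np.full_like(off, 1.0 / t2)))
        samples = (enc * phase) @ rho
    else:
        samples = np.zeros(ks.size, dtype=complex)
    samples = samples.reshape(traj.kx.shape)
    if noise_sigma > 0:
        rng = rng or np.random.default_rng()
        samples = samples + noise_sigma * (
            rng.standard_normal(samples.shape) + 1j * rng.standard_normal(samples.shape)
        )
    frame = KSpaceFrame(
        samples=samples,
        metabolite=met,
        t_acq=state.t,
        noise_sigma=noise_sigma,
        traj=traj,
        pulse=pulse,
    )
    return frame, state2


def run_dynamic_epi(
    phantom: DigitalPhantom,
    state: HPState,
    schedule: ProtocolSchedule,
    pulses: dict[str, SSRFPulse],
    traj: FlybackTrajectory,
    scanner: ScannerContext,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> tuple[list[KSpaceFrame], HPState]:
    """Alternating pyruvate/lactate dynamic EPI (pyruvate first).

    Acquires ``floor(duration/interval)`` frames per metabolite; the HP
    state evolves by half an interval between the two metabolites of a
    pair and between pairs.
    """
    rng = np.random.default_rng(seed)
    if state.t < schedule.start_delay:
        state = evolve_hp_state(state, schedule.start_delay - state.t, scanner.metab)
    frames: list[KSpaceFrame] = []
    order = [name for name, _ in schedule.flips]
    for _ in range(schedule.n_frames):
        for j, met in enumerate(order):
            frame, state = acquire_epi_frame(
                phantom, state, pulses[met], traj, scanner, noise_sigma, rng
            )
            frames.append(frame)
            state = evolve_hp_state(
                state, schedule.interval / len(order), scanner.metab
            )
    return frames, state


# ---------------------------------------------------------------------------
# CSI and slab spectroscopy
# ---------------------------------------------------------------------------

def acquire_csi(
    phantom: DigitalPhantom,
    state: HPState,
    proto: CSIProtocol,
    scanner: ScannerContext,
    t2star: float = 0.03,
    seed: int | None = None,
) -> tuple[list[SpectralGrid], HPState]:
    """Dynamic 2D chemical shift imaging with hard-pulse excitation.

    One non-selective excitation per phase encode (row-major order),
    ``Nx*Ny`` excitations per frame; every species is excited and
    consumed by cos(flip) at each excitation; the state evolves by TR
    between excitations.
    """
    rng = np.random.default_rng(seed)
    n_ph, n_rd = proto.geom.matrix
    species = list(state.mz)
    ycm, xcm = _voxel_coords_cm(phantom)
    yfrac = ycm.ravel() / (proto.geom.fov[0] / 10.0)
    xfrac = xcm.ravel() / (proto.geom.fov[1] / 10.0)
    t = np.arange(proto.n_points) / proto.sw
    kernels = {}
    for met in species:
        off = scanner.offset_map(phantom, met).ravel()
        kernels[met] = np.exp(np.outer(2j * np.pi * off - 1.0 / t2star, t))

    enc_list = []
    for py in range(n_ph):
        for px in range(n_rd):
            enc_list.append(
                np.exp(
                    -2j
                    * np.pi
                    * ((py - n_ph // 2) * yfrac + (px - n_rd // 2) * xfrac)
                )
            )

    frames = []
    for _ in range(proto.n_frames):
        t_start = state.t
        rows = {met: [] for met in species}
        for enc in enc_list:
            for met in species:
                state, sig = apply_rf_consumption(state, met, proto.flip, 1.0)
                rows[met].append(sig.ravel() * enc)
            state = evolve_hp_state(state, proto.tr, scanner.metab)
        fids = np.zeros((len(enc_list), proto.n_points), dtype=complex)
        for met in species:
            fids += np.asarray(rows[met]) @ kernels[met]
        if proto.noise_sigma > 0:
            fids += proto.noise_sigma * (
                rng.standard_normal(fids.shape) + 1j * rng.standard_normal(fids.shape)
            )
        frames.append(
            SpectralGrid(
                fids=fids.reshape(n_ph, n_rd, proto.n_points),
                sw=proto.sw,
                n_points=proto.n_points,
                tr=proto.tr,
                flip=proto.flip,
                t_acq=t_start,
                geom=proto.geom,
            )
        )
    return frames, state


def acquire_slab_spectrum(
    phantom: DigitalPhantom,
    state: HPState,
    proto: SlabProtocol,
    scanner: ScannerContext,
    slab_mask: np.ndarray | None = None,
    t2star: float = 0.03,
    seed: int | None = None,
) -> tuple[SpectralGrid, HPState]:
    """Single slab-selective low-flip spectrum (calibration pre-scan).

    Default slab: the whole object except the chest compartment (liver
    and kidneys in, heart/lungs out).  Consumption applies only inside
    the slab.
    """
    rng = np.random.default_rng(seed)
    if slab_mask is None:
        slab_mask = phantom.object_mask & ~phantom.masks["chest"]
    if not np.any(slab_mask):
        raise ValueError("slab does not intersect the phantom")
    t = np.arange(proto.n_points) / proto.sw
    fid = np.zeros(proto.n_points, dtype=complex)
    for met in list(state.mz):
        state, sig = apply_rf_consumption(
            state, met, proto.flip, slab_mask.astype(float)
        )
        amp = sig[slab_mask].ravel()
        off = scanner.offset_map(phantom, met)[slab_mask].ravel()
        if amp.size:
            fid += amp @ np.exp(np.outer(2j * np.pi * off - 1.0 / t2star, t))
    if proto.noise_sigma > 0:
        fid += proto.noise_sigma * (
            rng.standard_normal(fid.shape) + 1j * rng.standard_normal(fid.shape)
        )
    return (
        SpectralGrid(
            fids=fid, sw=proto.sw, n_points=proto.n_points, tr=1.2,
            flip=proto.flip, t_acq=state.t,
        ),
        state,
    )


# ---------------------------------------------------------------------------
# Swept-frequency profile measurement
# ---------------------------------------------------------------------------

def measure_pulse_profile(
    pulse: SSRFPulse,
    sweep_hz: float = 600.0,
    n_steps: int = 121,
    field: FieldParams | None = None,
    z_grid: np.ndarray | None = None,
    cylinder_length_cm: float = 8.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> bloch.MagnetizationProfile:
    """Emulate the swept center-frequency 1D profile measurement.

    For each center-frequency step the pulse is re-modulated and played
    (in Bloch simulation) on a long uniform 1D cylinder; the acquired
    spatial projection magnitude forms one column of the measured
    (z x f) profile.  A pulse centered ``+df`` above the carrier excites
    spins at off-resonance ``-df``, so the column for sweep step ``df``
    is stored at profile frequency ``-df`` to align with
    :func:`hpepi.bloch.simulate_profile`.
    """
    field = field or FieldParams()
    rng = np.random.default_rng(seed)
    if z_grid is None:
        z_grid = np.linspace(-3.0, 3.0, 121)
    z_grid = np.asarray(z_grid, dtype=float)
    density = (np.abs(z_grid) <= cylinder_length_cm / 2.0).astype(float)
    sweep = np.linspace(-sweep_hz, sweep_hz, n_steps)
    cols_abs = np.zeros((z_grid.size, n_steps))
    cols_mz = np.zeros((z_grid.size, n_steps))
    for j, df in enumerate(sweep):
        shifted = pulse.retuned(pulse.center_offset_hz + df)
        prof = bloch.simulate_profile(shifted, z_grid, np.array([0.0]), field)
        proj = np.abs(prof.mxy[:, 0]) * density
        if noise_sigma > 0:
            proj = np.abs(proj + noise_sigma * rng.standard_normal(proj.shape))
        # sweep +df probes spin off-resonance -df
        cols_abs[:, n_steps - 1 - j] = proj
        cols_mz[:, n_steps - 1 - j] = prof.mz[:, 0] * density
    f_axis = np.linspace(-sweep_hz, sweep_hz, n_steps)
    return bloch.MagnetizationProfile(
        z_grid=z_grid,
        f_grid=f_axis,
        mxy=cols_abs.astype(complex),
        mz=cols_mz,
        m0=1.0,
    )
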