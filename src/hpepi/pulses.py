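"""Metabolite-selective spectral-spatial RF (SSRF) pulse design.

An SSRF pulse is a train of slice-selective sub-pulses played on the
flat-tops of a flyback gradient train.  The k-th sub-pulse is weighted by
the k-th tap of a spectral FIR filter; since sub-pulses repeat every
``tau`` seconds, the spectral response of the train is the filter's
discrete-time response at sample rate ``fs = 1/tau`` (periodic in
frequency with ``fs``).  The design proceeds in four steps:

1. spatial sub-pulse + minimum-time trapezoidal gradient lobe;
2. complex least-squares spectral FIR filter with band weighting;
3. assembly onto the flyback gradient train;
4. amplitude scaling to the target flip angle by Bloch iteration.

Spectral band placement is done in aliased coordinates: stopbands beyond
the Nyquist range fold back into the fundamental period, which is a
faithful model of the physical pulse (its true response is periodic).
Ripple tolerances are specified on the *magnetization* (|Mxy| as a
fraction of full excitation) and converted to filter-domain tolerances
through the sine nonlinearity of the flip angle, which matters for the
90-degree lactate pulse: the passband tolerance relaxes (sin is flat at
90 degrees) while the stopband tolerance tightens (sin is steep at 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from . import bloch
from .core import FieldParams, MetaboliteTable, ppm_to_hz

__all__ = [
    "SSRFDesignSpec",
    "SSRFPulse",
    "InfeasibleDesignError",
    "AmplitudeLimitError",
    "design_spectral_filter",
    "design_spatial_subpulse",
    "assemble_ssrf",
    "scale_to_flip",
    "design_ssrf_pulse",
    "spectral_excitation_fraction",
]

# internal safety factor between the filter-design ripple targets and the
# magnetization-domain spec, leaving headroom for large-tip distortion
_DESIGN_MARGIN = 0.8


class InfeasibleDesignError(ValueError):
    """Raised when a pulse spec cannot be met (bands too close, etc.)."""


class AmplitudeLimitError(ValueError):
    """Raised when a design would exceed the transmit amplitude limit."""


@dataclass(frozen=True)
class SSRFDesignSpec:
    """Specification for one metabolite-selective SSRF excitation pulse.

    ``stopbands_ppm`` lists (center, half-width) pairs in ppm relative to
    the passband center.  ``slew_max`` is in G/cm/ms.
    """

    flip: float = 20.0
    pass_halfwidth_ppm: float = 0.5
    stopbands_ppm: tuple[tuple[float, float], ...] = ()
    tbw_spectral: float = 3.5
    max_ripple: float = 0.01
    slice_thickness: float = 20.0  # mm
    tbw_spatial: float = 4.0
    grad_max: float = 10.0         # G/cm
    slew_max: float = 50.0         # G/cm/ms
    dwell: float = 4.0e-6          # s
    max_duration: float = 0.025    # s

    def __post_init__(self) -> None:
        if not (0.0 < self.flip <= 180.0):
            raise ValueError("flip must be in (0, 180] degrees")
        if not (0.0 < self.max_ripple < 1.0):
            raise ValueError("max_ripple must be in (0, 1)")
        if self.pass_halfwidth_ppm <= 0:
            raise ValueError("pass_halfwidth_ppm must be positive")
        for c, h in self.stopbands_ppm:
            if abs(c) - h <= self.pass_halfwidth_ppm:
                raise ValueError(
                    f"stopband at {c} ppm overlaps the passband"
                )
        if self.slice_thickness <= 0 or self.grad_max <= 0 or self.slew_max <= 0:
            raise ValueError("slice thickness and gradient limits must be positive")


@dataclass
class SSRFPulse:
    """A designed SSRF pulse: complex RF plus synchronized gradient.

    ``rf`` in gauss, ``grad`` in G/cm, both on the ``dwell`` raster.
    ``center_offset_hz`` places the spectral passband relative to the
    scanner carrier; it is applied as a phase modulation at play time
    (see :meth:`played_rf`), so the stored baseband design is unchanged
    when the calibration stage retunes it.
    """

    rf: np.ndarray
    grad: np.ndarray
    dwell: float
    flip: float
    center_offset_hz: float = 0.0
    n_subpulses: int = 0
    metabolite: str | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rf = np.asarray(self.rf, dtype=complex)
        self.grad = np.asarray(self.grad, dtype=float)
        if self.rf.shape != self.grad.shape:
            raise ValueError("rf and grad must have equal length")

    @property
    def duration(self) -> float:
        """Total pulse width in seconds (= length x dwell)."""
        return self.rf.size * self.dwell

    @property
    def b1_peak(self) -> float:
        return float(np.max(np.abs(self.rf))) if self.rf.size else 0.0

    @property
    def times(self) -> np.ndarray:
        """Sample-center times in seconds."""
        return (np.arange(self.rf.size) + 0.5) * self.dwell

    def played_rf(self) -> np.ndarray:
        """RF as played: baseband design modulated to ``center_offset_hz``."""
        if self.center_offset_hz == 0.0:
            return self.rf
        return self.rf * np.exp(2j * np.pi * self.center_offset_hz * self.times)

    def retuned(self, center_offset_hz: float) -> "SSRFPulse":
        """Copy of the pulse with a new spectral center offset."""
        return replace(self, rf=self.rf.copy(), grad=self.grad.copy(),
                       center_offset_hz=center_offset_hz, meta=dict(self.meta))


# ---------------------------------------------------------------------------
# Gradient lobe construction
# ---------------------------------------------------------------------------

def _min_time_lobe(area: float, grad_max: float, slew_max_ms: float, dwell: float) -> np.ndarray:
    """Minimum-time trapezoid/triangle gradient lobe of a given area.

    Area in G/cm * s (signed); returns gradient samples starting and
    ending one slew step away from zero.  The discrete lobe with ``nr``
    ramp samples and ``nf`` flat samples has area amp*(nr+nf)*dwell.
    """
    if area == 0.0:
        return np.zeros(0)
    slew = slew_max_ms * 1e3  # G/cm/s
    sign = 1.0 if area > 0 else -1.0
    a = abs(area)
    # continuous-time optimum: triangle if its peak fits, else trapezoid
    peak = min(grad_max, math.sqrt(a * slew))
    nr0 = max(1, math.ceil(peak / (slew * dwell)))
    best: tuple[int, int, int, float] | None = None
    for nr in range(nr0, nr0 + 64):
        amp_cap = min(grad_max, nr * slew * dwell)
        nf = max(0, math.ceil(a / (amp_cap * dwell)) - nr)
        amp = a / ((nr + nf) * dwell)
        if amp > amp_cap * (1 + 1e-12):
            continue
        total = 2 * nr + nf
        if best is None or total < best[0]:
            best = (total, nr, nf, amp)
    if best is None:  # pragma: no cover - nr0 always admits a solution
        raise InfeasibleDesignError("gradient lobe construction did not converge")
    _, nr, nf, amp = best
    ramp_up = amp * np.arange(1, nr + 1) / nr
    flat = np.full(nf, amp)
    ramp_down = amp * np.arange(nr - 1, -1, -1) / nr
    return sign * np.concatenate([ramp_up, flat, ramp_down])


@dataclass
class SpatialSubPulse:
    """Slice-selective sub-pulse and its flyback gradient period.

    ``shape`` is the unit-peak RF envelope played during the ``nf``
    flat-top samples; one full period is ramp-up (nr), flat (nf),
    ramp-down (nr), then the rewinder lobe.
    """

    shape: np.ndarray
    grad_amp: float   # G/cm
    nr: int
    nf: int
    rewinder: np.ndarray
    dwell: float

    @property
    def period_samples(self) -> int:
        return 2 * self.nr + self.nf + self.rewinder.size

    @property
    def period(self) -> float:
        """Sub-pulse repetition time tau in seconds."""
        return self.period_samples * self.dwell

    def gradient_period(self) -> np.ndarray:
        g = np.zeros(self.period_samples)
        g[: self.nr] = self.grad_amp * np.arange(1, self.nr + 1) / self.nr
        g[self.nr : self.nr + self.nf] = self.grad_amp
        g[self.nr + self.nf : 2 * self.nr + self.nf] = (
            self.grad_amp * np.arange(self.nr - 1, -1, -1) / self.nr
        )
        g[2 * self.nr + self.nf :] = self.rewinder
        return g

    def flat_slice(self, k: int) -> slice:
        """Index range of the k-th period's RF flat-top."""
        start = k * self.period_samples + self.nr
        return slice(start, start + self.nf)


def design_spatial_subpulse(
    spec: SSRFDesignSpec,
    field: FieldParams | None = None,
    min_fs: float | None = None,
) -> SpatialSubPulse:
    """Design the windowed-sinc sub-pulse and flyback gradient period.

    The slice equation is
    ``grad_amp = tbw_spatial / (gamma * t_flat * thickness)``.

    With ``min_fs`` unset the flat-top duration minimizes the sub-pulse
    repetition period ``tau`` (maximizing the spectral sampling rate
    ``1/tau``), ties breaking toward longer flat-tops (lower peak B1).
    With ``min_fs`` set, the flat-top is instead the longest one keeping
    ``1/tau >= min_fs`` — the lowest-peak-B1 sub-pulse that preserves
    the requested spectral sampling rate.
    """
    field = field or FieldParams()
    gamma = field.gamma
    thick_cm = spec.slice_thickness / 10.0
    dwell = spec.dwell
    slew = spec.slew_max * 1e3

    nf_min = math.ceil(spec.tbw_spatial / (gamma * spec.grad_max * thick_cm) / dwell)
    nf_max = max(nf_min, int(2.0e-3 / dwell))
    candidates = []
    for nf in range(nf_min, nf_max + 1):
        t_flat = nf * dwell
        # a sub-pulse period longer than half the pulse budget cannot host
        # even a two-tap spectral filter
        if t_flat > spec.max_duration / 2.0:
            break
        g = spec.tbw_spatial / (gamma * t_flat * thick_cm)
        if g > spec.grad_max:
            continue
        nr = max(1, math.ceil(g / (slew * dwell)))
        lobe_area = g * (nr + nf) * dwell
        rew = _min_time_lobe(-lobe_area, spec.grad_max, spec.slew_max, dwell)
        period = 2 * nr + nf + rew.size
        candidates.append((period, nf, nr, g, rew))
    if not candidates:
        raise InfeasibleDesignError(
            f"slice of {spec.slice_thickness} mm unachievable under "
            f"grad_max={spec.grad_max} G/cm"
        )
    if min_fs is None:
        best = min(candidates, key=lambda c: (c[0], -c[1]))
    else:
        ok = [c for c in candidates if 1.0 / (c[0] * dwell) >= min_fs]
        if not ok:
            best = min(candidates, key=lambda c: (c[0], -c[1]))
        else:
            best = max(ok, key=lambda c: c[1])
    _, nf, nr, g, rew = best

    # Hamming-windowed sinc over the flat-top
    t = (np.arange(nf) + 0.5) / nf - 0.5          # [-0.5, 0.5)
    x = spec.tbw_spatial * t
    shape = np.sinc(x) * np.hamming(nf)
    shape /= np.max(np.abs(shape))
    return SpatialSubPulse(shape=shape, grad_amp=g, nr=nr, nf=nf, rewinder=rew, dwell=dwell)


# ---------------------------------------------------------------------------
# Spectral filter design
# ---------------------------------------------------------------------------

def _alias(f: np.ndarray | float, fs: float) -> np.ndarray | float:
    """Fold frequencies into the fundamental period (-fs/2, fs/2]."""
    return f - fs * np.round(np.asarray(f, dtype=float) / fs)


def _band_layout_hz(spec: SSRFDesignSpec, field: FieldParams, fs: float):
    """Passband/stopband edges in Hz, stop centers aliased into one period."""
    ph = ppm_to_hz(spec.pass_halfwidth_ppm, field)
    stops = []
    for c_ppm, h_ppm in spec.stopbands_ppm:
        c = ppm_to_hz(c_ppm, field)
        h = ppm_to_hz(h_ppm, field)
        span = abs(c) + h + ph  # extent of the layout from the passband center
        if span >= fs:
            raise InfeasibleDesignError(
                f"stopband at {c_ppm} ppm does not fit within one spectral "
                f"replication period ({fs:.0f} Hz)"
            )
        ca = float(_alias(c, fs))
        if abs(ca) - h <= ph:
            raise InfeasibleDesignError(
                f"stopband at {c_ppm} ppm aliases onto the passband "
                f"(period {fs:.0f} Hz)"
            )
        stops.append((ca, h, c_ppm))
    return ph, stops


def flip_ripple_targets(flip_deg: float, max_ripple: float) -> tuple[float, float]:
    """Convert magnetization-domain ripple to filter-domain tolerances.

    Returns (passband, stopband) fractional tolerances on the flip-angle
    profile such that |Mxy|/sin(flip) stays within ``max_ripple``.
    """
    th = math.radians(flip_deg)
    s = math.sin(th)
    lo = math.asin(max(0.0, (1.0 - max_ripple) * s))
    if (1.0 + max_ripple) * s >= 1.0:
        hi = math.pi - lo
    else:
        hi = math.asin((1.0 + max_ripple) * s)
    pass_tol = min(th - lo, hi - th) / th
    stop_tol = math.asin(min(1.0, max_ripple * s)) / th
    return pass_tol, stop_tol


def _envelope(shape: np.ndarray, dwell: float, f: np.ndarray) -> np.ndarray:
    """Normalized spectral envelope of the sub-pulse at frequencies f."""
    t = (np.arange(shape.size) + 0.5) * dwell
    t = t - t.mean()
    e = shape @ np.exp(-2j * np.pi * np.outer(t, f))
    return e / (np.sum(shape))


def design_spectral_filter(
    spec: SSRFDesignSpec,
    n_taps: int,
    field: FieldParams | None = None,
    sub_period: float | None = None,
    envelope_shape: np.ndarray | None = None,
    pass_tol: float | None = None,
    stop_tol: float | None = None,
    grid_per_band: int = 257,
) -> np.ndarray:
    """Weighted complex least-squares FIR design of the spectral filter.

    Taps are normalized to unit passband-center response.  The returned
    design is verified on a dense grid (``grid_per_band`` >= 64 points
    per band) by direct DTFT summation and fails loudly, naming the
    violated band, if a tolerance is exceeded.
    """
    field = field or FieldParams()
    if sub_period is None:
        sub_period = design_spatial_subpulse(spec, field).period
    fs = 1.0 / sub_period
    ph, stops = _band_layout_hz(spec, field, fs)
    if pass_tol is None or stop_tol is None:
        p, s = flip_ripple_targets(spec.flip, spec.max_ripple)
        pass_tol = pass_tol if pass_tol is not None else p * _DESIGN_MARGIN
        stop_tol = stop_tol if stop_tol is not None else s * _DESIGN_MARGIN

    if n_taps < 1:
        raise ValueError("n_taps must be >= 1")

    def response_matrix(freqs: np.ndarray) -> np.ndarray:
        k = np.arange(n_taps) - (n_taps - 1) / 2.0
        a = np.exp(-2j * np.pi * np.outer(freqs, k) * sub_period)
        if envelope_shape is not None:
            a = a * _envelope(envelope_shape, spec.dwell, freqs)[:, None]
        return a

    # design grid
    fp = np.linspace(-ph, ph, grid_per_band)
    rows = [response_matrix(fp)]
    targets = [np.ones(fp.size)]
    tols = [np.full(fp.size, pass_tol)]
    for ca, h, _ in stops:
        fstop = np.linspace(ca - h, ca + h, grid_per_band)
        rows.append(response_matrix(fstop))
        targets.append(np.zeros(fstop.size))
        tols.append(np.full(fstop.size, stop_tol))
    A = np.vstack(rows)
    d = np.concatenate(targets)
    tol = np.concatenate(tols)

    # Lawson-style iteratively reweighted least squares: reweighting by the
    # tolerance-scaled error drives the solution toward minimax ripple.
    w = 1.0 / tol
    lam = 1e-6 * np.sqrt(A.shape[0])  # tiny ridge tames don't-care regions
    ridge = lam * np.eye(n_taps)
    zeros = np.zeros(n_taps)
    taps = None
    for _ in range(40):
        Aw = np.vstack([A * w[:, None], ridge])
        dw = np.concatenate([d * w, zeros])
        new_taps, *_ = np.linalg.lstsq(Aw, dw, rcond=None)
        err = np.abs(A @ new_taps - d) / tol
        if taps is not None and np.max(np.abs(new_taps - taps)) < 1e-12:
            taps = new_taps
            break
        taps = new_taps
        w = w * np.clip(err, 0.3, 3.0)
        w *= A.shape[0] / np.sum(w)

    # normalize to exact unity at the passband center
    h0 = response_matrix(np.array([0.0]))[0] @ taps
    if abs(h0) < 1e-12:
        raise InfeasibleDesignError("degenerate filter (zero passband response)")
    taps = taps / h0

    # dense verification by direct DTFT summation
    dev_pass = np.abs(np.abs(response_matrix(fp) @ taps) - 1.0)
    if np.max(dev_pass) > pass_tol:
        raise InfeasibleDesignError(
            f"passband ripple {np.max(dev_pass):.4f} exceeds {pass_tol:.4f} "
            f"with {n_taps} taps"
        )
    for ca, h, c_ppm in stops:
        fstop = np.linspace(ca - h, ca + h, grid_per_band)
        mag = np.abs(response_matrix(fstop) @ taps)
        if np.max(mag) > stop_tol:
            raise InfeasibleDesignError(
                f"stopband at {c_ppm:+.1f} ppm: ripple {np.max(mag):.4f} "
                f"exceeds {stop_tol:.4f} with {n_taps} taps"
            )
    return taps


# ---------------------------------------------------------------------------
# Assembly and flip scaling
# ---------------------------------------------------------------------------

def assemble_ssrf(
    taps: np.ndarray,
    subpulse: SpatialSubPulse,
    spec: SSRFDesignSpec,
    field: FieldParams | None = None,
    metabolite: str | None = None,
) -> SSRFPulse:
    """Place tap-weighted sub-pulses on the flyback gradient train.

    RF is nonzero only on gradient flat-tops; rewinder segments carry no
    RF.  A final refocusing lobe returns the through-slice phase accrued
    from each flat-top center to zero.  The assembled amplitude is
    nominal (unit tap scale); use :func:`scale_to_flip` to hit a target
    flip angle.
    """
    field = field or FieldParams()
    taps = np.asarray(taps, dtype=complex)
    n = taps.size
    gper = subpulse.gradient_period()
    refocus = _min_time_lobe(
        subpulse.grad_amp * (subpulse.nf + subpulse.nr + 1) / 2.0 * subpulse.dwell,
        spec.grad_max,
        spec.slew_max,
        subpulse.dwell,
    )
    grad = np.concatenate([np.tile(gper, n), refocus])
    rf = np.zeros(grad.size, dtype=complex)
    for k in range(n):
        rf[subpulse.flat_slice(k)] = taps[k] * subpulse.shape
    pulse = SSRFPulse(
        rf=rf,
        grad=grad,
        dwell=subpulse.dwell,
        flip=spec.flip,
        n_subpulses=n,
        metabolite=metabolite,
        meta={
            "taps": taps,
            "sub_period": subpulse.period,
            "fs": 1.0 / subpulse.period,
            "grad_amp": subpulse.grad_amp,
        },
    )
    _check_hardware(pulse, spec, field)
    return pulse


def _check_hardware(pulse: SSRFPulse, spec: SSRFDesignSpec, field: FieldParams) -> None:
    if pulse.b1_peak > field.b1_max + 1e-12:
        raise AmplitudeLimitError(
            f"B1 peak {pulse.b1_peak:.3f} G exceeds limit {field.b1_max} G; "
            "consider a longer pulse (more sub-pulses or flat-top time)"
        )
    if pulse.grad.size:
        if np.max(np.abs(pulse.grad)) > spec.grad_max + 1e-9:
            raise InfeasibleDesignError("gradient amplitude limit exceeded")
        slew = np.max(np.abs(np.diff(np.concatenate([[0.0], pulse.grad, [0.0]])))) / pulse.dwell
        if slew > spec.slew_max * 1e3 * (1 + 1e-9):
            raise InfeasibleDesignError("gradient slew limit exceeded")


def scale_to_flip(
    pulse: SSRFPulse,
    flip: float,
    field: FieldParams | None = None,
    tol_deg: float = 0.05,
    max_iter: int = 20,
) -> SSRFPulse:
    """Scale RF amplitude so the Bloch-simulated on-resonance, slice-center
    flip equals ``flip`` degrees.

    Uses fixed-point iteration on the amplitude ratio, which converges in
    one step in the small-tip regime and within a few steps at 90
    degrees.  Raises :class:`AmplitudeLimitError` if the required B1
    exceeds the hardware limit.
    """
    field = field or FieldParams()
    if flip == 0.0:
        out = replace(pulse, rf=np.zeros_like(pulse.rf), flip=0.0, meta=dict(pulse.meta))
        return out
    if not (0.0 < flip <= 180.0):
        raise ValueError("target flip must be in [0, 180] degrees")

    rf = pulse.rf.copy()
    scale = 1.0
    achieved = None
    for _ in range(max_iter):
        test = replace(pulse, rf=rf * scale, meta=dict(pulse.meta))
        prof = bloch.simulate_profile(test, np.array([0.0]), np.array([0.0]), field)
        achieved = bloch.measure_flip(prof, 0.0, 0.0)
        if abs(achieved - flip) <= tol_deg:
            break
        if achieved <= 1e-6:
            # seed from the small-tip relation flip ~ gamma * integral(B1) dt
            area = np.abs(np.sum(rf)) * pulse.dwell
            scale = math.radians(flip) / (2 * np.pi * field.gamma * area)
        else:
            scale *= flip / achieved
    out = replace(pulse, rf=rf * scale, flip=flip, meta=dict(pulse.meta))
    if out.b1_peak > field.b1_max:
        raise AmplitudeLimitError(
            f"required B1 {out.b1_peak:.3f} G for {flip} degrees exceeds "
            f"limit {field.b1_max} G"
        )
    out.meta["achieved_flip"] = achieved
    return out


# ---------------------------------------------------------------------------
# Top-level design
# ---------------------------------------------------------------------------

def stopbands_for(
    metabolite: str,
    stop_targets: list[str],
    metabolites: MetaboliteTable,
    halfwidth_ppm: float = 0.5,
) -> tuple[tuple[float, float], ...]:
    """Stopband (center, half-width) ppm pairs relative to ``metabolite``."""
    own = metabolites[metabolite].shift_ppm
    return tuple(
        (metabolites[t].shift_ppm - own, halfwidth_ppm) for t in stop_targets
    )


def design_ssrf_pulse(
    spec: SSRFDesignSpec,
    field: FieldParams | None = None,
    metabolite: str | None = None,
) -> SSRFPulse:
    """Design, assemble and flip-scale an SSRF pulse meeting ``spec``.

    The number of sub-pulses is the smallest count that (a) satisfies the
    spectral time-bandwidth constraint on the sharpest transition and
    (b) meets the ripple tolerances both in the FIR design and in the
    final Bloch-simulated magnetization profile; ties break toward
    shorter pulses.
    """
    field = field or FieldParams()
    # Sub-pulse selection: the shortest period fixes the highest spectral
    # sampling rate fs_max; among rates that keep every (possibly aliased)
    # stopband at least the unaliased transition width away from the
    # passband, the longest flat-top (lowest peak B1) is preferred.
    sub0 = design_spatial_subpulse(spec, field)
    if spec.stopbands_ppm:
        ph_hz = ppm_to_hz(spec.pass_halfwidth_ppm, field)
        edges = [
            (abs(ppm_to_hz(c, field)), ppm_to_hz(h, field))
            for c, h in spec.stopbands_ppm
        ]
        t_base = min(c - h for c, h in edges) - ph_hz
        fs_floor = max(
            min(c + h + ph_hz + t_base, 2.0 * (c + h)) for c, h in edges
        )
        if fs_floor <= 1.0 / sub0.period:
            sub = design_spatial_subpulse(spec, field, min_fs=fs_floor)
        else:
            sub = sub0
    else:
        sub = sub0
    tau = sub.period
    fs = 1.0 / tau
    ph, stops = _band_layout_hz(spec, field, fs)
    if not stops:
        f_trans = fs / 2.0 - ph
    else:
        f_trans = min(abs(ca) - h for ca, h, _ in stops) - ph
    # spectral TBW sets the achievable transition edge: tbw / (2 * n * tau)
    n_min = max(2, math.ceil(spec.tbw_spectral / (2.0 * tau * (f_trans + ph))))
    n_max = int(spec.max_duration / tau)
    if n_max < n_min:
        raise InfeasibleDesignError(
            f"need at least {n_min} sub-pulses ({n_min * tau * 1e3:.1f} ms) "
            f"but max_duration allows {n_max}"
        )

    pass_tol, stop_tol = flip_ripple_targets(spec.flip, spec.max_ripple)
    f_extent = max([abs(ppm_to_hz(c, field)) + ppm_to_hz(h, field)
                    for c, h in spec.stopbands_ppm] + [ph]) + 50.0
    last_err: Exception | None = None
    for n in range(n_min, n_max + 1):
        try:
            taps = design_spectral_filter(
                spec, n, field, sub_period=tau, envelope_shape=sub.shape,
                pass_tol=pass_tol * _DESIGN_MARGIN, stop_tol=stop_tol * _DESIGN_MARGIN,
            )
            pulse = assemble_ssrf(taps, sub, spec, field, metabolite=metabolite)
            pulse = scale_to_flip(pulse, spec.flip, field)
        except (InfeasibleDesignError, AmplitudeLimitError) as err:
            last_err = err
            continue
        # final arbiter: Bloch-simulated magnetization ripple at slice center
        f_grid = np.linspace(-f_extent, f_extent, 1201)
        prof = bloch.simulate_profile(pulse, np.array([0.0]), f_grid, field)
        metrics = bloch.measure_band_metrics(
            prof,
            passband=(-ph, ph),
            stopbands=[(ppm_to_hz(c, field) - ppm_to_hz(h, field),
                        ppm_to_hz(c, field) + ppm_to_hz(h, field))
                       for c, h in spec.stopbands_ppm],
            nominal_flip=spec.flip,
            ripple_criterion=spec.max_ripple,
        )
        if metrics.pass_ripple <= spec.max_ripple and all(
            r <= spec.max_ripple for r in metrics.stop_ripple
        ):
            pulse.meta.update(
                design_ripple=float(
                    max([metrics.pass_ripple] + metrics.stop_ripple)
                ),
                pass_halfwidth_hz=metrics.pass_halfwidth_hz,
                n_taps=n,
            )
            return pulse
        last_err = InfeasibleDesignError(
            f"{n} taps: Bloch ripple pass={metrics.pass_ripple:.4f} "
            f"stop={max(metrics.stop_ripple):.4f} exceeds {spec.max_ripple}"
        )
    raise InfeasibleDesignError(
        f"no feasible design up to {n_max} sub-pulses: {last_err}"
    )


def spectral_excitation_fraction(
    pulse: SSRFPulse,
    f_grid: np.ndarray,
    field: FieldParams | None = None,
) -> np.ndarray:
    """Slice-center excitation fraction |Mxy|/sin(flip) vs frequency offset.

    Frequencies are relative to the scanner carrier; the pulse's
    ``center_offset_hz`` is accounted for by simulating the baseband
    design at ``f - center_offset_hz``.
    """
    field = field or FieldParams()
    base = pulse.retuned(0.0)
    f = np.asarray(f_grid, dtype=float) - pulse.center_offset_hz
    order = np.argsort(f)
    prof = bloch.simulate_profile(base, np.array([0.0]), f[order], field)
    frac = np.empty_like(f)
    frac[order] = np.abs(prof.mxy[0, :]) / np.sin(np.radians(pulse.flip))
    return frac
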