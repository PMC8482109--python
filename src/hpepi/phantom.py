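"""Synthetic rat-abdomen phantom and hyperpolarized magnetization dynamics.

The phantom is a 2D coronal cartoon of a rat abdomen: elliptical
compartments for liver, kidneys, chest, central vasculature, and an
external thermally-polarized urea reference vial, on a smooth random B0
off-resonance map.  Metabolite dynamics follow a unidirectional two-site
exchange model driven by a gamma-variate arterial inflow:

    dMp/dt = w(r) * inflow(t) - Mp / T1p - kpl(r) * Mp
    dMl/dt = kpl(r) * Mp - Ml / T1l

where ``w`` is a per-voxel perfusion weight and ``kpl`` the apparent
pyruvate->lactate conversion rate.  RF excitation consumes longitudinal
magnetization: a pulse of flip ``theta`` with per-voxel excitation
weight ``w`` yields transverse signal ``mz*sin(theta*w)`` and leaves
``mz*cos(theta*w)``.  The urea vial is thermal (not hyperpolarized):
its Gd-shortened T1 restores equilibrium between excitations, so its
longitudinal magnetization is treated as constant.

All parameters here are synthetic-model defaults; they emulate the
qualitative features of an in vivo experiment and are not fitted to any
animal data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import Geometry2D, MetaboliteTable, resolution

__all__ = [
    "InflowParams",
    "PhantomParams",
    "DigitalPhantom",
    "HPState",
    "build_rat_phantom",
    "initial_state",
    "gamma_variate",
    "evolve_hp_state",
    "apply_rf_consumption",
    "simulate_roi_curves",
    "fit_kpl",
]

#: per-compartment perfusion weights (fraction of the arterial inflow
#: reaching each tissue); purely synthetic
PERFUSION_WEIGHTS = {
    "vasculature": 1.0,
    "kidney_L": 0.8,
    "kidney_R": 0.8,
    "liver": 0.6,
    "chest": 0.4,
}


@dataclass(frozen=True)
class InflowParams:
    """Gamma-variate arterial input: A * (x/(a*b))**a * exp(a - x/b),
    x = t - delay; peaks at value ``amplitude`` when x = shape*scale."""

    amplitude: float = 1.0
    delay: float = 0.0
    shape: float = 3.0
    scale: float = 4.0  # peak at delay + shape*scale = 12 s


def gamma_variate(t: np.ndarray | float, p: InflowParams) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    x = np.maximum(t - p.delay, 0.0)
    xp = p.shape * p.scale
    with np.errstate(divide="ignore", invalid="ignore"):
        g = p.amplitude * (x / xp) ** p.shape * np.exp(p.shape - x / p.scale)
    return np.where(x > 0, g, 0.0)


@dataclass(frozen=True)
class PhantomParams:
    """Construction parameters for the synthetic phantom."""

    b0_rms: float = 15.0        # Hz over the body
    b0_max: float = 60.0        # Hz clip
    b0_corr_mm: float = 12.0    # correlation length of the smooth field
    chest_offset_hz: float = 60.0
    kpl_tissue: float = 0.02    # 1/s
    kpl_kidney: float = 0.05    # 1/s
    urea_signal: float = 0.2    # thermal vial amplitude, polarization units
    inflow: InflowParams = dc_field(default_factory=InflowParams)


@dataclass
class DigitalPhantom:
    """Compartment masks, B0 map and geometry of the synthetic phantom."""

    grid: Geometry2D
    masks: dict[str, np.ndarray]   # boolean, shape = grid.matrix
    b0_map: np.ndarray             # Hz, zero outside the object
    seed: int
    params: PhantomParams
    body: np.ndarray | None = None  # body outline (superset of tissue masks)

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) voxel-center coordinates in mm, origin at FOV center."""
        ny, nx = self.grid.matrix
        dy, dx = resolution(self.grid)
        y = (np.arange(ny) - ny // 2) * dy
        x = (np.arange(nx) - nx // 2) * dx
        return np.meshgrid(y, x, indexing="ij")

    @property
    def object_mask(self) -> np.ndarray:
        """Body outline plus the external reference vial."""
        m = np.zeros(self.grid.matrix, dtype=bool)
        for v in self.masks.values():
            m |= v
        if self.body is not None:
            m |= self.body
        return m


def _ellipse(yy, xx, cy, cx, ay, ax) -> np.ndarray:
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def build_rat_phantom(
    grid: Geometry2D,
    seed: int,
    params: PhantomParams | None = None,
) -> DigitalPhantom:
    """Deterministic-for-seed synthetic rat-abdomen phantom.

    Compartments are ellipses at anatomically plausible coronal
    positions (chest at the top, liver below it, kidneys flanking a
    central vascular column, urea vial outside the body at the bottom),
    made pairwise disjoint by priority carving.  The B0 map is
    bandlimited Gaussian noise scaled to ``b0_rms`` over the body,
    clipped at ``b0_max``, zero outside the object, with an extra
    constant offset over the chest.
    """
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    # fractional FOV coordinates of voxel centers in (-0.5, 0.5)
    yy, xx = np.meshgrid(
        *((np.arange(n) + 0.5) / n - 0.5 for n in grid.matrix),
        indexing="ij",
    )

    def jit(scale: float = 0.01) -> float:
        return float(rng.uniform(-scale, scale))

    body = _ellipse(yy, xx, 0.0 + jit(), 0.0 + jit(), 0.42, 0.33)
    chest = _ellipse(yy, xx, -0.30 + jit(), 0.0 + jit(), 0.12, 0.22) & body
    liver = _ellipse(yy, xx, -0.08 + jit(), -0.05 + jit(), 0.13, 0.22) & body
    kid_l = _ellipse(yy, xx, 0.16 + jit(), -0.17 + jit(), 0.09, 0.07) & body
    kid_r = _ellipse(yy, xx, 0.16 + jit(), 0.17 + jit(), 0.09, 0.07) & body
    vasc = _ellipse(yy, xx, 0.10 + jit(), 0.0 + jit(), 0.22, 0.025) & body
    vial = _ellipse(yy, xx, 0.44 + jit(0.005), 0.0 + jit(), 0.045, 0.045) & ~body

    # priority carving keeps compartments pairwise disjoint
    masks: dict[str, np.ndarray] = {}
    taken = np.zeros(grid.matrix, dtype=bool)
    for name, m in [
        ("chest", chest),
        ("liver", liver),
        ("kidney_L", kid_l),
        ("kidney_R", kid_r),
        ("vasculature", vasc),
        ("urea_vial", vial),
    ]:
        m = m & ~taken
        masks[name] = m
        taken |= m

    obj = body | vial
    dy_mm = resolution(grid)[0]
    noise = rng.standard_normal(grid.matrix)
    smooth = gaussian_filter(noise, sigma=params.b0_corr_mm / dy_mm, mode="wrap")
    rms = np.sqrt(np.mean(smooth[body] ** 2)) if np.any(body) else 1.0
    b0 = smooth / rms * params.b0_rms
    b0 = np.clip(b0, -params.b0_max, params.b0_max)
    b0[~obj] = 0.0
    b0[masks["chest"]] += params.chest_offset_hz

    return DigitalPhantom(grid=grid, masks=masks, b0_map=b0, seed=seed, params=params, body=body)


# ---------------------------------------------------------------------------
# Hyperpolarized state dynamics
# ---------------------------------------------------------------------------

@dataclass
class HPState:
    """Per-voxel, per-metabolite longitudinal magnetization.

    ``kpl`` and ``perfusion`` are per-voxel maps; ``thermal`` lists
    species whose mz is at thermal equilibrium and instantly recovered
    (the urea reference vial).
    """

    mz: dict[str, np.ndarray]
    t: float
    kpl: np.ndarray
    inflow: InflowParams
    perfusion: np.ndarray
    thermal: frozenset = frozenset({"urea"})

    def copy(self) -> "HPState":
        return replace(self, mz={k: v.copy() for k, v in self.mz.items()})

    def total(self, name: str) -> float:
        return float(np.sum(self.mz[name]))


def initial_state(phantom: DigitalPhantom, metab: MetaboliteTable) -> HPState:
    """Pre-injection state: no hyperpolarized signal, thermal urea vial."""
    shape = phantom.grid.matrix
    p = phantom.params
    kpl = np.zeros(shape)
    for name, rate in [
        ("liver", p.kpl_tissue),
        ("chest", p.kpl_tissue),
        ("kidney_L", p.kpl_kidney),
        ("kidney_R", p.kpl_kidney),
    ]:
        kpl[phantom.masks[name]] = rate
    perf = np.zeros(shape)
    for name, w in PERFUSION_WEIGHTS.items():
        perf[phantom.masks[name]] = w
    mz = {
        "pyruvate": np.zeros(shape),
        "lactate": np.zeros(shape),
    }
    if "urea" in metab:
        mz["urea"] = p.urea_signal * phantom.masks["urea_vial"].astype(float)
    return HPState(mz=mz, t=0.0, kpl=kpl, inflow=p.inflow, perfusion=perf)


def _decay_rate(t1: float) -> float:
    return 0.0 if math.isinf(t1) else 1.0 / t1


def evolve_hp_state(
    state: HPState,
    dt: float,
    metab: MetaboliteTable,
    max_substep: float = 0.25,
) -> HPState:
    """Advance the two-site exchange model by ``dt`` seconds.

    The homogeneous part (T1 decay and conversion) uses the exact
    exponential propagator of the lower-triangular system; the
    gamma-variate inflow is treated as piecewise constant over substeps
    of at most ``max_substep`` seconds (exact when inflow is zero).
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return state.copy()
    out = state.copy()
    mp = out.mz["pyruvate"]
    ml = out.mz["lactate"]
    r1p = _decay_rate(metab["pyruvate"].t1)
    r1l = _decay_rate(metab["lactate"].t1)
    a = r1p + state.kpl          # per-voxel pyruvate loss rate
    b = r1l
    n_sub = max(1, math.ceil(dt / max_substep))
    h = dt / n_sub
    ea = np.exp(-a * h)
    eb = math.exp(-b * h)
    # exact conversion kernel, with the a == b limit handled explicitly
    diff = b - a
    small = np.abs(diff) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        kern = state.kpl * (ea - eb) / np.where(small, 1.0, diff)
    kern = np.where(small, state.kpl * h * ea, kern)
    # inflow accumulation kernel: integral of e^{-a s} over the substep
    with np.errstate(divide="ignore", invalid="ignore"):
        acc = (1.0 - ea) / np.where(a > 0, a, 1.0)
    acc = np.where(a > 0, acc, h)
    t = state.t
    for _ in range(n_sub):
        i_mid = gamma_variate(t + 0.5 * h, state.inflow) * state.perfusion
        ml[...] = ml * eb + kern * mp
        mp[...] = mp * ea + i_mid * acc
        t += h
    out.t = state.t + dt
    return out


def apply_rf_consumption(
    state: HPState,
    metabolite: str,
    flip: float,
    excitation_weight: np.ndarray | float = 1.0,
) -> tuple[HPState, np.ndarray]:
    """Excite one metabolite: returns (new state, transverse signal map).

    ``excitation_weight`` is the per-voxel fraction of the nominal flip
    delivered (1 inside the slice/passband; from the Bloch profile
    elsewhere).  Signal is ``mz*sin(flip*w)``; remaining longitudinal
    magnetization is ``mz*cos(flip*w)``, except for thermal species
    which recover before the next excitation.
    """
    if metabolite not in state.mz:
        raise KeyError(f"unknown metabolite {metabolite!r}")
    if not (0.0 <= flip <= 180.0):
        raise ValueError("flip must be in [0, 180] degrees")
    w = np.clip(np.asarray(excitation_weight, dtype=float), 0.0, 1.0)
    theta = np.radians(flip) * w
    out = state.copy()
    signal = out.mz[metabolite] * np.sin(theta)
    if metabolite not in state.thermal:
        out.mz[metabolite] = out.mz[metabolite] * np.cos(theta)
    return out, signal


# ---------------------------------------------------------------------------
# Kinetic parameter recovery
# ---------------------------------------------------------------------------

def simulate_roi_curves(
    kpl: float,
    times: np.ndarray,
    metab: MetaboliteTable,
    inflow: InflowParams,
    perfusion: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free single-compartment (Mp, Ml) curves at ``times``."""
    times = np.asarray(times, dtype=float)
    state = HPState(
        mz={"pyruvate": np.zeros((1, 1)), "lactate": np.zeros((1, 1))},
        t=0.0,
        kpl=np.full((1, 1), kpl),
        inflow=inflow,
        perfusion=np.full((1, 1), perfusion),
        thermal=frozenset(),
    )
    mp, ml = [], []
    t_prev = 0.0
    for t in times:
        state = evolve_hp_state(state, t - t_prev, metab)
        mp.append(state.mz["pyruvate"][0, 0])
        ml.append(state.mz["lactate"][0, 0])
        t_prev = t
    return np.array(mp), np.array(ml)


def fit_kpl(
    times: np.ndarray,
    pyr: np.ndarray,
    lac: np.ndarray,
    metab: MetaboliteTable,
    inflow: InflowParams,
    kpl_bounds: tuple[float, float] = (1e-4, 0.5),
) -> float:
    """Least-squares estimate of the conversion rate from dynamic curves.

    Relaxation times and the inflow function are assumed known (they are
    model inputs); the free parameters are kpl and a common amplitude
    scale absorbing polarization level.
    """
    from scipy.optimize import least_squares

    times = np.asarray(times, dtype=float)
    data = np.concatenate([pyr, lac])

    def residual(log_kpl: np.ndarray) -> np.ndarray:
        mp, ml = simulate_roi_curves(float(np.exp(log_kpl[0])), times, metab, inflow)
        model = np.concatenate([mp, ml])
        denom = model @ model
        scale = (model @ data) / denom if denom > 0 else 1.0
        return scale * model - data

    res = least_squares(
        residual,
        x0=[np.log(0.03)],
        bounds=([np.log(kpl_bounds[0])], [np.log(kpl_bounds[1])]),
        method="trf",
    )
    return float(np.exp(res.x[0]))
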