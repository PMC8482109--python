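"""Virtual scanner: trajectory structure, EPI/CSI/slab acquisition
physics, magnetization ledgers and the swept profile measurement."""

import math

import numpy as np
import pytest

from hpepi import (
    CSIProtocol,
    Geometry2D,
    Metabolite,
    MetaboliteTable,
    ProtocolSchedule,
    ScannerContext,
    SlabProtocol,
    acquire_csi,
    acquire_epi_frame,
    acquire_slab_spectrum,
    build_rat_phantom,
    initial_state,
    make_flyback_trajectory,
    measure_pulse_profile,
    recon_epi_frame,
    run_dynamic_epi,
    simulate_profile,
    regrid_profile,
)
from hpepi.phantom import HPState, InflowParams


@pytest.fixture(scope="module")
def long_t2_metab():
    inf = math.inf
    return MetaboliteTable(
        [Metabolite("pyruvate", 172.0, inf, inf),
         Metabolite("lactate", 184.3, inf, inf)]
    )


def _state(shape, mz_p=0.0, mz_l=0.0):
    return HPState(
        mz={"pyruvate": np.full(shape, float(mz_p)),
            "lactate": np.full(shape, float(mz_l))},
        t=0.0,
        kpl=np.zeros(shape),
        inflow=InflowParams(amplitude=0.0),
        perfusion=np.zeros(shape),
        thermal=frozenset(),
    )


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def test_flyback_trajectory_structure(traj16, geom16):
    assert traj16.kx.shape == (16, 16)
    # dk = 1/FOV exactly, full Cartesian coverage
    assert np.allclose(np.diff(traj16.kx, axis=1), 0.125)
    assert np.allclose(np.diff(traj16.ky, axis=0), 0.125)
    assert traj16.kx[0, 8] == 0.0 and traj16.ky[8, 0] == 0.0
    assert traj16.bw_phase * traj16.esp == pytest.approx(1.0, rel=1e-12)
    assert traj16.readout_duration == pytest.approx(16 * traj16.esp)
    # every sample time falls within its line's gradient plateau
    for p in range(16):
        lo, hi = traj16.flat_intervals[p]
        assert np.all(traj16.t[p] >= lo) and np.all(traj16.t[p] <= hi)


def test_flyback_trajectory_single_point(field):
    traj = make_flyback_trajectory(Geometry2D((1, 1), (80.0, 80.0)), field)
    assert traj.kx.shape == (1, 1)
    assert traj.kx[0, 0] == 0.0 and traj.ky[0, 0] == 0.0


def test_flyback_infeasible_read_grad(geom16, field):
    with pytest.raises(ValueError):
        make_flyback_trajectory(geom16, field, grad_max=5.0, read_grad=8.0)


# ---------------------------------------------------------------------------
# EPI acquisition
# ---------------------------------------------------------------------------

def test_point_source_flat_kspace(geom16, traj16, field, long_t2_metab, unit_pulse):
    """A centered on-resonance point source gives flat-magnitude k-space."""
    phan = build_rat_phantom(geom16, 1)
    phan.b0_map[:] = 0.0
    st = _state(geom16.matrix)
    st.mz["pyruvate"][8, 8] = 1.0
    ctx = ScannerContext(field=field, metab=long_t2_metab)
    frame, _ = acquire_epi_frame(phan, st, unit_pulse("pyruvate", 90.0), traj16, ctx)
    mag = np.abs(frame.samples)
    assert np.allclose(mag, mag[0, 0], rtol=1e-9)


def test_disc_phantom_roundtrip(geom16, traj16, field, long_t2_metab, unit_pulse):
    """Noiseless on-resonance disc: recon recovers it within 5% RMS."""
    phan = build_rat_phantom(geom16, 1)
    phan.b0_map[:] = 0.0
    yy, xx = np.meshgrid(np.arange(16) - 8, np.arange(16) - 8, indexing="ij")
    disc = (yy**2 + xx**2 <= 16).astype(float)
    st = _state(geom16.matrix)
    st.mz["pyruvate"] = disc.copy()
    ctx = ScannerContext(field=field, metab=long_t2_metab)
    frame, _ = acquire_epi_frame(phan, st, unit_pulse("pyruvate", 90.0), traj16, ctx)
    img = np.abs(recon_epi_frame(frame))
    err = np.sqrt(np.mean((img - disc) ** 2)) / np.sqrt(np.mean(disc**2))
    assert err < 0.05


def test_consumption_between_frames(geom16, traj16, field, long_t2_metab, unit_pulse):
    """Pyruvate magnetization after frame k scales by cos(20 deg)^k."""
    phan = build_rat_phantom(geom16, 1)
    phan.b0_map[:] = 0.0
    st = _state(geom16.matrix, mz_p=1.0)
    ctx = ScannerContext(field=field, metab=long_t2_metab)
    pulses = {"pyruvate": unit_pulse("pyruvate", 20.0),
              "lactate": unit_pulse("lactate", 90.0)}
    sched = ProtocolSchedule(interval=3.0, duration=15.0, start_delay=0.0)
    frames, final = run_dynamic_epi(phan, st, sched, pulses, traj16, ctx)
    assert len(frames) == 10  # 5 per metabolite, pyruvate first
    assert frames[0].metabolite == "pyruvate"
    expected = math.cos(math.radians(20.0)) ** 5
    assert final.mz["pyruvate"][0, 0] == pytest.approx(expected, rel=1e-9)
    # k-space DC of successive pyruvate frames scales by sin * cos^k
    dc = [np.abs(f.samples[8, 8]) for f in frames if f.metabolite == "pyruvate"]
    ratios = np.array(dc[1:]) / np.array(dc[:-1])
    assert np.allclose(ratios, math.cos(math.radians(20.0)), rtol=1e-9)


def test_schedule_frame_counts(geom16, traj16, field, long_t2_metab, unit_pulse):
    phan = build_rat_phantom(geom16, 1)
    st = _state(geom16.matrix, mz_p=1.0)
    ctx = ScannerContext(field=field, metab=long_t2_metab)
    pulses = {"pyruvate": unit_pulse("pyruvate", 20.0),
              "lactate": unit_pulse("lactate", 90.0)}
    frames, _ = run_dynamic_epi(
        phan, st, ProtocolSchedule(interval=3.0, duration=0.0, start_delay=0.0),
        pulses, traj16, ctx,
    )
    assert frames == []


def test_epi_noise_rayleigh(geom16, traj16, field, long_t2_metab, unit_pulse):
    """Empty-object k-space magnitude follows Rayleigh statistics."""
    from scipy.stats import kstest, rayleigh

    phan = build_rat_phantom(geom16, 1)
    st = _state(geom16.matrix)  # no magnetization at all
    ctx = ScannerContext(field=field, metab=long_t2_metab)
    sigma = 0.7
    mags = []
    rng_seedseq = np.random.default_rng(123)
    for k in range(16):
        frame, _ = acquire_epi_frame(
            phan, st, unit_pulse("pyruvate", 20.0), traj16, ctx,
            noise_sigma=sigma, rng=rng_seedseq,
        )
        mags.append(np.abs(frame.samples).ravel())
    mags = np.concatenate(mags)
    assert mags.size == 4096
    stat = kstest(mags, rayleigh(scale=sigma).cdf)
    assert stat.pvalue > 0.01


# ---------------------------------------------------------------------------
# CSI and slab
# ---------------------------------------------------------------------------

def test_csi_budget_and_frame_period(field, long_t2_metab):
    """8x8 CSI: 64 excitations per frame, frame period 64*TR = 5.248 s,
    and after 6 frames RF alone leaves cos(10 deg)^384 of Mz."""
    g8 = Geometry2D((8, 8), (80.0, 80.0))
    proto = CSIProtocol(geom=g8, n_frames=6)
    assert proto.excitations_per_frame == 64
    assert proto.frame_period == pytest.approx(5.248)
    phan = build_rat_phantom(g8, 1)
    phan.b0_map[:] = 0.0
    st = _state(g8.matrix, mz_p=1.0)
    ctx = ScannerContext(field=field, metab=long_t2_metab)
    grids, final = acquire_csi(phan, st, proto, ctx)
    assert len(grids) == 6
    assert grids[0].fids.shape == (8, 8, 2048)
    expected = math.cos(math.radians(10.0)) ** 384
    assert final.mz["pyruvate"][0, 0] == pytest.approx(expected, rel=1e-9)
    assert expected == pytest.approx(0.0028, abs=2e-4)


def test_slab_spectrum_excludes_chest(field, metabolites, geom16):
    phan = build_rat_phantom(geom16, 2)
    st = initial_state(phan, metabolites)
    # signal only in the chest: the default slab must see nothing
    st.mz["pyruvate"][phan.masks["chest"]] = 1.0
    st.mz["urea"][:] = 0.0
    ctx = ScannerContext(field=field, metab=metabolites)
    spec, _ = acquire_slab_spectrum(phan, st, SlabProtocol(), ctx)
    assert np.allclose(spec.fids, 0.0)
    # spectral bin width from the protocol parameters
    assert spec.sw / spec.n_points == pytest.approx(10000 / 2048)
    assert np.diff(spec.freq_axis)[0] == pytest.approx(4.8828125)


def test_slab_spectrum_consumption_and_peak(field, metabolites, geom16):
    """In-slab magnetization loses cos(5 deg); pyruvate is the tallest
    tissue peak early after injection."""
    phan = build_rat_phantom(geom16, 2)
    phan.b0_map[:] = 0.0
    st = initial_state(phan, metabolites)
    st.mz["pyruvate"][phan.masks["liver"]] = 1.0
    st.mz["lactate"][phan.masks["liver"]] = 0.1
    before = st.mz["pyruvate"].copy()
    ctx = ScannerContext(field=field, metab=metabolites)
    spec, after = acquire_slab_spectrum(phan, st, SlabProtocol(), ctx)
    slab = phan.object_mask & ~phan.masks["chest"]
    ratio = after.mz["pyruvate"][slab & (before > 0)] / before[slab & (before > 0)]
    assert np.allclose(ratio, math.cos(math.radians(5.0)), rtol=1e-12)
    mag = np.abs(np.fft.fftshift(np.fft.fft(spec.fids)))
    peak_f = spec.freq_axis[np.argmax(mag)]
    assert abs(peak_f) < 10.0  # pyruvate sits at the carrier


def test_slab_empty_raises(field, metabolites, geom16):
    phan = build_rat_phantom(geom16, 2)
    st = initial_state(phan, metabolites)
    ctx = ScannerContext(field=field, metab=metabolites)
    with pytest.raises(ValueError):
        acquire_slab_spectrum(phan, st, SlabProtocol(), ctx,
                              slab_mask=np.zeros(geom16.matrix, dtype=bool))


# ---------------------------------------------------------------------------
# swept profile measurement
# ---------------------------------------------------------------------------

def test_zero_pulse_sweep_is_zero(field):
    from hpepi import SSRFPulse

    p = SSRFPulse(rf=np.zeros(100, dtype=complex), grad=np.zeros(100),
                  dwell=4e-6, flip=20.0)
    prof = measure_pulse_profile(p, 200.0, 11, field, z_grid=np.linspace(-2, 2, 21))
    assert np.allclose(np.abs(prof.mxy), 0.0)


def test_stopband_column_suppressed(pyruvate_pulse, field):
    """The measured profile column at the lactate offset (+623.61 Hz) is
    at most 1% of the passband amplitude."""
    z = np.linspace(-1.0, 1.0, 21)
    prof = measure_pulse_profile(pyruvate_pulse.retuned(0.0), 650.0, 66, field,
                                 z_grid=z)
    # sweep grid: 66 steps over +/-650 Hz -> step 20 Hz, 623.61 ~ column 62
    j_stop = int(np.argmin(np.abs(prof.f_grid - 623.61)))
    assert abs(prof.f_grid[j_stop] - 623.61) < 26.0
    j_pass = int(np.argmin(np.abs(prof.f_grid)))
    passband = np.max(np.abs(prof.mxy[:, j_pass]))
    assert np.max(np.abs(prof.mxy[:, j_stop])) <= 0.011 * passband
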