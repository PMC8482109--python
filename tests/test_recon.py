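"""Reconstruction: EPI FFT + displacement correction, CSI peak-height
maps, SNR normalization and ROI curve extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hpepi import (
    Geometry2D,
    Metabolite,
    MetaboliteTable,
    MetaboliteImageSeries,
    ScannerContext,
    SpectralGrid,
    apodize_fid,
    apply_chemshift_shift,
    build_rat_phantom,
    acquire_epi_frame,
    extract_roi_curves,
    recon_csi,
    recon_epi_frame,
    recon_epi_series,
    resample_mask,
)
from hpepi.scanner import KSpaceFrame
from hpepi.phantom import HPState, InflowParams


@pytest.fixture(scope="module")
def long_t2_metab():
    inf = math.inf
    return MetaboliteTable(
        [Metabolite("pyruvate", 172.0, inf, inf),
         Metabolite("lactate", 184.3, inf, inf)]
    )


def _state(shape, **mz):
    base = {"pyruvate": np.zeros(shape), "lactate": np.zeros(shape)}
    for k, v in mz.items():
        base[k] = v
    return HPState(mz=base, t=0.0, kpl=np.zeros(shape),
                   inflow=InflowParams(amplitude=0.0),
                   perfusion=np.zeros(shape), thermal=frozenset())


def test_flat_kspace_gives_centered_point(traj16):
    frame = KSpaceFrame(samples=np.ones((16, 16), dtype=complex),
                        metabolite="pyruvate", t_acq=0.0, noise_sigma=0.0,
                        traj=traj16)
    img = recon_epi_frame(frame)
    iy, ix = np.unravel_index(np.argmax(np.abs(img)), img.shape)
    assert (iy, ix) == (8, 8)
    off_center = np.abs(img).copy()
    off_center[8, 8] = 0.0
    assert np.max(off_center) < 1e-10


def test_forward_inverse_identity(traj16):
    rng = np.random.default_rng(0)
    img_true = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
    # forward transform matching the recon convention
    samples = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img_true)))
    frame = KSpaceFrame(samples=samples, metabolite="pyruvate", t_acq=0.0,
                        noise_sigma=0.0, traj=traj16)
    img = recon_epi_frame(frame)
    assert np.max(np.abs(img - img_true)) / np.max(np.abs(img_true)) < 1e-12


def test_incomplete_grid_rejected(traj16):
    bad = np.ones((16, 16), dtype=complex)
    bad[3, 4] = np.nan
    frame = KSpaceFrame(samples=bad, metabolite="pyruvate", t_acq=0.0,
                        noise_sigma=0.0, traj=traj16)
    with pytest.raises(ValueError):
        recon_epi_frame(frame)
    frame = KSpaceFrame(samples=np.ones((8, 16), dtype=complex),
                        metabolite="pyruvate", t_acq=0.0, noise_sigma=0.0,
                        traj=traj16)
    with pytest.raises(ValueError):
        recon_epi_frame(frame)


def test_shift_zero_is_identity(traj16):
    rng = np.random.default_rng(1)
    img = rng.standard_normal((16, 16)) + 0j
    out = apply_chemshift_shift(img, 0.0, traj16)
    assert np.allclose(out, img, atol=1e-14)


def test_shift_inverse_property(traj16):
    rng = np.random.default_rng(2)
    img = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
    out = apply_chemshift_shift(
        apply_chemshift_shift(img, 623.61, traj16), -623.61, traj16
    )
    assert np.max(np.abs(out - img)) < 1e-10


def test_displacement_correction_end_to_end(geom16, traj16, field, long_t2_metab, unit_pulse):
    """A source offset by the lactate-pyruvate separation is restored to
    its true position within 0.1 voxel by the fractional-bandwidth
    shift correction."""
    from scipy.ndimage import center_of_mass

    phan = build_rat_phantom(geom16, 1)
    df = 623.61
    phan.b0_map[:] = df
    st = _state(geom16.matrix)
    st.mz["pyruvate"][5, 9] = 1.0
    ctx = ScannerContext(field=field, metab=long_t2_metab)
    frame, _ = acquire_epi_frame(phan, st, unit_pulse("pyruvate", 90.0), traj16, ctx)
    img = apply_chemshift_shift(recon_epi_frame(frame), df, traj16)
    cy, cx = center_of_mass(np.abs(img) ** 2)
    assert abs(cy - 5) < 0.1 and abs(cx - 9) < 0.1


def test_epi_series_snr_units(geom16, traj16, field, long_t2_metab, unit_pulse):
    """Pure-noise reconstruction lands near the Rayleigh mean (~1.25)."""
    phan = build_rat_phantom(geom16, 1)
    st = _state(geom16.matrix)
    ctx = ScannerContext(field=field, metab=long_t2_metab)
    rng = np.random.default_rng(5)
    frames = []
    for _ in range(8):
        f, _ = acquire_epi_frame(phan, st, unit_pulse("pyruvate", 20.0), traj16,
                                 ctx, noise_sigma=0.5, rng=rng)
        f.t_acq = len(frames) * 3.0
        frames.append(f)
    series = recon_epi_series(frames)
    vals = series.images["pyruvate"].ravel()
    assert vals.size >= 1024
    assert 0.9 <= vals.mean() <= 1.5


# ---------------------------------------------------------------------------
# apodization
# ---------------------------------------------------------------------------

def test_apodize_identity_and_t0():
    rng = np.random.default_rng(3)
    fid = rng.standard_normal(256) + 1j * rng.standard_normal(256)
    assert np.array_equal(apodize_fid(fid, 0.0, 1e-4), fid)
    out = apodize_fid(fid, 12.0, 1e-4)
    assert out[0] == fid[0]
    with pytest.raises(ValueError):
        apodize_fid(fid, -1.0, 1e-4)


def test_apodize_adds_lorentzian_width():
    """A 2 Hz FWHM Lorentzian FID apodized at 12 Hz shows a 14 Hz FWHM
    spectral line, within one spectral bin."""
    sw, n = 2000.0, 16384
    t = np.arange(n) / sw
    fid = np.exp(-np.pi * 2.0 * t)     # 2 Hz FWHM Lorentzian
    # phased absorption line (real part); the magnitude-mode Lorentzian
    # is sqrt(3) broader
    spec = np.real(np.fft.fftshift(np.fft.fft(apodize_fid(fid, 12.0, 1 / sw))))
    f = np.fft.fftshift(np.fft.fftfreq(n, 1 / sw))
    half = spec >= spec.max() / 2
    fwhm = f[half][-1] - f[half][0]
    bin_width = sw / n
    assert fwhm == pytest.approx(14.0, abs=2 * bin_width + 0.2)


# ---------------------------------------------------------------------------
# CSI maps
# ---------------------------------------------------------------------------

def _lorentzian_grid(metab, field, voxel, amp, shift_name, sw=25000.0, n=2048,
                     t2=0.05, noise=0.0, seed=0):
    """Synthetic CSI raw data: one Lorentzian FID in a single voxel."""
    rng = np.random.default_rng(seed)
    g8 = Geometry2D((8, 8), (80.0, 80.0))
    f0 = (metab[shift_name].shift_ppm - 172.0) * field.f0
    t = np.arange(n) / sw
    fid = amp * np.exp((2j * np.pi * f0 - 1 / t2) * t)
    fids = np.zeros((8, 8, n), dtype=complex)
    yfrac = (voxel[0] - 4) / 8
    xfrac = (voxel[1] - 4) / 8
    for iy in range(8):
        for ix in range(8):
            enc = np.exp(-2j * np.pi * ((iy - 4) * yfrac + (ix - 4) * xfrac))
            fids[iy, ix] = fid * enc
    if noise > 0:
        fids += noise * (rng.standard_normal(fids.shape)
                         + 1j * rng.standard_normal(fids.shape))
    return [SpectralGrid(fids=fids, sw=sw, n_points=n, tr=0.082, flip=10.0,
                         t_acq=0.0, geom=g8)]


def test_csi_single_voxel_lorentzian(metabolites, field):
    """A lactate-shift Lorentzian in one voxel peaks in the lactate map at
    that voxel; the pyruvate map stays near the noise floor."""
    grids = _lorentzian_grid(metabolites, field, (2, 6), 1.0, "lactate",
                             noise=1e-4, seed=4)
    series = recon_csi(grids, 12.0, metabolites, field, 172.0,
                       species=["pyruvate", "lactate"])
    lac = series.images["lactate"][0]
    pyr = series.images["pyruvate"][0]
    assert np.unravel_index(np.argmax(lac), lac.shape) == (2, 6)
    assert pyr.max() < 0.03 * lac.max()


def test_csi_zero_input(metabolites, field):
    g8 = Geometry2D((8, 8), (80.0, 80.0))
    grids = [SpectralGrid(fids=np.zeros((8, 8, 2048), dtype=complex),
                          sw=25000.0, n_points=2048, tr=0.082, flip=10.0,
                          geom=g8)]
    series = recon_csi(grids, 12.0, metabolites, field, 172.0,
                       species=["pyruvate", "lactate"])
    assert np.all(series.images["pyruvate"] == 0)
    assert np.all(series.images["lactate"] == 0)


def test_csi_linearity(metabolites, field):
    """Peak-height maps are linear in the source amplitude to 1e-9."""
    a = _lorentzian_grid(metabolites, field, (3, 3), 1.0, "lactate")
    b = _lorentzian_grid(metabolites, field, (3, 3), 3.0, "lactate")
    sa = recon_csi(a, 12.0, metabolites, field, 172.0,
                   species=["lactate"], snr_normalize=False)
    sb = recon_csi(b, 12.0, metabolites, field, 172.0,
                   species=["lactate"], snr_normalize=False)
    assert np.allclose(sb.images["lactate"], 3.0 * sa.images["lactate"],
                       rtol=1e-9, atol=1e-12)


def test_csi_two_equal_voxels(metabolites, field):
    a = _lorentzian_grid(metabolites, field, (1, 1), 1.0, "lactate")
    b = _lorentzian_grid(metabolites, field, (6, 5), 1.0, "lactate")
    grids = [SpectralGrid(fids=a[0].fids + b[0].fids, sw=25000.0,
                          n_points=2048, tr=0.082, flip=10.0,
                          geom=a[0].geom)]
    s = recon_csi(grids, 12.0, metabolites, field, 172.0, species=["lactate"])
    img = s.images["lactate"][0]
    assert img[1, 1] == pytest.approx(img[6, 5], rel=0.01)


def test_csi_overlapping_windows_rejected(metabolites, field):
    grids = _lorentzian_grid(metabolites, field, (0, 0), 1.0, "lactate")
    with pytest.raises(ValueError):
        recon_csi(grids, 12.0, metabolites, field, 172.0,
                  window_halfwidth_ppm=3.0)


# ---------------------------------------------------------------------------
# ROI curves
# ---------------------------------------------------------------------------

def _series(images, geom):
    n_t = images.shape[0]
    return MetaboliteImageSeries(
        images={"pyruvate": images},
        timestamps={"pyruvate": np.arange(n_t) * 3.0},
        geometry=geom,
    )


def test_roi_uniform_image(geom16):
    s = _series(np.full((3, 16, 16), 2.5), geom16)
    mask = np.zeros((16, 16), dtype=bool)
    mask[4:8, 4:8] = True
    curves = extract_roi_curves(s, {"roi": mask})
    assert np.allclose(curves["roi"]["pyruvate"], 2.5)


def test_roi_partition_combines_to_global_mean(geom16):
    rng = np.random.default_rng(6)
    img = rng.random((2, 16, 16))
    s = _series(img, geom16)
    left = np.zeros((16, 16), dtype=bool)
    left[:, :10] = True
    right = ~left
    curves = extract_roi_curves(s, {"L": left, "R": right})
    combined = (
        curves["L"]["pyruvate"] * left.sum() + curves["R"]["pyruvate"] * right.sum()
    ) / 256
    assert np.allclose(combined, img.mean(axis=(1, 2)), atol=1e-12)


def test_roi_decay_rate_recovery(geom16):
    """A monoexponential ROI curve yields the generating rate within 5%."""
    rate = 1 / 12.0
    t = np.arange(20) * 3.0
    imgs = np.exp(-rate * t)[:, None, None] * np.ones((20, 16, 16))
    s = _series(imgs, geom16)
    mask = np.zeros((16, 16), dtype=bool)
    mask[2:6, 3:9] = True
    curve = extract_roi_curves(s, {"roi": mask})["roi"]["pyruvate"]
    fit = np.polyfit(t, np.log(curve), 1)
    assert -fit[0] == pytest.approx(rate, rel=0.05)


def test_roi_empty_mask_rejected(geom16):
    s = _series(np.ones((2, 16, 16)), geom16)
    with pytest.raises(ValueError):
        extract_roi_curves(s, {"roi": np.zeros((16, 16), dtype=bool)})


def test_resample_mask_blocks():
    mask = np.zeros((32, 32), dtype=bool)
    mask[8:16, 8:16] = True
    out = resample_mask(mask, (16, 16))
    assert out.shape == (16, 16)
    assert out[4:8, 4:8].all()
    assert not out[0, 0]


@settings(deadline=None, derandomize=True, max_examples=20)
@given(df=st.floats(-2000, 2000, allow_nan=False))
def test_shift_roundtrip_property(df):
    from hpepi import FieldParams, make_flyback_trajectory

    traj = make_flyback_trajectory(Geometry2D((16, 16), (80.0, 80.0)), FieldParams())
    rng = np.random.default_rng(9)
    img = rng.standard_normal((16, 16)) + 0j
    out = apply_chemshift_shift(apply_chemshift_shift(img, df, traj), -df, traj)
    assert np.max(np.abs(out - img)) < 1e-9
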