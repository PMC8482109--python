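"""PNG/HTML report: simulated-vs-measured profiles, temporally summed
metabolite maps, dynamic ROI curves, and the calibration slab spectrum.

Display-oriented interpolation (2x linear followed by nearest-neighbor
upsampling) lives only here; quantitative paths never resample.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.ndimage import zoom

__all__ = ["write_report", "display_upsample"]


def display_upsample(img: np.ndarray, nearest_factor: int = 4) -> np.ndarray:
    """2x linear then nearest-neighbor upsampling, display only."""
    lin = zoom(img, 2, order=1)
    return np.repeat(np.repeat(lin, nearest_factor, axis=0), nearest_factor, axis=1)


def _profile_panel(fig_dir: Path, result) -> Path | None:
    if not result.profiles_sim:
        return None
    names = list(result.profiles_sim)
    fig, axes = plt.subplots(len(names), 2, figsize=(9, 4 * len(names)), squeeze=False)
    for i, name in enumerate(names):
        for j, (profiles, title) in enumerate(
            [(result.profiles_sim, "simulated"), (result.profiles_meas, "measured")]
        ):
            p = profiles[name]
            ax = axes[i][j]
            im = ax.imshow(
                np.abs(p.mxy),
                extent=[p.f_grid[0], p.f_grid[-1], p.z_grid[0], p.z_grid[-1]],
                aspect="auto",
                origin="lower",
                cmap="viridis",
            )
            ax.set_title(f"{name} ({title}, RMS {100*result.profile_rms[name]:.1f}%)")
            ax.set_xlabel("frequency offset (Hz)")
            ax.set_ylabel("z (cm)")
            fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    path = fig_dir / "profiles.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _summed_maps(fig_dir: Path, result) -> Path | None:
    if result.epi_series is None:
        return None
    mets = [m for m in result.epi_series.images if m != "urea"]
    fig, axes = plt.subplots(len(mets), 2, figsize=(8, 4 * len(mets)), squeeze=False)
    for i, met in enumerate(mets):
        for j, (series, title, nn) in enumerate(
            [(result.epi_series, "EPI", 4), (result.csi_series, "CSI", 8)]
        ):
            if series is None or met not in series.images:
                continue
            ax = axes[i][j]
            summed = series.images[met].sum(axis=0)
            ax.imshow(display_upsample(summed, nn), cmap="hot")
            ax.set_title(f"{met} ({title}, summed)")
            ax.axis("off")
    fig.tight_layout()
    path = fig_dir / "summed_maps.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _curves(fig_dir: Path, result) -> Path | None:
    if result.roi_curves_epi is None:
        return None
    panels = [("EPI", result.roi_curves_epi, result.epi_series),
              ("CSI", result.roi_curves_csi, result.csi_series)]
    mets = [m for m in result.epi_series.images if m != "urea"]
    fig, axes = plt.subplots(2, len(mets), figsize=(5 * len(mets), 8), squeeze=False)
    colors = {"liver": "tab:red", "kidney_L": "tab:blue", "kidney_R": "tab:cyan"}
    for i, (title, curves, series) in enumerate(panels):
        if curves is None:
            continue
        for j, met in enumerate(mets):
            ax = axes[i][j]
            for roi, d in curves.items():
                if met in d:
                    ax.plot(series.timestamps[met], d[met],
                            color=colors.get(roi, "k"), label=roi)
            ax.set_title(f"{met} ({title})")
            ax.set_xlabel("time since injection (s)")
            ax.set_ylabel("mean ROI SNR")
            ax.legend(fontsize=8)
    fig.tight_layout()
    path = fig_dir / "roi_curves.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _spectrum(fig_dir: Path, result) -> Path | None:
    if result.slab_spectrum is None:
        return None
    spec = result.slab_spectrum
    mag = np.abs(np.fft.fftshift(np.fft.fft(np.asarray(spec.fids))))
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(spec.freq_axis, mag, lw=0.8)
    if result.calibration is not None:
        ax.axvline(result.calibration.pyruvate_freq, color="tab:red", ls="--",
                   label=f"pyruvate {result.calibration.pyruvate_freq:+.1f} Hz")
        ax.legend()
    ax.set_xlabel("offset from carrier (Hz)")
    ax.set_ylabel("|S(f)|")
    ax.set_title("calibration slab spectrum")
    fig.tight_layout()
    path = fig_dir / "slab_spectrum.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def write_report(result, report_dir: str | Path) -> Path:
    """Write PNG panels plus an index.html; returns the index path."""
    report_dir = Path(report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    sections = []
    for builder, heading in [
        (_profile_panel, "Excitation profiles: simulation vs swept measurement"),
        (_spectrum, "Center-frequency calibration"),
        (_summed_maps, "Temporally summed metabolite maps"),
        (_curves, "Dynamic ROI curves"),
    ]:
        path = builder(report_dir, result)
        if path is not None:
            sections.append((heading, path.name))
    html = ["<html><head><title>hpepi report</title></head><body>",
            "<h1>hpepi virtual experiment report</h1>"]
    for heading, fname in sections:
        html.append(f"<h2>{heading}</h2><img src='{fname}' width='900'>")
    html.append("</body></html>")
    index = report_dir / "index.html"
    index.write_text("\n".join(html))
    return index
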